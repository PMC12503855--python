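"""Functional linear models of lagged monthly weather effects.

The response in census year t is regressed on the whole lagged monthly
weather history x_{t,m}, m = 0..L, through a smooth coefficient
function s(m):

    g(E[y_t]) = beta_0 [+ gamma * t] + sum_m s(m) * x_{t,m}

with s(m) a penalized cubic B-spline (second-difference penalty,
smoothing parameter chosen by REML).  Lag m = 0 is the July census
month of year t; L = 19 reaches back to December of t-2, and L = 11
(seedling recruitment) to August of t-1, the month of seed release.
Binomial responses are annual successes/trials, Poisson responses are
annual counts with a log-exposure offset, and Gaussian responses (log
lambda_t) are plain annual values.

A weather variable is reported as acting at the lags where the
pointwise 95% CI of s(m) excludes zero, and only when the overall
smooth-term test has p < 0.01 — approximate GAM p-values run low, so
the screen is deliberately strict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from scipy.special import expit

DEFAULT_L = 19
SEEDLING_L = 11
CENSUS_MONTH = 7
GROWING_SEASON = (5, 6, 7, 8, 9)  # May-September


class FLMError(ValueError):
    pass


@dataclass
class LagDesign:
    """Lagged monthly weather matrix for a set of census years.

    ``X[i, m]`` is the weather variable at m months before the census
    month of ``years[i]``; ``calendar_months[m]`` is the calendar month
    that lag m falls in, and ``growing_mask`` marks lags in the May-
    September growing season.
    """

    years: np.ndarray
    L: int
    X: np.ndarray
    calendar_months: np.ndarray
    growing_mask: np.ndarray
    variable: str = ""
    census_month: int = CENSUS_MONTH


def build_lag_matrix(monthly: pd.DataFrame, variable: str, years,
                     L: int = DEFAULT_L,
                     census_month: int = CENSUS_MONTH) -> LagDesign:
    """Assemble the n_years x (L+1) lagged design matrix.

    ``monthly`` needs columns year, month and ``variable``.  Missing
    months raise with the full list of gaps.
    """
    years = np.asarray(sorted(years))
    series = monthly.set_index(["year", "month"])[variable]
    X = np.empty((years.size, L + 1))
    missing = []
    cal = np.empty(L + 1, dtype=int)
    for m in range(L + 1):
        total = census_month - m
        yr_off = (total - 1) // 12
        cal[m] = total - 12 * yr_off
        for i, t in enumerate(years):
            key = (int(t) + yr_off, int(cal[m]))
            if key in series.index:
                X[i, m] = series[key]
            else:
                missing.append(key)
    if missing:
        raise FLMError(f"weather coverage gaps for lags: {sorted(set(missing))}")
    grow = np.isin(cal, GROWING_SEASON)
    return LagDesign(years=years, L=L, X=X, calendar_months=cal,
                     growing_mask=grow, variable=variable,
                     census_month=census_month)


def _bspline_basis(L: int, k_basis: int | None = None) -> np.ndarray:
    """Cubic B-spline basis evaluated at integer lags 0..L."""
    if k_basis is None:
        k_basis = min(10, max(4, L // 2))
    n_interior = k_basis - 4
    knots = np.concatenate([np.zeros(4),
                            np.linspace(0, L, n_interior + 2)[1:-1],
                            np.full(4, float(L))])
    x = np.arange(L + 1, dtype=float)
    return BSpline.design_matrix(x, knots, 3).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


@dataclass
class FLMFit:
    """A fitted functional linear model.

    ``coef``/``lo95``/``hi95`` give the coefficient function s(m) and
    its pointwise 95% CI on the integer lag grid; ``p_overall`` is the
    approximate Wald test of s(m) = 0 for all m; ``edf`` the effective
    degrees of freedom of the smooth.
    """

    response: str
    variable: str
    family: str
    L: int
    intercept: float
    coef: np.ndarray
    se: np.ndarray
    lo95: np.ndarray = field(init=False)
    hi95: np.ndarray = field(init=False)
    edf: float = 0.0
    edf_total: float = 0.0
    p_overall: float = 1.0
    loglik: float = np.nan
    aic: float = np.nan
    lam: float = np.nan
    converged: bool = True
    year_trend: float | None = None
    calendar_months: np.ndarray | None = None

    def __post_init__(self):
        self.lo95 = self.coef - 1.96 * self.se
        self.hi95 = self.coef + 1.96 * self.se

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "m": np.arange(self.L + 1),
            "calendar_month": self.calendar_months,
            "estimate": self.coef, "lo95": self.lo95, "hi95": self.hi95})


def _gaussian_reml(y, C, S, pen_rank, n_unpen):
    """Profile-REML choice of the smoothing parameter for Gaussian data.

    Returns (beta, lam, phi, Vbeta_unscaled, edf_by_col)."""
    n, p = C.shape
    CtC = C.T @ C
    Cty = C.T @ y
    s_eig = np.linalg.eigvalsh(S)
    log_pdet_S = np.sum(np.log(s_eig[s_eig > 1e-10 * s_eig.max()])) \
        if s_eig.max() > 0 else 0.0

    def neg_reml(log_lam):
        # 2*l_R = -(RSS + pen)/phi - log|H| + log|lam*S|_+ - (n-Mp)*log(2*pi*phi)
        # with phi profiled out; Mp = dim of the unpenalized space
        # (parametric columns plus the penalty null space).
        lam = np.exp(log_lam)
        H = CtC + lam * S
        try:
            cho = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return 1e10
        beta = np.linalg.solve(H, Cty)
        rss = float(y @ y - 2 * beta @ Cty + beta @ CtC @ beta)
        pen = float(lam * beta @ S @ beta)
        mp = n_unpen
        phi = max((rss + pen) / max(n - mp, 1), 1e-12)
        logdet_H = 2.0 * np.sum(np.log(np.diag(cho)))
        log_pdet_lamS = pen_rank * log_lam + log_pdet_S
        two_lr = (-(rss + pen) / phi - logdet_H + log_pdet_lamS
                  - (n - mp) * np.log(2 * np.pi * phi))
        return -0.5 * two_lr

    grid = np.linspace(-8, 12, 41)
    vals = [neg_reml(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg_reml, bounds=(g0 - 1.5, g0 + 1.5),
                          method="bounded", options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    H = CtC + lam * S
    beta = np.linalg.solve(H, Cty)
    rss = float(np.sum((y - C @ beta) ** 2))
    Hinv = np.linalg.inv(H)
    edf_by_col = np.einsum("ij,ji->i", Hinv, CtC)
    phi = rss / max(n - float(edf_by_col.sum()), 1.0)
    return beta, lam, phi, Hinv, edf_by_col


def fit_flm(design: LagDesign, response, family: str, trials=None,
            exposure=None, response_name: str = "",
            year_trend: bool = False, k_basis: int | None = None,
            min_years: int = 10) -> FLMFit:
    """Fit the penalized signal regression of a response on lagged weather.

    ``response`` is per-year: successes (binomial, with ``trials``),
    counts (poisson, with ``exposure``), or values (gaussian).
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    if n != design.years.size:
        raise FLMError("response length does not match design years")
    if n < min_years:
        raise FLMError(f"need >= {min_years} response years, got {n}")
    B = _bspline_basis(design.L, k_basis)
    K = B.shape[1]
    Z = design.X @ B
    cols = [np.ones(n)]
    if year_trend:
        cols.append(design.years - design.years.mean())
    n_unpen = len(cols)
    C = np.column_stack(cols + [Z])
    p = C.shape[1]
    S = np.zeros((p, p))
    S[n_unpen:, n_unpen:] = _second_diff_penalty(K)
    pen_rank = K - 2

    if family == "gaussian":
        if np.ptp(y) < 1e-12:
            raise FLMError("response has zero variance")
        beta, lam, phi, Hinv, edf_cols = _gaussian_reml(
            y, C, S, pen_rank, n_unpen + 2)  # +2: penalty null space
        W = np.ones(n)
        eta = C @ beta
        mu = eta
        ll = float(np.sum(stats.norm.logpdf(y, mu, np.sqrt(phi))))
        converged = True
    elif family in ("binomial", "poisson"):
        if family == "binomial":
            if trials is None:
                raise FLMError("binomial family needs trials")
            trials = np.asarray(trials, dtype=float)
            if np.ptp(np.divide(y, trials, out=np.zeros_like(y),
                                where=trials > 0)) < 1e-12:
                raise FLMError("response has zero variance")
        else:
            if exposure is None:
                exposure = np.ones(n)
            exposure = np.asarray(exposure, dtype=float)
            if np.ptp(np.divide(y, exposure, out=np.zeros_like(y),
                                where=exposure > 0)) < 1e-12:
                raise FLMError("response has zero variance")
        beta, lam, Hinv, W, converged = _pirls(
            y, C, S, pen_rank, n_unpen, family, trials, exposure)
        eta = C @ beta
        if family == "binomial":
            mu = expit(eta) * trials
            var_mu = np.clip(trials * expit(eta) * (1 - expit(eta)), 1e-10, None)
            ll = float(np.sum(stats.binom.logpmf(y, trials, expit(eta))))
        else:
            mu = exposure * np.exp(eta)
            var_mu = np.clip(mu, 1e-10, None)
            ll = float(np.sum(stats.poisson.logpmf(y, mu)))
        CtWC = C.T @ (W[:, None] * C)
        edf_cols = np.einsum("ij,ji->i", Hinv, CtWC)
        # quasi-likelihood dispersion: annual counts are overdispersed
        # whenever year-level heterogeneity exceeds the weather signal.
        # Floored at 1 — apparent underdispersion in these short series
        # is sampling noise and would inflate the Wald statistic.
        pearson = float(np.sum((y - mu) ** 2 / var_mu))
        phi = max(pearson / max(n - float(edf_cols.sum()), 1.0), 1.0)
    else:
        raise FLMError(f"unknown family {family!r}")

    theta = beta[n_unpen:]
    V_theta = Hinv[n_unpen:, n_unpen:] * phi
    coef = B @ theta
    V_s = B @ V_theta @ B.T
    se = np.sqrt(np.clip(np.diag(V_s), 0.0, None))
    edf_spline = float(np.sum(edf_cols[n_unpen:]))
    edf_total = float(np.sum(edf_cols))

    p_overall = _smooth_term_pvalue(coef, V_s, edf_spline, family,
                                    n, edf_total)
    aic = -2.0 * ll + 2.0 * edf_total
    return FLMFit(response=response_name, variable=design.variable,
                  family=family, L=design.L, intercept=float(beta[0]),
                  coef=coef, se=se, edf=edf_spline, edf_total=edf_total,
                  p_overall=p_overall, loglik=ll, aic=aic, lam=lam,
                  converged=converged,
                  year_trend=float(beta[1]) if year_trend else None,
                  calendar_months=design.calendar_months)


def _pirls(y, C, S, pen_rank, n_unpen, family, trials, exposure,
           max_outer: int = 50, tol: float = 1e-8):
    """Penalized IRLS with REML smoothing-parameter updates on the
    working model (performance iteration)."""
    n = y.size
    if family == "binomial":
        p0 = np.clip((y + 0.5) / (trials + 1.0), 1e-4, 1 - 1e-4)
        eta = np.log(p0 / (1 - p0))
    else:
        mu0 = np.clip(y, 0.5, None)
        eta = np.log(mu0 / np.clip(exposure, 1e-12, None))
    beta = np.zeros(C.shape[1])
    lam = 1.0
    converged = False
    for _ in range(max_outer):
        if family == "binomial":
            mu = expit(eta)
            w = np.clip(trials * mu * (1 - mu), 1e-10, None)
            z = eta + (y - trials * mu) / w
        else:
            mu = exposure * np.exp(eta)
            w = np.clip(mu, 1e-10, None)
            z = eta + (y - mu) / w
        sw = np.sqrt(w)
        Cw = sw[:, None] * C
        zw = sw * z
        beta_new, lam, _, Hinv, _ = _gaussian_reml(
            zw, Cw, S, pen_rank, n_unpen + 2)
        eta_new = C @ beta_new
        step = np.max(np.abs(eta_new - eta)) / max(1.0, np.max(np.abs(eta_new)))
        eta, beta = eta_new, beta_new
        if step < tol:
            converged = True
            break
    if not np.all(np.isfinite(beta)):
        raise FLMError("PIRLS diverged (non-finite coefficients)")
    # final working quantities at convergence
    if family == "binomial":
        mu = expit(eta)
        w = np.clip(trials * mu * (1 - mu), 1e-10, None)
    else:
        w = np.clip(exposure * np.exp(eta), 1e-10, None)
    H = C.T @ (w[:, None] * C) + lam * S
    Hinv = np.linalg.inv(H)
    return beta, lam, Hinv, w, converged


def _smooth_term_pvalue(coef, V_s, edf, family, n, edf_total):
    """Wald test of s(m) = 0 using a rank-r pseudoinverse of the curve
    covariance, r = rounded effective degrees of freedom (the classic
    GAM approximation; conservative-leaning by construction)."""
    r = int(np.clip(np.round(edf), 1, None))
    vals, vecs = np.linalg.eigh(V_s)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    r = min(r, int(np.sum(vals > 1e-12 * max(vals.max(), 1e-300))))
    if r < 1:
        return 1.0
    proj = vecs[:, :r].T @ coef
    T = float(np.sum(proj**2 / vals[:r]))
    # the dispersion is estimated in every family (quasi-likelihood for
    # counts), so an F reference with the residual df is used throughout
    df2 = max(n - edf_total, 1.0)
    return float(stats.f.sf(T / r, r, df2))


def significant_windows(fit: FLMFit, alpha_overall: float = 0.01) -> list[dict]:
    """Maximal lag intervals where the pointwise CI excludes zero.

    Empty unless the overall smooth-term p-value clears the strict
    screen (p < ``alpha_overall``).  Each window carries its sign and
    calendar-month span.
    """
    if not fit.converged or not (fit.p_overall < alpha_overall):
        return []
    sig = (fit.lo95 > 0) | (fit.hi95 < 0)
    windows = []
    m = 0
    L = fit.L
    while m <= L:
        if not sig[m]:
            m += 1
            continue
        start = m
        sign = 1 if fit.lo95[m] > 0 else -1
        while m + 1 <= L and sig[m + 1] and (
                (fit.lo95[m + 1] > 0) == (sign == 1)):
            m += 1
        entry = {"m_start": int(start), "m_end": int(m),
                 "sign": "+" if sign == 1 else "-"}
        if fit.calendar_months is not None:
            entry["months"] = [int(fit.calendar_months[j])
                               for j in range(start, m + 1)]
        windows.append(entry)
        m += 1
    return windows


def select_lag_length(monthly: pd.DataFrame, variable: str, years,
                      response, family: str, candidates=range(7, 44),
                      trials=None, exposure=None, **kwargs
                      ) -> tuple[int, pd.DataFrame]:
    """Fit one FLM per candidate maximum lag L; choose the minimum AIC.

    Returns (chosen_L, table of L vs AIC/EDF/p)."""
    rows = []
    for L in candidates:
        try:
            design = build_lag_matrix(monthly, variable, years, L=L)
            fit = fit_flm(design, response, family, trials=trials,
                          exposure=exposure, **kwargs)
            rows.append((L, fit.aic, fit.edf, fit.p_overall, True))
        except (FLMError, np.linalg.LinAlgError):
            rows.append((L, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(rows, columns=["L", "aic", "edf", "p_overall",
                                        "converged"])
    ok = table.dropna(subset=["aic"])
    if ok.empty:
        raise FLMError("no candidate lag length produced a converged fit")
    chosen = int(ok.loc[ok["aic"].idxmin(), "L"])
    return chosen, table


def run_flm_battery(site: str, responses: dict, monthly: pd.DataFrame,
                    variables=("tanom_c", "panom_mm", "spei"),
                    alpha_overall: float = 0.01) -> tuple[pd.DataFrame, dict]:
    """Fit every (demographic parameter x weather variable) FLM.

    ``responses`` maps name -> dict with keys ``family``, ``years``,
    ``y`` and optionally ``trials``/``exposure``/``L``.  Failures
    (non-convergence, zero variance) are recorded, not raised,
    mirroring how sparse vital rates behave in practice.  Returns the
    summary table and the dict of successful fits.
    """
    rows = []
    fits = {}
    for name, spec in responses.items():
        L = spec.get("L", DEFAULT_L)
        for var in variables:
            try:
                design = build_lag_matrix(monthly, var, spec["years"], L=L)
                fit = fit_flm(design, spec["y"], spec["family"],
                              trials=spec.get("trials"),
                              exposure=spec.get("exposure"),
                              response_name=name)
                wins = significant_windows(fit, alpha_overall)
                fits[(name, var)] = fit
                rows.append((site, name, var, L, fit.edf, fit.p_overall,
                             json.dumps(wins), fit.converged))
            except (FLMError, np.linalg.LinAlgError) as err:
                rows.append((site, name, var, L, np.nan, np.nan,
                             json.dumps({"error": str(err)}), False))
    table = pd.DataFrame(rows, columns=["site", "response", "variable", "L",
                                        "edf", "p_overall", "windows",
                                        "converged"])
    return table, fits
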