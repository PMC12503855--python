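"""Random-intercept GLMMs by exact 1-D Gauss–Hermite marginal likelihood.

Annual vital rates are modelled as a fixed intercept plus a Gaussian
year effect on the link scale:

    link(p_t) = mu + b_t,   b_t ~ N(0, sigma^2)

with binomial (logit) or Poisson (log, with exposure offset) data per
year.  Because the only random effect is one scalar per year, the
marginal likelihood factorizes over years into one-dimensional
integrals, which Gauss–Hermite quadrature evaluates essentially
exactly; (mu, log sigma) are then optimized directly.  Per-year
estimates are posterior means of mu + b_t, shrunk toward the fixed
effect in proportion to each year's information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)
# rewrite for N(0,1): integral f(z) phi(z) dz = sum w_i f(sqrt(2) x_i) / sqrt(pi)
_Z = np.sqrt(2.0) * _GH_NODES
_LOGW = np.log(_GH_WEIGHTS) - 0.5 * np.log(np.pi)


class GLMMError(ValueError):
    pass


def _binom_loglik(eta, k, n):
    """log Binom(k | n, expit(eta)) up to the binomial coefficient."""
    return k * eta - n * np.logaddexp(0.0, eta)


def _pois_loglik(eta, k, log_e):
    """log Pois(k | E * exp(eta)) up to log(k!)."""
    return k * (log_e + eta) - np.exp(log_e + eta)


@dataclass
class AnnualFit:
    """Result of a year-random-effect GLMM fit.

    ``estimate`` is on the response scale (probability or per-capita
    rate); ``flag`` is "estimated", "fixed-effect-substituted" (years
    with no trials) or "degenerate" (boundary data, no likelihood fit).
    """

    years: np.ndarray
    estimate: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    flag: list
    mu: float
    sigma: float
    overall_mean: float
    family: str
    loglik: float = np.nan
    eta: np.ndarray = field(default=None)

    def as_dict(self):
        return dict(zip(self.years.tolist(), self.estimate.tolist()))


def _fit_gh(years, k, size, family):
    """Shared fitting core.

    ``size`` is trials (binomial) or exposure (poisson), per year.
    Years with size == 0 are excluded from the likelihood and get the
    fixed-effect mean afterwards.
    """
    years = np.asarray(years)
    k = np.asarray(k, dtype=float)
    size = np.asarray(size, dtype=float)
    info = size > 0
    if not info.any():
        raise GLMMError("no informative years (all trials/exposures zero)")
    ki, si = k[info], size[info]

    if family == "binomial":
        loglik = lambda eta, j: _binom_loglik(eta, ki[j], si[j])
        inv = expit
        pooled = ki.sum() / si.sum()
    elif family == "poisson":
        log_e = np.log(si)
        loglik = lambda eta, j: _pois_loglik(eta, ki[j], log_e[j])
        inv = np.exp
        pooled = ki.sum() / si.sum()
    else:
        raise GLMMError(f"unknown family {family!r}")

    # boundary data: the MLE of mu is at +-inf; report raw rates, no CI
    if ki.sum() == 0 or (family == "binomial" and (ki == si).all()):
        p = np.full(years.shape, np.nan)
        p[info] = ki / si
        p[~info] = pooled
        flags = ["degenerate" if i else "fixed-effect-substituted" for i in info]
        return AnnualFit(years=years, estimate=p, lo95=np.full_like(p, np.nan),
                         hi95=np.full_like(p, np.nan), flag=flags,
                         mu=np.inf if ki.sum() else -np.inf, sigma=0.0,
                         overall_mean=pooled, family=family)

    nyr = ki.size

    def neg_marginal(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        # per-year quadrature: shape (nyr, Q)
        etas = mu + sigma * _Z[None, :]
        per = loglik(np.broadcast_to(etas, (nyr, _Z.size)),
                     np.arange(nyr)[:, None])
        m = per.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(per - m + _LOGW[None, :]).sum(axis=1))
        return -lse.sum()

    if family == "binomial":
        mu0 = float(logit(np.clip(pooled, 1e-4, 1 - 1e-4)))
    else:
        mu0 = float(np.log(max(pooled, 1e-6)))
    best = None
    for s0 in (-1.2, 0.0):
        res = minimize(neg_marginal, x0=np.array([mu0, s0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x
    sigma = float(np.exp(log_sigma))
    if nyr == 1:
        sigma = 0.0  # single year: the random effect is unidentifiable

    # curvature of the marginal likelihood in mu (for fixed-effect SE)
    h = 1e-4
    f0 = neg_marginal(best.x)
    fp = neg_marginal(best.x + [h, 0.0])
    fm = neg_marginal(best.x - [h, 0.0])
    d2 = (fp - 2 * f0 + fm) / h**2
    var_mu = 1.0 / d2 if d2 > 1e-12 else np.inf

    # per-year posterior of b_t given (mu, sigma)
    eta_hat = np.empty(years.shape)
    var_eta = np.empty(years.shape)
    flags = []
    jmap = np.cumsum(info) - 1
    for i in range(years.size):
        if not info[i]:
            eta_hat[i] = mu
            var_eta[i] = var_mu + sigma**2
            flags.append("fixed-effect-substituted")
            continue
        j = jmap[i]
        per = loglik(mu + sigma * _Z, np.full(_Z.size, j))
        logw = per + _LOGW
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        bz = float(np.sum(w * _Z))
        bz2 = float(np.sum(w * _Z**2))
        eta_hat[i] = mu + sigma * bz
        var_eta[i] = sigma**2 * max(bz2 - bz**2, 0.0) + var_mu
        flags.append("estimated")

    se = np.sqrt(var_eta)
    fit = AnnualFit(years=years, estimate=inv(eta_hat),
                    lo95=inv(eta_hat - 1.96 * se),
                    hi95=inv(eta_hat + 1.96 * se),
                    flag=flags, mu=float(mu), sigma=sigma,
                    overall_mean=float(inv(mu)), family=family,
                    loglik=-float(best.fun), eta=eta_hat)
    return fit


def fit_annual_probability(successes, trials, years) -> AnnualFit:
    """Binomial-logit GLMM with a Gaussian year random intercept.

    Per-year probabilities are posterior means shrunk toward the fixed
    effect; years with zero trials receive the fixed-effect mean and
    are flagged ``fixed-effect-substituted``.
    """
    return _fit_gh(years, successes, trials, "binomial")


def fit_annual_rate(counts, exposures, years) -> AnnualFit:
    """Poisson-log GLMM with exposure offset and year random intercept.

    ``counts`` and ``exposures`` are per-year totals (plot-level data
    may be summed first: the year total is sufficient under a shared
    year effect).
    """
    return _fit_gh(years, counts, exposures, "poisson")
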