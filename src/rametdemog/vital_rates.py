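"""Annual vital rates from transition tables.

Each origin stage's multinomial fate distribution is decomposed into a
chain of nested binomials — survival, then flowering given survival,
then multiple-vs-single given flowering, then dormancy given
non-flowering, then multiple-vs-single given aboveground — so that
every conditional denominator is observable and the reconstructed
unconditional probabilities sum to one by construction.  Each
conditional is fitted across years with a year-random-intercept logit
GLMM; recruitment (seedlings per flowering ramet, sprouts per capita of
the taproot-owning pool) uses Poisson GLMMs with log-exposure offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rametdemog.census import FATE_STAGES, ORIGIN_STAGES, TransitionTable
from rametdemog.glmm import (AnnualFit, GLMMError, fit_annual_probability,
                             fit_annual_rate)

#: Fates each origin can take.  Seedlings cannot flower in their
#: recruitment year; inactive ramets do not re-emerge directly as
#: flowering multiple rosettes.  Both exclusions are configurable by
#: passing a different mapping.
DEFAULT_ALLOWED_FATES = {
    "Sd": ("SR", "MR", "IA", "DEAD"),
    "SR": ("SR", "MR", "SF", "MF", "IA", "DEAD"),
    "MR": ("SR", "MR", "SF", "MF", "IA", "DEAD"),
    "IA": ("SR", "MR", "SF", "IA", "DEAD"),
}

SPROUT_CLASSES = ("SR_rec", "MR_rec", "SF_rec", "MF_rec")


class VitalRateError(ValueError):
    pass


def conditional_decomposition(fate_counts: dict, allowed_fates=None) -> dict:
    """Decompose one origin-stage fate row into nested binomial steps.

    ``fate_counts`` maps fate code -> count for a single origin stage
    and year.  Returns ``{step_name: (successes, trials)}`` over the
    conditioning chain; steps whose branch is structurally absent for
    this origin are omitted.  Zero denominators are legitimate data
    (no trials that year), not errors.
    """
    allowed = tuple(allowed_fates) if allowed_fates is not None \
        else tuple(fate_counts.keys())
    n = {f: int(fate_counts.get(f, 0)) for f in FATE_STAGES}
    bad = [f for f in FATE_STAGES if n[f] > 0 and f not in allowed]
    if bad:
        raise VitalRateError(f"counts present for disallowed fates {bad}")
    total = sum(n.values())
    survivors = total - n["DEAD"]
    flowers = n["SF"] + n["MF"]
    nonflower = survivors - flowers
    above = nonflower - n["IA"]

    steps = {"survival": (survivors, total)}
    can_flower = "SF" in allowed or "MF" in allowed
    if can_flower:
        steps["flowering"] = (flowers, survivors)
    if "SF" in allowed and "MF" in allowed:
        steps["mf_given_flowering"] = (n["MF"], flowers)
    if "IA" in allowed:
        steps["ia_given_nonflowering"] = (n["IA"], nonflower)
    if "SR" in allowed and "MR" in allowed:
        steps["mr_given_aboveground"] = (n["MR"], above)
    return steps


def reconstruct_unconditional(probs: dict, allowed_fates) -> dict:
    """Map chain conditionals back to unconditional fate probabilities.

    ``probs`` maps step name -> probability (steps absent from the
    chain are treated as structurally determined).  The result sums to
    exactly 1 over ``allowed_fates`` by construction.
    """
    allowed = tuple(allowed_fates)
    p_surv = probs.get("survival", 0.0)
    can_flower = "SF" in allowed or "MF" in allowed
    p_fl = probs.get("flowering", 0.0) if can_flower else 0.0
    if "SF" in allowed and "MF" in allowed:
        p_mf = probs.get("mf_given_flowering", 0.0)
    else:
        p_mf = 1.0 if "MF" in allowed else 0.0
    p_ia = probs.get("ia_given_nonflowering", 0.0) if "IA" in allowed else 0.0
    if "SR" in allowed and "MR" in allowed:
        p_mr = probs.get("mr_given_aboveground", 0.0)
    else:
        p_mr = 1.0 if "MR" in allowed else 0.0

    out = dict.fromkeys(FATE_STAGES, 0.0)
    out["DEAD"] = 1.0 - p_surv
    out["SF"] = p_surv * p_fl * (1.0 - p_mf)
    out["MF"] = p_surv * p_fl * p_mf
    out["IA"] = p_surv * (1.0 - p_fl) * p_ia
    out["MR"] = p_surv * (1.0 - p_fl) * (1.0 - p_ia) * p_mr
    out["SR"] = p_surv * (1.0 - p_fl) * (1.0 - p_ia) * (1.0 - p_mr)
    for f in FATE_STAGES:
        if f not in allowed:
            out.pop(f)
    return out


def fit_recruitment(counts_by_year, exposures_by_year, years) -> AnnualFit:
    """Per-capita recruitment rates with a year random effect.

    ``counts_by_year`` are recruits observed at census t+1; the
    exposure is the relevant parental pool at census t (flowering
    ramets for seedlings, the SR+MR+IA taproot pool for sprouts).
    Returns per-year expected recruits per capita.
    """
    return fit_annual_rate(counts_by_year, exposures_by_year, years)


@dataclass
class SiteVitalRates:
    """All fitted annual vital rates for one site.

    ``table`` is long-form: year, parameter, estimate, lo95, hi95,
    flag.  Parameter names follow the life-cycle arrow labels:
    ``delta_<origin>`` for survival, ``<origin>_to_<fate>`` for
    unconditional transitions, ``f`` for seedlings per flowering ramet,
    ``<stage>_rec`` for per-capita sprout recruitment.
    ``conditional_fits`` and ``recruit_fits`` keep the underlying GLMM
    objects for diagnostics.
    """

    site: str
    years: np.ndarray
    table: pd.DataFrame
    allowed_fates: dict = field(default_factory=lambda: DEFAULT_ALLOWED_FATES)
    conditional_fits: dict = field(default_factory=dict)
    recruit_fits: dict = field(default_factory=dict)

    def wide(self) -> pd.DataFrame:
        """Year-by-parameter matrix of point estimates."""
        return self.table.pivot(index="year", columns="parameter",
                                values="estimate")

    def year_row(self, year: int) -> dict:
        sub = self.table[self.table["year"] == year]
        if sub.empty:
            raise VitalRateError(f"no vital rates for year {year}")
        return dict(zip(sub["parameter"], sub["estimate"]))


def assemble_vital_rates(table: TransitionTable, allowed_fates=None,
                         years=None,
                         require_all_origins: bool = False) -> SiteVitalRates:
    """Fit every arrow of the life cycle and assemble per-year rates.

    Transition years are those with tracked ramets; recruitment at
    census t+1 is attributed to year t (the parental year).  The first
    census year contributes exposures only — its "first observations"
    are the initial tagging, not recruitment.  An origin stage never
    observed gets all-zero outgoing rates flagged ``degenerate`` unless
    ``require_all_origins`` asks for a hard error.
    """
    allowed = dict(DEFAULT_ALLOWED_FATES if allowed_fates is None
                   else allowed_fates)
    counts = table.counts
    if counts.empty:
        raise VitalRateError(f"site {table.site}: no transitions to fit")
    obs_years = np.array(sorted(counts.index.get_level_values("year").unique()))
    if years is not None:
        obs_years = np.asarray(sorted(years))

    cond_fits: dict[tuple[str, str], AnnualFit] = {}
    rows = []
    for origin in ORIGIN_STAGES:
        fates = allowed.get(origin)
        if fates is None:
            continue
        succ, tri = {}, {}
        present = False
        for y in obs_years:
            if (y, origin) in counts.index:
                fc = counts.loc[(y, origin)].to_dict()
                present = True
            else:
                fc = dict.fromkeys(FATE_STAGES, 0)
            for step, (s, t) in conditional_decomposition(fc, fates).items():
                succ.setdefault(step, []).append(s)
                tri.setdefault(step, []).append(t)
        if not present:
            if require_all_origins:
                raise VitalRateError(
                    f"site {table.site}: origin stage {origin} never "
                    f"observed; arrow {origin}->* cannot be estimated")
            for y in obs_years:
                rows.append((y, f"delta_{origin}", 0.0, np.nan, np.nan,
                             "degenerate"))
                for fate in fates:
                    if fate != "DEAD":
                        rows.append((y, f"{origin}_to_{fate}", 0.0,
                                     np.nan, np.nan, "degenerate"))
            continue
        for step in succ:
            try:
                fit = fit_annual_probability(np.array(succ[step]),
                                             np.array(tri[step]), obs_years)
            except GLMMError:
                # conditioning event never occurred (zero trials in all
                # years): the branch probability is taken as zero
                nan = np.full(len(obs_years), np.nan)
                fit = AnnualFit(years=obs_years,
                                estimate=np.zeros(len(obs_years)),
                                lo95=nan, hi95=nan,
                                flag=["degenerate"] * len(obs_years),
                                mu=-np.inf, sigma=0.0, overall_mean=0.0,
                                family="binomial")
            cond_fits[(origin, step)] = fit

        for i, y in enumerate(obs_years):
            probs = {step: cond_fits[(origin, step)].estimate[i]
                     for step in succ}
            clean = {k: (0.0 if not np.isfinite(v) else float(v))
                     for k, v in probs.items()}
            uncond = reconstruct_unconditional(clean, fates)
            flags = {step: cond_fits[(origin, step)].flag[i] for step in succ}
            flag = ("fixed-effect-substituted"
                    if any(fl == "fixed-effect-substituted" for fl in flags.values())
                    else "estimated")
            rows.append((y, f"delta_{origin}", clean["survival"],
                         *_ci(cond_fits[(origin, "survival")], i), flag))
            for fate, p in uncond.items():
                if fate == "DEAD":
                    continue
                rows.append((y, f"{origin}_to_{fate}", p, np.nan, np.nan, flag))

    # recruitment: counts at t+1, exposure at t
    rec_fits: dict[str, AnnualFit] = {}
    rec = table.recruits
    first_year = int(table.exposures["year"].min())
    rec_years = obs_years  # parental years
    for cls, expo_fn in [("Sd_rec", table.flowering_at),
                         *[(c, table.sprout_pool_at) for c in SPROUT_CLASSES]]:
        cnts, expos = [], []
        for y in rec_years:
            r = rec.query("year == @y + 1 and rec_class == @cls")["n"].sum()
            cnts.append(int(r) if y + 1 > first_year else 0)
            expos.append(expo_fn(int(y)))
        name = "f" if cls == "Sd_rec" else cls
        try:
            fit = fit_annual_rate(np.array(cnts), np.array(expos), rec_years)
        except GLMMError:
            # no exposure in any year (e.g. flowering never observed):
            # the rate is unidentified; report zero, flagged
            for y in rec_years:
                rows.append((y, name, 0.0, np.nan, np.nan, "degenerate"))
            continue
        rec_fits[cls] = fit
        for i, y in enumerate(rec_years):
            est = fit.estimate[i]
            rows.append((y, name, 0.0 if not np.isfinite(est) else float(est),
                         *_ci(fit, i), fit.flag[i]))

    out = pd.DataFrame(rows, columns=["year", "parameter", "estimate",
                                      "lo95", "hi95", "flag"])
    out.insert(0, "site", table.site)
    return SiteVitalRates(site=table.site, years=obs_years, table=out,
                          allowed_fates=allowed, conditional_fits=cond_fits,
                          recruit_fits=rec_fits)


def _ci(fit: AnnualFit, i: int) -> tuple[float, float]:
    return float(fit.lo95[i]), float(fit.hi95[i])
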