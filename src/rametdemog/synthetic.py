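"""Synthetic census and weather generation with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a six-stage annual ramet life cycle (seedling, juvenile single/multiple
rosette, flowering single/multiple rosette, inactive) with monocarpic
flowering, year-to-year logit-scale heterogeneity in every conditional
vital rate, weather-linked rates through known lag kernels, Poisson
recruitment of seedlings (per flowering ramet) and anonymous taproot
sprouts (per capita of the SR+MR+IA pool), and seasonal monthly weather
with autocorrelated temperature anomalies and gamma-distributed
precipitation.  Inactive ramets emit no aboveground record, so the
observation process genuinely requires retrospective fate resolution.

Every latent transition is logged, giving downstream estimators an
exact recovery target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from rametdemog.census import CENSUS_COLUMNS, FATE_STAGES
from rametdemog.vital_rates import (DEFAULT_ALLOWED_FATES,
                                    reconstruct_unconditional)

#: Seasonal curves loosely shaped like a semiarid continental sand
#: prairie: cold winters, ~23 C July, summer-peaked precipitation.
SANDHILLS_T_MEAN = np.array([-5.0, -2.5, 2.5, 9.0, 15.0, 20.5,
                             23.5, 22.5, 17.0, 10.0, 2.0, -4.0])
SANDHILLS_PPT_MEAN = np.array([10., 13., 25., 45., 75., 80.,
                               70., 55., 40., 28., 15., 11.])


class SyntheticError(ValueError):
    pass


def _default_cond_probs():
    # baseline conditional chain probabilities at zero anomaly,
    # shaped like the field estimates: SR survival ~0.66, MR ~0.74,
    # seedling ~0.51, rare dormancy, flowering mostly single-rosette
    return {
        "Sd": {"survival": 0.51, "ia_given_nonflowering": 0.03,
               "mr_given_aboveground": 0.05},
        "SR": {"survival": 0.66, "flowering": 0.12,
               "mf_given_flowering": 0.10, "ia_given_nonflowering": 0.03,
               "mr_given_aboveground": 0.07},
        "MR": {"survival": 0.74, "flowering": 0.18,
               "mf_given_flowering": 0.30, "ia_given_nonflowering": 0.03,
               "mr_given_aboveground": 0.55},
        "IA": {"survival": 0.60, "flowering": 0.10,
               "ia_given_nonflowering": 0.05, "mr_given_aboveground": 0.20},
    }


def _default_recruit_rates():
    # per-capita rates: f = seedlings per flowering ramet; sprouts per
    # member of the SR+MR+IA taproot pool
    return {"Sd_rec": 1.5, "SR_rec": 0.45, "MR_rec": 0.030,
            "SF_rec": 0.020, "MF_rec": 0.005}


def _default_init_stages():
    return {"Sd": 4, "SR": 60, "MR": 4, "SF": 5, "MF": 1, "IA": 0}


@dataclass
class TruthParameters:
    """Ground-truth parameters of the synthetic study system.

    ``lag_kernels`` maps (rate_key, variable) to a length-(L+1) vector
    of logit/log-scale effects per unit standardized monthly anomaly;
    rate_key is (origin, step) for a conditional vital rate or
    ("rec", class) for a recruitment rate; variable is "tanom"
    (temperature) or "panom" (precipitation), both standardized by
    their generating scales.
    """

    cond_probs: dict = field(default_factory=_default_cond_probs)
    recruit_rates: dict = field(default_factory=_default_recruit_rates)
    year_sd: float = 0.4
    lag_kernels: dict = field(default_factory=dict)
    L: int = 19
    t_month_mean: np.ndarray = field(
        default_factory=lambda: SANDHILLS_T_MEAN.copy())
    ppt_month_mean: np.ndarray = field(
        default_factory=lambda: SANDHILLS_PPT_MEAN.copy())
    t_anom_sd: float = 1.8
    t_anom_rho: float = 0.35
    ppt_cv: float = 0.55
    latitude_deg: float = 42.0
    init_stages: dict = field(default_factory=_default_init_stages)
    allowed_fates: dict = field(
        default_factory=lambda: {k: tuple(v)
                                 for k, v in DEFAULT_ALLOWED_FATES.items()})

    def __post_init__(self):
        for origin, steps in self.cond_probs.items():
            for step, p in steps.items():
                if not 0.0 <= p <= 1.0:
                    raise SyntheticError(
                        f"baseline probability {origin}/{step}={p} not in [0,1]")
        for key, kern in self.lag_kernels.items():
            if len(np.atleast_1d(kern)) != self.L + 1:
                raise SyntheticError(
                    f"lag kernel {key} must have length L+1={self.L + 1}")


def gen_weather(site: str, first_year: int, last_year: int,
                truth: TruthParameters, seed) -> pd.DataFrame:
    """Monthly weather table: seasonal means plus AR(1) temperature
    anomalies and gamma-distributed precipitation.  Deterministic given
    the seed; zero anomaly scales reproduce the seasonal curves exactly.
    """
    if last_year < first_year:
        raise SyntheticError("last_year must be >= first_year")
    rng = np.random.default_rng(seed)
    n_months = (last_year - first_year + 1) * 12
    years = np.repeat(np.arange(first_year, last_year + 1), 12)
    months = np.tile(np.arange(1, 13), last_year - first_year + 1)

    tanom = np.zeros(n_months)
    if truth.t_anom_sd > 0:
        innov_sd = truth.t_anom_sd * np.sqrt(1.0 - truth.t_anom_rho**2)
        eps = rng.normal(0.0, innov_sd, size=n_months)
        tanom[0] = rng.normal(0.0, truth.t_anom_sd)
        for i in range(1, n_months):
            tanom[i] = truth.t_anom_rho * tanom[i - 1] + eps[i]
    tmean = truth.t_month_mean[months - 1] + tanom

    mu = truth.ppt_month_mean[months - 1]
    if truth.ppt_cv > 0:
        shape = 1.0 / truth.ppt_cv**2
        ppt = rng.gamma(shape, mu / shape)
    else:
        ppt = mu.copy()
    return pd.DataFrame({"site": site, "year": years, "month": months,
                         "tmean_c": tmean, "ppt_mm": ppt})


def standardized_anomalies(weather: pd.DataFrame,
                           truth: TruthParameters) -> pd.DataFrame:
    """Monthly anomalies standardized by the generating scales (the
    covariates the truth kernels act on)."""
    w = weather.sort_values(["year", "month"]).reset_index(drop=True)
    t_sd = truth.t_anom_sd if truth.t_anom_sd > 0 else 1.0
    tanom = (w["tmean_c"].to_numpy()
             - truth.t_month_mean[w["month"] - 1]) / t_sd
    mu = truth.ppt_month_mean[w["month"] - 1]
    p_sd = np.where(mu * truth.ppt_cv > 0, mu * truth.ppt_cv, 1.0)
    panom = (w["ppt_mm"].to_numpy() - mu) / p_sd
    return pd.DataFrame({"year": w["year"], "month": w["month"],
                         "tanom": tanom, "panom": panom})


def _lag_vector(anoms: pd.Series, census_year: int, L: int,
                census_month: int = 7) -> np.ndarray:
    out = np.empty(L + 1)
    for m in range(L + 1):
        total = census_month - m
        yr_off = (total - 1) // 12
        cal = total - 12 * yr_off
        out[m] = anoms[(census_year + yr_off, cal)]
    return out


@dataclass
class SyntheticTruth:
    """Hidden truth log: latent transitions, realized per-year rates."""

    params: TruthParameters
    transitions: pd.DataFrame  # year, origin, fate, n (latent, exact)
    cond_rates: pd.DataFrame   # year, origin, step, p_true
    recruit_rates: pd.DataFrame  # year, rec_class, rate_true

    def to_json(self, path) -> None:
        params = asdict(self.params)
        params["lag_kernels"] = {
            "|".join(["/".join(map(str, rk)), var]): np.asarray(k).tolist()
            for (rk, var), k in params["lag_kernels"].items()}
        payload = {
            "params": json.loads(json.dumps(params, default=_jsonify)),
            "transitions": self.transitions.to_dict(orient="list"),
            "cond_rates": self.cond_rates.to_dict(orient="list"),
            "recruit_rates": self.recruit_rates.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def gen_population(site: str, plots, first_year: int, last_year: int,
                   truth: TruthParameters, weather: pd.DataFrame,
                   seed) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a tagged-ramet census and return records plus truth log.

    Inactive years emit no record, first observations carry the
    distance/cotyledon fields the new-ramet rule needs, and recruits
    appear with fresh tags.  Weather must cover July lags back to
    ``first_year - 2``.
    """
    wyears = set(weather["year"])
    need = set(range(first_year - 2, last_year + 1))
    if not need <= wyears:
        raise SyntheticError(
            f"weather coverage insufficient: missing years {sorted(need - wyears)}")
    rng = np.random.default_rng(seed)
    anoms_df = standardized_anomalies(weather, truth)
    anoms = {
        "tanom": anoms_df.set_index(["year", "month"])["tanom"],
        "panom": anoms_df.set_index(["year", "month"])["panom"],
    }

    def kernel_effect(rate_key, year):
        eff = 0.0
        for (rk, var), kern in truth.lag_kernels.items():
            if rk == rate_key:
                x = _lag_vector(anoms[var], year, truth.L)
                eff += float(np.dot(np.asarray(kern, float), x))
        return eff

    # realized per-year rates: baseline logit + year effect + kernel effect
    years = list(range(first_year, last_year + 1))
    cond_rows, rec_rows = [], []
    cond_p: dict[tuple[int, str, str], float] = {}
    rec_r: dict[tuple[int, str], float] = {}
    for y in years:
        for origin, steps in truth.cond_probs.items():
            for step, p0 in steps.items():
                if p0 <= 0.0 or p0 >= 1.0:
                    p = p0
                else:
                    eta = (logit(p0) + rng.normal(0.0, truth.year_sd)
                           + kernel_effect((origin, step), y))
                    p = float(expit(eta))
                cond_p[(y, origin, step)] = p
                cond_rows.append((y, origin, step, p))
        for cls, r0 in truth.recruit_rates.items():
            if r0 <= 0:
                r = 0.0
            else:
                r = float(np.exp(np.log(r0) + rng.normal(0.0, truth.year_sd)
                                 + kernel_effect(("rec", cls), y)))
            rec_r[(y, cls)] = r
            rec_rows.append((y, cls, r))

    records = []
    trans_counts: dict[tuple[int, str, str], int] = {}
    next_tag = 1
    # live ramets: tag -> (plot, stage)
    population: dict[int, tuple[str, str]] = {}
    for plot in plots:
        for stage, n in truth.init_stages.items():
            for _ in range(n):
                population[next_tag] = (plot, stage)
                next_tag += 1

    first_seen: set[int] = set()
    ia_run: dict[int, int] = {}  # consecutive unobserved (IA) censuses per tag

    def emit(tag, plot, year, stage, entry_class=None):
        if stage == "IA":
            return
        if tag not in first_seen:
            first_seen.add(tag)
            if entry_class == "seedling":
                records.append((site, plot, f"T{tag}", year, stage,
                                round(float(rng.uniform(1.0, 8.0)), 1), True))
                return
            if entry_class == "sprout":
                records.append((site, plot, f"T{tag}", year, stage,
                                round(float(rng.uniform(10.5, 40.0)), 1), False))
                return
        records.append((site, plot, f"T{tag}", year, stage, np.nan, False))

    for tag, (plot, stage) in population.items():
        cls = "seedling" if stage == "Sd" else "sprout"
        emit(tag, plot, first_year, stage, entry_class=cls)

    for y in years[:-1]:
        # recruitment exposures measured at census y
        by_plot_flower = {p: 0 for p in plots}
        by_plot_pool = {p: 0 for p in plots}
        for plot, stage in population.values():
            if stage in ("SF", "MF"):
                by_plot_flower[plot] += 1
            if stage in ("SR", "MR", "IA"):
                by_plot_pool[plot] += 1

        new_population: dict[int, tuple[str, str]] = {}
        for tag, (plot, stage) in population.items():
            if stage in ("SF", "MF"):
                trans_counts[(y, stage, "DEAD")] = \
                    trans_counts.get((y, stage, "DEAD"), 0) + 1
                continue  # monocarpic: dies after flowering
            fates = truth.allowed_fates[stage]
            probs = {step: cond_p[(y, stage, step)]
                     for step in truth.cond_probs[stage]}
            fate = _draw_fate(rng, probs, fates)
            trans_counts[(y, stage, fate)] = \
                trans_counts.get((y, stage, fate), 0) + 1
            if fate == "DEAD":
                continue
            if fate == "IA":
                ia_run[tag] = ia_run.get(tag, 0) + 1
                new_population[tag] = (plot, fate)
                continue
            if ia_run.get(tag, 0) >= 3:
                # the tag sat unobserved >= 3 censuses: the field protocol
                # has written it off as dead, so its re-emergence is
                # recorded under a fresh tag as an anonymous sprout
                del ia_run[tag]
                new_population[next_tag] = (plot, fate)
                emit(next_tag, plot, y + 1, fate, entry_class="sprout")
                next_tag += 1
                continue
            ia_run.pop(tag, None)
            new_population[tag] = (plot, fate)
            emit(tag, plot, y + 1, fate)

        for plot in plots:
            n_sd = rng.poisson(rec_r[(y, "Sd_rec")] * by_plot_flower[plot])
            for _ in range(n_sd):
                new_population[next_tag] = (plot, "Sd")
                emit(next_tag, plot, y + 1, "Sd", entry_class="seedling")
                next_tag += 1
            for cls in ("SR_rec", "MR_rec", "SF_rec", "MF_rec"):
                n_new = rng.poisson(rec_r[(y, cls)] * by_plot_pool[plot])
                for _ in range(n_new):
                    new_population[next_tag] = (plot, cls[:2])
                    emit(next_tag, plot, y + 1, cls[:2], entry_class="sprout")
                    next_tag += 1
        population = new_population

    records_df = pd.DataFrame(records, columns=CENSUS_COLUMNS)
    records_df = records_df.sort_values(["plot", "tag_id", "year"],
                                        kind="stable").reset_index(drop=True)
    trans_df = pd.DataFrame(
        [(y, o, f, n) for (y, o, f), n in sorted(trans_counts.items())],
        columns=["year", "origin", "fate", "n"])
    truth_log = SyntheticTruth(
        params=truth,
        transitions=trans_df,
        cond_rates=pd.DataFrame(cond_rows,
                                columns=["year", "origin", "step", "p_true"]),
        recruit_rates=pd.DataFrame(rec_rows,
                                   columns=["year", "rec_class", "rate_true"]))
    return records_df, truth_log


def _draw_fate(rng, cond_probs: dict, allowed_fates) -> str:
    uncond = reconstruct_unconditional(cond_probs, allowed_fates)
    fates = [f for f in FATE_STAGES if f in uncond]
    p = np.array([uncond[f] for f in fates])
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return fates[rng.choice(len(fates), p=p)]


def true_unconditional(truth_log: SyntheticTruth, year: int,
                       origin: str) -> dict:
    """Ground-truth unconditional fate probabilities for one origin-year."""
    sub = truth_log.cond_rates.query("year == @year and origin == @origin")
    probs = dict(zip(sub["step"], sub["p_true"]))
    return reconstruct_unconditional(probs,
                                     truth_log.params.allowed_fates[origin])
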