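"""Drought indexing: Thornthwaite PET, water balance, and SPEI.

The standardized precipitation–evapotranspiration index (SPEI) measures
how unusual a month's climatic water balance D = PPT − PET is relative
to a fixed reference period.  For each calendar month a three-parameter
log-logistic distribution is fitted to the reference-period D values by
unbiased probability-weighted moments; the SPEI of any D is then the
standard-normal quantile of the fitted CDF, so 0 is normal, positive is
wetter than the reference norm and negative is drier.

Potential evapotranspiration follows the classic Thornthwaite monthly
formula with an annual heat index and a day-length correction from
solar geometry at the site latitude.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

REFERENCE_PERIOD = (1950, 1989)

#: Day-of-year of the middle of each month (non-leap), for solar declination.
_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_DAYS_IN_MONTH = np.array([calendar.monthrange(2001, m)[1] for m in range(1, 13)])


class WeatherError(ValueError):
    """Raised for malformed weather inputs or degenerate reference data."""


def day_length_hours(latitude_deg: float) -> np.ndarray:
    """Mean day length (hours) per calendar month at a given latitude."""
    if not -90.0 <= latitude_deg <= 90.0:
        raise WeatherError(f"latitude {latitude_deg} outside [-90, 90]")
    phi = np.deg2rad(latitude_deg)
    decl = 0.409 * np.sin(2.0 * np.pi / 365.0 * _MID_MONTH_DOY - 1.39)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 / np.pi * omega


def thornthwaite_pet(tmean_c: np.ndarray, latitude_deg: float) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) from monthly mean temperature.

    ``tmean_c`` is a length-12k array of consecutive monthly means
    starting in January; the heat index is computed per calendar year.
    Months with T <= 0 °C evaporate nothing; 0 < T < 26.5 °C uses the
    exponential Thornthwaite formula; T >= 26.5 °C uses the standard
    polynomial branch.  The result is scaled by day length and month
    length (the "K" correction).
    """
    t = np.asarray(tmean_c, dtype=float)
    if t.ndim != 1 or t.size == 0 or t.size % 12:
        raise WeatherError("temperature series must be whole calendar years "
                           "(length a positive multiple of 12)")
    n_years = t.size // 12
    tm = t.reshape(n_years, 12)
    tp = np.clip(tm, 0.0, None)
    heat_index = np.sum((tp / 5.0) ** 1.514, axis=1, where=tp > 0, initial=0.0)
    heat_index = np.maximum(heat_index, 1e-9)
    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index + 0.49239)
    pet = np.zeros_like(tm)
    mild = (tm > 0) & (tm < 26.5)
    hot = tm >= 26.5
    ratio = np.where(mild, 10.0 * tm / heat_index[:, None], 0.0)
    pet[mild] = (16.0 * ratio ** a[:, None])[mild]
    pet[hot] = (-415.85 + 32.24 * tm - 0.43 * tm**2)[hot]
    k = (day_length_hours(latitude_deg) / 12.0) * (_DAYS_IN_MONTH / 30.0)
    return (pet * k[None, :]).ravel()


def water_balance(ppt_mm, pet_mm):
    """Climatic water balance D = PPT − PET, elementwise."""
    if isinstance(ppt_mm, pd.Series) and isinstance(pet_mm, pd.Series):
        if not ppt_mm.index.equals(pet_mm.index):
            raise WeatherError("PPT and PET series have misaligned indices")
        return ppt_mm - pet_mm
    ppt = np.asarray(ppt_mm, dtype=float)
    pet = np.asarray(pet_mm, dtype=float)
    if ppt.shape != pet.shape:
        raise WeatherError("PPT and PET series have different shapes")
    return ppt - pet


def _unbiased_pwm(x: np.ndarray, r: int) -> float:
    """Unbiased estimator of the probability-weighted moment
    w_r = E[X (1-F(X))^r] (Hosking), from the ascending order statistics."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    i = np.arange(1, n + 1)
    if r == 0:
        w = np.ones(n)
    else:
        num = np.ones(n)
        den = 1.0
        for j in range(r):
            num *= (n - i - j)
            den *= (n - 1.0 - j)
        w = num / den
    return float(np.mean(w * x))


def fit_loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the log-logistic (generalized logistic) family by unbiased PWMs.

    Uses the generalized-logistic parameterization (location xi, scale
    alpha, shape kappa), whose L-moment estimators are stable for
    either skew sign; kappa < 0 is exactly the 3-parameter log-logistic
    with shape beta = -1/kappa.  Returns (xi, alpha, kappa).
    """
    w0 = _unbiased_pwm(x, 0)
    w1 = _unbiased_pwm(x, 1)
    w2 = _unbiased_pwm(x, 2)
    l1 = w0
    l2 = w0 - 2.0 * w1
    l3 = w0 - 6.0 * w1 + 6.0 * w2
    if abs(l2) < 1e-12:
        raise WeatherError("degenerate sample: zero L-scale")
    t3 = l3 / l2
    kappa = -t3
    if abs(kappa) < 1e-8:
        return float(l1), float(l2), 0.0
    gg = gamma_fn(1.0 + kappa) * gamma_fn(1.0 - kappa)
    alpha = l2 / gg
    xi = l1 - alpha * (1.0 - gg) / kappa
    return float(xi), float(alpha), float(kappa)


def loglogistic_cdf(x, xi: float, alpha: float, kappa: float):
    """CDF of the generalized-logistic / log-logistic family."""
    x = np.asarray(x, dtype=float)
    if abs(kappa) < 1e-8:
        y = (x - xi) / alpha
    else:
        arg = 1.0 - kappa * (x - xi) / alpha
        # beyond the support bound the CDF saturates at 0 or 1
        y = np.where(arg > 1e-12, -np.log(np.clip(arg, 1e-12, None)) / kappa,
                     np.sign(kappa) * np.inf)
    return 1.0 / (1.0 + np.exp(-y))


def spei(d: pd.Series, reference: tuple[int, int] = REFERENCE_PERIOD,
         k: int = 1) -> pd.DataFrame:
    """Standardize a monthly water-balance series against a reference period.

    ``d`` must be indexed by a MultiIndex (year, month).  The series is
    first aggregated to rolling k-month sums (k=1 leaves it unchanged),
    then, per calendar month, a log-logistic distribution fitted to the
    reference-period values maps each aggregate through Phi^-1(F(.)).

    Returns a DataFrame with columns year, month, D_mm (the k-month
    aggregate), spei.
    """
    if k < 1:
        raise WeatherError("aggregation timescale k must be >= 1")
    d = d.sort_index()
    years = d.index.get_level_values(0).to_numpy()
    months = d.index.get_level_values(1).to_numpy()
    vals = d.to_numpy(dtype=float)
    # rolling k-month sum ending at each month
    agg = np.full_like(vals, np.nan)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    agg[k - 1:] = csum[k:] - csum[:-k]

    ref_lo, ref_hi = reference
    in_ref = (years >= ref_lo) & (years <= ref_hi)
    if not in_ref.any():
        raise WeatherError("reference period absent from the series")
    out = np.full_like(vals, np.nan)
    for m in range(1, 13):
        sel_ref = in_ref & (months == m) & np.isfinite(agg)
        ref_vals = agg[sel_ref]
        # the first k-1 months of the series have no k-month aggregate,
        # so allow that boundary loss but nothing more
        need = (ref_hi - ref_lo + 1) - (1 + (k - 1) // 12)
        if ref_vals.size < max(need, 10):
            raise WeatherError(
                f"reference period incomplete for calendar month {m}")
        if np.ptp(ref_vals) < 1e-9:
            raise WeatherError(
                f"constant reference water balance for calendar month {m}")
        xi, alpha, kappa = fit_loglogistic_pwm(ref_vals)
        sel = (months == m) & np.isfinite(agg)
        f = loglogistic_cdf(agg[sel], xi, alpha, kappa)
        out[sel] = norm.ppf(np.clip(f, 1e-8, 1.0 - 1e-8))
    return pd.DataFrame({"year": years, "month": months,
                         "D_mm": agg, "spei": out})


#: Census-year SPEI window: June of t-1 through July of t, inclusive.
ANNUAL_WINDOW_MONTHS = 14


def annual_mean_spei(spei_df: pd.DataFrame, census_year: int) -> float:
    """Mean 1-month SPEI from June of t−1 through July of census year t.

    The sign of this 14-month mean classifies the census year: positive
    (or exactly zero) is a non-drought year, negative a drought year.
    """
    want = ([(census_year - 1, m) for m in range(6, 13)]
            + [(census_year, m) for m in range(1, 8)])
    idx = spei_df.set_index(["year", "month"])["spei"]
    missing = [ym for ym in want if ym not in idx.index or not np.isfinite(idx[ym])]
    if missing:
        raise WeatherError(f"missing SPEI months for census year "
                           f"{census_year}: {missing}")
    return float(np.mean([idx[ym] for ym in want]))


def is_drought_year(mean_spei: float) -> bool:
    """Drought iff the annual mean SPEI is strictly negative (ties: non-drought)."""
    return mean_spei < 0.0


def anomaly(annual_values: pd.Series, baseline_years: tuple[int, int]
            = REFERENCE_PERIOD) -> pd.Series:
    """Annual deviation from the baseline-period mean (same units as input)."""
    lo, hi = baseline_years
    base = annual_values[(annual_values.index >= lo) & (annual_values.index <= hi)]
    if base.empty:
        raise WeatherError("baseline period absent from the annual series")
    return annual_values - base.mean()


def monthly_anomalies(weather: pd.DataFrame,
                      baseline_years: tuple[int, int] = REFERENCE_PERIOD
                      ) -> pd.DataFrame:
    """Per-month deviations of temperature and precipitation from the
    baseline-period monthly means, for one site's weather table."""
    lo, hi = baseline_years
    base = weather[(weather["year"] >= lo) & (weather["year"] <= hi)]
    if base.empty:
        raise WeatherError("baseline period absent from the weather table")
    clim = base.groupby("month")[["tmean_c", "ppt_mm"]].mean()
    out = weather.copy()
    out["tanom_c"] = out["tmean_c"] - out["month"].map(clim["tmean_c"])
    out["panom_mm"] = out["ppt_mm"] - out["month"].map(clim["ppt_mm"])
    return out


def site_spei(weather: pd.DataFrame, latitude_deg: float,
              reference: tuple[int, int] = REFERENCE_PERIOD,
              k: int = 1) -> pd.DataFrame:
    """PET → water balance → SPEI for one site's monthly weather table.

    ``weather`` needs columns year, month, tmean_c, ppt_mm covering
    whole calendar years including the reference period.
    """
    w = weather.sort_values(["year", "month"]).reset_index(drop=True)
    if len(w) % 12 or not (w.groupby("year")["month"].count() == 12).all():
        raise WeatherError("weather table must cover whole calendar years")
    pet = thornthwaite_pet(w["tmean_c"].to_numpy(), latitude_deg)
    d = pd.Series(w["ppt_mm"].to_numpy() - pet,
                  index=pd.MultiIndex.from_arrays([w["year"], w["month"]]))
    return spei(d, reference=reference, k=k)
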