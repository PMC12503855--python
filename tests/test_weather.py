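"""PET, water balance, SPEI standardization and annual drought index."""

import numpy as np
import pandas as pd
import pytest

from rametdemog import weather
from rametdemog.weather import (WeatherError, annual_mean_spei, anomaly,
                                day_length_hours, spei, thornthwaite_pet,
                                water_balance)


def _reference_thornthwaite(tmean, lat):
    """Independent textbook implementation of the Thornthwaite monthly
    formula, written directly from the classic definitions (annual heat
    index, exponent polynomial, day-length/month-length correction)."""
    import math
    mid_doy = [15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
    ndays = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    I = sum((t / 5.0) ** 1.514 for t in tmean if t > 0)
    a = (6.75e-7 * I**3) - (7.71e-5 * I**2) + (1.792e-2 * I) + 0.49239
    out = []
    for j, t in enumerate(tmean):
        if t <= 0:
            pet = 0.0
        elif t < 26.5:
            pet = 16.0 * (10.0 * t / I) ** a
        else:
            pet = -415.85 + 32.24 * t - 0.43 * t * t
        delta = 0.409 * math.sin(2 * math.pi / 365 * mid_doy[j] - 1.39)
        cosw = -math.tan(math.radians(lat)) * math.tan(delta)
        cosw = min(1.0, max(-1.0, cosw))
        N = 24.0 / math.pi * math.acos(cosw)
        out.append(pet * (N / 12.0) * (ndays[j] / 30.0))
    return out


class TestThornthwaite:
    def test_subzero_months_evaporate_nothing(self):
        t = np.array([-5.0] * 6 + [10.0] * 6)
        pet = thornthwaite_pet(t, 42.0)
        assert np.all(pet[:6] == 0.0)
        assert np.all(pet[6:] > 0.0)

    def test_linear_in_day_length_correction(self):
        # PET scales linearly with the K correction, so two latitudes
        # differ exactly by the ratio of their corrections
        t = np.full(12, 15.0)
        pet_a = thornthwaite_pet(t, 0.0)
        pet_b = thornthwaite_pet(t, 50.0)
        ka = day_length_hours(0.0)
        kb = day_length_hours(50.0)
        np.testing.assert_allclose(pet_b, pet_a * kb / ka, rtol=1e-12)

    def test_matches_independent_reference(self):
        tmean = [-4.0, -1.5, 3.0, 9.5, 15.5, 21.0,
                 24.0, 23.0, 17.5, 10.5, 2.5, -3.0]
        got = thornthwaite_pet(np.array(tmean), 42.0)
        want = _reference_thornthwaite(tmean, 42.0)
        np.testing.assert_allclose(got, want, atol=0.5)

    def test_hot_branch(self):
        t = np.full(12, 28.0)
        pet = thornthwaite_pet(t, 0.0)
        raw = -415.85 + 32.24 * 28.0 - 0.43 * 28.0**2
        k = day_length_hours(0.0) / 12.0 * np.array(
            [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]) / 30.0
        np.testing.assert_allclose(pet, raw * k, rtol=1e-10)

    def test_monotone_in_temperature(self):
        base = np.full(12, 10.0)
        warm = base.copy()
        warm[6] = 12.0
        assert thornthwaite_pet(warm, 42.0)[6] > thornthwaite_pet(base, 42.0)[6]

    def test_bad_latitude(self):
        with pytest.raises(WeatherError):
            thornthwaite_pet(np.full(12, 10.0), 95.0)

    def test_partial_year_rejected(self):
        with pytest.raises(WeatherError):
            thornthwaite_pet(np.full(10, 10.0), 42.0)


class TestWaterBalance:
    def test_scalar_and_vector(self):
        assert water_balance(np.array([50.0]), np.array([30.0]))[0] == 20.0
        ppt = np.array([10.0, 20.0, 30.0])
        np.testing.assert_array_equal(water_balance(ppt, np.zeros(3)), ppt)

    def test_misaligned_rejected(self):
        a = pd.Series([1.0], index=[1])
        b = pd.Series([1.0], index=[2])
        with pytest.raises(WeatherError):
            water_balance(a, b)


def _gamma_like_d(seed, first=1950, last=1989, extra_years=0):
    rng = np.random.default_rng(seed)
    years = np.arange(first, last + 1 + extra_years)
    idx = pd.MultiIndex.from_product([years, range(1, 13)])
    month_mean = 40 + 30 * np.sin(np.arange(1, 13) / 12 * 2 * np.pi)
    vals = rng.gamma(4.0, np.tile(month_mean, years.size) / 4.0) - 60.0
    return pd.Series(vals, index=idx)


class TestSPEI:
    def test_reference_standardization(self):
        d = _gamma_like_d(3)
        out = spei(d)
        ref = out[(out.year >= 1950) & (out.year <= 1989)]
        by_month = ref.groupby("month")["spei"]
        assert by_month.mean().abs().max() < 0.05
        assert ((by_month.std() - 1.0).abs() < 0.1).all()

    def test_monotone_within_calendar_month(self):
        d = _gamma_like_d(4, extra_years=10)
        out = spei(d)
        for m in (1, 7):
            sub = out[out.month == m].dropna()
            order = np.argsort(sub["D_mm"].to_numpy())
            s = sub["spei"].to_numpy()[order]
            assert np.all(np.diff(s) >= 0)

    def test_shift_invariance_through_refit(self):
        d = _gamma_like_d(5, extra_years=5)
        out1 = spei(d)
        out2 = spei(d + 10.0)
        np.testing.assert_allclose(out1["spei"], out2["spei"], atol=1e-6)

    def test_constant_month_errors_naming_month(self):
        d = _gamma_like_d(6)
        d.loc[pd.IndexSlice[:, 3]] = 5.0
        with pytest.raises(WeatherError, match="month 3"):
            spei(d)

    def test_k_aggregation(self):
        d = _gamma_like_d(7)
        out = spei(d, k=3)
        # first two months of the series have no 3-month window
        assert out["spei"].isna().sum() == 2
        vals = d.to_numpy()
        np.testing.assert_allclose(out["D_mm"].to_numpy()[2:],
                                   vals[2:] + vals[1:-1] + vals[:-2])


class TestAnnualMeanSPEI:
    def _frame(self, value=0.5):
        rows = [(y, m, value) for y in (1994, 1995) for m in range(1, 13)]
        return pd.DataFrame(rows, columns=["year", "month", "spei"])

    def test_constant_window(self):
        df = self._frame(0.5)
        assert annual_mean_spei(df, 1995) == pytest.approx(0.5)
        assert not weather.is_drought_year(0.5)

    def test_zero_is_non_drought(self):
        df = self._frame(0.0)
        assert annual_mean_spei(df, 1995) == 0.0
        assert not weather.is_drought_year(0.0)

    def test_alternating_cancels_over_even_window(self):
        # the 14-month window is even, so a strict +1/-1 alternation
        # averages exactly zero whatever the phase
        df = self._frame()
        df["spei"] = [(1 if (12 * r.year + r.month) % 2 == 0 else -1)
                      for r in df.itertuples()]
        assert annual_mean_spei(df, 1995) == pytest.approx(0.0)
        df["spei"] = -df["spei"]
        assert annual_mean_spei(df, 1995) == pytest.approx(0.0)

    def test_missing_months_listed(self):
        df = self._frame()
        df = df[~((df.year == 1994) & (df.month == 6))]
        with pytest.raises(WeatherError, match=r"\(1994, 6\)"):
            annual_mean_spei(df, 1995)


class TestAnomaly:
    def test_examples(self):
        idx = np.arange(1950, 1995)
        vals = pd.Series(8.6, index=idx)
        vals.loc[1994] = 9.6
        out = anomaly(vals)
        assert out.loc[1994] == pytest.approx(1.0)
        assert out.loc[1960] == pytest.approx(0.0, abs=1e-12)

    def test_baseline_anomalies_sum_to_zero(self):
        rng = np.random.default_rng(0)
        idx = np.arange(1950, 2000)
        vals = pd.Series(rng.normal(8.0, 1.0, idx.size), index=idx)
        out = anomaly(vals)
        assert out.loc[1950:1989].sum() == pytest.approx(0.0, abs=1e-9)
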