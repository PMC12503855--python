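"""Functional linear models: lag design, fitting, significance screens."""

import numpy as np
import pandas as pd
import pytest

from rametdemog import flm
from rametdemog.flm import (FLMError, FLMFit, LagDesign, build_lag_matrix,
                            fit_flm, select_lag_length, significant_windows)


def _monthly(first=1988, last=2009, seed=0, trend=False):
    rng = np.random.default_rng(seed)
    rows = []
    for y in range(first, last + 1):
        for m in range(1, 13):
            v = rng.normal(0, 1) + (0.001 * y if trend else 0.0)
            rows.append((y, m, v))
    return pd.DataFrame(rows, columns=["year", "month", "x"])


def _design(n=30, L=19, seed=0):
    rng = np.random.default_rng(seed)
    return LagDesign(years=np.arange(n), L=L,
                     X=rng.normal(0, 1, (n, L + 1)),
                     calendar_months=(7 - np.arange(L + 1) - 1) % 12 + 1,
                     growing_mask=np.zeros(L + 1, bool), variable="x")


class TestBuildLagMatrix:
    def test_lag_to_calendar_mapping(self):
        monthly = _monthly()
        d = build_lag_matrix(monthly, "x", [1995], L=19)
        series = monthly.set_index(["year", "month"])["x"]
        assert d.X[0, 0] == series[(1995, 7)]     # m=0 is July of t
        assert d.X[0, 1] == series[(1995, 6)]
        assert d.X[0, 19] == series[(1993, 12)]   # m=19 is December of t-2
        assert d.calendar_months[0] == 7
        assert d.calendar_months[19] == 12

    def test_seedling_lag_ends_at_seed_release(self):
        monthly = _monthly()
        d = build_lag_matrix(monthly, "x", [1995], L=11)
        series = monthly.set_index(["year", "month"])["x"]
        assert d.X[0, 11] == series[(1994, 8)]    # August of t-1

    def test_growing_season_mask(self):
        d = build_lag_matrix(_monthly(), "x", [1995], L=19)
        grow = {7, 6, 5, 9, 8}  # May-September, as calendar months
        for m in range(20):
            assert d.growing_mask[m] == (d.calendar_months[m] in grow)

    def test_coverage_gap_listed(self):
        monthly = _monthly(first=1995)
        with pytest.raises(FLMError, match="1993"):
            build_lag_matrix(monthly, "x", [1995], L=19)

    def test_constant_series_gives_identical_columns(self):
        monthly = _monthly()
        monthly["x"] = 1.0
        d = build_lag_matrix(monthly, "x", range(1995, 2005), L=19)
        assert np.ptp(d.X) == 0.0


class TestFitFLM:
    def test_boxcar_kernel_recovery(self):
        rng = np.random.default_rng(10)
        d = _design(n=30, seed=10)
        truth = np.zeros(20)
        truth[2:9] = 0.05
        y = d.X @ truth + rng.normal(0, 0.05, 30)
        fit = fit_flm(d, y, "gaussian", response_name="sim")
        assert np.corrcoef(fit.coef, truth)[0, 1] >= 0.8
        wins = significant_windows(fit)
        assert wins, "a strong kernel must be detected"
        covered = set()
        for w in wins:
            covered |= set(range(w["m_start"], w["m_end"] + 1))
        assert covered & set(range(2, 9))

    def test_zero_variance_response_rejected(self):
        d = _design()
        with pytest.raises(FLMError):
            fit_flm(d, np.full(30, 1.3), "gaussian")

    def test_too_few_years_rejected(self):
        d = _design(n=5)
        with pytest.raises(FLMError):
            fit_flm(d, np.arange(5.0), "gaussian")

    def test_binomial_family(self):
        rng = np.random.default_rng(11)
        d = _design(n=25, seed=11)
        truth = np.zeros(20)
        truth[0:6] = 0.3
        from scipy.special import expit
        p = expit(-0.5 + d.X @ truth)
        trials = np.full(25, 150.0)
        y = rng.binomial(150, p).astype(float)
        fit = fit_flm(d, y, "binomial", trials=trials)
        assert fit.converged
        assert np.corrcoef(fit.coef, truth)[0, 1] >= 0.7

    def test_permutation_destroys_significance(self):
        rng = np.random.default_rng(12)
        d = _design(n=30, seed=12)
        truth = np.zeros(20)
        truth[2:9] = 0.1
        y = d.X @ truth + rng.normal(0, 0.05, 30)
        base = fit_flm(d, y, "gaussian")
        assert base.p_overall < 0.01
        hits = 0
        n_perm = 100
        for _ in range(n_perm):
            yp = rng.permutation(y)
            hits += fit_flm(d, yp, "gaussian").p_overall < 0.01
        assert hits / n_perm < 0.05

    def test_intercept_absorbs_column_shift(self):
        # shifting every lag column by a constant changes only the
        # intercept, not the fitted coefficient curve
        rng = np.random.default_rng(13)
        d = _design(n=30, seed=13)
        y = d.X @ np.linspace(0, 0.1, 20) + rng.normal(0, 0.05, 30)
        f1 = fit_flm(d, y, "gaussian")
        d2 = LagDesign(years=d.years, L=d.L, X=d.X + 5.0,
                       calendar_months=d.calendar_months,
                       growing_mask=d.growing_mask, variable="x")
        f2 = fit_flm(d2, y, "gaussian")
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-6)


class TestSignificantWindows:
    def _fit(self, lo, hi, p):
        L = len(lo) - 1
        coef = (np.asarray(lo) + np.asarray(hi)) / 2
        se = (np.asarray(hi) - np.asarray(lo)) / (2 * 1.96)
        f = FLMFit(response="r", variable="v", family="gaussian", L=L,
                   intercept=0.0, coef=coef, se=se, p_overall=p,
                   calendar_months=np.arange(L + 1) % 12 + 1)
        return f

    def test_no_windows_when_screen_fails(self):
        lo = np.full(20, 0.5)
        hi = np.full(20, 1.0)
        f = self._fit(lo, hi, p=0.5)
        assert significant_windows(f) == []

    def test_interval_extraction(self):
        lo = np.full(20, -1.0)
        hi = np.full(20, 1.0)
        lo[2:8] = 0.1   # CI excludes 0 on m=2..7 (positive)
        hi[12] = -0.1
        lo[12] = -1.0   # CI excludes 0 at m=12 (negative)
        f = self._fit(lo, hi, p=0.001)
        wins = significant_windows(f)
        spans = [(w["m_start"], w["m_end"], w["sign"]) for w in wins]
        assert spans == [(2, 7, "+"), (12, 12, "-")]

    def test_empty_when_ci_straddles_zero(self):
        f = self._fit(np.full(20, -1.0), np.full(20, 1.0), p=0.001)
        assert significant_windows(f) == []


class TestSelectLagLength:
    def test_single_candidate(self):
        monthly = _monthly()
        rng = np.random.default_rng(14)
        years = range(1995, 2008)
        y = rng.normal(0, 1, 13)
        chosen, table = select_lag_length(monthly, "x", years, y, "gaussian",
                                          candidates=[19])
        assert chosen == 19
        assert list(table["L"]) == [19]

    def test_chooses_longer_lag_for_long_kernel(self):
        monthly = _monthly(first=1980)
        series = monthly.set_index(["year", "month"])["x"]
        years = list(range(1990, 2009))
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            d = build_lag_matrix(monthly, "x", years, L=12)
            truth = np.full(13, 0.4)
            y = d.X @ truth + rng.normal(0, 0.2, len(years))
            chosen, _ = select_lag_length(monthly, "x", years, y, "gaussian",
                                          candidates=[7, 10, 13, 16])
            hits += chosen >= 10
        assert hits >= 8


class TestBattery:
    def test_bookkeeping_and_failure_recording(self):
        monthly = _monthly()
        monthly["x2"] = monthly["x"] * 0.5 + 1.0
        rng = np.random.default_rng(15)
        years = np.arange(1995, 2008)
        responses = {
            "good": {"family": "gaussian", "years": years,
                     "y": rng.normal(0, 1, 13)},
            "flat": {"family": "gaussian", "years": years,
                     "y": np.full(13, 2.0)},  # zero variance: recorded
        }
        table, fits = flm.run_flm_battery("s", responses, monthly,
                                          variables=("x", "x2"))
        assert len(table) == 2 * 2
        flat = table[table.response == "flat"]
        assert (~flat["converged"]).all()
        good = table[table.response == "good"]
        assert good["converged"].all()
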