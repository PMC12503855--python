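"""Projection matrices: assembly, eigen-analysis, transient growth."""

import numpy as np
import pytest
from scipy import linalg

from rametdemog.mpm import (MPMError, ProjectionMatrix, asymptotic_lambda,
                            build_annual_matrix, mean_matrix,
                            stable_stage_distribution, transient_growth,
                            STAGE_INDEX)


def _pm(U=None, F=None, R=None, site="s", year=2000):
    z = np.zeros((6, 6))
    return ProjectionMatrix(site=site, year=year,
                            survival=z if U is None else U,
                            fecundity=z if F is None else F,
                            recruitment=z if R is None else R)


def _random_rates(rng):
    """A random valid vital-rates mapping via random conditional chains."""
    from rametdemog.vital_rates import (DEFAULT_ALLOWED_FATES,
                                        reconstruct_unconditional)
    rates = {}
    for origin, fates in DEFAULT_ALLOWED_FATES.items():
        probs = {s: rng.uniform(0, 1) for s in
                 ("survival", "flowering", "mf_given_flowering",
                  "ia_given_nonflowering", "mr_given_aboveground")}
        for fate, p in reconstruct_unconditional(probs, fates).items():
            if fate != "DEAD":
                rates[f"{origin}_to_{fate}"] = p
    rates["f"] = rng.uniform(0, 3)
    for cls in ("SR_rec", "MR_rec", "SF_rec", "MF_rec"):
        rates[cls] = rng.uniform(0, 0.5)
    return rates


class TestBuildAnnualMatrix:
    def test_pure_stasis(self):
        pm = build_annual_matrix({"SR_to_SR": 1.0})
        assert pm.A[STAGE_INDEX["SR"], STAGE_INDEX["SR"]] == 1.0
        assert pm.A.sum() == 1.0
        assert asymptotic_lambda(pm) == pytest.approx(1.0)

    def test_three_stage_loop_unit_lambda(self):
        # Sd -> SR -> SF -> Sd with f=2 and P(SR->SF)=0.5: the cycle
        # product is 1*0.5*2 = 1, so lambda = 1 exactly
        pm = build_annual_matrix({"Sd_to_SR": 1.0, "SR_to_SF": 0.5, "f": 2.0})
        assert asymptotic_lambda(pm) == pytest.approx(1.0, abs=1e-10)

    def test_monocarpy_enforced(self):
        U = np.zeros((6, 6))
        U[STAGE_INDEX["SR"], STAGE_INDEX["SF"]] = 0.3  # SF may not survive
        with pytest.raises(MPMError, match="SF"):
            _pm(U=U)

    def test_column_sum_cap_enforced(self):
        U = np.zeros((6, 6))
        U[0, 1] = 0.6
        U[1, 1] = 0.6
        with pytest.raises(MPMError, match="SR"):
            _pm(U=U)

    def test_sprout_rate_enters_all_pool_columns(self):
        pm = build_annual_matrix({"SR_rec": 0.2})
        row = STAGE_INDEX["SR"]
        for col in ("SR", "MR", "IA"):
            assert pm.recruitment[row, STAGE_INDEX[col]] == 0.2
        assert pm.recruitment.sum() == pytest.approx(0.6)

    def test_random_rates_always_valid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            pm = build_annual_matrix(_random_rates(rng))
            assert (pm.survival.sum(axis=0) <= 1 + 1e-10).all()


class TestAsymptoticLambda:
    def test_identity(self):
        assert asymptotic_lambda(np.eye(6)) == pytest.approx(1.0)

    def test_two_stage_cycle(self):
        A = np.array([[0.0, 2.0], [0.5, 0.0]])
        assert asymptotic_lambda(A) == pytest.approx(1.0, abs=1e-10)

    def test_matches_eig_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            A = rng.uniform(0, 1, (6, 6))
            want = np.max(np.abs(linalg.eigvals(A)))
            assert asymptotic_lambda(A) == pytest.approx(want, abs=1e-10)

    def test_nonfinite_rejected(self):
        A = np.eye(6)
        A[0, 0] = np.nan
        with pytest.raises(MPMError):
            asymptotic_lambda(A)

    def test_monotone_in_entries(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            A = rng.uniform(0, 1, (6, 6))
            lam = asymptotic_lambda(A)
            B = A.copy()
            i, j = rng.integers(0, 6, 2)
            B[i, j] += rng.uniform(0, 0.5)
            assert asymptotic_lambda(B) >= lam - 1e-12

    def test_substochastic_lambda_at_most_one(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            A = rng.uniform(0, 1, (6, 6))
            A /= np.maximum(A.sum(axis=0), 1.0)[None, :]  # column sums <= 1
            assert asymptotic_lambda(A) <= 1.0 + 1e-12


class TestStableStageDistribution:
    def test_two_stage_cycle(self):
        A = np.array([[0.0, 2.0], [0.5, 0.0]])
        w = stable_stage_distribution(A)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-10)

    def test_identity_ambiguous_uniform(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            w = stable_stage_distribution(np.eye(6))
        np.testing.assert_allclose(w, np.full(6, 1 / 6))

    def test_strict_mode_raises_on_ambiguity(self):
        with pytest.raises(MPMError, match="mean matrix"):
            stable_stage_distribution(np.eye(6), strict=True)

    def test_eigen_residual(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            A = rng.uniform(0, 1, (6, 6))
            w = stable_stage_distribution(A)
            lam = asymptotic_lambda(A)
            assert np.max(np.abs(A @ w - lam * w)) < 1e-8
            assert w.sum() == pytest.approx(1.0)

    def test_projection_from_ssd_grows_at_lambda(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, (6, 6))
        w = stable_stage_distribution(A)
        lam = asymptotic_lambda(A)
        n0 = 50 * w
        n1 = A @ n0
        assert n1.sum() / n0.sum() == pytest.approx(lam, abs=1e-8)


class TestTransientGrowth:
    def test_constant_population(self):
        assert transient_growth(100, 100) == 1.0
        assert transient_growth(100, 100, mode="ratio") == 1.0

    def test_59_percent_spike(self):
        # a 100 -> 159 increase: e^0.59 under the exponential-relative
        # definition, 1.59 as a plain ratio
        assert transient_growth(100, 159) == pytest.approx(np.exp(0.59))
        assert transient_growth(100, 159) == pytest.approx(1.8040, abs=5e-4)
        assert transient_growth(100, 159, mode="ratio") == 1.59

    def test_small_change_taylor_bound(self):
        for dn in (0.1, 1.0, 5.0):
            er = transient_growth(100, 100 + dn)
            ra = transient_growth(100, 100 + dn, mode="ratio")
            assert abs(er - ra) <= (dn / 100) ** 2 * np.e / 2

    def test_zero_start_rejected(self):
        with pytest.raises(MPMError):
            transient_growth(0, 10)


class TestMeanMatrix:
    def test_single_matrix_is_itself(self):
        rng = np.random.default_rng(6)
        pm = build_annual_matrix(_random_rates(rng))
        np.testing.assert_array_equal(mean_matrix([pm]).A, pm.A)

    def test_average_of_scaled_pair(self):
        U = np.zeros((6, 6))
        U[1, 1] = 0.2
        a = _pm(U=U)
        b = _pm(U=3 * U)
        np.testing.assert_allclose(mean_matrix([a, b]).A, 2 * U)

    def test_mixed_sites_rejected(self):
        a = _pm(site="x")
        b = _pm(site="y")
        with pytest.raises(MPMError):
            mean_matrix([a, b])
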