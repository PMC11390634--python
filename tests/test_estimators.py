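"""Closed-form, oracle and calibration checks of the MR estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dtmr.estimators import (
    EggerRegression,
    InsufficientInstruments,
    IVWEstimator,
    MRPresso,
    SteigerTest,
    WaldRatio,
)
from dtmr.mr import (
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mr_presso,
    orient_per_mmhg_decline,
    pairs_frame,
    steiger,
    wald_ratio,
)

from conftest import simulated_pairs


class TestWaldRatio:
    def test_unit_divisor(self):
        est = wald_ratio(pairs_frame([1.0], [0.01], [0.5], [0.1]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.method == "wald"

    def test_sign_and_scale(self):
        est = wald_ratio(pairs_frame([-0.5], [0.01], [0.1], [0.05]))
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_gives_or_one(self):
        est = wald_ratio(pairs_frame([0.3], [0.01], [0.0], [0.05]))
        assert est.beta == 0.0 and est.or_ == 1.0 and est.pval == 1.0

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(ValueError, match="beta_exp"):
            wald_ratio(pairs_frame([0.0], [0.01], [0.1], [0.05]))


class TestIVW:
    def test_two_snp_closed_form(self, two_snp_pairs):
        est = ivw(two_snp_pairs, model="fixed")
        assert est.beta == pytest.approx((100 * 0.2 + 25 * 0.4) / 125)
        assert est.se == pytest.approx(1 / np.sqrt(125))

    def test_mre_floor_engages_for_underdispersion(self, two_snp_pairs):
        fixed = ivw(two_snp_pairs, model="fixed")
        mre = ivw(two_snp_pairs, model="mre")
        # Q = 0.8 < k-1 = 1, so the MRE scaling floors at 1
        assert mre.beta == fixed.beta
        assert mre.se == fixed.se

    def test_identical_snps_symmetry(self):
        k = 5
        pairs = pairs_frame([1.0] * k, [0.01] * k, [0.3] * k, [0.1] * k)
        est = ivw(pairs, model="fixed")
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.1 / np.sqrt(k))

    def test_single_pair_equals_wald(self):
        pair = pairs_frame([0.04], [0.005], [0.01], [0.006])
        a, b = ivw(pair), wald_ratio(pair)
        assert (a.beta, a.se, a.method) == (b.beta, b.se, "wald")

    def test_all_zero_exposure_betas_error(self):
        with pytest.raises(ValueError, match="zero"):
            ivw(pairs_frame([0.0, 0.0], [0.01, 0.01], [0.1, 0.2], [0.1, 0.1]))

    def test_or_ci_invariants(self, random_pairs_factory):
        est = ivw(random_pairs_factory(0))
        assert est.or_ == pytest.approx(np.exp(est.beta), rel=1e-12)
        assert est.ci_low < est.or_ < est.ci_high
        # formatting identity: OR is the geometric mean of its CI bounds
        assert np.exp((np.log(est.ci_low) + np.log(est.ci_high)) / 2) == pytest.approx(
            est.or_, rel=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_row_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 12))
        pairs = pairs_frame(
            rng.uniform(0.01, 0.05, k), rng.uniform(0.003, 0.008, k),
            rng.normal(0, 0.01, k), rng.uniform(0.003, 0.01, k),
        )
        shuffled = pairs.sample(frac=1, random_state=1).reset_index(drop=True)
        a, b = ivw(pairs), ivw(shuffled)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_mre_se_never_below_fixed(self, random_pairs_factory):
        for seed in range(20):
            pairs = random_pairs_factory(seed, k=8)
            assert ivw(pairs, "mre").se >= ivw(pairs, "fixed").se - 1e-15
            assert ivw(pairs, "mre").beta == ivw(pairs, "fixed").beta


class TestCochranQ:
    def test_two_snp_fixture(self, two_snp_pairs):
        beta = ivw(two_snp_pairs).beta
        q, df, p = cochran_q(two_snp_pairs, beta)
        assert q == pytest.approx(0.8)
        assert df == 1
        assert p == pytest.approx(0.37109, abs=1e-4)

    def test_homogeneous_ratios_give_zero_q(self):
        pairs = pairs_frame([1.0, 2.0], [0.01, 0.01], [0.3, 0.6], [0.1, 0.1])
        beta = ivw(pairs).beta
        q, _, p = cochran_q(pairs, beta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_duplicating_snps_doubles_q_and_df(self, two_snp_pairs):
        beta = ivw(two_snp_pairs).beta
        doubled = pd.concat([two_snp_pairs, two_snp_pairs], ignore_index=True)
        q1, df1, _ = cochran_q(two_snp_pairs, beta)
        q2, df2, p2 = cochran_q(doubled, beta)
        assert q2 == pytest.approx(2 * q1)
        assert df2 == 3
        assert p2 == pytest.approx(float(stats.chi2.sf(2 * q1, 3)))

    def test_single_pair_errors(self):
        with pytest.raises(InsufficientInstruments):
            cochran_q(pairs_frame([1.0], [0.01], [0.1], [0.1]), 0.1)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.02, 0.03, 0.04, 0.055])
        by = 0.01 + 0.5 * bx
        res = egger(pairs_frame(bx, [0.005] * 4, by, [0.004, 0.005, 0.006, 0.007]))
        assert res.intercept == pytest.approx(0.01, abs=1e-10)
        assert res.estimate.beta == pytest.approx(0.5, abs=1e-10)

    def test_collinear_exposure_errors(self):
        pairs = pairs_frame([0.03] * 4, [0.005] * 4, [0.1, 0.2, 0.1, 0.3], [0.1] * 4)
        with pytest.raises(ValueError, match="collinear"):
            egger(pairs)

    def test_k_below_3_raises_insufficient(self, two_snp_pairs):
        with pytest.raises(InsufficientInstruments):
            egger(two_snp_pairs)

    def test_orientation_invariance(self, random_pairs_factory):
        """Flipping a pair's signs (exposure and outcome together) changes
        nothing: Egger orients exposure betas non-negative first."""
        pairs = random_pairs_factory(3, k=8)
        flipped = pairs.copy()
        flipped["beta_exp"] *= -1
        flipped["beta_out"] *= -1
        a, b = egger(pairs), egger(flipped)
        assert a.estimate.beta == pytest.approx(b.estimate.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_balanced_pleiotropy_intercept_calibration(self):
        """Under balanced pleiotropy the intercept test rejects at ~5%."""
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            pairs, _ = simulated_pairs(seed, true_effect=0.1,
                                       pleiotropy_frac=1.0,
                                       pleiotropy_mean=0.0,
                                       pleiotropy_sd=0.01)
            if egger(pairs).intercept_pval < 0.05:
                rejections += 1
        assert 0.025 <= rejections / n_rep <= 0.075


class TestSteiger:
    @staticmethod
    def _pairs_with_r2(r2x, r2y, n=100_000.0):
        zx = np.sqrt(r2x / (1 - r2x) * n)
        zy = np.sqrt(r2y / (1 - r2y) * n)
        return pairs_frame([zx * 0.005], [0.005], [zy * 0.004], [0.004])

    def test_strong_exposure_direction(self):
        res = steiger(self._pairs_with_r2(0.01, 0.001), 100_000, 100_000)
        assert res.direction is True
        assert res.r2_exp == pytest.approx(0.01, rel=1e-9)
        assert res.r2_out == pytest.approx(0.001, rel=1e-9)
        assert res.pval < 1e-10

    def test_tie_not_established(self):
        res = steiger(self._pairs_with_r2(0.005, 0.005), 100_000, 100_000)
        assert res.direction is None
        assert res.pval == 1.0

    def test_role_swap_inverts_direction(self):
        pairs = self._pairs_with_r2(0.01, 0.001)
        swapped = pairs_frame(
            pairs["beta_out"], pairs["se_out"], pairs["beta_exp"], pairs["se_exp"]
        )
        fwd = steiger(pairs, 100_000, 100_000)
        rev = steiger(swapped, 100_000, 100_000)
        assert fwd.direction is True and rev.direction is False
        assert fwd.pval == pytest.approx(rev.pval)

    def test_small_sample_sizes_error(self):
        with pytest.raises(ValueError):
            steiger(self._pairs_with_r2(0.01, 0.001), 3, 100)


class TestLeaveOneOut:
    def test_identical_snps_all_equal_full(self):
        pairs = pairs_frame([1.0] * 4, [0.01] * 4, [0.3] * 4, [0.1] * 4)
        res = leave_one_out(pairs)
        full = ivw(pairs)
        for e in res.estimates:
            assert e.beta == pytest.approx(full.beta)
        assert res.max_abs_deviation == pytest.approx(0.0, abs=1e-15)

    def test_gross_outlier_has_largest_deviation(self):
        pairs = pairs_frame(
            [0.03, 0.04, 0.05, 0.035], [0.005] * 4,
            [0.003, 0.004, 0.005, 0.08], [0.005] * 4,
            variant_id=["a", "b", "c", "outlier"],
        )
        res = leave_one_out(pairs)
        devs = {vid: abs(e.beta - ivw(pairs).beta)
                for vid, e in zip(res.variant_ids, res.estimates)}
        assert max(devs, key=devs.get) == "outlier"
        assert res.max_abs_deviation == pytest.approx(devs["outlier"])

    def test_matches_brute_force(self, random_pairs_factory):
        pairs = random_pairs_factory(5, k=7)
        res = leave_one_out(pairs, model="mre")
        for i, est in enumerate(res.estimates):
            brute = ivw(pairs.drop(index=i), model="mre")
            assert est.beta == pytest.approx(brute.beta, rel=1e-12)
            assert est.se == pytest.approx(brute.se, rel=1e-12)

    def test_k_below_3_raises(self, two_snp_pairs):
        with pytest.raises(InsufficientInstruments):
            leave_one_out(two_snp_pairs)


class TestOrientation:
    def test_negates_exposure_only_and_is_involution(self, random_pairs_factory):
        pairs = random_pairs_factory(1)
        once = orient_per_mmhg_decline(pairs)
        assert (once["beta_exp"] == -pairs["beta_exp"]).all()
        assert (once["beta_out"] == pairs["beta_out"]).all()
        pd.testing.assert_frame_equal(orient_per_mmhg_decline(once), pairs)

    def test_wald_or_is_reciprocal(self):
        pair = pairs_frame([0.03], [0.005], [0.01], [0.004])
        before = wald_ratio(pair)
        after = wald_ratio(orient_per_mmhg_decline(pair))
        assert after.or_ == pytest.approx(1 / before.or_, rel=1e-12)

    def test_ivw_beta_negates_se_unchanged(self, random_pairs_factory):
        pairs = random_pairs_factory(2)
        before = ivw(pairs)
        after = ivw(orient_per_mmhg_decline(pairs))
        assert after.beta == pytest.approx(-before.beta, rel=1e-12)
        assert after.se == pytest.approx(before.se, rel=1e-12)


class TestPresso:
    def test_same_seed_identical(self, random_pairs_factory):
        pairs = random_pairs_factory(4, k=10)
        a = mr_presso(pairs, nsim=500, seed=11)
        b = mr_presso(pairs, nsim=500, seed=11)
        assert a.global_pval == b.global_pval
        assert a.outliers == b.outliers

    def test_small_k_errors(self):
        with pytest.raises(InsufficientInstruments):
            mr_presso(pairs_frame([0.03], [0.005], [0.01], [0.004]), seed=0)

    def test_low_nsim_warns(self, random_pairs_factory):
        with pytest.warns(UserWarning, match="nsim"):
            mr_presso(random_pairs_factory(0), nsim=50, seed=0)

    def test_flags_gross_outliers_with_corrected_estimate(self):
        rng = np.random.default_rng(0)
        k = 20
        bx = rng.uniform(0.03, 0.05, k)
        sy = np.full(k, 0.005)
        by = 0.1 * bx + rng.standard_normal(k) * sy
        by[3] += 8 * sy[3]
        by[15] += 8 * sy[15]
        pairs = pairs_frame(bx, [0.005] * k, by, sy,
                            variant_id=[f"rs{i}" for i in range(k)])
        res = mr_presso(pairs, nsim=1000, seed=1)
        assert {"rs3", "rs15"}.issubset(set(res.outliers))
        assert res.global_pval < 0.05
        assert res.corrected is not None
        assert abs(res.corrected.beta - 0.1) < abs(ivw(pairs).beta - 0.1)
        assert res.distortion_pval is not None


def test_estimator_classes_expose_sklearn_params(two_snp_pairs):
    """get_params/set_params/clone work, and fitted attributes use the
    trailing-underscore convention."""
    from sklearn.base import clone

    est = IVWEstimator(model="fixed")
    assert est.get_params() == {"model": "fixed"}
    est2 = clone(est).set_params(model="mre").fit(two_snp_pairs)
    assert est2.beta_ == pytest.approx(0.24)
    presso = MRPresso(nsim=200, random_state=7)
    assert clone(presso).get_params()["random_state"] == 7
    for cls in (WaldRatio, EggerRegression, SteigerTest):
        clone(cls())


def test_ivw_and_egger_match_wls_oracle_smoke(random_pairs_factory):
    """Spot check against statsmodels WLS (the full sweep lives in the
    acceptance suite)."""
    import statsmodels.api as sm

    pairs = random_pairs_factory(123, k=12)
    w = 1 / pairs["se_out"] ** 2
    ols = sm.WLS(pairs["beta_out"], pairs[["beta_exp"]], weights=w).fit()
    est = ivw(pairs, model="fixed")
    assert est.beta == pytest.approx(ols.params.iloc[0], abs=1e-10)
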