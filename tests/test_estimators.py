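"""Causal estimators: Wald ratios, IVW, weighted medians, Egger, LOO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit.estimators import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    _weighted_median,
    ivw,
    leave_one_out,
    mr_egger,
    ratio_estimates,
    to_odds_ratio,
    weighted_median,
)

from conftest import make_harmonized, plant_outlier


class TestRatioEstimates:
    def test_arithmetic(self):
        h = make_harmonized([0.2], [0.1], [0.02])
        [(snp, theta, sigma)] = ratio_estimates(h)
        assert theta == pytest.approx(0.5) and sigma == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        h = make_harmonized([0.2], [0.0], [0.02])
        assert ratio_estimates(h)[0][1] == 0.0

    def test_zero_exposure_effect_names_the_snp(self):
        h = make_harmonized([0.2, 0.0], [0.1, 0.1], [0.02, 0.02])
        with pytest.raises(DegenerateInstrumentError, match="rs0001"):
            ratio_estimates(h)

    @given(st.floats(0.01, 2), st.floats(-1, 1), st.floats(0.001, 0.1))
    @settings(max_examples=30, deadline=None)
    def test_joint_sign_flip_invariance(self, bx, by, sy):
        h1 = make_harmonized([bx], [by], [sy])
        h2 = make_harmonized([-bx], [-by], [sy])
        assert ratio_estimates(h1)[0][1] == pytest.approx(ratio_estimates(h2)[0][1])


class TestIVW:
    def test_exact_fit_has_zero_heterogeneity(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        est = ivw(h)
        assert est.beta == pytest.approx(0.5) and est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_three_snp_instance(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.02, 0.05, 0.04], 0.01)
        assert ivw(h).beta == pytest.approx(0.024 / 0.14, abs=1e-12)

    def test_equals_weight_normalized_mean_of_ratios(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 15)
        by = rng.normal(0.2 * bx, 0.02)
        h = make_harmonized(bx, by, 0.02)
        est = ivw(h, re_policy="fixed")
        theta = np.array([t for _, t, _ in ratio_estimates(h)])
        sig = np.array([s for _, _, s in ratio_estimates(h)])
        w = 1 / sig**2
        assert est.beta == pytest.approx(float(np.sum(w * theta) / np.sum(w)))
        assert est.se == pytest.approx(float(1 / np.sqrt(np.sum(w))))

    def test_multiplicative_scaling_floors_at_one(self):
        # exact-fit data: multiplicative SE must equal fixed SE, never shrink
        h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], 0.01)
        assert ivw(h).se == pytest.approx(ivw(h, re_policy="fixed").se)

    def test_overdispersed_data_inflates_se(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.3, 20)
        by = rng.normal(0.2 * bx, 0.1)  # 10x the nominal SE
        h = make_harmonized(bx, by, 0.01)
        assert ivw(h).se > 2 * ivw(h, re_policy="fixed").se

    def test_outcome_negation_equivariance(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.3, 10)
        by = rng.normal(0.2 * bx, 0.02)
        h1 = make_harmonized(bx, by, 0.02)
        h2 = make_harmonized(bx, -by, 0.02)
        assert ivw(h1).beta == pytest.approx(-ivw(h2).beta)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_harmonized([0.1], [0.05], [0.01]))

    def test_or_and_ci_consistent(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.02, 0.05, 0.04], 0.01)
        est = ivw(h)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low < est.or_ < est.ci_high


class TestWeightedMedian:
    def test_equal_weight_midpoint(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], 1.0)
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.2)

    def test_constant_ratios_return_constant(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.05, 0.02])
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.3)

    def test_equal_weights_odd_n_equals_plain_median(self):
        theta = np.array([0.4, -0.1, 0.2, 0.9, 0.3])
        w = np.ones(5)
        assert _weighted_median(theta, w) == pytest.approx(float(np.median(theta)))

    def test_duplicate_snp_with_halved_weight_stability(self):
        # Splitting one SNP's weight across two copies leaves the cumulative
        # weight function unchanged except at the interpolation knots, so the
        # estimate can move by at most one inter-ratio gap.
        rng = np.random.default_rng(17)
        for _ in range(20):
            theta = np.sort(rng.normal(0.3, 0.2, 7))
            w = rng.uniform(0.5, 2.0, 7)
            k = int(rng.integers(0, 7))
            dup_theta = np.append(theta, theta[k])
            dup_w = np.append(w, w[k] / 2)
            dup_w[k] = w[k] / 2
            a = _weighted_median(theta, w)
            b = _weighted_median(dup_theta, dup_w)
            max_gap = np.max(np.diff(theta))
            assert abs(a - b) <= max_gap + 1e-12

    def test_bootstrap_seed_reproducible(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.3, 12)
        by = rng.normal(0.2 * bx, 0.02)
        h = make_harmonized(bx, by, 0.02, se_exp=0.01)
        a = weighted_median(h, n_boot=200, seed=9)
        b = weighted_median(h, n_boot=200, seed=9)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_penalized_downweights_outlier(self):
        bx = np.full(11, 0.2)
        by = 0.5 * bx
        by[0] += 0.5  # gross outlier
        h = make_harmonized(bx, by, 0.02, se_exp=1e-4)
        plain = weighted_median(h, n_boot=50, seed=0).beta
        pen = weighted_median(h, penalized=True, n_boot=50, seed=0).beta
        assert abs(pen - 0.5) <= abs(plain - 0.5) + 1e-12

    def test_parameter_validation(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.02, 0.05, 0.04], 0.01)
        with pytest.raises(ValueError):
            weighted_median(h, n_boot=0)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_harmonized([0.1, 0.2], [0.02, 0.05], 0.01))


class TestEgger:
    def test_recovers_exact_linear_data(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        by = 0.01 + 1.0 * bx
        est = mr_egger(make_harmonized(bx, by, 0.01))
        assert est.beta == pytest.approx(1.0, abs=1e-12)
        assert est.intercept == pytest.approx(0.01, abs=1e-12)

    def test_symmetric_data_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        by = 0.5 * bx
        est = mr_egger(make_harmonized(bx, by, 0.01))
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_orientation_applied_before_fit(self):
        # negating one instrument's pair must not change the fit
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        by = 0.02 + 0.7 * bx
        h1 = make_harmonized(bx, by, 0.01)
        bx2, by2 = bx.copy(), by.copy()
        bx2[1], by2[1] = -bx2[1], -by2[1]
        h2 = make_harmonized(bx2, by2, 0.01)
        assert mr_egger(h1).beta == pytest.approx(mr_egger(h2).beta)
        assert mr_egger(h1).intercept == pytest.approx(mr_egger(h2).intercept)

    def test_slope_equals_ivw_when_intercept_zero(self):
        bx = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        by = 0.5 * bx  # fitted intercept exactly 0
        h = make_harmonized(bx, by, 0.01)
        assert mr_egger(h).beta == pytest.approx(ivw(h).beta, abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_harmonized([0.1, 0.2], [0.05, 0.1], 0.01))


class TestLeaveOneOut:
    def test_identical_ratios_leave_estimate_unchanged(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], 0.01)
        full = ivw(h).beta
        for _, est in leave_one_out(h):
            assert est.beta == pytest.approx(full)

    def test_planted_outlier_moves_estimate_most_when_omitted(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.1, 0.3, 12)
        by = rng.normal(0.3 * bx, 0.01)
        h = plant_outlier(make_harmonized(bx, by, 0.01), k=4)
        full = ivw(h).beta
        shifts = {snp: abs(est.beta - full) for snp, est in leave_one_out(h)}
        assert max(shifts, key=shifts.get) == h.records[4].snp

    def test_output_length(self):
        h = make_harmonized([0.1, 0.2, 0.3, 0.4], [0.02, 0.05, 0.04, 0.1], 0.01)
        assert len(leave_one_out(h)) == 4


class TestOddsRatio:
    def test_null(self):
        or_, lo, hi, p = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0 and p == pytest.approx(1.0)

    def test_log_two(self):
        or_, *_ = to_odds_ratio(0.6931, 0.1)
        assert or_ == pytest.approx(2.0, abs=1e-3)

    @given(st.floats(-1, 1), st.floats(0.01, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_ci_matches_normal_quantiles(self, beta, se):
        or_, lo, hi, p = to_odds_ratio(beta, se)
        assert lo == pytest.approx(np.exp(stats.norm.ppf(0.025, beta, se)), rel=1e-3)
        assert hi == pytest.approx(np.exp(stats.norm.ppf(0.975, beta, se)), rel=1e-3)
        assert p == pytest.approx(2 * stats.norm.sf(abs(beta) / se))

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.0)
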