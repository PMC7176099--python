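"""Predictive distributions, shrinkage, replication probability, sample size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repforecast import (
    NOT_ATTAINABLE,
    MethodSpec,
    NormalPredictive,
    ShrinkageResult,
    ZEstimate,
    flat_predictive,
    g_hat,
    prediction_interval,
    predictive_t,
    replication_probability,
    required_replication_n,
    sceptical_predictive,
    shrinkage_factor,
)
from repforecast.transforms import relative_heterogeneity, variance_ratio, z_variance

Z975 = stats.norm.ppf(0.975)


class TestFlatPredictive:
    def test_naive_reduction(self):
        pred = flat_predictive(ZEstimate(0.2, 0.04, 28), sigma_r2=0.02, tau=0.0)
        assert (pred.mean, pred.variance) == (0.2, pytest.approx(0.06))

    def test_with_heterogeneity(self):
        pred = flat_predictive(ZEstimate(0.2, 0.04, 28), sigma_r2=0.02, tau=0.08)
        assert pred.variance == pytest.approx(0.04 + 0.02 + 2 * 0.0064)

    def test_variance_increasing_in_tau(self):
        z = ZEstimate(0.2, 0.04, 28)
        vs = [flat_predictive(z, 0.02, tau).variance for tau in (0.0, 0.05, 0.1, 0.2)]
        assert np.all(np.diff(vs) > 0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            flat_predictive(ZEstimate(0.2, 0.04, 28), sigma_r2=0.0)


class TestShrinkage:
    def test_g_hat(self):
        assert g_hat(ZEstimate(0.2, 0.01, 103)) == pytest.approx(3.0)
        assert g_hat(ZEstimate(0.1, 0.01, 103), tau=math.sqrt(0.09)) == 0.0  # clipped
        assert g_hat(ZEstimate(0.1, 0.01, 103), tau=100.0) == 0.0

    def test_shrinkage_result_links_g_and_s(self):
        res = ShrinkageResult(3.0)
        assert res.s == pytest.approx(0.75)
        with pytest.raises(ValueError):
            ShrinkageResult(-0.5)

    @pytest.mark.parametrize(
        "t_o, d, expected",
        [(1.0, 0.0, 0.0), (Z975, 0.0, 1 - 1 / Z975**2), (2.0, 1.0, 0.5), (0.0, 0.0, 0.0)],
    )
    def test_values(self, t_o, d, expected):
        assert shrinkage_factor(t_o, d) == pytest.approx(expected)

    def test_limits_and_monotonicity(self):
        assert shrinkage_factor(1e9, 0.0) == pytest.approx(1.0)
        ts = np.linspace(1.2, 10, 50)
        assert np.all(np.diff(shrinkage_factor(ts, 0.5)) > 0)
        ds = np.linspace(0, 5, 50)
        assert np.all(np.diff(shrinkage_factor(3.0, ds)) <= 0)


class TestScepticalPredictive:
    def test_example(self):
        pred = sceptical_predictive(ZEstimate(0.2, 0.01, 103), sigma_r2=0.01, tau=0.0)
        assert pred.mean == pytest.approx(0.15)
        assert pred.variance == pytest.approx(0.0175)

    def test_zero_shrinkage_branch(self):
        pred = sceptical_predictive(ZEstimate(0.05, 0.01, 103), sigma_r2=0.02, tau=0.08)
        assert pred.mean == 0.0
        assert pred.variance == pytest.approx(0.02 + 0.0064)

    @given(
        st.floats(-3, 3),
        st.floats(0.01, 0.5),
        st.floats(0.01, 0.5),
        st.floats(0, 0.3),
    )
    @settings(max_examples=100, deadline=None)
    def test_sharper_than_flat(self, theta, v_o, v_r, tau):
        z = ZEstimate(theta, v_o, 50)
        sc = sceptical_predictive(z, v_r, tau)
        fl = flat_predictive(z, v_r, tau)
        assert sc.variance < fl.variance  # s < 1 for finite t_o


class TestPredictiveT:
    @pytest.mark.parametrize(
        "prior, expected_mean, expected_var",
        [("flat", Z975, 2.0), ("sceptical", (1 - 1 / Z975**2) * Z975, 2 - 1 / Z975**2)],
    )
    def test_just_significant_original(self, prior, expected_mean, expected_var):
        pred = predictive_t(Z975, c=1.0, d=0.0, prior=prior)
        assert pred.mean == pytest.approx(expected_mean)
        assert pred.variance == pytest.approx(expected_var)

    def test_flat_no_heterogeneity_form(self):
        pred = predictive_t(1.5, c=4.0, d=0.0, prior="flat")
        assert (pred.mean, pred.variance) == (pytest.approx(3.0), pytest.approx(5.0))

    @given(
        st.floats(-4, 4),
        st.floats(5, 500),
        st.floats(5, 500),
        st.floats(0, 0.3),
        st.sampled_from(["flat", "sceptical"]),
    )
    @settings(max_examples=150, deadline=None)
    def test_scale_consistency(self, theta, n_o, n_r, tau, prior):
        """The t-scale predictive is the z-scale predictive divided by sigma_r."""
        v_o, v_r = z_variance(n_o), z_variance(n_r)
        z = ZEstimate(theta, v_o, n_o)
        zpred = (
            flat_predictive(z, v_r, tau) if prior == "flat" else sceptical_predictive(z, v_r, tau)
        )
        tpred = predictive_t(
            z.t, variance_ratio(n_o, n_r), relative_heterogeneity(tau, n_o), prior
        )
        assert tpred.mean == pytest.approx(zpred.mean / math.sqrt(v_r), abs=1e-12, rel=1e-10)
        assert tpred.variance == pytest.approx(zpred.variance / v_r, rel=1e-10)


class TestPredictionInterval:
    def test_standard_normal(self):
        lo, hi = prediction_interval(NormalPredictive(0.0, 1.0), 0.95)
        assert (lo, hi) == (pytest.approx(-1.959964, abs=1e-5), pytest.approx(1.959964, abs=1e-5))

    def test_flat_two_unit_variances(self):
        pred = flat_predictive(ZEstimate(0.0, 1.0, 4), sigma_r2=1.0, tau=0.0)
        lo, hi = prediction_interval(pred, 0.95)
        assert hi == pytest.approx(1.959964 * math.sqrt(2), abs=1e-5)

    def test_correlation_scale_is_tanh_of_endpoints(self):
        pred = flat_predictive(ZEstimate(0.3, 0.02, 53), 0.02, 0.08)
        lo_z, hi_z = prediction_interval(pred, 0.95)
        lo_r, hi_r = prediction_interval(pred, 0.95, output_scale="correlation")
        assert (lo_r, hi_r) == (pytest.approx(math.tanh(lo_z)), pytest.approx(math.tanh(hi_z)))
        assert -1 < lo_r < hi_r < 1

    def test_width_increases_with_tau(self):
        z = ZEstimate(0.3, 0.02, 53)
        widths = [
            np.diff(prediction_interval(flat_predictive(z, 0.02, tau), 0.95))[0]
            for tau in (0.0, 0.08, 0.2)
        ]
        assert np.all(np.diff(widths) > 0)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            prediction_interval(NormalPredictive(0.0, 1.0), 1.5)


class TestReplicationProbability:
    def test_just_significant_flat_is_half(self):
        assert replication_probability(Z975, 1.0, 0.0, 0.05, "flat") == pytest.approx(0.5)

    def test_sceptical_lower(self):
        p = replication_probability(Z975, 1.0, 0.0, 0.05, "sceptical")
        # independent oracle: normal tail with the sceptical t-scale moments
        s = 1 - 1 / Z975**2
        oracle = stats.norm.sf(Z975, loc=s * Z975, scale=math.sqrt(s + 1))
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p < 0.5

    def test_limits_and_monotonicity(self):
        assert replication_probability(50.0, 1.0, 0.0) == pytest.approx(1.0)
        ts = np.linspace(0.5, 6, 40)
        probs = replication_probability(ts, 1.0, 0.0, prior="flat")
        assert np.all(np.diff(probs) > 0)
        cs = np.linspace(0.2, 5, 40)
        probs_c = replication_probability(2.5, cs, 0.0, prior="flat")
        assert np.all(np.diff(probs_c) > 0)
        # under the sceptical prior, monotone increasing past the s > 0 threshold
        ts = np.linspace(1.5, 6, 40)
        probs_s = replication_probability(ts, 1.0, 0.5, prior="sceptical")
        assert np.all(np.diff(probs_s) > 0)

    def test_requires_oriented_positive_t(self):
        with pytest.raises(ValueError):
            replication_probability(-1.0, 1.0, 0.0)

    def test_two_sided_adds_opposite_tail(self):
        one = replication_probability(3.0, 1.0, 0.0, prior="flat")
        two = replication_probability(3.0, 1.0, 0.0, prior="flat", two_sided=True)
        assert two > one
        assert two - one < 1e-3  # opposite tail is negligible here


class TestRequiredReplicationN:
    def brute_force(self, t_o, n_o, target, alpha, method, n_max=5000):
        for n_r in range(4, n_max):
            p = replication_probability(
                t_o,
                variance_ratio(n_o, n_r),
                relative_heterogeneity(method.tau, n_o),
                alpha,
                method.prior,
            )
            if p >= target:
                return n_r
        return NOT_ATTAINABLE

    def test_flat_example(self):
        assert required_replication_n(2.8, 53, 0.8, 0.05, MethodSpec("flat", 0.0)) == 71

    @pytest.mark.parametrize(
        "t_o, n_o, target, method",
        [
            (2.8, 53, 0.8, MethodSpec("flat", 0.0)),
            (2.8, 53, 0.8, MethodSpec("sceptical", 0.0)),
            (2.2, 40, 0.6, MethodSpec("flat", 0.08)),
            (3.5, 100, 0.9, MethodSpec("sceptical", 0.08)),
        ],
    )
    def test_matches_scan_oracle(self, t_o, n_o, target, method):
        assert required_replication_n(t_o, n_o, target, 0.05, method) == self.brute_force(
            t_o, n_o, target, 0.05, method
        )

    def test_not_attainable_zero_shrinkage(self):
        # t_o^2 <= 1 + d: the sceptical forecast is mean zero
        assert (
            required_replication_n(0.9, 50, 0.5, 0.05, MethodSpec("sceptical", 0.0))
            is NOT_ATTAINABLE
        )

    def test_not_attainable_above_power_limit(self):
        # flat-prior power is bounded by Phi(t_o / sqrt(1 + 2 d))
        limit = stats.norm.cdf(1.5)
        assert (
            required_replication_n(1.5, 50, limit + 0.01, 0.05, MethodSpec("flat", 0.0))
            is NOT_ATTAINABLE
        )
        assert required_replication_n(1.5, 50, limit - 0.05, 0.05, MethodSpec("flat", 0.0)) > 4


def test_method_spec_labels():
    assert MethodSpec("flat", 0.0).label == "N"
    assert MethodSpec("sceptical", 0.0).label == "S"
    assert MethodSpec("flat", 0.08).label == "H"
    assert MethodSpec("sceptical", 0.08).label == "SH"
    assert MethodSpec.from_label("sh", tau=0.1) == MethodSpec("sceptical", 0.1)
    with pytest.raises(ValueError):
        MethodSpec.from_label("X")
    with pytest.raises(ValueError):
        MethodSpec("improper", 0.0)
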