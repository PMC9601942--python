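"""Domain types, step-stress distribution functions, sufficient statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from stepstress import (
    CensoringScheme,
    RateParams,
    StepStressDataset,
    cause_density,
    cem_shift,
    lifetime_cdf,
    lifetime_pdf,
    sufficient_stats,
    validate_scheme,
)

PARAMS = RateParams(2.0, 1.0, 4.0, 2.0)

rates = st.floats(0.05, 20.0)
four_rates = st.tuples(rates, rates, rates, rates).map(lambda t: RateParams(*t))


class TestCensoringScheme:
    @pytest.mark.parametrize(
        "n, N1, N2, removals",
        [
            (40, 15, 15, (0,) * 11 + (1, 1, 2, 1) + (0,) * 11 + (1, 1, 2, 1)),
            (30, 1, 1, (28, 0)),
        ],
    )
    def test_valid_schemes_pass(self, n, N1, N2, removals):
        scheme = CensoringScheme(n, N1, N2, removals)
        assert validate_scheme(scheme) is scheme

    def test_accounting_violation_names_deficit(self):
        with pytest.raises(ValueError, match="deficit 6"):
            validate_scheme(CensoringScheme(10, 2, 2, (0, 0, 0, 0)))

    @pytest.mark.parametrize("N1, N2", [(0, 5), (5, 0)])
    def test_each_stage_needs_a_failure(self, N1, N2):
        with pytest.raises(ValueError, match="at least one failure"):
            validate_scheme(CensoringScheme(5, N1, N2, (0,) * (N1 + N2)))

    def test_negative_removals_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            validate_scheme(CensoringScheme(4, 2, 2, (-1, 1, 0, 0)))


class TestLifetimeDistribution:
    def test_cdf_at_origin_is_zero(self):
        assert lifetime_cdf(0.0, PARAMS, tau=1.0) == 0.0

    def test_cdf_closed_form_both_stages(self):
        # below tau the total hazard is 3; past tau the accumulated hazard is
        # 3*tau + 6*(t - tau)
        assert lifetime_cdf(1.0, PARAMS, tau=1.0) == pytest.approx(1 - math.exp(-3))
        assert lifetime_cdf(2.0, PARAMS, tau=1.0) == pytest.approx(1 - math.exp(-9))

    def test_cdf_matches_integrated_density(self):
        # independent oracle: numerically integrate the marginal density
        val, _ = integrate.quad(lambda u: lifetime_pdf(u, PARAMS, 1.0), 0, 2.0, points=[1.0])
        assert lifetime_cdf(2.0, PARAMS, tau=1.0) == pytest.approx(val, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            lifetime_cdf(-0.5, PARAMS, tau=1.0)

    @settings(max_examples=50, deadline=None)
    @given(params=four_rates, tau=st.floats(0.01, 5.0))
    def test_cdf_continuous_at_stress_change(self, params, tau):
        eps = 1e-12 * tau
        left = lifetime_cdf(tau - eps, params, tau)
        right = lifetime_cdf(tau + eps, params, tau)
        assert abs(left - right) < 1e-10


class TestCauseDensity:
    def test_substitution_below_tau(self):
        assert cause_density(0.5, 1, PARAMS, tau=1.0) == pytest.approx(2 * math.exp(-1.5))

    @settings(max_examples=50, deadline=None)
    @given(params=four_rates, t=st.floats(0.0, 10.0), tau=st.floats(0.01, 5.0))
    def test_cause_densities_sum_to_marginal(self, params, t, tau):
        total = cause_density(t, 1, params, tau) + cause_density(t, 2, params, tau)
        assert total == pytest.approx(lifetime_pdf(t, params, tau), rel=1e-12)

    def test_cause_probability_by_quadrature(self):
        # P(cause 1) = p1 F(tau) + p2 (1 - F(tau)) with stage-wise cause shares
        tau = 0.4
        below, _ = integrate.quad(lambda u: cause_density(u, 1, PARAMS, tau), 0, tau)
        above, _ = integrate.quad(lambda u: cause_density(u, 1, PARAMS, tau), tau, np.inf)
        val = below + above
        F_tau = lifetime_cdf(tau, PARAMS, tau)
        expected = PARAMS.cause_prob(1) * F_tau + PARAMS.cause_prob(2) * (1 - F_tau)
        assert val == pytest.approx(expected, rel=1e-8)

    def test_invalid_cause_rejected(self):
        with pytest.raises(ValueError, match="cause"):
            cause_density(0.5, 3, PARAMS, tau=1.0)


class TestCemShift:
    def test_no_stress_effect_gives_zero_shift(self):
        params = RateParams(2.0, 1.0, 2.0, 1.0)
        assert cem_shift(1, params, tau=1.0) == 0.0
        assert cem_shift(2, params, tau=1.0) == 0.0

    def test_substitution(self):
        assert cem_shift(1, PARAMS, tau=1.0) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(params=four_rates, tau=st.floats(0.01, 5.0), cause=st.sampled_from([1, 2]))
    def test_defining_identity(self, params, tau, cause):
        # F_1j(tau) = F_2j(tau - a_j) for the per-cause exponential CDFs
        a = cem_shift(cause, params, tau)
        l1, l2 = params[(1, cause)], params[(2, cause)]
        assert -math.expm1(-l1 * tau) == pytest.approx(
            -math.expm1(-l2 * (tau - a)), rel=1e-10
        )


class TestSufficientStats:
    def test_illustrative_dataset_matches_hand_summation(self, illustrative_stats):
        s = illustrative_stats
        assert s.counts == (4, 6, 5, 7)
        assert s.T1 == pytest.approx(1.18767, abs=1e-5)
        assert s.T21 == pytest.approx(2.45664, abs=1e-5)
        assert s.T22 == pytest.approx(3.44791, abs=1e-5)

    def test_two_failure_hand_example(self):
        data = StepStressDataset(
            scheme=CensoringScheme(2, 1, 1, (0, 0)), times=(1.0, 2.0), causes=(1, 2)
        )
        s = sufficient_stats(data)
        assert s.counts == (1, 0, 0, 1)
        assert (s.T1, s.T21, s.T22) == (1.0, 1.0, 1.0)

    def test_time_scaling_homogeneity(self, illustrative):
        s = sufficient_stats(illustrative)
        scaled = StepStressDataset(
            scheme=illustrative.scheme,
            times=tuple(10.0 * t for t in illustrative.times),
            causes=illustrative.causes,
        )
        s10 = sufficient_stats(scaled)
        assert s10.counts == s.counts
        for attr in ("T1", "T21", "T22"):
            assert getattr(s10, attr) == pytest.approx(10 * getattr(s, attr), rel=1e-12)

    def test_t21_identity(self, illustrative, illustrative_stats):
        # T21 / tau = N2 + sum of stage-2 removals, exactly
        scheme = illustrative.scheme
        expected = scheme.N2 + sum(scheme.removals[scheme.N1 :])
        assert illustrative_stats.T21 / illustrative.tau == pytest.approx(expected, rel=1e-12)

    def test_storage_order_invariance(self, illustrative, illustrative_stats):
        # reading the same records from any storage order, sorted by time,
        # reduces to identical statistics
        records = sorted(
            zip(illustrative.times, illustrative.causes, illustrative.scheme.removals),
            key=lambda r: -r[0],
        )
        records = sorted(records)
        rebuilt = StepStressDataset(
            scheme=CensoringScheme(
                illustrative.scheme.n,
                illustrative.scheme.N1,
                illustrative.scheme.N2,
                tuple(r[2] for r in records),
            ),
            times=tuple(r[0] for r in records),
            causes=tuple(r[1] for r in records),
        )
        assert sufficient_stats(rebuilt) == illustrative_stats

    def test_tau_is_last_stage1_failure(self, illustrative):
        assert illustrative.tau == illustrative.times[illustrative.scheme.N1 - 1]

    def test_tied_times_warn(self):
        with pytest.warns(UserWarning, match="tied"):
            StepStressDataset(
                scheme=CensoringScheme(2, 1, 1, (0, 0)), times=(1.0, 1.0), causes=(1, 2)
            )
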