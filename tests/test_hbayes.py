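"""Hierarchical posterior quadrature and importance resampling."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from stepstress import (
    HyperPrior,
    LossSpec,
    PARAM_KEYS,
    QuadratureSpec,
    SufficientStats,
    ebayes_estimate,
    hbayes_estimate,
    hbayes_sample,
    log_marginal_weight,
)


def stats_single(n, T):
    return SufficientStats(n, 1, 1, 1, T1=T / 2, T21=T / 2, T22=1.0)


class TestLogMarginalWeight:
    @pytest.mark.parametrize("alpha,beta,n,T", [(0.3, 0.1, 4, 3.6), (0.9, 0.02, 12, 8.0)])
    def test_matches_direct_lambda_integral(self, alpha, beta, n, T):
        # oracle: integrate prior-normalizer * lambda^(n+alpha-1) e^{-(beta+T)lambda}
        direct, _ = integrate.quad(
            lambda lam: math.exp(
                alpha * math.log(beta)
                - gammaln(alpha)
                + (n + alpha - 1) * math.log(lam)
                - (beta + T) * lam
            ),
            0,
            np.inf,
        )
        assert log_marginal_weight(alpha, beta, n, T) == pytest.approx(
            math.log(direct), abs=1e-10
        )

    def test_weight_ratios_match_integral_ratios(self):
        n, T = 6, 4.2
        pts = [(0.2, 0.05), (0.7, 0.15)]

        def direct(alpha, beta):
            v, _ = integrate.quad(
                lambda lam: lam ** (n + alpha - 1) * math.exp(-(beta + T) * lam),
                0,
                np.inf,
            )
            return math.log(v) + alpha * math.log(beta) - gammaln(alpha)

        lhs = log_marginal_weight(*pts[0], n, T) - log_marginal_weight(*pts[1], n, T)
        rhs = direct(*pts[0]) - direct(*pts[1])
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_log_space_never_overflows(self):
        val = log_marginal_weight(0.5, 0.1, 10_000, 1e6)
        assert np.isfinite(val)


LOSSES = [LossSpec("self"), LossSpec("elf"), LossSpec("linex", 4.0)]


class TestEstimate:
    def test_node_doubling_agreement(self, illustrative_stats):
        hyper = HyperPrior(0.2, "uniform")
        coarse = hbayes_estimate(
            illustrative_stats, hyper, quad=QuadratureSpec(64, 64, 1e-4)
        )
        fine = hbayes_estimate(
            illustrative_stats, hyper, quad=QuadratureSpec(128, 128, 1e-4)
        )
        for key in PARAM_KEYS:
            assert fine[key] == pytest.approx(coarse[key], rel=1e-8)

    @pytest.mark.parametrize("family", ["uniform", "linear"])
    @pytest.mark.parametrize("loss", LOSSES, ids=lambda lo: lo.loss)
    def test_matches_importance_sampling_oracle(self, family, loss):
        # self-normalized importance sampling against the hyperprior
        rng = np.random.default_rng(31)
        n, T, c = 5, 4.0, 0.3
        hyper = HyperPrior(c, family)
        est = hbayes_estimate(stats_single(n, T), hyper, loss)[(1, 1)]
        M = 400_000
        alpha, beta = hyper.sample_hyperparams(M, rng)
        logw = log_marginal_weight(alpha, beta, n, T)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        if loss.loss == "self":
            g = (n + alpha) / (beta + T)
            mean = float(np.sum(w * g))
            se = math.sqrt(float(np.sum(w**2 * (g - mean) ** 2)))
            assert abs(est - mean) < max(3 * se, 1e-8)
        elif loss.loss == "elf":
            g = (beta + T) / (n + alpha - 1)
            mean = float(np.sum(w * g))
            se = math.sqrt(float(np.sum(w**2 * (g - mean) ** 2)))
            assert abs(est - 1 / mean) < max(3 * se / mean**2, 1e-8)
        else:
            k = loss.k
            g = ((beta + T) / (beta + T + k)) ** (n + alpha)
            mean = float(np.sum(w * g))
            se = math.sqrt(float(np.sum(w**2 * (g - mean) ** 2)))
            assert abs(est - (-math.log(mean) / k)) < max(3 * se / (k * mean), 1e-8)

    def test_self_estimate_within_conditional_mean_range(self, illustrative_stats):
        hyper = HyperPrior(0.2, "uniform")
        est = hbayes_estimate(illustrative_stats, hyper)
        for i, j in PARAM_KEYS:
            n, T = illustrative_stats.count(i, j), illustrative_stats.exposure(i)
            assert n / (hyper.c + T) < est[(i, j)] < (n + 1) / T

    def test_small_c_limit_concentrates_at_flat_prior(self, illustrative_stats):
        # as c -> 0 the beta^alpha factor of the marginal likelihood puts all
        # hyperposterior mass at alpha -> 0, so the hierarchical SELF estimate
        # descends toward the no-prior-count limit n/T (unlike the E-Bayes
        # average, which stays at (n + 1/2)/T)
        n, T = illustrative_stats.n11, illustrative_stats.exposure(1)
        ests = [
            hbayes_estimate(illustrative_stats, HyperPrior(c, "uniform"))[(1, 1)]
            for c in (1e-2, 1e-4, 1e-8)
        ]
        assert all(a > b for a, b in zip(ests, ests[1:]))
        for e in ests:
            assert n / T < e < (n + 1) / T
        assert abs(ests[-1] - n / T) < abs(ests[0] - n / T) / 2

    def test_dialects_nearly_cancel_for_small_c(self, illustrative_stats):
        hyper = HyperPrior(0.2, "uniform")  # c = T/18 here
        a = hbayes_estimate(illustrative_stats, hyper, dialect="corrected")
        b = hbayes_estimate(illustrative_stats, hyper, dialect="paper_literal")
        for key in PARAM_KEYS:
            assert abs(a[key] - b[key]) / a[key] < 0.01

    def test_loss_ordering(self, illustrative_stats):
        hyper = HyperPrior(0.2, "linear")
        se = hbayes_estimate(illustrative_stats, hyper, LossSpec("self"))
        ee = hbayes_estimate(illustrative_stats, hyper, LossSpec("elf"))
        le = hbayes_estimate(illustrative_stats, hyper, LossSpec("linex", 4.0))
        for key in PARAM_KEYS:
            assert le[key] < se[key]
            assert ee[key] < se[key]

    def test_elf_undefined_without_failures(self):
        s = SufficientStats(0, 2, 1, 1, T1=1.0, T21=1.0, T22=1.0)
        est = hbayes_estimate(s, HyperPrior(0.2, "uniform"), LossSpec("elf"))
        assert est[(1, 1)] is None
        assert est[(1, 2)] is not None


class TestSampler:
    def test_mean_matches_quadrature(self, illustrative_stats):
        hyper = HyperPrior(0.2, "uniform")
        draws = hbayes_sample(illustrative_stats, hyper, N=100_000, seed=8)
        est = hbayes_estimate(illustrative_stats, hyper)
        for key in PARAM_KEYS:
            se = draws[key].std() / math.sqrt(draws[key].size)
            assert abs(draws[key].mean() - est[key]) < 4 * se

    def test_seed_reproducibility(self, illustrative_stats):
        hyper = HyperPrior(0.2, "linear")
        a = hbayes_sample(illustrative_stats, hyper, N=500, seed=2)
        b = hbayes_sample(illustrative_stats, hyper, N=500, seed=2)
        for key in PARAM_KEYS:
            assert np.array_equal(a[key], b[key])

    def test_hpd_no_wider_than_equal_tail(self, illustrative_stats):
        from stepstress import equal_tail_cri, hpd_interval

        hyper = HyperPrior(0.2, "uniform")
        draws = hbayes_sample(illustrative_stats, hyper, N=20_000, seed=3)
        for key in PARAM_KEYS:
            lo_h, hi_h = hpd_interval(draws[key], 0.95)
            lo_e, hi_e = equal_tail_cri(draws[key], 0.95)
            assert hi_h - lo_h <= hi_e - lo_e
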