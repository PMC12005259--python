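"""Tests of the analytic steady-state machinery.

Wherever a formula has an independent route (brute-force summation, numeric
integration, an algebraic identity), the test computes the expectation
through that route rather than through the function under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from driftbarrier import theory as th
from driftbarrier.model import ModelConfig, SiteTypeScheme


class TestNeutralDistribution:
    def test_fair_binomial(self):
        np.testing.assert_allclose(
            th.neutral_distribution(2, 1.0), [0.25, 0.5, 0.25], atol=1e-12
        )

    @given(L=st.integers(1, 60), beta=st.floats(0.01, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_normalized_with_neutral_mean(self, L, beta):
        p = th.neutral_distribution(L, beta)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)
        assert th.expected_mean_exact(p) == pytest.approx(
            L * beta / (1 + beta), rel=1e-9
        )


def _stationary_oracle(L, beta, Ne, s, theta_S):
    """Independent brute force: plain-Python term-by-term summation."""
    q = beta / (1.0 + beta)
    terms = []
    for z in range(L + 1):
        binom = math.comb(L, z) * q**z * (1 - q) ** (L - z)
        terms.append(binom * math.exp(-s * (z - theta_S) ** 2) ** (2 * Ne))
    total = sum(terms)
    return [t / total for t in terms]


class TestStationaryDistribution:
    def test_matches_bruteforce_oracle(self):
        got = th.stationary_distribution(4, 1.0, 100, 0.01, 2.0)
        np.testing.assert_allclose(got, _stationary_oracle(4, 1.0, 100, 0.01, 2.0),
                                   rtol=1e-10)

    def test_biased_case_matches_oracle(self):
        got = th.stationary_distribution(6, 0.33, 250, 0.004, 5.0)
        np.testing.assert_allclose(got, _stationary_oracle(6, 0.33, 250, 0.004, 5.0),
                                   rtol=1e-10)

    def test_no_selection_reduces_to_neutral(self):
        np.testing.assert_allclose(
            th.stationary_distribution(8, 0.4, 500, 0.0, 4.0),
            th.neutral_distribution(8, 0.4),
            rtol=1e-12,
        )

    def test_strong_selection_concentrates_on_optimum(self):
        p = th.stationary_distribution(10, 1.0, 10**7, 0.1, 7.0)
        assert p[7] == pytest.approx(1.0, abs=1e-6)

    def test_survives_extreme_exponents(self):
        # 2 Ne s up to 1e6 must not underflow the log-domain computation
        p = th.stationary_distribution(20, 0.5, 5 * 10**6, 0.1, 10.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)


class TestExpectedMeanExact:
    def test_symmetric_case_is_midpoint(self):
        p = th.stationary_distribution(6, 1.0, 200, 0.02, 3.0)
        assert th.expected_mean_exact(p) == pytest.approx(3.0, abs=1e-12)

    def test_biased_small_L_against_oracle(self):
        p = th.stationary_distribution(4, 0.5, 50, 0.02, 4.0)
        oracle = sum(z * w for z, w in enumerate(_stationary_oracle(4, 0.5, 50, 0.02, 4.0)))
        assert th.expected_mean_exact(p) == pytest.approx(oracle, rel=1e-10)


class TestKappaConventions:
    def test_unbiased_is_2NLs(self):
        assert th.kappa(1e4, 10, 1e-5, convention="unbiased") == pytest.approx(2.0)

    def test_biased_at_beta1_is_half_unbiased(self):
        # the documented factor-2 tension between the two printed pathways
        kb = th.kappa(1e4, 10, 1e-5, beta=1.0, convention="biased")
        ku = th.kappa(1e4, 10, 1e-5, beta=1.0, convention="unbiased")
        assert kb == pytest.approx(ku / 2)

    def test_zero_selection_gives_zero(self):
        for conv in ("biased", "unbiased"):
            assert th.kappa(1e4, 10, 0.0, convention=conv) == 0.0

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            th.kappa(1e4, 10, 1e-5, convention="other")


class TestGaussianApprox:
    def test_limits(self):
        assert th.gaussian_mean_approx(0.0, 7.0, 3.0) == 3.0
        assert th.gaussian_mean_approx(1e12, 7.0, 3.0) == pytest.approx(7.0)
        assert th.gaussian_mean_approx(1.0, 7.0, 3.0) == pytest.approx(5.0)
        assert th.gaussian_var_approx(0.0, 2.5) == 2.5
        assert th.gaussian_var_approx(1e12, 2.5) == pytest.approx(0.0, abs=1e-9)

    @given(
        Ne=st.floats(10, 1e6),
        L=st.integers(2, 1000),
        s=st.floats(1e-6, 0.1),
        beta=st.floats(0.05, 1.0),
        x=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_biased_kappa_reproduces_general_optimum_formulas(self, Ne, L, s, beta, x):
        """The Gaussian-approximation pathway with the biased kappa must agree
        identically with the printed general-optimum deviation and SD."""
        kb = th.kappa(Ne, L, s, beta, "biased")
        theta_N = L * beta / (1 + beta)
        mu = th.gaussian_mean_approx(kb, x * L, theta_N)
        var = th.gaussian_var_approx(kb, th.sigma_N_sq(L, beta))
        dev, sd = th.general_optimum_deviation(Ne, L, s, beta, x)
        assert x * L - mu == pytest.approx(dev, rel=1e-9, abs=1e-12)
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-9)


class TestMadPredictors:
    def test_weak_selection_direct_value(self):
        # 2NLs = 2 at N=1e4, L=10, s=1e-5
        assert th.mad_weak_selection(1e4, 10, 1e-5) == pytest.approx(
            math.sqrt(10 / (3 * math.pi)), rel=1e-12
        )

    def test_weak_selection_neutral_ceiling(self):
        assert th.mad_weak_selection(1e4, 10, 0.0) == pytest.approx(
            math.sqrt(10 / math.pi)
        )

    @pytest.mark.parametrize(
        "N,L,s", [(1e5, 100, 1e-3), (1e4, 1000, 1e-4), (1e6, 50, 1e-2)]
    )
    def test_weak_selection_large_NLs_limit(self, N, L, s):
        """Converges on (2 pi N s)^-1/2 with relative error below 1/(2NLs)."""
        full = th.mad_weak_selection(N, L, s)
        limit = (2 * math.pi * N * s) ** -0.5
        assert abs(full - limit) / limit < 1 / (2 * N * L * s)

    def test_segregating_direct_value(self):
        assert th.mad_segregating(1e-6, 100, 1e-3) == pytest.approx(0.2)
        assert th.mad_segregating(0.0, 100, 1e-3) == 0.0

    @given(u=st.floats(0, 1e-4), L=st.integers(1, 1000), s=st.floats(1e-5, 0.1))
    @settings(max_examples=40, deadline=None)
    def test_general_bias_form_reduces_at_beta1(self, u, L, s):
        assert th.mad_segregating(u, L, s, beta=1.0) == pytest.approx(
            2 * u * L / s, rel=1e-12, abs=1e-15
        )

    def test_blend_endpoints_and_midpoint(self):
        assert th.mad_blend(1.0, 0.2, 0, 1e-3, 10) == pytest.approx(1.0)
        assert th.mad_blend(1.0, 0.2, 1e9, 1e-3, 10) == pytest.approx(0.2)
        # 2Ns/L = 1
        assert th.mad_blend(1.0, 0.2, 500, 1e-3, 1) == pytest.approx(
            0.2 + 0.8 * math.exp(-1)
        )

    def test_free_recombination_benchmark(self):
        assert th.free_recombination_delta(1000, 0.01, 1.0) == pytest.approx(1 / 40)
        assert th.free_recombination_delta(1000, 0.01, 0.1) == pytest.approx(
            (1 + math.log(10)) / 40
        )
        betas = np.linspace(0.05, 1.0, 30)
        deltas = [th.free_recombination_delta(1000, 0.01, b) for b in betas]
        assert np.all(np.diff(deltas) < 0)


class TestHalfGaussianAndGeneralOptimum:
    def test_direct_evaluation(self):
        # L=100, beta=0.33, Ne*s=0.1
        got = th.halfgauss_mean_deviation(100, 100, 1e-3, 0.33)
        expected = 100 * 1.33 / (4 * 0.1 * 100 * 0.33 + 1.33**2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_bias_asymptote(self):
        # NesL >> 1: within 1% of 1/(2 Ne s)
        Ne, L, s = 1e5, 1000, 1e-3
        assert th.halfgauss_mean_deviation(Ne, L, s, 1.0) == pytest.approx(
            1 / (2 * Ne * s), rel=0.01
        )

    def test_strong_bias_asymptote(self):
        # beta << 1, NesLbeta >> 1: within 5% of 1/(4 Ne s beta)
        Ne, L, s, beta = 1e6, 10000, 1e-3, 0.01
        assert th.halfgauss_mean_deviation(Ne, L, s, beta) == pytest.approx(
            1 / (4 * Ne * s * beta), rel=0.05
        )

    @given(
        Ne=st.floats(10, 1e6),
        L=st.integers(2, 10000),
        s=st.floats(1e-6, 0.1),
        beta=st.floats(0.05, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_general_optimum_at_x1_equals_halfgauss(self, Ne, L, s, beta):
        dev, _ = th.general_optimum_deviation(Ne, L, s, beta, 1.0)
        assert dev == pytest.approx(
            th.halfgauss_mean_deviation(Ne, L, s, beta), rel=1e-12
        )

    def test_deviation_vanishes_at_neutral_optimum(self):
        beta = 0.4
        dev, _ = th.general_optimum_deviation(500, 100, 1e-3, beta, beta / (1 + beta))
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_sd_large_NesL_limit(self):
        Ne, L, s = 1e5, 10000, 1e-3
        _, sd = th.general_optimum_deviation(Ne, L, s, 1.0, 1.0)
        assert sd == pytest.approx((4 * Ne * s) ** -0.5, rel=0.01)

    def test_monotonicity_in_Nes_and_beta(self):
        devs = [th.halfgauss_mean_deviation(Ne, 1000, 1e-3, 0.5) for Ne in
                np.logspace(2, 6, 20)]
        assert np.all(np.diff(devs) < 0)
        # for fixed Nes and large L, deviation grows as beta decreases
        devs_b = [th.halfgauss_mean_deviation(1e4, 10000, 1e-3, b)
                  for b in (1.0, 0.5, 0.2, 0.1)]
        assert np.all(np.diff(devs_b) > 0)

    def test_halfgauss_blend_endpoints(self):
        # Ns -> infinity leaves only the segregating load L u10 / s
        assert th.halfgauss_mad_blend(99.0, 100, 1e-6, 1e-3, 1e9) == pytest.approx(0.1)
        # Ns = 0 gives the full fixation deficit L - mu
        assert th.halfgauss_mad_blend(99.0, 100, 1e-6, 1e-3, 0) == pytest.approx(1.0)
        # printed-style midpoint: Ns = 1
        assert th.halfgauss_mad_blend(99.0, 100, 1e-6, 1e-3, 1000) == pytest.approx(
            0.1 + 0.9 * math.exp(-2)
        )


class TestFoldedNormalMad:
    def test_central_case(self):
        assert th.folded_normal_mad(5.0, 2.0, 5.0) == pytest.approx(
            2.0 * math.sqrt(2 / math.pi)
        )

    def test_far_from_optimum_tends_to_abs_mean(self):
        assert th.folded_normal_mad(30.0, 1.0, 5.0) == pytest.approx(25.0, rel=1e-3)

    def test_against_numeric_integration(self):
        mu, sd, theta = 6.0, 1.0, 5.0
        oracle, _ = integrate.quad(
            lambda x: abs(x - theta) * stats.norm.pdf(x, mu, sd), -20, 40
        )
        assert th.folded_normal_mad(mu, sd, theta) == pytest.approx(oracle, rel=1e-8)
        assert oracle == pytest.approx(1.16663, abs=2e-5)

    @given(m=st.floats(-10, 10), sd=st.floats(0.01, 10))
    @settings(max_examples=60, deadline=None)
    def test_dominates_signed_deviation(self, m, sd):
        assert th.folded_normal_mad(5.0 + m, sd, 5.0) >= abs(m) - 1e-12

    def test_two_sd_switch_rule(self):
        # far from the optimum the signed deviation is used as-is; close in,
        # the folded-normal expectation takes over
        assert th.mad_from_gaussian(10.0, 1.0, 5.0) == 5.0
        near = th.mad_from_gaussian(5.5, 1.0, 5.0)
        assert near == pytest.approx(th.folded_normal_mad(5.5, 1.0, 5.0))
        assert near > 0.5
        # threshold is configurable
        assert th.mad_from_gaussian(7.0, 1.0, 5.0, overlap_threshold=3.0) == (
            pytest.approx(th.folded_normal_mad(7.0, 1.0, 5.0))
        )


class TestPhiEstimation:
    def _cfg(self, **kw):
        base = dict(N=1000, L=100, s=1e-2, theta_S=100.0, u10=1e-5, beta=0.33)
        base.update(kw)
        return ModelConfig(**base)

    @pytest.mark.parametrize("phi_true", [0.05, 0.37, 1.0, 2.0])
    def test_mean_method_round_trip(self, phi_true):
        cfg = self._cfg()
        dev, _ = th.general_optimum_deviation(
            phi_true * cfg.N, cfg.L, cfg.s, cfg.beta, 1.0
        )
        est = th.estimate_phi(dev, cfg, method="mean")
        assert est.phi == pytest.approx(phi_true, rel=1e-6)
        assert est.Ne == pytest.approx(phi_true * cfg.N, rel=1e-6)

    @pytest.mark.parametrize("phi_true", [0.2, 0.9, 1.5])
    def test_mad_method_round_trip(self, phi_true):
        cfg = self._cfg(L=10, s=1e-3, theta_S=5.0, beta=1.0)
        mad1 = th.mad_weak_selection(phi_true * cfg.N, cfg.L, cfg.s)
        mad2 = th.mad_segregating(cfg.u10, cfg.L, cfg.s)
        obs = th.mad_blend(mad1, mad2, cfg.N, cfg.s, cfg.L)
        est = th.estimate_phi(obs, cfg, method="mad")
        assert est.phi == pytest.approx(phi_true, rel=1e-6)

    def test_observation_outside_range_rejected(self):
        cfg = self._cfg()
        ceiling = cfg.L * (1 + cfg.beta) * (1 - cfg.beta / (1 + cfg.beta))
        with pytest.raises(ValueError, match="range"):
            th.estimate_phi(ceiling * 10, cfg, method="mean")

    def test_optimum_below_neutral_mean_rejected(self):
        cfg = self._cfg(theta_S=10.0)  # below theta_N ~ 24.8
        with pytest.raises(ValueError, match="neutral"):
            th.estimate_phi(0.5, cfg, method="mean")


class TestCompositeBiasParameter:
    def test_endpoint_and_exact_fraction(self):
        assert th.interference_bias_parameter(1.0) == 0.0
        assert th.interference_bias_parameter(1 / 3) == pytest.approx(1 / 8)

    def test_argmax_is_one_third(self):
        assert th.interference_bias_argmax() == pytest.approx(1 / 3, abs=1e-6)


class TestInterferenceEquivalence:
    def test_same_type_is_identity(self):
        assert th.interference_equivalent_sites(100, 1e-3, 1e-3) == 100

    def test_tenfold_ratio(self):
        assert th.interference_equivalent_sites(100, 1e-3, 1e-4) == pytest.approx(1.0)
        assert th.interference_equivalent_sites(3333, 1e-3, 1e-4) == pytest.approx(
            33.33
        )


class TestMultitypeComposition:
    SCHEME = SiteTypeScheme(classes=((33, 1e-3), (333, 1e-4), (3333, 1e-5)))

    def test_single_type_identity(self):
        one = SiteTypeScheme(classes=((50, 1e-3),))
        assert th.multitype_mad([0.7], one, "intermediate") == pytest.approx(0.7)

    def test_intermediate_uses_printed_weighting(self):
        a, b, c = 0.9, 2.4, 7.0
        assert th.multitype_mad([a, b, c], self.SCHEME, "intermediate") == (
            pytest.approx(a + b / 10 + c / 100)
        )

    def test_extreme_perfect_adaptation_is_zero(self):
        assert th.multitype_mad([0, 0, 0], self.SCHEME, "extreme") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_halfgauss_per_type_pipeline(self):
        # per-type deviations from the single-type machinery compose into a
        # positive total on the performance scale, and the reduced-intensity
        # switch (s_x/10) inflates each per-type deviation
        mads = th.multitype_halfgauss_mads(self.SCHEME, N=10_000, u10=1e-7,
                                           beta=0.5)
        assert len(mads) == 3 and all(m > 0 for m in mads)
        oracle = th.halfgauss_mean_deviation(10_000, 33, 1e-3, 0.5)
        oracle = th.halfgauss_mad_blend(33 - oracle, 33, 1e-7, 1e-3, 10_000)
        assert mads[0] == pytest.approx(oracle, rel=1e-12)
        reduced = th.multitype_halfgauss_mads(self.SCHEME, N=10_000, u10=1e-7,
                                              beta=0.5, reduced_intensity=True)
        assert all(r > m for r, m in zip(reduced, mads))
        total = th.multitype_mad(mads, self.SCHEME, "extreme")
        assert total > 0


class TestPredictBundle:
    def test_bundle_is_coherent(self):
        cfg = ModelConfig(N=2000, L=100, s=1e-3, theta_S=50.0, u10=1e-5, beta=0.5)
        pred = th.predict(cfg, phi=0.8)
        assert pred.stationary.sum() == pytest.approx(1.0, abs=1e-9)
        assert pred.theta_N == pytest.approx(100 / 3)
        assert pred.var_mean >= 0
        assert pred.sd_mean == pytest.approx(math.sqrt(pred.var_mean))
        assert pred.mad1 >= 0 and pred.mad2 >= 0
        assert 0 <= pred.mu_mean <= cfg.L
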