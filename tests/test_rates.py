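"""Analytic rates: fixation kernels, stationary density, alpha, r3, beta."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from compsub.model import make_parameters
from compsub.rates import (
    alpha_rate,
    beta_direct,
    compute_rates,
    expected_reversions,
    fix_prob_beneficial,
    fix_prob_deleterious,
    p_type2,
    rate_r1,
    rate_r2,
    rate_r3_r4,
    stationary_density,
    stationary_state_probs,
)
from ._oracles import exact_fixation_probability


class TestFixationProbabilities:
    def test_neutral_limit_is_one_over_two_N(self):
        p = make_parameters(200, 0.1, 0.0)
        assert fix_prob_deleterious(p) == pytest.approx(1 / 200, rel=1e-12)
        assert fix_prob_beneficial(p) == pytest.approx(1 / 200, rel=1e-12)

    def test_known_value_at_s_001(self):
        # expm1(0.02)/expm1(4), frozen from the verified closed form
        p = make_parameters(200, 0.1, 1.0)
        assert fix_prob_deleterious(p) == pytest.approx(3.7690e-4, rel=1e-4)

    def test_agrees_with_exact_chain_at_weak_selection(self):
        # the diffusion kernels against the 201-state chain (moderate s only;
        # the acceptance suite probes the full range)
        for s in (0.005, 0.01):
            p = make_parameters(200, 0.1, 100 * s)
            assert fix_prob_deleterious(p) == pytest.approx(
                exact_fixation_probability(200, 1 - s), rel=0.03
            )
            assert fix_prob_beneficial(p) == pytest.approx(
                exact_fixation_probability(200, 1 + p.t), rel=0.03
            )

    def test_deleterious_monotone_decreasing_in_s(self):
        vals = [fix_prob_deleterious(make_parameters(200, 0.1, Ns))
                for Ns in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_advantage_beats_disadvantage(self):
        p = make_parameters(200, 0.1, 1.0)
        assert fix_prob_beneficial(p) > 1 / 200 > fix_prob_deleterious(p)


class TestArrowRates:
    def test_neutral_rates_equal_mu(self):
        p = make_parameters(200, 0.1, 0.0)
        assert rate_r1(p) == pytest.approx(p.mu, rel=1e-12)
        assert rate_r2(p) == pytest.approx(p.mu, rel=1e-12)

    def test_zero_mutation_means_zero_rates(self):
        p = make_parameters(200, 0.0, 1.0)
        assert rate_r1(p) == 0.0
        assert rate_r2(p) == 0.0

    def test_r2_dominates_r1_under_selection(self):
        p = make_parameters(200, 0.1, 1.0)
        assert rate_r2(p) > rate_r1(p)
        assert rate_r1(p) == pytest.approx(0.05 * fix_prob_deleterious(p), rel=1e-12)
        assert rate_r2(p) == pytest.approx(0.05 * fix_prob_beneficial(p), rel=1e-12)


class TestStationaryDensity:
    def test_theta_zero_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            stationary_density(make_parameters(200, 0.0, 1.0))

    def test_neutral_density_symmetric(self):
        d = stationary_density(make_parameters(200, 0.25, 0.0))
        assert d.mean_x() == pytest.approx(0.5, abs=1e-10)

    def test_normalizes_to_one(self):
        d = stationary_density(make_parameters(200, 0.5, 0.0))
        assert d.expectation(lambda x: np.ones_like(x)) == pytest.approx(1.0, rel=1e-12)
        assert (d.weights > 0).all()

    def test_selection_depletes_deleterious_class(self):
        d = stationary_density(make_parameters(200, 0.1, 2.0))
        assert d.mean_x() < 0.5

    def test_printed_sign_piles_mass_on_deleterious_class(self):
        d = stationary_density(make_parameters(200, 0.1, 2.0), sign="printed")
        assert d.mean_x() > 0.5

    def test_doubling_nodes_is_stable_across_grid(self):
        for theta in (0.001, 0.01, 0.1, 1.0):
            for Ns in (0.0, 1.0, 2.0, 3.0):
                d = stationary_density(make_parameters(200, theta, Ns))
                assert d.convergence_delta < 1e-8


class TestAlpha:
    def test_neutral_alpha_is_half_mu(self):
        for theta in (0.01, 0.1, 0.5):
            p = make_parameters(200, theta, 0.0)
            assert alpha_rate(p) == pytest.approx(p.mu / 2, rel=1e-10)

    def test_zero_mutation_gives_zero(self):
        assert alpha_rate(make_parameters(200, 0.0, 1.0)) == 0.0

    def test_density_parameter_mismatch_rejected(self):
        d = stationary_density(make_parameters(200, 0.1, 1.0))
        with pytest.raises(ValueError, match="different parameters"):
            alpha_rate(make_parameters(200, 0.1, 2.0), density=d)

    def test_integrand_matches_paired_parameter_form(self):
        # the literal-kernel integrand written directly in population-scaled
        # form: x (1 - e^{-2s(2N(1-x)+1)}) / ((1 - e^{-4Ns}) (2N(1-x)+1))
        from compsub.rates import _p_ab_given_x

        p = make_parameters(200, 0.1, 2.0)
        x = np.linspace(0.01, 0.99, 23)
        direct = (
            x * (-np.expm1(-2 * p.s * (200 * (1 - x) + 1)))
            / ((-np.expm1(-4 * p.N * p.s)) * (200 * (1 - x) + 1))
        )
        np.testing.assert_allclose(
            x * _p_ab_given_x(p, x, kernel="literal"), direct, rtol=1e-12
        )

    def test_advantage_kernel_endpoint_equals_beneficial_fixation(self):
        # at x = 1 the new ab mutant sits on an all-deleterious background,
        # so its fixation probability is the beneficial kernel exactly
        from compsub.rates import _p_ab_given_x

        p = make_parameters(200, 0.1, 2.0)
        assert _p_ab_given_x(p, np.array([1.0]))[0] == pytest.approx(
            fix_prob_beneficial(p), rel=1e-12
        )


class TestStationaryStateProbs:
    def test_neutral_is_uniform(self):
        np.testing.assert_allclose(
            stationary_state_probs(make_parameters(200, 0.1, 0.0)), 0.25, rtol=1e-12
        )

    def test_strong_selection_concentrates_on_fit_states(self):
        pi = stationary_state_probs(make_parameters(200, 0.1, 3.0))
        assert pi[0] == pytest.approx(0.5, abs=1e-3)
        assert pi[1] < 1e-3

    def test_class_ratio_is_fixation_probability_ratio(self):
        p = make_parameters(200, 0.1, 1.0)
        pi = stationary_state_probs(p)
        assert (pi[1] + pi[2]) / (pi[0] + pi[3]) == pytest.approx(
            fix_prob_deleterious(p) / fix_prob_beneficial(p), rel=1e-12
        )

    def test_symmetry_and_normalization(self):
        pi = stationary_state_probs(make_parameters(200, 0.01, 2.0))
        assert pi[0] == pi[3] and pi[1] == pi[2]
        assert pi.sum() == pytest.approx(1.0, rel=1e-14)

    def test_zero_mutation_rejected(self):
        with pytest.raises(ValueError):
            stationary_state_probs(make_parameters(200, 0.0, 1.0))


class TestDirectRates:
    def test_neutral_direct_rate_vanishes(self):
        p = make_parameters(200, 0.1, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs = compute_rates(p)
        assert abs(rs.r3) <= 1e-10 * p.mu
        assert rs.beta == 0.0

    def test_zero_flux_arithmetic(self):
        pi = np.array([0.25, 0.25, 0.25, 0.25])
        p = make_parameters(200, 0.1, 0.0)
        assert rate_r3_r4(p, alpha=0.0, pi=pi, r2=0.0) == (0.0, 0.0)

    def test_r3_equals_r4(self):
        rs = compute_rates(make_parameters(200, 0.1, 3.0))
        assert rs.r3 == rs.r4
        assert rs.r3 > 0

    def test_substantially_negative_flux_raises(self):
        p = make_parameters(200, 0.1, 1.0)
        pi = np.array([0.4, 0.1, 0.1, 0.4])
        with pytest.raises(RuntimeError, match="negative direct rate"):
            rate_r3_r4(p, alpha=1e-6, pi=pi, r2=1e-4)

    def test_conditioned_and_per_state_denominators(self):
        p = make_parameters(200, 0.01, 2.0)
        rs_c = compute_rates(p)
        rs_p = compute_rates(p, r3_denominator="per_state")
        pi = rs_c.pi
        assert rs_p.r3 == pytest.approx(rs_c.r3 * (pi[0] + pi[3]) / pi[0], rel=1e-12)

    def test_flux_reassembly_identities(self):
        # alpha recovered exactly from (pi, r2, r3) in each convention
        for theta, Ns in [(0.01, 1.0), (0.1, 2.0), (1.0, 3.0)]:
            p = make_parameters(200, theta, Ns)
            rs_c = compute_rates(p)
            pi = rs_c.pi
            back_c = (pi[1] + pi[2]) * rs_c.r2 + (pi[0] + pi[3]) * rs_c.r3
            assert back_c == pytest.approx(rs_c.alpha, rel=1e-12)
            rs_p = compute_rates(p, r3_denominator="per_state")
            back_p = (pi[1] + pi[2]) * rs_p.r2 + pi[0] * rs_p.r3
            assert back_p == pytest.approx(rs_p.alpha, rel=1e-12)


class TestPathwayQuantities:
    @pytest.mark.parametrize("beta, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)])
    def test_p_type2_arithmetic(self, beta, expected):
        assert p_type2(beta) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("beta, expected", [(0.0, 1.0), (1.0, 0.0), (0.5, 1 / 3)])
    def test_expected_reversions_arithmetic(self, beta, expected):
        assert expected_reversions(beta) == pytest.approx(expected, rel=1e-14)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_bounds_and_monotonicity(self, beta):
        assert 0.0 <= p_type2(beta) <= 1.0
        assert 0.0 <= expected_reversions(beta) <= 1.0
        eps = 1e-6
        if beta + eps <= 1.0:
            assert p_type2(beta + eps) >= p_type2(beta)
            assert expected_reversions(beta + eps) <= expected_reversions(beta)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_out_of_range_beta_rejected(self, bad):
        with pytest.raises(ValueError):
            p_type2(bad)
        with pytest.raises(ValueError):
            expected_reversions(bad)

    def test_beta_monotone_in_selection_over_grid(self):
        for theta in (0.01, 0.1):
            betas = [beta_direct(make_parameters(200, theta, Ns))
                     for Ns in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)]
            assert all(b2 >= b1 for b1, b2 in zip(betas, betas[1:]))

    def test_compute_rates_requires_theta(self):
        with pytest.raises(ValueError):
            compute_rates(make_parameters(200, 0.0, 1.0))


class TestNeutralClosure:
    """At s = 0 every pathway quantity collapses to its neutral value."""

    @pytest.mark.parametrize("theta", [0.01, 0.1])
    def test_closure(self, theta):
        p = make_parameters(200, theta, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rs = compute_rates(p)
        mu = p.mu
        assert rs.r1 == pytest.approx(mu, rel=1e-10)
        assert rs.r2 == pytest.approx(mu, rel=1e-10)
        assert rs.alpha == pytest.approx(mu / 2, rel=1e-10)
        assert abs(rs.r3) <= 1e-10 * mu
        assert abs(rs.r4) <= 1e-10 * mu
        assert rs.beta == pytest.approx(0.0, abs=1e-10)
        assert rs.p_type2 == pytest.approx(0.0, abs=1e-10)
        assert rs.expected_reversions == pytest.approx(1.0, rel=1e-10)
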