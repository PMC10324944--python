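"""Constant-size Ewens-type formulas: exact values, oracles, asymptotics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import gammaln

from latentmut import ewens
from latentmut.ewens import (
    MutationModel,
    SampleCounts,
    augmented_error,
    augmented_error_coefficient,
    augmented_root_model,
    k_allele_ordered_prob,
    k_allele_unordered_prob,
    large_n_sampling_approx,
    latent_mutation_pmf,
    log_rising,
    log_stirling1,
    stirling1_unsigned,
    two_allele_sampling_pmf,
)


class TestStirling:
    @pytest.mark.parametrize(
        "n,k,expected", [(1, 1, 1), (3, 2, 3), (4, 2, 11), (0, 0, 1), (5, 1, 24)]
    )
    def test_known_values(self, n, k, expected):
        assert stirling1_unsigned(n, k) == expected

    def test_against_sympy(self):
        """Independent oracle: sympy's signed/unsigned Stirling numbers."""
        from sympy.functions.combinatorial.numbers import stirling

        for n in (2, 7, 15, 30):
            for k in range(0, n + 1):
                assert stirling1_unsigned(n, k) == stirling(
                    n, k, kind=1, signed=False
                )

    def test_row_sum_is_factorial(self):
        # sum_k |S(n,k)| = n! (total permutations)
        for n in (5, 20, 100):
            assert sum(stirling1_unsigned(n, k) for k in range(n + 1)) == math.factorial(n)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            stirling1_unsigned(3, 4)
        with pytest.raises(ValueError):
            stirling1_unsigned(-1, 0)

    def test_log_accessor_matches_exact(self):
        for n, k in [(10, 3), (40, 7), (300, 40)]:
            assert log_stirling1(n, k) == pytest.approx(
                _log_of_int(stirling1_unsigned(n, k)), rel=1e-12
            )


def _log_of_int(v: int) -> float:
    shift = max(0, v.bit_length() - 60)
    return math.log(v >> shift) + shift * math.log(2.0)


class TestLatentMutationPMF:
    def test_single_copy_forces_one_mutation(self):
        d = latent_mutation_pmf(1, 0.7)
        assert d.as_dict() == {1: 1.0}

    def test_two_copies_closed_form(self):
        # P(k=1) = 1/(1+theta1), P(k=2) = theta1/(1+theta1)
        d = latent_mutation_pmf(2, 0.2)
        assert d.pmf[0] == pytest.approx(5 / 6, abs=1e-12)
        assert d.pmf[1] == pytest.approx(1 / 6, abs=1e-12)

    def test_small_theta_limit_single_mutation(self):
        d = latent_mutation_pmf(3, 1e-10)
        assert d.pmf[0] == pytest.approx(1.0, abs=1e-8)

    def test_zero_count_convention(self):
        d = latent_mutation_pmf(0, 0.5)
        assert d.as_dict() == {0: 1.0}

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            latent_mutation_pmf(3, 0.0)

    @given(
        n1=st.integers(min_value=1, max_value=200),
        theta1=st.floats(min_value=1e-6, max_value=10.0),
    )
    def test_normalization(self, n1, theta1):
        d = latent_mutation_pmf(n1, theta1)
        assert abs(d.pmf.sum() - 1.0) < 1e-12

    def test_conditional_equals_joint_over_marginal(self):
        # P(k1|n1) must equal [|S| theta^k / n1!] / [theta^(n1) / n1!]
        n1, t1 = 12, 0.35
        d = latent_mutation_pmf(n1, t1)
        joint = np.array(
            [
                math.exp(log_stirling1(n1, k) + k * math.log(t1) - gammaln(n1 + 1))
                for k in range(1, n1 + 1)
            ]
        )
        marg = math.exp(float(log_rising(t1, n1)) - gammaln(n1 + 1))
        np.testing.assert_allclose(d.pmf, joint / marg, rtol=1e-10)

    @pytest.mark.parametrize("n1", [2, 5, 10])
    @pytest.mark.parametrize("theta1", [0.02, 0.2, 2.0])
    def test_monte_carlo_bernoulli_chain(self, n1, theta1):
        """MC oracle: k1 is a sum of Bernoullis with probs theta/(theta+j-1)."""
        reps = 100_000
        rng = np.random.default_rng(1234 + n1)
        k = np.zeros(reps, dtype=int)
        for j in range(n1, 0, -1):
            k += rng.random(reps) < theta1 / (theta1 + j - 1)
        d = latent_mutation_pmf(n1, theta1)
        for kk, p in d.as_dict().items():
            emp = np.mean(k == kk)
            se = math.sqrt(max(p * (1 - p), 1e-12) / reps)
            assert abs(emp - p) < 3 * se + 1e-9


class TestTwoAlleleSampling:
    def test_n2_closed_form(self):
        m = MutationModel(theta=1.0, pis=(0.5, 0.5))
        p = two_allele_sampling_pmf(2, m)
        np.testing.assert_allclose(p, [0.375, 0.25, 0.375], atol=1e-12)

    @pytest.mark.parametrize("n", [1, 10, 100, 500])
    def test_normalization(self, n):
        m = MutationModel(theta=0.7, pis=(0.3, 0.7))
        assert two_allele_sampling_pmf(n, m).sum() == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_under_pi_swap(self):
        m = MutationModel(theta=0.05, pis=(0.5, 0.5))
        p = two_allele_sampling_pmf(100, m)
        np.testing.assert_allclose(p, p[::-1], rtol=1e-9)

    def test_polymorphic_conditioning(self):
        m = MutationModel(theta=0.01, pis=(0.9, 0.1))
        p = two_allele_sampling_pmf(50, m, condition_polymorphic=True)
        assert p[0] == 0.0 and p[-1] == 0.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_theta_spectrum_shape(self):
        # p(n1)/p(n1+1) -> (n1+1)/n1 for small counts (1/n1 spectrum)
        m = MutationModel(theta=1e-4, pis=(0.5, 0.5))
        p = two_allele_sampling_pmf(1000, m)
        for n1 in (1, 2, 3):
            assert p[n1] / p[n1 + 1] == pytest.approx((n1 + 1) / n1, rel=2e-3)

    def test_small_theta_two_spectra_mixture(self):
        # p(n1;n) = pi2 t1/n1 + pi1 t2/(n-n1) + O(theta^2)
        theta = 1e-4
        m = MutationModel(theta=theta, pis=(0.3, 0.7))
        n = 200
        p = two_allele_sampling_pmf(n, m)
        t1, t2 = m.thetas
        for n1 in range(1, n):
            lead = 0.7 * t1 / n1 + 0.3 * t2 / (n - n1)
            assert p[n1] / lead == pytest.approx(1.0, abs=5 * theta)

    def test_requires_two_alleles(self):
        m = MutationModel(theta=0.5, pis=(0.3, 0.3, 0.4))
        with pytest.raises(ValueError):
            two_allele_sampling_pmf(5, m)


class TestKAllele:
    def test_reduces_to_two_allele(self):
        m = MutationModel(theta=0.8, pis=(0.4, 0.6))
        p2 = two_allele_sampling_pmf(6, m)
        for n1 in range(7):
            c = SampleCounts((n1, 6 - n1))
            assert k_allele_unordered_prob(c, m) == pytest.approx(p2[n1], rel=1e-10)

    def test_single_draw_is_pi(self):
        m = MutationModel(theta=0.5, pis=(0.2, 0.3, 0.5))
        for j in range(3):
            counts = [0, 0, 0]
            counts[j] = 1
            assert k_allele_ordered_prob(SampleCounts(tuple(counts)), m) == pytest.approx(
                m.pis[j], rel=1e-12
            )

    def test_dirichlet_moment_oracle(self):
        """The sampling probability is a Dirichlet moment; check by MC."""
        m = MutationModel(theta=0.3, pis=(1 / 3, 1 / 3, 1 / 3))
        c = SampleCounts((1, 1, 1))
        exact = k_allele_unordered_prob(c, m)
        rng = np.random.default_rng(7)
        X = rng.dirichlet(m.thetas, size=400_000)
        draws = math.factorial(3) * X[:, 0] * X[:, 1] * X[:, 2]
        mc = draws.mean()
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(mc - exact) < 4 * se

    def test_dimension_mismatch(self):
        m = MutationModel(theta=0.5, pis=(0.5, 0.5))
        with pytest.raises(ValueError):
            k_allele_ordered_prob(SampleCounts((1, 1, 1)), m)


class TestLargeNApprox:
    def test_ratio_tends_to_one(self):
        m = MutationModel(theta=0.001, pis=(0.5, 0.5))
        exact = two_allele_sampling_pmf(10**6, m)[3]
        approx = large_n_sampling_approx(3, 10**6, m)
        assert exact / approx == pytest.approx(1.0, abs=1e-4)

    def test_limit_ratio_is_pi2_to_leading_order(self):
        # exp(t1*gamma) Gamma(theta)/Gamma(t2) = pi2 + O(theta^2)
        for theta in (1e-3, 1e-2):
            m = MutationModel(theta=theta, pis=(0.4, 0.6))
            t1, t2 = m.thetas
            val = math.exp(
                t1 * ewens.EULER_GAMMA + gammaln(theta) - gammaln(t2)
            )
            assert abs(val - 0.6) < 5 * theta**2

    def test_small_theta_infinite_sites_form(self):
        # leading order pi2 * theta1 / n1: the 1/n1 spectrum for mutants of
        # allele 1 arising in an allele-2 background
        m = MutationModel(theta=1e-6, pis=(0.5, 0.5))
        t1 = m.thetas[0]
        pi2 = m.pis[1]
        for n1 in (1, 2, 5):
            approx = large_n_sampling_approx(n1, 10**5, m)
            assert approx / (pi2 * t1 / n1) == pytest.approx(1.0, abs=1e-3)


class TestAugmentedRootModel:
    def test_r1_reduces_to_pi2_times_poisson_form(self):
        m = MutationModel(theta=0.3, pis=(0.4, 0.6))
        t1 = m.thetas[0]
        n, n1 = 100, 5
        H = sum(1 / i for i in range(1, n))
        poisson_form = math.exp(
            float(log_rising(t1, n1)) - gammaln(n1 + 1) - t1 * H
        )
        assert augmented_root_model(1, n1, n, m) == pytest.approx(
            0.6 * poisson_form, rel=1e-10
        )

    def test_error_reduction_r2_vs_r1(self):
        ratio = 1 - augmented_error_coefficient(2, 0.4) / augmented_error_coefficient(
            1, 0.4
        )
        # psi'(2)/psi'(1) = (pi^2/6 - 1)/(pi^2/6): about a 60% error cut
        assert ratio == pytest.approx(0.6079, abs=1e-3)

    def test_large_r_error_expansion(self):
        # error -> 1 + (2-pi1) pi1 theta^2 / (2 r)
        theta, pi1 = 0.1, 0.4
        m = MutationModel(theta=theta, pis=(pi1, 1 - pi1))
        for r in (50, 200):
            expected = 1.0 + (2 - pi1) * pi1 * theta**2 / (2 * r)
            assert augmented_error(r, m) == pytest.approx(expected, abs=2e-3 / r)

    def test_error_approaches_one_in_r(self):
        m = MutationModel(theta=0.2, pis=(0.5, 0.5))
        errs = [abs(augmented_error(r, m) - 1.0) for r in (1, 2, 5, 20)]
        assert errs == sorted(errs, reverse=True)

    def test_small_theta_quadratic_error(self):
        # error - 1 ~ coeff * theta^2 for small theta
        pi1 = 0.3
        for r in (1, 2):
            theta = 1e-3
            m = MutationModel(theta=theta, pis=(pi1, 1 - pi1))
            coeff = augmented_error_coefficient(r, pi1)
            assert (augmented_error(r, m) - 1.0) / theta**2 == pytest.approx(
                coeff, rel=5e-2
            )

    def test_domain(self):
        m = MutationModel(theta=0.2, pis=(0.5, 0.5))
        with pytest.raises(ValueError):
            augmented_root_model(10, 2, 10, m)


class TestModelValidation:
    def test_pis_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MutationModel(theta=1.0, pis=(0.5, 0.6))

    def test_theta_positive(self):
        with pytest.raises(ValueError):
            MutationModel(theta=-1.0, pis=(0.5, 0.5))

    def test_counts_nonnegative(self):
        with pytest.raises(ValueError):
            SampleCounts((1, -2))
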