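import math
from fractions import Fraction

import numpy as np
import pytest

from chromoran import (
    FitnessScheme,
    HeterogeneityParams,
    fitness_from_heterogeneity,
    fixation_directed,
    fixation_from_state,
    fixation_star,
    fixation_symmetric,
    fixation_uniform,
    selection_condition,
    zeta_biregular,
    zeta_directed,
)

from conftest import random_scheme


def two_node_first_step(a_G, a_R, b_G, b_R):
    """Independent first-step oracle for K_{1,1} (exact rationals).

    From a single mutant on the green node the process either fixes
    (mutant reproduces, probability a_G / (a_G + b_R)) or goes extinct;
    likewise from the red node.  The uniform single-mutant average is
    the mean of the two.
    """
    from_green = Fraction(a_G, a_G + b_R)
    from_red = Fraction(a_R, a_R + b_G)
    return Fraction(1, 2) * (from_green + from_red)


class TestFitnessFromHeterogeneity:
    def test_zero_offsets_give_flat_fitness(self):
        h = HeterogeneityParams(1.5, 1.0, 0.0, 0.0, 3, 5)
        f = fitness_from_heterogeneity(h)
        assert (f.a_G, f.a_R, f.b_G, f.b_R) == (1.5, 1.5, 1.0, 1.0)

    def test_equal_counts_reduce_to_plus_minus(self):
        h = HeterogeneityParams(1.0, 1.0, 0.3, 0.3, 4, 4)
        f = fitness_from_heterogeneity(h)
        assert (f.a_G, f.a_R, f.b_G, f.b_R) == (1.3, 0.7, 1.3, 0.7)

    def test_asymmetric_counts_scale_red_offset(self):
        f = fitness_from_heterogeneity(HeterogeneityParams(1.5, 1.0, 1.0, 0.0, 1, 3))
        assert f.a_G == 2.5
        assert f.a_R == pytest.approx(1.5 - 1 / 3)
        # round trip: the population mean is preserved
        assert (1 * f.a_G + 3 * f.a_R) / 4 == pytest.approx(1.5)

    def test_nonpositive_induced_fitness_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            fitness_from_heterogeneity(HeterogeneityParams(1.5, 1.0, 1.0, 1.0, 3, 1))


class TestZetas:
    def test_neutral_scheme_gives_unit_zetas(self):
        z = zeta_biregular(FitnessScheme.neutral(), 3, 3)
        assert z.zeta_G == pytest.approx(1.0) and z.zeta_R == pytest.approx(1.0)

    def test_two_node_values(self):
        z = zeta_biregular(FitnessScheme(2, 1, 1, 1), 1, 1)
        assert z.zeta_G == pytest.approx(2 / 3)
        assert z.zeta_R == pytest.approx(3 / 4)

    def test_product_identity_random_schemes(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            f = random_scheme(rng)
            k_G, k_R = rng.integers(1, 9, size=2)
            z = zeta_biregular(f, k_G, k_R)
            assert z.zeta_G * z.zeta_R == pytest.approx(
                (f.b_G * f.b_R) / (f.a_G * f.a_R), rel=1e-12
            )

    def test_directed_reduces_to_biregular_on_random_walk_weights(self):
        # K_{2,4} random-walk weighted: w_G_out = w_R_out = 1,
        # w_G_in = k_G / k_R, w_R_in = k_R / k_G
        rng = np.random.default_rng(7)
        for _ in range(20):
            f = random_scheme(rng)
            zb = zeta_biregular(f, 4, 2)
            zd = zeta_directed(f, 4 / 2, 1.0, 2 / 4, 1.0)
            assert zd.zeta_G == pytest.approx(zb.zeta_G, abs=1e-12)
            assert zd.zeta_R == pytest.approx(zb.zeta_R, abs=1e-12)

    def test_directed_solves_defining_linear_system(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = random_scheme(rng)
            wGi, wGo, wRi, wRo = rng.uniform(0.3, 3.0, size=4)
            z = zeta_directed(f, wGi, wGo, wRi, wRo)
            res1 = f.b_R * (1 / z.zeta_G - 1) * wGi + f.a_G * (z.zeta_R - 1) * wGo
            res2 = f.b_G * (1 / z.zeta_R - 1) * wRi + f.a_R * (z.zeta_G - 1) * wRo
            assert abs(res1) < 1e-12 and abs(res2) < 1e-12

    def test_zeta_deviation_sign_matches_selection(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            f = random_scheme(rng)
            z = zeta_biregular(f, 2, 5)
            sign = np.sign(f.a_G * f.a_R - f.b_G * f.b_R)
            assert np.sign(1 - z.zeta_G) == sign == np.sign(1 - z.zeta_R)


class TestFixationFromState:
    def test_absorbing_endpoints(self):
        z = zeta_biregular(FitnessScheme(2, 1, 1, 1), 1, 1)
        colors = np.array(["G", "R"])
        assert fixation_from_state([1, 1], z, colors) == pytest.approx(1.0)
        assert fixation_from_state([0, 0], z, colors) == pytest.approx(0.0)

    def test_single_mutant_average_matches_first_step_oracle(self):
        f = FitnessScheme(2, 1, 1, 1)
        z = zeta_biregular(f, 1, 1)
        colors = np.array(["G", "R"])
        mean = 0.5 * (
            fixation_from_state([1, 0], z, colors)
            + fixation_from_state([0, 1], z, colors)
        )
        assert mean == pytest.approx(float(two_node_first_step(2, 1, 1, 1)), abs=1e-12)

    def test_neutral_limit_uses_count_fraction(self):
        z = zeta_biregular(FitnessScheme.neutral(), 2, 2)
        colors = np.array(["G", "R", "G", "R"])
        assert fixation_from_state([1, 0, 1, 0], z, colors) == pytest.approx(0.5)


class TestFixationUniform:
    def test_neutral_is_one_over_n(self, biregular_suite):
        f = FitnessScheme.neutral()
        for _name, g, (N_G, N_R, k_G, k_R) in biregular_suite:
            res = fixation_uniform(N_G, N_R, k_G, k_R, f)
            assert res.rho_A == pytest.approx(1 / (N_G + N_R), abs=1e-15)

    def test_colorblind_scheme_recovers_classical_moran(self):
        r, N = 1.4, 12
        f = FitnessScheme(r, r, 1, 1)
        res = fixation_uniform(N // 2, N // 2, 3, 3, f)
        assert res.rho_A == pytest.approx((1 - 1 / r) / (1 - r**-N), rel=1e-12)

    def test_two_node_oracle(self):
        res = fixation_uniform(1, 1, 1, 1, FitnessScheme(2, 1, 1, 1))
        assert res.rho_A == pytest.approx(7 / 12, abs=1e-12)
        assert res.rho_B == pytest.approx(5 / 12, abs=1e-12)
        assert res.rho_A + res.rho_B == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_degrees_rejected(self):
        with pytest.raises(ValueError, match="N_G\\*k_G"):
            fixation_uniform(3, 3, 2, 5, FitnessScheme(2, 1, 1, 1))

    def test_rho_B_role_swap_matches_printed_formula(self):
        # independent transcription of the mean-B fixation probability
        rng = np.random.default_rng(19)
        for _ in range(50):
            f = random_scheme(rng)
            N_G, N_R, k_G, k_R = 2, 4, 4, 2
            zG = (f.a_R * (f.b_R * k_G + f.a_G * k_R)) / (
                f.b_R * (f.b_G * k_R + f.a_R * k_G)
            )
            zR = (f.a_G * (f.b_G * k_R + f.a_R * k_G)) / (
                f.b_G * (f.b_R * k_G + f.a_G * k_R)
            )
            N = N_G + N_R
            num = 1 - (N_G * zG + N_R * zR) / N
            den = 1 - zG**N_G * zR**N_R
            expected = num / den if abs(den) > 1e-12 else 1 / N
            res = fixation_uniform(N_G, N_R, k_G, k_R, f)
            assert res.rho_B == pytest.approx(expected, rel=1e-10)

    def test_large_population_no_overflow(self):
        # N = 200 with a disadvantageous mutant: zeta^N would overflow
        res = fixation_uniform(100, 100, 4, 4, FitnessScheme(0.5, 0.5, 1, 1))
        assert 0.0 <= res.rho_A < 1e-30
        assert res.rho_B > 0.4


class TestFixationStar:
    def test_two_node_neutral(self):
        assert fixation_star(2, FitnessScheme.neutral()).rho_A == pytest.approx(0.5)

    def test_two_node_oracle(self):
        res = fixation_star(2, FitnessScheme(2, 1, 1, 1))
        assert res.rho_A == pytest.approx(7 / 12, abs=1e-12)

    def test_specializes_the_uniform_formula(self):
        rng = np.random.default_rng(23)
        for N in range(2, 13):
            f = random_scheme(rng)
            star = fixation_star(N, f)
            uni = fixation_uniform(N - 1, 1, 1, N - 1, f)
            assert star.rho_A == pytest.approx(uni.rho_A, abs=1e-14)


class TestFixationSymmetric:
    def test_sigma_zero_recovers_classical_moran(self):
        for N, r in [(10, 1.2), (6, 0.8), (20, 2.0)]:
            rho = fixation_symmetric(N, r, 0.0).rho_A
            assert rho == pytest.approx((1 - 1 / r) / (1 - r**-N), rel=1e-12)

    def test_neutral_mutant_independent_of_sigma(self):
        for sigma in [0.0, 0.3, 0.7, 0.9]:
            assert fixation_symmetric(10, 1.0, sigma).rho_A == pytest.approx(0.1)

    def test_monotonic_in_sigma(self):
        grid = np.arange(0.0, 0.75, 0.05)
        rising = [fixation_symmetric(10, 1.2, s).rho_A for s in grid]
        falling = [fixation_symmetric(10, 0.8, s).rho_A for s in grid]
        assert np.all(np.diff(rising) > 0)
        assert np.all(np.diff(falling) < 0)

    def test_agrees_with_uniform_formula(self):
        for N, r, sigma in [(8, 1.3, 0.4), (14, 0.9, 0.5), (10, 1.7, 0.8)]:
            direct = fixation_symmetric(N, r, sigma).rho_A
            via_table = fixation_uniform(
                N // 2, N // 2, 2, 2, FitnessScheme.from_sigma(r, sigma)
            ).rho_A
            assert direct == pytest.approx(via_table, rel=1e-12)

    def test_infeasible_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            fixation_symmetric(10, 1.2, 1.0)


class TestSelectionCondition:
    def test_equal_products_are_neutral_with_drift_probability(self):
        f = FitnessScheme(2.0, 0.5, 1.0, 1.0)  # a_G a_R = b_G b_R = 1
        assert selection_condition(f) == "neutral"
        assert fixation_uniform(3, 3, 3, 3, f).rho_A == pytest.approx(1 / 6)

    def test_heterogeneity_neutrality_curve(self):
        # r^2 - sigma_A^2 = 1 - sigma_B^2 makes A neutral relative to B
        r, sigma_B = 1.1, 0.6
        sigma_A = math.sqrt(r**2 - 1 + sigma_B**2)
        f = FitnessScheme(r + sigma_A, r - sigma_A, 1 + sigma_B, 1 - sigma_B)
        assert selection_condition(f) == "neutral"

    def test_favored_mutant_beats_drift_on_k22(self):
        f = FitnessScheme(2, 1, 1, 1)
        assert selection_condition(f) == "favors_A"
        res = fixation_uniform(2, 2, 2, 2, f)
        assert res.rho_A > 1 / 4 > res.rho_B

    def test_geometric_mean_identity_random_draws(self):
        # the per-color numerator/denominator differences factor through
        # the product gap a_G a_R - b_G b_R
        rng = np.random.default_rng(5)
        for _ in range(100):
            f = random_scheme(rng)
            k_G, k_R = rng.integers(1, 7, size=2)
            gap = f.a_G * f.a_R - f.b_G * f.b_R
            lhs1 = f.a_R * (f.a_G * k_R + f.b_R * k_G) - f.b_R * (
                f.a_R * k_G + f.b_G * k_R
            )
            lhs2 = f.a_G * (f.a_R * k_G + f.b_G * k_R) - f.b_G * (
                f.a_G * k_R + f.b_R * k_G
            )
            assert lhs1 == pytest.approx(k_R * gap, rel=1e-12, abs=1e-12)
            assert lhs2 == pytest.approx(k_G * gap, rel=1e-12, abs=1e-12)


class TestDirected:
    def test_neutral_directed_is_one_over_n(self):
        res = fixation_directed(2, 4, 2.0, 1.0, 0.5, 1.0, FitnessScheme.neutral())
        assert res.rho_A == pytest.approx(1 / 6)

    def test_agrees_with_uniform_on_random_walk_weighted_star(self):
        rng = np.random.default_rng(31)
        N = 5
        for _ in range(20):
            f = random_scheme(rng)
            # leaves: out 1, in 1/(N-1); center: out 1, in N-1
            res_d = fixation_directed(N - 1, 1, 1 / (N - 1), 1.0, N - 1, 1.0, f)
            res_u = fixation_star(N, f)
            assert res_d.rho_A == pytest.approx(res_u.rho_A, abs=1e-12)
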