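"""Payoffs, fitness components, reduced coefficients, coinfection algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minicrispr import (
    CoinfectionMarginals,
    PairConfig,
    StrainParams,
    bayes_coinfection,
    fitness_components,
    mean_fitness,
    payoff_matrix,
    read_pair_config,
    reduced_coefficients,
    split_by_arrival,
    write_pair_config,
)
from minicrispr.game_core import coefficients_from_payoff, replace_param

from conftest import random_pair


class TestValidation:
    @pytest.mark.parametrize("field,value", [
        ("c", -0.1), ("c", 1.0), ("w", 1.5), ("q", -0.2), ("d", 1.0),
    ])
    def test_strain_out_of_range_names_field(self, field, value):
        kwargs = {"c": 0.1, "w": 0.5, "q": 0.5, "d": 0.0}
        kwargs[field] = value
        with pytest.raises(ValueError, match=field):
            StrainParams(**kwargs)

    def test_bad_lifestyle_and_variant(self):
        with pytest.raises(ValueError, match="lifestyle"):
            StrainParams(c=0.1, w=0.5, q=0.5, lifestyle="lysogenic")
        s = StrainParams(c=0.1, w=0.5, q=0.5)
        with pytest.raises(ValueError, match="variant"):
            PairConfig(s, s, 0.2, 0.2, variant="nonsense")

    def test_q_sum_exceeding_one_rejected(self):
        a = StrainParams(c=0.1, w=0.5, q=0.7)
        b = StrainParams(c=0.1, w=0.5, q=0.6)
        with pytest.raises(ValueError, match="q_A"):
            PairConfig(a, b, 0.2, 0.2)
        # q_A + q_B < 1 (mutual destruction) is allowed as-is
        PairConfig(a, StrainParams(c=0.1, w=0.5, q=0.1), 0.2, 0.2)


class TestPayoffMatrix:
    def test_no_cost_no_coinfection_is_neutral(self):
        pm = payoff_matrix(StrainParams(c=0.0, w=0.3, q=0.7), 0.0)
        assert pm.as_tuple() == (1.0, 1.0, 1.0, 1.0)

    def test_standard_entries(self):
        # direct evaluation of the four productivity formulas
        pm = payoff_matrix(StrainParams(c=0.1, w=0.8, q=0.5), 0.2)
        assert pm.as_tuple() == pytest.approx((0.81, 0.9, 0.8, 0.96))

    def test_provirus_variant_modifies_self_only(self):
        pm = payoff_matrix(StrainParams(c=0.1, w=0.5, q=0.5), 0.2,
                           "provirus_pair")
        assert pm.self_only == pytest.approx(0.81)
        assert pm.both_target == pytest.approx(0.81)
        assert pm.other_only == pytest.approx(0.8)

    def test_se_blocking_is_strategy_independent_for_opponent(self):
        pm = payoff_matrix(StrainParams(c=0.1, w=0.5, q=0.5), 0.4,
                           "se_blocking")
        assert pm.both_target == pm.self_only
        assert pm.other_only == pm.neither
        assert pm.both_target == pytest.approx(0.9 * pm.neither)

    def test_self_only_independent_of_p(self):
        s = StrainParams(c=0.15, w=0.4, q=0.3)
        for p in (0.0, 0.3, 0.9):
            assert payoff_matrix(s, p).self_only == pytest.approx(0.85)

    def test_monotonicity_in_c_p_q(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            c, w, q, p = rng.uniform(0, 1, 4)
            c *= 0.9
            s = StrainParams(c=c, w=w, q=q)
            pm = payoff_matrix(s, p)
            dc = payoff_matrix(StrainParams(c=min(c + 0.05, 0.99), w=w, q=q), p)
            assert dc.both_target <= pm.both_target
            assert dc.self_only <= pm.self_only
            dp = payoff_matrix(s, min(p + 0.05, 1.0))
            assert dp.both_target <= pm.both_target + 1e-15
            assert dp.other_only <= pm.other_only
            assert dp.neither <= pm.neither
            dq = payoff_matrix(StrainParams(c=c, w=w, q=min(q + 0.05, 1.0)), p)
            assert dq.both_target >= pm.both_target - 1e-15


class TestFitness:
    def test_pure_opponent_selects_rows(self):
        s = StrainParams(c=0.1, w=0.8, q=0.5)
        pm = payoff_matrix(s, 0.2)
        assert fitness_components(s, 0.2, 0.0) == (pm.self_only, pm.neither)
        assert fitness_components(s, 0.2, 1.0) == (pm.both_target, pm.other_only)

    def test_midpoint_mixture(self):
        s = StrainParams(c=0.1, w=0.8, q=0.5)
        f1, f2 = fitness_components(s, 0.2, 0.5)
        assert (f1, f2) == pytest.approx((0.855, 0.88))
        assert mean_fitness(s, 0.2, 0.5, 0.5) == pytest.approx(0.8675)

    def test_mean_fitness_limits_and_bounds(self):
        s = StrainParams(c=0.2, w=0.3, q=0.6)
        f1, f2 = fitness_components(s, 0.4, 0.7)
        assert mean_fitness(s, 0.4, 1.0, 0.7) == pytest.approx(f1)
        assert mean_fitness(s, 0.4, 0.0, 0.7) == pytest.approx(f2)
        phi = mean_fitness(s, 0.4, 0.3, 0.7)
        assert min(f1, f2) <= phi <= max(f1, f2)

    def test_x_out_of_range(self):
        s = StrainParams(c=0.1, w=0.5, q=0.5)
        with pytest.raises(ValueError, match="x_other"):
            fitness_components(s, 0.2, 1.2)


class TestReducedCoefficients:
    def test_no_coinfection_no_selection(self):
        s = StrainParams(c=0.1, w=0.4, q=0.3)
        co = reduced_coefficients(PairConfig(s, s, 0.0, 0.0))
        assert (co.a, co.b, co.a_prime, co.b_prime) == (-0.1, 0.0, -0.1, 0.0)

    def test_asymmetric_reference_values(self, cyclic_pair):
        co = reduced_coefficients(cyclic_pair)
        assert co.a == pytest.approx(-0.06)
        assert co.b == pytest.approx(0.07)
        assert co.a_prime == pytest.approx(0.05)
        assert co.b_prime == pytest.approx(-0.066)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(c=st.floats(0, 0.99), w=st.floats(0, 1), q=st.floats(0, 1),
           p=st.floats(0, 1), x=st.sampled_from([0.0, 0.25, 0.5, 1.0]))
    def test_invasion_fitness_is_linear_in_opponent(self, c, w, q, p, x):
        """f1(x) - f2(x) = a + b x for the standard game."""
        s = StrainParams(c=c, w=w, q=q)
        f1, f2 = fitness_components(s, p, x)
        pair = PairConfig(s, StrainParams(c=0.0, w=0.5, q=0.0), p, 0.0)
        co = reduced_coefficients(pair)
        assert f1 - f2 == pytest.approx(co.a + co.b * x, abs=1e-12)

    def test_identity_a_plus_b(self):
        """a + b = p(q - qc + c) - c on random draws."""
        rng = np.random.default_rng(42)
        for _ in range(500):
            pair = random_pair(rng, c_max=0.99)
            co = reduced_coefficients(pair)
            A, p = pair.strain_A, pair.p_B_given_A
            expect = p * (A.q - A.q * A.c + A.c) - A.c
            assert co.a + co.b == pytest.approx(expect, abs=1e-12)

    def test_payoff_route_matches_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            pair = random_pair(rng, c_max=0.99)
            co = reduced_coefficients(pair)
            a2, b2 = coefficients_from_payoff(
                payoff_matrix(pair.strain_A, pair.p_B_given_A))
            assert (co.a, co.b) == pytest.approx((a2, b2), abs=1e-14)


class TestCoinfectionAlgebra:
    def test_bayes_symmetric_marginals(self):
        m = CoinfectionMarginals(p_A=0.2, p_B=0.2)
        assert bayes_coinfection(m, 0.07) == pytest.approx(0.07)

    def test_bayes_direct_value(self):
        m = CoinfectionMarginals(p_A=0.1, p_B=0.2)
        assert bayes_coinfection(m, 0.05) == pytest.approx(0.1)

    def test_bayes_undefined_and_inconsistent(self):
        with pytest.raises(ValueError, match="p_A = 0"):
            bayes_coinfection(CoinfectionMarginals(p_A=0.0, p_B=0.2), 0.1)
        with pytest.raises(ValueError, match="inconsistent"):
            bayes_coinfection(CoinfectionMarginals(p_A=0.01, p_B=0.9), 0.5)

    def test_marginals_bayes_consistency_enforced(self):
        CoinfectionMarginals(p_A=0.2, p_B=0.1, p_AB_given_A=0.02,
                             p_BA_given_A=0.03, p_AB_given_B=0.04,
                             p_BA_given_B=0.06)
        with pytest.raises(ValueError, match="inconsistent"):
            CoinfectionMarginals(p_A=0.2, p_B=0.1, p_AB_given_A=0.1,
                                 p_BA_given_A=0.1, p_AB_given_B=0.01,
                                 p_BA_given_B=0.01)

    @pytest.mark.parametrize("p,q,expect", [
        (0.2, 1.0, (0.2, 0.0)),
        (0.2, 0.5, (0.1, 0.1)),
        (0.3, 0.0, (0.0, 0.3)),
    ])
    def test_split_by_arrival(self, p, q, expect):
        first, second = split_by_arrival(p, q)
        assert (first, second) == pytest.approx(expect)
        assert first + second == pytest.approx(p)


class TestConfigIO:
    def test_round_trip_both_dialects(self, tmp_path, cyclic_pair):
        for suffix in (".yaml", ".json"):
            path = tmp_path / f"pair{suffix}"
            write_pair_config(cyclic_pair, path)
            assert read_pair_config(path) == cyclic_pair

    def test_unknown_and_missing_keys(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"c_A": 0.1}')
        with pytest.raises(ValueError, match="missing"):
            read_pair_config(path)
        path.write_text(
            '{"c_A": 0.1, "c_B": 0.1, "w_A": 0.5, "w_B": 0.5, "q_A": 0.5,'
            ' "q_B": 0.5, "p_B_given_A": 0.2, "p_A_given_B": 0.2,'
            ' "bogus": 1}')
        with pytest.raises(ValueError, match="bogus"):
            read_pair_config(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_pair_config(path)

    def test_replace_param(self, cyclic_pair):
        out = replace_param(cyclic_pair, "c_B", 0.2)
        assert out.strain_B.c == 0.2
        assert out.strain_A == cyclic_pair.strain_A
        out = replace_param(cyclic_pair, "p_A_given_B", 0.9)
        assert out.p_A_given_B == 0.9
        with pytest.raises(ValueError, match="unknown parameter"):
            replace_param(cyclic_pair, "z_A", 0.1)
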