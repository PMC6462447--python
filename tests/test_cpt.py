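import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from seqrisk import CPTParams, Gamble
from seqrisk import cpt
from conftest import simulate_sessions


def prelec1(lam=10.0, rho=1.0, alpha=1.0, **kw):
    return CPTParams(family="prelec1", lam=lam, rho=rho, alpha=alpha, **kw)


class TestUtility:
    def test_anchoring(self):
        assert cpt.utility(0.5, rho=3.7) == 1.0
        assert cpt.utility(0.0, rho=0.4) == 0.0

    def test_hand_computed_value(self):
        assert cpt.utility(0.25, rho=2.0) == pytest.approx(0.25)

    def test_out_of_range_magnitude_rejected(self):
        with pytest.raises(ValueError):
            cpt.utility(0.6, rho=1.0)


FAMILY_STRATEGY = st.sampled_from([
    ("prelec1", {"alpha": 0.4}), ("prelec1", {"alpha": 2.5}),
    ("prelec2", {"alpha": 0.7, "beta": 1.4}),
    ("tversky", {"epsilon": 0.61}),
    ("gonzalez", {"gamma": 0.5, "delta": 1.5}),
])


class TestWeighting:
    def test_identity_case(self):
        p = np.linspace(0, 1, 11)
        w = cpt.weight_prob(p, prelec1(alpha=1.0))
        assert np.allclose(w, p, atol=1e-12)

    def test_prelec_fixed_point_at_1_over_e(self):
        for alpha in (0.33, 0.67, 1.5, 3.0):
            w = cpt.weight_prob(1 / math.e, prelec1(alpha=alpha))
            assert w == pytest.approx(1 / math.e, abs=1e-12)

    def test_numeric_oracle_value(self):
        # direct evaluation: w(0.5) = exp(-(ln 2)^2) for alpha = 2
        w = cpt.weight_prob(0.5, prelec1(alpha=2.0))
        assert w == pytest.approx(math.exp(-math.log(2.0) ** 2), abs=1e-14)

    def test_inverse_s_crosses_identity_at_1_over_e(self):
        params = prelec1(alpha=0.6)
        assert cpt.weight_prob(0.05, params) > 0.05
        assert cpt.weight_prob(0.9, params) < 0.9
        params = prelec1(alpha=1.8)
        assert cpt.weight_prob(0.05, params) < 0.05
        assert cpt.weight_prob(0.9, params) > 0.9

    @given(FAMILY_STRATEGY)
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_endpoints_and_monotonicity(self, family_spec):
        family, shape = family_spec
        params = CPTParams(family=family, lam=1.0, rho=1.0, **shape)
        grid = np.linspace(0.0, 1.0, 201)
        w = cpt.weight_prob(grid, params)
        assert w[0] == 0.0 and w[-1] == 1.0
        assert np.all(np.diff(w) > 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_prelec1_inverse_round_trip(self):
        p = np.linspace(0.01, 0.99, 50)
        for alpha in (0.33, 1.0, 2.4):
            w = cpt.weight_prob(p, prelec1(alpha=alpha))
            assert np.allclose(cpt.prelec1_inverse(w, alpha), p, atol=1e-12)


class TestSubjectiveValue:
    def test_safe_reward_uses_utility_only(self):
        assert cpt.subjective_value(Gamble.safe(0.25), prelec1()) == pytest.approx(0.5)

    def test_standard_gamble_reduces_to_weighted_utility(self):
        g = Gamble.from_probability(0.37)
        assert cpt.subjective_value(g, prelec1()) == pytest.approx(0.37)

    def test_two_nonzero_outcome_gamble_rank_dependent_sum(self):
        # hand evaluation: u(0.5)*w(0.6) + u(0.25)*(1 - w(0.6)) with linear u, w
        g = Gamble(((0.5, 0.6), (0.25, 0.4)))
        assert cpt.subjective_value(g, prelec1()) == pytest.approx(0.6 + 0.5 * 0.4)

    def test_three_outcome_gambles_rejected(self):
        g = Gamble(((0.0, 0.2), (0.25, 0.3), (0.5, 0.5)))
        with pytest.raises(ValueError):
            cpt.subjective_value(g, prelec1())


class TestChoiceProb:
    def test_equal_values_give_half(self):
        assert cpt.choice_prob(0.4, 0.4, lam=7.0) == pytest.approx(0.5)
        assert cpt.choice_prob(0.4, 0.4, lam=7.0, k=0.5) == pytest.approx(0.5)

    def test_zero_temperature_is_indifferent(self):
        assert cpt.choice_prob(0.9, 0.1, lam=0.0) == pytest.approx(0.5)

    def test_deterministic_limit(self):
        assert cpt.choice_prob(0.9, 0.1, lam=1e6) == pytest.approx(1.0)

    def test_attention_weight_shifts_choice(self):
        # k > 0.5 overweights the safe value: gamble chosen less often
        p_eq = cpt.choice_prob(0.5, 0.5, lam=10.0, k=0.7)
        assert p_eq < 0.5


class TestNegLogLikelihood:
    def test_single_trial_at_even_odds(self, linear_agent_records):
        g = Gamble.from_probability(0.5)
        records = [r for r in linear_agent_records
                   if r.gamble == g and r.safe.magnitude == 0.25][:1]
        # v_g = v_s = 0.5 so P_G = 0.5 regardless of choice
        assert cpt.neg_log_likelihood(records, prelec1()) == pytest.approx(
            math.log(2.0), abs=1e-12)

    def test_matches_brute_force_per_trial_oracle(self, distorting_agent_records):
        records = distorting_agent_records[:20]
        params = CPTParams(family="prelec1", lam=8.0, rho=1.7, alpha=0.8)
        total = 0.0
        for r in records:  # independent per-trial evaluation
            w = math.exp(-((-math.log(r.gamble.win_probability)) ** 0.8))
            v_g = w  # u(0.5) = 1, low outcome 0
            v_s = (r.safe.magnitude / 0.5) ** 1.7
            p_g = 1.0 / (1.0 + math.exp(-8.0 * (v_g - v_s)))
            p_g = min(max(p_g, 1e-12), 1 - 1e-12)
            total -= math.log(p_g) if r.chose_gamble else math.log(1.0 - p_g)
        assert cpt.neg_log_likelihood(records, params) == pytest.approx(
            total, abs=1e-12)

    def test_duplicated_dataset_doubles_likelihood(self, linear_agent_records):
        records = linear_agent_records[:15]
        params = prelec1(lam=6.0, rho=1.2, alpha=0.9)
        one = cpt.neg_log_likelihood(records, params)
        two = cpt.neg_log_likelihood(list(records) + list(records), params)
        assert two == pytest.approx(2.0 * one, abs=1e-10)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            cpt.neg_log_likelihood([], prelec1())


class TestFitMLE:
    def test_linear_agent_recovered(self, linear_agent_records):
        fit = cpt.fit_mle(linear_agent_records, n_restarts=3, seed=0)
        assert fit.converged
        assert fit.params.rho == pytest.approx(1.0, abs=0.1)
        assert fit.params.alpha == pytest.approx(1.0, abs=0.1)
        assert fit.params.lam == pytest.approx(10.0, rel=0.2)

    def test_optimum_at_least_as_likely_as_truth(self, distorting_agent_records):
        true = CPTParams(family="prelec1", lam=10.0, rho=2.0, alpha=0.67)
        fit = cpt.fit_mle(distorting_agent_records, n_restarts=3, seed=1)
        assert fit.neg_ll <= cpt.neg_log_likelihood(
            distorting_agent_records, true) + 1e-9

    def test_bic_identity(self, linear_agent_records):
        fit = cpt.fit_mle(linear_agent_records[:594], n_restarts=2, seed=2)
        assert fit.bic == fit.n_free_params * math.log(fit.n_trials) + 2 * fit.neg_ll


class TestCompareModels:
    def test_equal_likelihood_penalizes_extra_parameter(self):
        a = cpt.ModelFit(params=prelec1(), neg_ll=100.0, n_trials=594,
                         n_free_params=3, converged=True)
        b = cpt.ModelFit(
            params=CPTParams(family="prelec2", lam=10, rho=1, alpha=1, beta=1),
            neg_ll=100.0, n_trials=594, n_free_params=4, converged=True)
        assert b.bic - a.bic == pytest.approx(math.log(594))

    def test_generating_family_preferred_in_majority(self):
        wins = 0
        for seed in range(5):
            records = simulate_sessions(
                CPTParams(family="prelec1", lam=10.0, rho=2.0, alpha=0.67),
                n_sessions=1, seed=100 + seed)
            table, _ = cpt.compare_models(records, ("prelec1", "prelec2"),
                                          n_restarts=3, seed=seed)
            by_family = table.set_index("family")["bic"]
            wins += by_family["prelec1"] <= by_family["prelec2"]
        assert wins >= 3

    def test_single_family_table(self, linear_agent_records):
        table, fits = cpt.compare_models(linear_agent_records[:200],
                                         ("prelec1",), n_restarts=2, seed=0)
        assert len(table) == 1 and table.loc[0, "best"]
        assert set(fits) == {"prelec1"}


class TestPredictedCE:
    def test_risk_neutral_ce_equals_ev(self):
        for p in (0.1, 0.5, 0.9):
            assert cpt.predicted_ce(prelec1(), p) == pytest.approx(0.5 * p)

    def test_fixed_point_survives_any_curvature(self):
        p = 1 / math.e
        for rho in (0.3, 1.0, 2.0):
            params = prelec1(rho=rho, alpha=1.7)
            assert cpt.predicted_ce(params, p) == pytest.approx(
                0.5 * (1 / math.e) ** (1 / rho))

    def test_matches_numeric_utility_inversion(self):
        # root-finding oracle: solve u(ce) = w(p) for ce
        for rho, alpha in ((2.0, 0.67), (0.5, 1.5), (1.3, 0.33)):
            params = prelec1(rho=rho, alpha=alpha)
            for p in np.linspace(0.05, 0.95, 19):
                w = cpt.weight_prob(p, params)
                ce_oracle = optimize.brentq(
                    lambda m: cpt.utility(m, rho) - w, 0.0, 0.5,
                    xtol=1e-14, rtol=1e-15)
                assert cpt.predicted_ce(params, p) == pytest.approx(
                    ce_oracle, abs=1e-10)


class TestParameterRecovery:
    def test_single_rep_is_reproducible(self):
        grid = [CPTParams(family="prelec1", lam=10.0, rho=2.0, alpha=0.67)]
        a = cpt.parameter_recovery(grid, n_mc=1, seed=5, n_restarts=2)
        b = cpt.parameter_recovery(grid, n_mc=1, seed=5, n_restarts=2)
        assert a.equals(b)

    def test_small_recovery_brackets_truth(self):
        grid = [CPTParams(family="prelec1", lam=10.0, rho=2.0, alpha=0.67)]
        table = cpt.parameter_recovery(grid, n_mc=30, seed=6, n_restarts=2)
        assert table["in_ci"].all()
        assert table["n_trials"].iloc[0] == 594


class TestAttentionModel:
    def test_null_attention_recovered_near_half(self):
        # the standard softmax agent is the k = 0.5 model up to lam rescaling
        records = simulate_sessions(prelec1(lam=10.0), n_sessions=4, seed=21)
        table, test = cpt.fit_attention_model(records, n_restarts=4, seed=0)
        assert abs(table["k"].mean() - 0.5) < 0.1
        assert test.pvalue > 0.01

    def test_safe_overweighting_recovered(self):
        params = CPTParams(family="prelec1", lam=20.0, rho=1.0, alpha=1.0, k=0.7)
        records = simulate_sessions(params, n_sessions=3, seed=22)
        table, _ = cpt.fit_attention_model(records, n_restarts=4, seed=1)
        assert (table["k"] > 0.5).all()

    def test_single_session_skips_test_with_notice(self):
        records = simulate_sessions(prelec1(lam=10.0), n_sessions=1, seed=23)
        with pytest.warns(RuntimeWarning, match="single session"):
            table, test = cpt.fit_attention_model(records, n_restarts=2, seed=2)
        assert len(table) == 1
        assert math.isnan(float(test.pvalue))
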