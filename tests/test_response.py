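"""Tests of arbitration, belief integration, choice and wager models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import socarb
from socarb.hgf import filter_branches
from socarb.params import PerceptualParams, ResponseParams
from socarb.response import (arbitrate, card_to_advice_frame,
                             choice_probability, data_loglik,
                             integrate_belief, predict_run, wager_loglik,
                             wager_mean)


class TestArbitrate:
    def test_equal_precisions_equal_weights(self):
        assert arbitrate(3.0, 3.0, 1.0) == (0.5, 0.5)

    def test_zeta_zero_is_card_only(self):
        xi_a, xi_c = arbitrate(5.0, 2.0, 0.0)
        assert (xi_a, xi_c) == (0.0, 1.0)

    def test_zeta_two_with_unit_precisions(self):
        xi_a, xi_c = arbitrate(1.0, 1.0, 2.0)
        assert xi_a == pytest.approx(2.0 / 3.0)
        assert xi_c == pytest.approx(1.0 / 3.0)

    def test_zeta_inf_is_advice_only(self):
        assert arbitrate(0.1, 100.0, math.inf) == (1.0, 0.0)

    def test_rejects_nonpositive_precisions(self):
        with pytest.raises(ValueError):
            arbitrate(0.0, 0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pa=st.floats(0.1, 50), pc=st.floats(0.1, 50),
           zeta=st.floats(0.01, 20))
    def test_monotonicity(self, pa, pc, zeta):
        """xi_a increases in advice precision and zeta, decreases in card
        precision."""
        xi, _ = arbitrate(pa, pc, zeta)
        up_pa, _ = arbitrate(pa * 1.1, pc, zeta)
        up_pc, _ = arbitrate(pa, pc * 1.1, zeta)
        up_z, _ = arbitrate(pa, pc, zeta * 1.1)
        assert up_pa > xi and up_z > xi and up_pc < xi


class TestBeliefIntegration:
    def test_pure_advice_weighting(self):
        assert integrate_belief(1.0, 0.73, 0.0, 0.2) == pytest.approx(0.73)

    def test_agreeing_sources_are_invariant_to_weights(self):
        for w in (0.0, 0.3, 0.9):
            assert integrate_belief(w, 0.6, 1 - w, 0.6) == pytest.approx(0.6)

    def test_frame_flip_for_green_advice(self):
        # advice says green while the card branch gives p(blue) = 0.7
        assert card_to_advice_frame(0.7, 0) == pytest.approx(0.3)
        assert card_to_advice_frame(0.7, 1) == pytest.approx(0.7)


class TestChoiceProbability:
    def test_probability_matching_at_unit_temperature(self):
        assert choice_probability(0.7, 1.0) == pytest.approx(0.7)

    def test_indifference_for_any_temperature(self):
        for b in (0.5, 1.0, 10.0, 500.0):
            assert choice_probability(0.5, b) == pytest.approx(0.5)

    def test_greedy_limit(self):
        assert choice_probability(0.6, 1e4) == pytest.approx(1.0, abs=1e-12)


class TestWagerModel:
    def test_intercept_only(self):
        resp = ResponseParams(beta0=1.5)
        assert wager_mean(0.2, 0.5, 0.1, 0.1, 0.6, 0.6, resp) == pytest.approx(1.5)

    def test_higher_advisor_volatility_lowers_wager(self):
        # group-level beta5 is negative: more perceived advisor volatility,
        # fewer points wagered
        resp = socarb.group_mean_response()
        low = wager_mean(0.2, 0.5, 0.1, 0.1, 0.3, 0.5, resp)
        high = wager_mean(0.2, 0.5, 0.1, 0.1, 0.9, 0.5, resp)
        assert resp.beta5 < 0 and high < low

    def test_belief_uncertainty_peaks_at_half(self):
        mu = np.linspace(0.01, 0.99, 99)
        sigma_b = mu * (1 - mu)
        assert sigma_b.max() == pytest.approx(0.25, abs=1e-4)
        assert np.argmax(sigma_b) == 49

    def test_loglik_maximal_at_the_mean(self):
        m = math.log(4.0)
        assert wager_loglik(4, m, 0.5) > wager_loglik(5, m, 0.5)
        assert wager_loglik(4, m, 0.5) > wager_loglik(3, m, 0.5)

    def test_doubling_scale_costs_log_two_at_mode(self):
        m = math.log(6.0)
        assert (wager_loglik(6, m, 0.4) - wager_loglik(6, m, 0.8)
                ) == pytest.approx(math.log(2.0))

    def test_rejects_out_of_range_wagers(self):
        with pytest.raises(ValueError):
            wager_loglik(0, 1.0, 0.5)
        with pytest.raises(ValueError):
            wager_loglik(11, 1.0, 0.5)


class TestRunLikelihood:
    # Frozen from a 40-digit arbitrary-precision hand evaluation of the
    # three-trial fixture: advice accuracy [1,0,1], outcomes [1,1,0],
    # advice colors [1,0,1], choices [1,0,1], wagers [4,7,2].
    ORACLE_LOGLIK = -5.1740706061465989

    @staticmethod
    def _fixture():
        perc = PerceptualParams(kappa_a=0.6, kappa_c=0.5, theta_a=0.6,
                                theta_c=0.55, omega_a=-3, omega_c=-3)
        resp = ResponseParams(zeta=1.4, beta_ch=3.0, beta0=2.0, beta1=0.5,
                              beta2=-0.4, beta3=0.3, beta4=-0.2, beta5=0.1,
                              beta6=-0.6, beta_wager=0.4)
        ua = np.array([1, 0, 1])
        uc = np.array([1, 1, 0])
        advice = np.array([1, 0, 1])
        return perc, resp, ua, uc, advice

    def test_total_loglik_matches_hand_computation(self):
        perc, resp, ua, uc, advice = self._fixture()
        ta, tc = filter_branches(ua, uc, perc)
        pred = predict_run(ta, tc, advice, resp, "arbitrated")
        ll = data_loglik(np.array([1, 0, 1]), np.array([4, 7, 2]), pred, resp)
        assert ll == pytest.approx(self.ORACLE_LOGLIK, rel=1e-12)

    def test_xi_weights_sum_to_one(self, default_schedule, group_params):
        perc, resp = group_params
        ta, tc = filter_branches(default_schedule.advice_accurate,
                                 default_schedule.outcome_color, perc)
        pred = predict_run(ta, tc, default_schedule.advice_color, resp)
        np.testing.assert_allclose(pred.xi_a + pred.xi_c, 1.0, rtol=1e-12)

    @pytest.mark.parametrize("variant,zeta", [("card_only", 0.0),
                                              ("advice_only", math.inf)])
    def test_degenerate_variants_equal_pinned_arbitration(
            self, default_schedule, group_params, variant, zeta):
        perc, resp = group_params
        ta, tc = filter_branches(default_schedule.advice_accurate,
                                 default_schedule.outcome_color, perc)
        import dataclasses

        pinned = dataclasses.replace(resp, zeta=zeta)
        a = predict_run(ta, tc, default_schedule.advice_color, pinned, "arbitrated")
        b = predict_run(ta, tc, default_schedule.advice_color, resp, variant)
        np.testing.assert_allclose(a.p_take_advice, b.p_take_advice, atol=1e-10)
        np.testing.assert_allclose(a.wager_mean_log, b.wager_mean_log, atol=1e-10)

    def test_card_only_ignores_advice_beliefs(self, default_schedule, group_params):
        perc, resp = group_params
        ta, tc = filter_branches(default_schedule.advice_accurate,
                                 default_schedule.outcome_color, perc)
        other_a, _ = filter_branches(1 - default_schedule.advice_accurate,
                                     default_schedule.outcome_color, perc)
        p1 = predict_run(ta, tc, default_schedule.advice_color, resp, "card_only")
        p2 = predict_run(other_a, tc, default_schedule.advice_color, resp, "card_only")
        np.testing.assert_allclose(p1.p_take_advice, p2.p_take_advice)

    def test_advice_only_is_softmax_of_advice_belief(self, default_schedule,
                                                     group_params):
        perc, resp = group_params
        ta, tc = filter_branches(default_schedule.advice_accurate,
                                 default_schedule.outcome_color, perc)
        pred = predict_run(ta, tc, default_schedule.advice_color, resp, "advice_only")
        np.testing.assert_allclose(
            pred.p_take_advice, choice_probability(ta.mu1hat, resp.beta_ch),
            atol=1e-12)

    def test_choice_likelihood_is_frame_invariant(self, default_schedule,
                                                  group_params):
        """Relabeling the two colors everywhere leaves the likelihood of the
        same behavior unchanged."""
        perc, resp = group_params
        sched = default_schedule
        choices = (np.random.default_rng(5).random(len(sched)) < 0.5).astype(int)
        wagers = np.full(len(sched), 5)

        ta, tc = filter_branches(sched.advice_accurate, sched.outcome_color, perc)
        pred = predict_run(ta, tc, sched.advice_color, resp)
        ll = data_loglik(choices, wagers, pred, resp)

        ta2, tc2 = filter_branches(sched.advice_accurate,
                                   1 - sched.outcome_color, perc)
        pred2 = predict_run(ta2, tc2, 1 - sched.advice_color, resp)
        ll2 = data_loglik(choices, wagers, pred2, resp)
        assert ll2 == pytest.approx(ll, rel=1e-9)

    def test_arbitration_favors_advice_more_in_stable_blocks(
            self, default_schedule, group_params):
        perc, resp = group_params
        sched = default_schedule
        ta, tc = filter_branches(sched.advice_accurate, sched.outcome_color, perc)
        pred = predict_run(ta, tc, sched.advice_color, resp)
        stable = sched.advice_phase == "stable"
        assert pred.xi_a[stable].mean() > pred.xi_a[~stable].mean()
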