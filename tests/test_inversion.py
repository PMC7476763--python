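"""Tests of MAP estimation and Laplace model evidence."""

import math

import numpy as np
import pytest

import socarb
from socarb.inversion import (OptimizerConfig, joint_log_posterior,
                              log_model_evidence, map_fit)
from socarb.params import (PriorSpec, model_by_name, to_estimation)
from socarb.task import GeneratorConfig, SubjectData


@pytest.fixture(scope="module")
def sim_subject(group_params):
    perc, resp = group_params
    sched = socarb.generate_schedule(GeneratorConfig(seed=77))
    data = socarb.simulate_agent(sched, perc, resp, "hgf3_arb", seed=13)
    return sched, data


class TestJointLogPosterior:
    # frozen closed-form sum of the 14 free parameters' Gaussian log
    # densities at their prior means (variances 1,1,1,1,25,1,4*7,100)
    PRIOR_ONLY = -21.629192734213182

    def test_empty_data_reduces_to_prior(self, default_schedule):
        model = model_by_name("hgf3_arb")
        priors = model.priors()
        x0 = np.array([priors[n].est_mean for n in model.free_parameters])
        empty = SubjectData(np.empty(0, int), np.empty(0, int), np.empty(0, int))
        sched = default_schedule
        lp = joint_log_posterior(x0, empty,
                                 _truncate(sched, 0), model)
        assert lp == pytest.approx(self.PRIOR_ONLY, rel=1e-12)

    def test_certain_trial_contributes_zero(self, default_schedule):
        """A trial whose choice has probability ~1 and whose wager sits at
        the predicted mean changes the posterior only by the wager
        normalization constant."""
        model = model_by_name("hgf3_advice")
        priors = dict(model.priors())
        # extreme temperature, certain advisor: p(take advice) ~ 1
        priors["beta_ch"] = PriorSpec("beta_ch", 1e4, 0.0, "log")
        cfg = GeneratorConfig(advisor_info_accuracy=0.999,
                              target_advice_accuracy=0.999,
                              advice_phases=(("stable", 160),), seed=3)
        sched = socarb.generate_schedule(cfg)
        names = tuple(n for n in priors if not priors[n].fixed)
        x0 = np.array([priors[n].est_mean for n in names])

        short = _truncate(sched, 3)
        data3 = SubjectData(np.arange(1, 4), np.ones(3, int), np.full(3, 5))
        lp3 = joint_log_posterior(x0, data3, short, model, priors)
        data2 = SubjectData(np.arange(1, 3), np.ones(2, int), np.full(2, 5))
        lp2 = joint_log_posterior(x0, data2, _truncate(sched, 2), model, priors)
        delta = lp3 - lp2
        # choice term of the added trial is log(1) = 0; only the wager term remains
        from socarb.hgf import filter_branches
        from socarb.response import predict_run, wager_loglik

        perc, resp = model.build_params(
            {n: priors[n].native_mean for n in priors if priors[n].fixed} |
            {n: priors[n].native_mean for n in names})
        ta, tc = filter_branches(short.advice_accurate, short.outcome_color, perc)
        pred = predict_run(ta, tc, short.advice_color, resp, model.response_variant)
        expected = wager_loglik(5, pred.wager_mean_log[2], resp.beta_wager)
        assert delta == pytest.approx(expected, rel=1e-9)

    def test_three_trial_fixture_matches_hand_computation(self):
        """Same arbitrary-precision oracle as the response-likelihood fixture,
        now through the model-space interface with priors added."""
        from socarb.params import ModelSpec

        model = ModelSpec("fixture", "three_level", "arbitrated")
        priors = model.priors()
        names = model.free_parameters
        native = {"kappa_a": 0.6, "kappa_c": 0.5, "theta_a": 0.6,
                  "theta_c": 0.55, "zeta": 1.4, "beta_ch": 3.0, "beta0": 2.0,
                  "beta1": 0.5, "beta2": -0.4, "beta3": 0.3, "beta4": -0.2,
                  "beta5": 0.1, "beta6": -0.6, "beta_wager": 0.4}
        x = np.array([to_estimation(native[n], priors[n].transform)
                      for n in names])
        sched = socarb.TaskSchedule(
            trial_index=np.arange(1, 4),
            card_phase=np.array(["stable"] * 3),
            advice_phase=np.array(["stable"] * 3),
            p_blue=np.full(3, 0.8),
            outcome_color=np.array([1, 1, 0]),
            advisor_info=np.array([1, 0, 1]),
            advice_color=np.array([1, 0, 1]),
            advice_accurate=np.array([1, 0, 1]),
        )
        data = SubjectData(np.arange(1, 4), np.array([1, 0, 1]),
                           np.array([4, 7, 2]))
        lp = joint_log_posterior(x, data, sched, model)
        prior_term = sum(
            -0.5 * math.log(2 * math.pi * priors[n].variance)
            - 0.5 * (xv - priors[n].est_mean) ** 2 / priors[n].variance
            for n, xv in zip(names, x))
        assert lp - prior_term == pytest.approx(-5.1740706061465989, rel=1e-10)


class TestMapFit:
    def test_fully_fixed_model_returns_prior_means(self, sim_subject):
        sched, data = sim_subject
        model = model_by_name("normative_card")
        priors = {n: PriorSpec(n, p.mean_native, 0.0, p.transform,
                               p.mean_is_estimation_space)
                  for n, p in model.priors().items()}
        fit = map_fit(data, sched, model, prior_spec=priors)
        assert fit.free_names == ()
        assert fit.converged
        assert fit.lme == pytest.approx(fit.log_likelihood)

    def test_two_parameter_fit_matches_grid_search(self, group_params):
        """MAP on a 2-free-parameter model agrees with an exhaustive grid
        search over the transformed parameter plane."""
        perc, resp = group_params
        sched = socarb.generate_schedule(GeneratorConfig(seed=31))
        data = socarb.simulate_agent(sched, perc, resp, "hgf3_arb", seed=5)
        sched20 = _truncate(sched, 20)
        data20 = SubjectData(data.trial_index[:20], data.choice[:20],
                             data.wager[:20])

        model = model_by_name("hgf3_arb")
        base = model.priors()
        priors = {}
        for n, p in base.items():
            if n in ("zeta", "beta_ch"):
                priors[n] = p
            else:
                fixed_native = {"kappa_a": 0.56, "kappa_c": 0.58,
                                "theta_a": 0.62, "theta_c": 0.59,
                                "beta0": 3.18, "beta_wager": 0.5}.get(n, 0.0)
                priors[n] = PriorSpec(n, fixed_native, 0.0, p.transform)

        fit = map_fit(data20, sched20, model, prior_spec=priors,
                      optimizer=OptimizerConfig(n_starts=6, seed=3))

        grid = np.linspace(-4, 4, 81)
        best = (-np.inf, None)
        for z in grid:
            for b in np.linspace(-1, 4, 81):
                lp = joint_log_posterior(np.array([z, b]), data20, sched20,
                                         model, priors)
                if lp > best[0]:
                    best = (lp, (z, b))
        assert fit.log_posterior >= best[0] - 1e-6
        step = grid[1] - grid[0]
        assert abs(fit.x_est[0] - best[1][0]) <= step
        assert abs(fit.x_est[1] - best[1][1]) <= step

    def test_multistart_agreement(self, sim_subject):
        sched, data = sim_subject
        model = model_by_name("hgf3_card")
        a = map_fit(data, sched, model,
                    optimizer=OptimizerConfig(n_starts=3, seed=1))
        b = map_fit(data, sched, model,
                    optimizer=OptimizerConfig(n_starts=3, seed=99))
        assert a.log_posterior == pytest.approx(b.log_posterior, abs=0.05)

    def test_free_zeta_fits_at_least_as_well_as_pinned(self, sim_subject):
        """With the social bias free and its prior covering the pinned value,
        the maximized joint posterior likelihood can only improve."""
        sched, data = sim_subject
        free = map_fit(data, sched, model_by_name("hgf3_arb"),
                       optimizer=OptimizerConfig(n_starts=3, seed=2))
        pinned = map_fit(data, sched, model_by_name("hgf3_card"),
                         optimizer=OptimizerConfig(n_starts=3, seed=2))
        assert free.log_likelihood >= pinned.log_likelihood - 0.5


class TestLogModelEvidence:
    def test_laplace_is_exact_for_gaussian_log_posterior(self):
        # log posterior = log N(x; mu, Sigma) + log Z: the Laplace integral
        # recovers log Z exactly
        mu = np.array([0.3, -1.2])
        prec = np.array([[2.0, 0.3], [0.3, 1.5]])
        log_z = 1.7

        def logpost(x):
            d = x - mu
            return (log_z + 0.5 * np.log(np.linalg.det(prec))
                    - np.log(2 * np.pi) - 0.5 * d @ prec @ d)

        lme = log_model_evidence(logpost, mu, logpost(mu), 2)
        assert lme == pytest.approx(log_z, abs=1e-5)

    def test_unused_free_parameter_lowers_evidence(self, group_params):
        """A free social-bias parameter that the generating process does not
        use costs evidence relative to the matched pinned model."""
        perc, resp = group_params
        import dataclasses

        card_resp = dataclasses.replace(resp, zeta=0.0)
        sched = socarb.generate_schedule(GeneratorConfig(seed=55))
        deltas = []
        for seed in range(3):
            data = socarb.simulate_agent(sched, perc, card_resp, "hgf3_card",
                                         seed=seed)
            rich = map_fit(data, sched, model_by_name("hgf3_arb"),
                           optimizer=OptimizerConfig(n_starts=3, seed=seed))
            lean = map_fit(data, sched, model_by_name("hgf3_card"),
                           optimizer=OptimizerConfig(n_starts=3, seed=seed))
            deltas.append(lean.lme - rich.lme)
        assert np.mean(deltas) > 0


def _truncate(schedule, n):
    return socarb.TaskSchedule(
        trial_index=schedule.trial_index[:n],
        card_phase=schedule.card_phase[:n],
        advice_phase=schedule.advice_phase[:n],
        p_blue=schedule.p_blue[:n],
        outcome_color=schedule.outcome_color[:n],
        advisor_info=schedule.advisor_info[:n],
        advice_color=schedule.advice_color[:n],
        advice_accurate=schedule.advice_accurate[:n],
    )
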