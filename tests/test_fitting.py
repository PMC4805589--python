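import numpy as np
import pytest

from rovingsj.core import DualTrial, ObserverParams, SingleTrial
from rovingsj.fitting import (GridSpec, deviance, fit_2xsj, fit_model,
                              fit_sj_pipeline, fit_toj, group_dual,
                              group_single, log_likelihood, make_model,
                              nested_lr_test, saturated_loglik)
from rovingsj.adaptive import make_design
from rovingsj.simulate import SyntheticObserver, simulate_response, \
    simulate_session

SMALL_GRID = GridSpec(mu_starts=(-50.0, 50.0), sigma_starts=(30.0, 100.0),
                      beta_starts=(1.0,), c_starts=(0.0,))


class TestLogLikelihood:
    def test_single_trial_half(self):
        trials = [SingleTrial(0.0, 1)]
        model = make_model("toj_null")
        assert log_likelihood(model, [0.0], trials) == \
            pytest.approx(np.log(0.5))

    def test_additivity(self):
        one = [SingleTrial(20.0, 1)]
        many = one * 17
        theta = [10.0, np.log(60.0)]
        assert log_likelihood("toj", theta, many) == \
            pytest.approx(17 * log_likelihood("toj", theta, one))

    def test_grouped_equals_trialwise(self, rng):
        soas = rng.choice([-100.0, -20.0, 0.0, 40.0, 160.0], size=200)
        trials = [SingleTrial(s, int(rng.random() < 0.5)) for s in soas]
        grouped = group_single(trials, "toj")
        theta = [5.0, np.log(45.0)]
        assert log_likelihood("toj", theta, grouped) == \
            pytest.approx(log_likelihood("toj", theta, trials), abs=1e-9)

    def test_empty_data_errors(self):
        with pytest.raises(ValueError):
            group_single([], "toj")
        with pytest.raises(ValueError):
            group_dual([DualTrial(0.0, 10.0, 1, canceled=True)])

    def test_canceled_trials_excluded(self):
        kept = [DualTrial(0.0, 100.0, 1), DualTrial(0.0, -100.0, 2)]
        extra = kept + [DualTrial(0.0, 100.0, 1, canceled=True)]
        assert group_dual(extra).n_trials == group_dual(kept).n_trials == 2


class TestDeviance:
    def test_zero_when_model_reproduces_proportions(self):
        # guessing null at the empirical rate reproduces a flat dataset
        trials = [SingleTrial(s, r) for s in (-50.0, 50.0)
                  for r in (0, 1)]             # 50% everywhere
        from scipy.special import logit
        assert deviance("toj_null", [logit(0.5)], trials) == \
            pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_condition_binomial(self):
        # conditions: (k=8, n=10) and (k=3, n=10); model predicts 0.5
        trials = ([SingleTrial(-50.0, 1)] * 8 + [SingleTrial(-50.0, 0)] * 2
                  + [SingleTrial(50.0, 1)] * 3 + [SingleTrial(50.0, 0)] * 7)
        from scipy.special import logit
        expected = 2 * (8 * np.log(0.8 / 0.5) + 2 * np.log(0.2 / 0.5)
                        + 3 * np.log(0.3 / 0.5) + 7 * np.log(0.7 / 0.5))
        assert deviance("toj_null", [logit(0.5)], trials) == \
            pytest.approx(expected, abs=1e-9)

    def test_guessing_on_ordered_data_is_large(self, toj_block):
        from scipy.special import logit
        assert deviance("toj_null", [logit(0.5)], toj_block) > 20


class TestNestedLrTest:
    def _fake(self, model_id, dev, n_params):
        from rovingsj.core import FitResult
        return FitResult(model_id=model_id, params=None, loglik=0.0,
                         deviance=dev, n_params=n_params, converged=True)

    def test_chi2_quantiles(self):
        d, df, p, rej = nested_lr_test(self._fake("toj_null", 3.841, 1),
                                       self._fake("toj", 0.0, 2))
        assert df == 1 and p == pytest.approx(0.05, abs=1e-3)
        d, df, p, rej = nested_lr_test(self._fake("2xsj_null", 5.991, 1),
                                       self._fake("2xsj_constant", 0.0, 3))
        assert df == 2 and p == pytest.approx(0.05, abs=1e-3)

    def test_zero_improvement(self):
        d, df, p, rej = nested_lr_test(self._fake("toj_null", 1.0, 1),
                                       self._fake("toj", 1.0, 2))
        assert d == 0.0 and p == 1.0 and not rej

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError):
            nested_lr_test(self._fake("toj", 1.0, 2),
                           self._fake("sj4", 0.0, 4))


class TestFitModel:
    def test_toj_parameter_recovery(self):
        rng = np.random.default_rng(77)
        obs = SyntheticObserver(params=ObserverParams(mu=10.0, sigma=60.0))
        soas = np.tile(np.arange(-300.0, 301.0, 60.0), 91)[:1000]
        trials = [SingleTrial(float(s),
                              simulate_response(obs, "toj", float(s), rng))
                  for s in soas]
        fit = fit_model("toj", trials, SMALL_GRID)
        assert fit.converged
        assert fit.params.mu == pytest.approx(10.0, abs=8.0)
        assert fit.params.sigma == pytest.approx(60.0, abs=12.0)

    def test_refit_at_optimum_is_fixed_point(self, toj_block):
        fit = fit_model("toj", toj_block, SMALL_GRID)
        refit = fit_model("toj", toj_block, GridSpec.warm(fit.free_params))
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_loglik_beats_every_start(self, toj_block):
        g = group_single(toj_block, "toj")
        fit = fit_model("toj", g, SMALL_GRID)
        model = make_model("toj")
        for start in model.starts(SMALL_GRID, g):
            assert fit.loglik >= log_likelihood(model, start, g) - 1e-9

    def test_lapse_never_free(self):
        assert make_model("toj").n_params == 2
        assert make_model("2xsj_constant").n_params == 3
        assert make_model("sj4").n_params == 4


class TestFit2xsj:
    def test_constant_bias_recovered(self, dual_block_constant_bias):
        fit = fit_2xsj(dual_block_constant_bias, SMALL_GRID)
        assert fit.derived["beats_guessing"]
        assert fit.params.bias_form == "constant"
        assert fit.derived["pss"] == pytest.approx(0.0, abs=25.0)

    def test_proportional_bias_recovered(self):
        # the two bias families are nearly indistinguishable in a single
        # 152-trial block, so the contest is checked at the 2280-trial scale
        rng = np.random.default_rng(21)
        obs = SyntheticObserver(params=ObserverParams(
            mu=0.0, sigma=50.0, bias_form="proportional", bias=2.0))
        trials = simulate_session(obs, make_design("exp1a_2xsj"), rng)
        fit = fit_2xsj(trials, SMALL_GRID)
        assert fit.params.bias_form == "proportional"
        assert fit.params.bias == pytest.approx(2.0, rel=0.3)
        assert fit.derived["beats_guessing"]

    def test_unbiased_observer_small_bias(self):
        rng = np.random.default_rng(8)
        obs = SyntheticObserver(params=ObserverParams(mu=0.0, sigma=50.0))
        design = make_design("exp1a_2xsj")
        trials = simulate_session(obs, design, rng)
        assert len(trials) == 2280
        fit = fit_2xsj(trials, SMALL_GRID)
        if fit.params.bias_form == "constant":
            assert abs(fit.params.bias) < 10.0
        else:
            assert 0.8 < fit.params.bias < 1.25

    def test_ladder_deviance_monotone(self, dual_block_constant_bias):
        g = group_dual(dual_block_constant_bias)
        base = fit_model("2xsj_none", g, SMALL_GRID)
        fit = fit_2xsj(g, SMALL_GRID)
        assert fit.deviance <= base.deviance + 1e-6


class TestSjPipeline:
    def test_midpoint_pss(self, sj_dataset):
        fit = fit_sj_pipeline(sj_dataset, SMALL_GRID)
        p = fit.params
        assert fit.derived["pss"] == \
            pytest.approx(0.5 * (p.crit_low + p.crit_high), abs=1e-9)
        assert fit.derived["beats_sj2"]
        # generating criteria were -60/+80: midpoint 10
        assert fit.derived["pss"] == pytest.approx(10.0, abs=20.0)
        assert fit.derived["precision"] == pytest.approx(40.0, abs=12.0)

    def test_asymmetric_data_selects_four_param(self):
        rng = np.random.default_rng(31)
        obs = SyntheticObserver(params=ObserverParams(
            mu=0.0, sigma=28.0, crit_low=-80.0, crit_high=100.0,
            sigma_low=30.0, sigma_high=90.0))
        soas = np.tile([-400, -250, -150, -100, -60, -30, 0, 30, 60, 100,
                        150, 250, 400], 154)[:2000]
        trials = [SingleTrial(float(s),
                              simulate_response(obs, "sj", float(s), rng))
                  for s in soas]
        fit = fit_sj_pipeline(trials, SMALL_GRID)
        assert fit.model_id == "sj4"
        assert fit.derived["precision"] == pytest.approx(30.0, abs=10.0)


def test_parameter_recovery_bias_shrinks_with_trials():
    """Absolute estimation error of (pss, sigma) shrinks from the 152-trial
    to the 2280-trial dual design (averaged over a few seeded replicates)."""
    design_small = make_design("exp1b_2xsj")
    design_big = make_design("exp1a_2xsj")
    errs = {"small": [], "big": []}
    for seed in range(3):
        rng = np.random.default_rng(1000 + seed)
        obs = SyntheticObserver(params=ObserverParams(mu=-10.0, sigma=50.0))
        for label, design in (("small", design_small), ("big", design_big)):
            trials = simulate_session(obs, design, rng)
            fit = fit_model("2xsj_none", trials, SMALL_GRID)
            errs[label].append(abs(fit.params.pss - 10.0)
                               + abs(fit.params.sigma - 50.0))
    assert np.mean(errs["big"]) < np.mean(errs["small"])
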