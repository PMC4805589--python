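import numpy as np
import pytest

from rovingsj.core import ObserverParams, designate_standard
from rovingsj.adaptive import make_design
from rovingsj.models import p_choose_standard_2xsj, p_first_toj, \
    p_simultaneous_sj, ternary_probs
from rovingsj.fitting import GridSpec, fit_2xsj
from rovingsj.simulate import (SyntheticObserver, simulate_response,
                               simulate_rt_dataset, simulate_session)


class TestSimulateResponse:
    def test_noise_free_limit(self):
        obs = SyntheticObserver(params=ObserverParams(
            mu=0.0, sigma=1e-9, lapse=0.0))
        rng = np.random.default_rng(1)
        assert all(simulate_response(obs, "2xsj", (10.0, 50.0), rng) == 1
                   for _ in range(20))

    def test_task_stimulus_mismatch(self):
        obs = SyntheticObserver()
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            simulate_response(obs, "toj", (0.0, 10.0), rng)
        with pytest.raises(ValueError):
            simulate_response(obs, "2xsj", 0.0, rng)
        with pytest.raises(ValueError):
            simulate_response(obs, "quaternary", 0.0, rng)

    def test_seed_reproducibility(self):
        obs = SyntheticObserver(params=ObserverParams(mu=5.0, sigma=40.0))
        a = [simulate_response(obs, "toj", 20.0, np.random.default_rng(9))
             for _ in range(5)]
        b = [simulate_response(obs, "toj", 20.0, np.random.default_rng(9))
             for _ in range(5)]
        assert a == b

    @pytest.mark.parametrize("task,stim", [
        ("toj", 30.0), ("sj", -20.0), ("ternary", 50.0),
        ("2xsj", (0.0, 80.0)),
    ])
    def test_frequencies_match_analytic_model(self, task, stim, rng):
        obs = SyntheticObserver(params=ObserverParams(
            mu=-10.0, sigma=45.0, crit_low=-60.0, crit_high=70.0,
            bias_form="constant", bias=20.0))
        n = 20000
        responses = [simulate_response(obs, task, stim, rng)
                     for _ in range(n)]
        if task == "toj":
            expect = float(p_first_toj(stim, obs.params))
            got = np.mean(np.array(responses) == 1)
        elif task == "sj":
            expect = float(p_simultaneous_sj(stim, obs.params))
            got = np.mean(np.array(responses) == 1)
        elif task == "ternary":
            expect = float(ternary_probs(stim, obs.params)[1])
            got = np.mean(np.array(responses) == 0)
        else:
            s, t, first = stim[0], stim[1], True
            expect = float(p_choose_standard_2xsj(s, t, first, obs.params))
            got = np.mean(np.array(responses) == 1)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(got - expect) < 3 * se + 1e-3


class TestSimulateSession:
    def test_exp1b_counts_and_balance(self, rng):
        obs = SyntheticObserver(params=ObserverParams(mu=0.0, sigma=50.0))
        trials = simulate_session(obs, make_design("exp1b_2xsj"), rng)
        assert len(trials) == 152
        # each constant-stimuli SOA appears 4x per interval by construction;
        # identify the constant SOA as the member of the scheduled set that
        # accounts for the balance
        from collections import Counter
        interval1 = Counter()
        design = make_design("exp1b_2xsj")
        step = 20.0
        for t in trials:
            on_grid1 = t.soa1 in design.constant_soas
            on_grid2 = t.soa2 in design.constant_soas
            assert on_grid1 or on_grid2
        # every SOA value of the roving component is a multiple of the step
        for t in trials:
            assert (abs(t.soa1 / step - round(t.soa1 / step)) < 1e-9
                    or abs(t.soa2 / step - round(t.soa2 / step)) < 1e-9)

    def test_exp1a_total(self, rng):
        obs = SyntheticObserver(params=ObserverParams(mu=0.0, sigma=50.0))
        trials = simulate_session(obs, make_design("exp1a_2xsj"), rng)
        assert len(trials) == 2280

    def test_combined_design_sj_yield(self, rng):
        obs = SyntheticObserver(params=ObserverParams(
            mu=0.0, sigma=50.0, crit_low=-60.0, crit_high=60.0))
        duals, sjs = simulate_session(obs, make_design("exp1c_combined"), rng)
        assert len(duals) == 152
        assert len(sjs) == 304          # two SJ responses per dual trial

    def test_cancel_path(self, rng):
        obs = SyntheticObserver(params=ObserverParams(mu=0.0, sigma=50.0),
                                cancel_prob=0.1)
        trials = simulate_session(obs, make_design("exp1b_2xsj"), rng)
        n_canceled = sum(t.canceled for t in trials)
        assert n_canceled > 0
        assert len(trials) >= 152      # canceled trials repeated at block end
        assert sum(not t.canceled for t in trials) >= 152 - n_canceled

    def test_toj_session(self, rng):
        obs = SyntheticObserver(params=ObserverParams(mu=0.0, sigma=60.0))
        trials = simulate_session(obs, make_design("exp1b_toj"), rng)
        assert len(trials) == 100
        assert all(t.response in (0, 1) for t in trials)

    def test_ternary_session(self, rng):
        obs = SyntheticObserver(params=ObserverParams(
            mu=0.0, sigma=50.0, crit_low=-50.0, crit_high=50.0))
        trials = simulate_session(obs, make_design("exp2_ternary"), rng)
        assert len(trials) == 100
        assert {t.response for t in trials} <= {-1, 0, 1}

    def test_full_loop_recovery_exp1a_scale(self):
        """simulate_session -> fit_2xsj recovers the generating parameters
        at the 2280-trial scale."""
        rng = np.random.default_rng(2024)
        obs = SyntheticObserver(params=ObserverParams(mu=-20.0, sigma=60.0))
        trials = simulate_session(obs, make_design("exp1a_2xsj"), rng)
        grid = GridSpec(mu_starts=(-50.0, 50.0), sigma_starts=(30.0, 100.0),
                        beta_starts=(1.0,), c_starts=(0.0,))
        fit = fit_2xsj(trials, grid)
        assert fit.derived["pss"] == pytest.approx(20.0, abs=10.0)
        assert fit.derived["precision"] == pytest.approx(60.0, abs=10.0)

    def test_empirical_u_shape_minimum(self):
        """Proportion-choosing-standard curves grouped by standard have
        minima within one roving step of the subjective minimum."""
        rng = np.random.default_rng(99)
        obs = SyntheticObserver(params=ObserverParams.from_pss(20.0,
                                                               sigma=45.0))
        trials = simulate_session(obs, make_design("exp1a_2xsj"), rng)
        by_test = {}
        for t in trials:
            s, te, first = designate_standard(t)
            if abs(s) > 20:
                continue
            chose_std = (t.choice == 1) == first
            by_test.setdefault(te, [0, 0])
            by_test[te][0] += chose_std
            by_test[te][1] += 1
        tests = np.array(sorted(k for k, v in by_test.items()
                                if v[1] >= 15))
        props = np.array([by_test[k][0] / by_test[k][1] for k in tests])
        assert tests[np.argmin(props)] == pytest.approx(20.0, abs=20.0)


class TestSimulateRT:
    def test_counts_and_positivity(self, rng):
        obs = SyntheticObserver()
        trials = simulate_rt_dataset(obs, 50, rng)
        assert len(trials) == 100
        assert all(t.rt > 0 for t in trials)
        mods = {t.modality for t in trials}
        assert mods == {"light", "sound"}

    def test_reproducible(self):
        obs = SyntheticObserver()
        a = simulate_rt_dataset(obs, 10, np.random.default_rng(4))
        b = simulate_rt_dataset(obs, 10, np.random.default_rng(4))
        assert a == b
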