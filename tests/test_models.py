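import numpy as np
import pytest
from scipy.stats import norm

from rovingsj.core import ObserverParams
from rovingsj.models import (null_model_prob, p_choose_standard_2xsj,
                             p_first_toj, p_simultaneous_sj, ternary_probs)


def mc_dual_decision(soa_s, soa_t, standard_first, params, rng, n=10**5):
    """Independent Monte-Carlo of the full generative decision rule."""
    d_s = rng.normal(soa_s + params.mu, params.sigma, n)
    d_t = rng.normal(soa_t + params.mu, params.sigma, n)
    i1, i2 = (d_s, d_t) if standard_first else (d_t, d_s)
    if params.bias_form == "proportional":
        pick1 = i1**2 < params.bias * i2**2
    elif params.bias_form == "constant":
        pick1 = np.abs(i1) - np.abs(i2) < params.bias
    else:
        pick1 = np.abs(i1) < np.abs(i2)
    chose_std = pick1 == standard_first
    lapse = rng.random(n) < params.lapse
    chose_std = np.where(lapse, rng.random(n) < 0.5, chose_std)
    return chose_std.mean()


class TestDualModel:
    def test_symmetric_point(self):
        p = ObserverParams(mu=0.0, sigma=50.0, lapse=0.0)
        assert float(p_choose_standard_2xsj(0.0, 0.0, True, p)) == \
            pytest.approx(0.5, abs=1e-12)

    def test_easy_discrimination(self):
        p = ObserverParams(mu=0.0, sigma=50.0, lapse=0.0)
        val = float(p_choose_standard_2xsj(0.0, 300.0, True, p))
        assert val >= 0.95

    def test_ky_proportional_order_pair(self):
        """Table-1-scale proportional-bias observer: the two presentation
        orders give distinct probabilities whose average is near (but,
        with bias, not identical to) the bias-free value; frozen against
        the quadrature oracle."""
        p = ObserverParams(mu=-5.0, sigma=24.0, bias_form="proportional",
                           bias=1.79, lapse=0.01)
        p1 = float(p_choose_standard_2xsj(0.0, 100.0, True, p))
        p2 = float(p_choose_standard_2xsj(0.0, 100.0, False, p))
        assert p1 == pytest.approx(0.99338136, abs=1e-6)   # quadrature oracle
        assert p2 == pytest.approx(0.97580776, abs=1e-6)
        assert p1 > p2                         # beta > 1 favours interval 1
        assert 0.5 * (p1 + p2) == pytest.approx(0.98459456, abs=1e-6)

    @pytest.mark.parametrize("bias_form,bias", [
        ("none", 0.0), ("proportional", 1.79), ("constant", 30.0),
        ("proportional", 0.6), ("constant", -40.0),
    ])
    @pytest.mark.parametrize("stim", [
        (0.0, 100.0, True), (0.0, 100.0, False), (-20.0, 60.0, True),
        (40.0, -140.0, False),
    ])
    def test_matches_generative_monte_carlo(self, bias_form, bias, stim, rng):
        params = ObserverParams(mu=-5.0, sigma=40.0, bias_form=bias_form,
                                bias=bias, lapse=0.01)
        analytic = float(p_choose_standard_2xsj(*stim, params))
        mc = mc_dual_decision(*stim, params, rng, n=10**5)
        se = np.sqrt(analytic * (1 - analytic) / 10**5)
        assert abs(analytic - mc) < 3 * se + 1e-4

    def test_u_shape_minimum_shared_across_standards(self):
        """Every predicted function (one per standard) attains its minimum
        at the same test SOA: the subjective-simultaneity point."""
        params = ObserverParams(mu=15.0, sigma=50.0, bias_form="constant",
                                bias=25.0)
        tests = np.arange(-300.0, 301.0, 5.0)
        argmins = []
        for std in (-40.0, -20.0, 0.0, 20.0, 40.0):
            pr = 0.5 * (p_choose_standard_2xsj(std, tests, True, params)
                        + p_choose_standard_2xsj(std, tests, False, params))
            argmins.append(tests[np.argmin(pr)])
        assert len(set(argmins)) == 1
        assert argmins[0] == pytest.approx(-params.mu, abs=5.0)

    def test_invalid_bias_form(self):
        p = ObserverParams(mu=0.0, sigma=50.0)
        object.__setattr__(p, "bias_form", "weird")
        with pytest.raises(ValueError):
            p_choose_standard_2xsj(0.0, 100.0, True, p)


class TestTojModel:
    def test_pss_crossing_and_ceiling(self):
        p = ObserverParams(mu=35.0, sigma=19.0, lapse=0.01)
        assert float(p_first_toj(-35.0, p)) == pytest.approx(0.5, abs=1e-12)
        assert float(p_first_toj(1e5, p)) == pytest.approx(1 - 0.005,
                                                           abs=1e-9)
        # one sigma above the PSS: Phi(1) pre-lapse (Table-1-scale values)
        pre = (float(p_first_toj(-16.0, p)) - 0.005) / 0.99
        assert pre == pytest.approx(norm.cdf(1.0), abs=1e-9)


class TestSjModel:
    def test_criterion_crossing_is_half(self):
        p = ObserverParams(sigma=10.0, crit_low=-200.0, crit_high=200.0,
                           lapse=0.0)
        assert float(p_simultaneous_sj(-200.0, p)) == pytest.approx(0.5,
                                                                    abs=1e-4)

    def test_wide_plateau_saturates(self):
        p = ObserverParams(sigma=5.0, crit_low=-300.0, crit_high=300.0,
                           lapse=0.0)
        assert float(p_simultaneous_sj(0.0, p)) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_table1_scale_value(self):
        # B_low=-34, B_high=3, sigma=21: difference of two normal CDFs
        p = ObserverParams(sigma=21.0, crit_low=-34.0, crit_high=3.0,
                           lapse=0.01)
        ref = norm.cdf(34 / 21) - norm.cdf(-3 / 21)
        assert float(p_simultaneous_sj(0.0, p)) == \
            pytest.approx(0.99 * ref + 0.005, abs=1e-12)

    def test_unimodal_and_floor(self):
        p = ObserverParams(sigma=30.0, crit_low=-50.0, crit_high=90.0,
                           lapse=0.01)
        soas = np.linspace(-600, 600, 241)
        vals = np.asarray(p_simultaneous_sj(soas, p))
        peak = np.argmax(vals)
        assert np.all(np.diff(vals[:peak + 1]) >= -1e-12)
        assert np.all(np.diff(vals[peak:]) <= 1e-12)
        assert vals[0] == pytest.approx(0.005, abs=1e-6)


class TestTernary:
    def test_normalisation(self):
        p = ObserverParams(sigma=30.0, crit_low=-40.0, crit_high=60.0,
                           lapse=0.01, sigma_low=35.0, sigma_high=50.0)
        soas = np.linspace(-500, 500, 101)
        t = np.stack(ternary_probs(soas, p, four_param=True))
        assert np.allclose(t.sum(axis=0), 1.0, atol=1e-12)

    def test_limits_and_symmetry(self):
        p = ObserverParams(sigma=30.0, crit_low=-60.0, crit_high=60.0,
                           lapse=0.01)
        pb, ps, pa = ternary_probs(-1e5, p)
        assert float(pb) == pytest.approx(1 - 2 * 0.01 / 3, abs=1e-9)
        assert float(ps) == pytest.approx(0.01 / 3, abs=1e-9)
        pb, ps, pa = ternary_probs(0.0, p)          # criterion midpoint
        assert float(pb) == pytest.approx(float(pa), abs=1e-12)

    def test_sim_component_matches_sj(self):
        p = ObserverParams(sigma=30.0, crit_low=-40.0, crit_high=60.0,
                           lapse=0.0)
        soas = np.linspace(-200, 200, 21)
        _, ps, _ = ternary_probs(soas, p)
        assert np.allclose(ps, p_simultaneous_sj(soas, p), atol=1e-12)


class TestNullModels:
    def test_examples(self):
        assert float(null_model_prob("2xsj", 0.5, standard_first=True)) == 0.5
        assert float(null_model_prob("toj", 0.7)) == 0.7
        np.testing.assert_allclose(null_model_prob("ternary", (0.2, 0.5)),
                                   [0.2, 0.5, 0.3])

    def test_2xsj_depends_only_on_interval(self):
        sf = np.array([True, False, True])
        np.testing.assert_allclose(
            null_model_prob("2xsj", 0.8, standard_first=sf), [0.8, 0.2, 0.8])

    def test_range_errors(self):
        with pytest.raises(ValueError):
            null_model_prob("toj", 1.3)
        with pytest.raises(ValueError):
            null_model_prob("ternary", (0.7, 0.7))


def test_lapse_mixing_bounds():
    """All predictions live inside the lapse-mixing band
    [lapse/K, 1 - lapse (K-1)/K]."""
    lam = 0.01
    p2 = ObserverParams(mu=-30.0, sigma=20.0, bias_form="constant",
                        bias=50.0, lapse=lam)
    soas = np.linspace(-400, 400, 81)
    vals = p_choose_standard_2xsj(0.0, soas, False, p2)
    assert np.all(vals >= lam / 2 - 1e-12)
    assert np.all(vals <= 1 - lam / 2 + 1e-12)
    p3 = ObserverParams(sigma=25.0, crit_low=-30.0, crit_high=40.0, lapse=lam)
    t = np.stack(ternary_probs(soas, p3))
    assert np.all(t >= lam / 3 - 1e-12)
    assert np.all(t <= 1 - 2 * lam / 3 + 1e-12)
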