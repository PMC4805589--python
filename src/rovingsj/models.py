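"""Forward psychometric predictions for every task, from ObserverParams.

Each function is vectorised over SOA inputs and returns lapse-adjusted
probabilities: with a lapse rate ``lam`` and ``K`` response options the
reported probability is ``(1 - lam) * p + lam / K`` (symmetric keying
errors; keeps guessing nulls cleanly nested).

Dual-presentation (2xSJ) probabilities route through the exact
folded-normal closed form of :mod:`rovingsj.numerics`; for an unbiased
observer this coincides with the CDF of a doubly non-central F(1,1) ratio
evaluated at 1, and for a proportional bias with the same CDF evaluated at
the bias threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .core import ObserverParams
from .numerics import folded_normal_diff_cdf

__all__ = [
    "p_choose_standard_2xsj",
    "p_first_toj",
    "p_simultaneous_sj",
    "ternary_probs",
    "null_model_prob",
    "lapse_mix",
]


def lapse_mix(p, lapse, n_options):
    """Mix a decision probability with a uniform lapse channel."""
    return (1.0 - lapse) * np.asarray(p, dtype=float) + lapse / n_options


def _dual_pre_lapse(soa_standard, soa_test, standard_first, params):
    """Pre-lapse probability that the standard pair is chosen."""
    soa_standard = np.asarray(soa_standard, dtype=float)
    soa_test = np.asarray(soa_test, dtype=float)
    standard_first = np.asarray(standard_first, dtype=bool)
    m_std = soa_standard + params.mu
    m_test = soa_test + params.mu
    sigma = params.sigma

    if params.bias_form == "none":
        # P(dt_std^2 / dt_test^2 < 1) == P(|dt_std| < |dt_test|)
        return folded_normal_diff_cdf(m_std, sigma, m_test, sigma, 0.0)
    if params.bias_form == "proportional":
        beta = params.bias
        # threshold beta when the standard leads, 1/beta when it trails
        x = np.where(standard_first, beta, 1.0 / beta)
        sx = np.sqrt(x)
        # P(dt_std^2/dt_test^2 < x) = P(|dt_std| < |sqrt(x) dt_test|)
        return folded_normal_diff_cdf(m_std, sigma, sx * m_test, sx * sigma, 0.0)
    if params.bias_form == "constant":
        c = params.bias
        # interval 1 chosen when |dt_1| - |dt_2| < c
        cc = np.where(standard_first, c, -c)
        return folded_normal_diff_cdf(m_std, sigma, m_test, sigma, cc)
    raise ValueError(f"invalid bias_form {params.bias_form!r}")


def p_choose_standard_2xsj(soa_standard, soa_test, standard_first,
                           params: ObserverParams):
    """Lapse-adjusted probability that the standard pair (the SOA nearer
    zero) is reported "more simultaneous".

    Vectorised over the three stimulus arguments.  As a function of
    ``soa_test`` with the standard fixed, the prediction is U-shaped with
    its minimum at the subjective-simultaneity SOA.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    p = _dual_pre_lapse(soa_standard, soa_test, standard_first, params)
    return lapse_mix(p, params.lapse, 2)


def p_first_toj(soa, params: ObserverParams):
    """Lapse-adjusted probability of the positive-direction order response
    (e.g. "flash first" for AV).  A cumulative Gaussian crossing 0.5 at the
    PSS (= ``-params.mu``)."""
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    soa = np.asarray(soa, dtype=float)
    p = ndtr((soa + params.mu) / params.sigma)
    return lapse_mix(p, params.lapse, 2)


def _sj_pre_lapse(soa, params: ObserverParams, four_param: bool):
    soa = np.asarray(soa, dtype=float)
    bl, bh = params.crit_low, params.crit_high
    if bl is None or bh is None:
        raise ValueError("SJ model requires crit_low and crit_high")
    if four_param:
        sl = params.sigma_low if params.sigma_low is not None else params.sigma
        sh = params.sigma_high if params.sigma_high is not None else params.sigma
    else:
        sl = sh = params.sigma
    p_ge_low = ndtr((soa - bl) / sl)    # internal response above low criterion
    p_ge_high = ndtr((soa - bh) / sh)
    # difference of cumulative Gaussians; clipped at 0 because with unequal
    # sigmas the raw difference can turn (negligibly) negative in the far
    # tails where the noisy criteria may cross
    return p_ge_low, p_ge_high, np.maximum(p_ge_low - p_ge_high, 0.0)


def p_simultaneous_sj(soa, params: ObserverParams, four_param: bool = False):
    """Lapse-adjusted P("simultaneous"): difference of two cumulative
    Gaussians centred on the decision criteria.  With ``four_param`` the two
    flanks carry separate SDs (noisy criteria)."""
    _, _, p = _sj_pre_lapse(soa, params, four_param)
    return lapse_mix(p, params.lapse, 2)


def ternary_probs(soa, params: ObserverParams, four_param: bool = False):
    """Lapse-adjusted (p_before, p_simultaneous, p_after) for the ternary
    task; components sum to one and p_simultaneous matches the SJ
    prediction pre-lapse."""
    p_ge_low, p_ge_high, p_sim = _sj_pre_lapse(soa, params, four_param)
    p_before = 1.0 - p_ge_low
    p_after = p_ge_high
    total = p_before + p_sim + p_after       # 1 unless the clip engaged
    p_before, p_sim, p_after = (p_before / total, p_sim / total,
                                p_after / total)
    lam = params.lapse
    return (lapse_mix(p_before, lam, 3), lapse_mix(p_sim, lam, 3),
            lapse_mix(p_after, lam, 3))


def null_model_prob(task: str, guess_params, standard_first=None):
    """SOA-independent guessing predictions.

    * ``2xsj``: ``guess_params`` is g = P(choose interval 1); returns the
      probability of choosing the *standard*, which is g when the standard
      is in interval 1 and 1-g otherwise (``standard_first`` required).
    * ``toj`` / ``sj``: a single constant response rate.
    * ``ternary``: (g_before, g_sim) with complement g_after.
    """
    g = np.asarray(guess_params, dtype=float)
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("guess rates must lie in [0, 1]")
    if task == "2xsj":
        if standard_first is None:
            raise ValueError("2xsj null needs standard_first")
        sf = np.asarray(standard_first, dtype=bool)
        return np.where(sf, float(g), 1.0 - float(g))
    if task in ("toj", "sj"):
        return g
    if task == "ternary":
        g1, g2 = float(g[0]), float(g[1])
        if g1 + g2 > 1.0 + 1e-12:
            raise ValueError("ternary guess rates must lie on the simplex")
        return np.array([g1, g2, 1.0 - g1 - g2])
    raise ValueError(f"unknown task {task!r}")
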