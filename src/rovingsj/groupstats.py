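"""Group-level and auxiliary statistics around the model fits.

Covers the RT-based PSS/noise summary, sign-flip permutation paired
t-tests (with a max-t correction across comparison families), Pearson
correlations with BCa bootstrap significance, detection-theoretic d-prime,
and Wilson score binomial intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import binomtest, pearsonr

from .core import RTTrial
from .validation import bca_interval

__all__ = [
    "RTSummary", "rt_summary", "permutation_paired_t",
    "corr_with_bootstrap_ci", "dprime", "wilson_interval",
]

RT_FLOOR_MS = 100.0
RT_SD_MULTIPLIER = 2.5


@dataclass(frozen=True)
class RTSummary:
    """RT-based analogues of the timing-model parameters.

    ``pss_rt`` is trimmed-mean RT(light) minus trimmed-mean RT(sound): the
    head start sound appears to have over light.  ``sigma_rt`` sums the
    per-modality trimmed variances and takes the square root, matching the
    SD of the arrival-time difference under independent channels.
    """
    pss_rt: float
    sigma_rt: float
    n_excluded: dict
    trimmed_means: dict
    trimmed_vars: dict


def rt_summary(rt_trials, modalities=("light", "sound")) -> RTSummary:
    """Trim and summarise simple-RT trials.

    Trials with RT < 100 ms or RT > mean + 2.5 SD (mean/SD computed on the
    pre-trim data of that modality, single pass) are excluded per modality.
    """
    by_mod = {m: np.array([t.rt for t in rt_trials if t.modality == m])
              for m in modalities}
    means, variances, excluded = {}, {}, {}
    for m, rts in by_mod.items():
        if rts.size == 0:
            raise ValueError(f"no trials for modality {m!r}")
        ceiling = rts.mean() + RT_SD_MULTIPLIER * rts.std(ddof=1)
        keep = (rts >= RT_FLOOR_MS) & (rts <= ceiling)
        excluded[m] = int((~keep).sum())
        trimmed = rts[keep]
        if trimmed.size < 2:
            raise ValueError(f"fewer than 2 trials left for {m!r} after "
                             "trimming")
        means[m] = float(trimmed.mean())
        variances[m] = float(trimmed.var(ddof=1))
    m1, m2 = modalities
    return RTSummary(pss_rt=means[m1] - means[m2],
                     sigma_rt=float(np.sqrt(variances[m1] + variances[m2])),
                     n_excluded=excluded, trimmed_means=means,
                     trimmed_vars=variances)


def _t_stat(d):
    sd = d.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d.mean(axis=-1) / (sd / np.sqrt(d.shape[-1]))
    return np.where(sd == 0, 0.0, t)


def permutation_paired_t(x, y, n_perm: int = 10000, seed=None, rng=None):
    """Sign-flip permutation paired t-test(s), two-tailed.

    ``x`` and ``y`` are equal-length paired samples.  1-D inputs give a
    single ``(t_obs, p)``.  2-D inputs of shape (n, m) are treated as a
    family of m paired comparisons and return ``(t_obs, p_corrected)``
    arrays where the reference distribution is the maximum |t| across the
    family per sign flip (max-t multiple-comparison correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    rng = rng if rng is not None else np.random.default_rng(seed)

    d = x - y
    single = d.ndim == 1
    if single:
        d = d[:, None]
    n, m = d.shape
    t_obs = _t_stat(d.T)                       # (m,)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    t_perm = _t_stat(signs[:, None, :] * d.T[None, :, :])   # (n_perm, m)
    ref = np.abs(t_perm).max(axis=1)           # max-|t| across the family
    p = (np.sum(ref[:, None] >= np.abs(t_obs)[None, :], axis=0) + 1) \
        / (n_perm + 1)
    if single:
        return float(t_obs[0]), float(p[0])
    return t_obs, p


def corr_with_bootstrap_ci(x, y, n_resamples: int = 1999, level: float = 0.95,
                           seed=None, rng=None):
    """Pearson correlation with a BCa bootstrap CI from pair resampling.

    Returns ``(r, ci_low, ci_high, significant)`` where significance means
    the interval excludes zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    rng = rng if rng is not None else np.random.default_rng(seed)

    r = float(pearsonr(x, y).statistic)

    def _r(idx):
        xi, yi = x[idx], y[idx]
        if np.std(xi) == 0 or np.std(yi) == 0:
            return None
        return float(np.corrcoef(xi, yi)[0, 1])

    boot = []
    while len(boot) < n_resamples:
        v = _r(rng.integers(0, n, size=n))
        if v is not None:
            boot.append(v)
    jack = []
    for i in range(n):
        v = _r(np.delete(np.arange(n), i))
        if v is not None:
            jack.append(v)
    lo, hi = bca_interval(boot, r, jack, level=level)
    return r, lo, hi, not (lo <= 0.0 <= hi)


def dprime(hit_rate, fa_rate, n_signal=None, n_noise=None):
    """Detection-theoretic sensitivity ``z(hit) - z(fa)``.

    Degenerate rates (0 or 1) are corrected to ``1/(2N)`` from the boundary
    when the relevant trial count is supplied, and rejected otherwise.
    """
    def _fix(rate, n, label):
        if 0.0 < rate < 1.0:
            return rate
        if rate in (0.0, 1.0) and n:
            return 1.0 / (2 * n) if rate == 0.0 else 1.0 - 1.0 / (2 * n)
        raise ValueError(f"{label} rate {rate} not correctable "
                         "(supply the trial count)")

    h = _fix(float(hit_rate), n_signal, "hit")
    f = _fix(float(fa_rate), n_noise, "false-alarm")
    return float(ndtri(h) - ndtri(f))


def wilson_interval(k: int, n: int, level: float = 0.95):
    """Wilson score binomial confidence interval for k successes in n."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    ci = binomtest(int(k), int(n)).proportion_ci(confidence_level=level,
                                                 method="wilson")
    return float(ci.low), float(ci.high)
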