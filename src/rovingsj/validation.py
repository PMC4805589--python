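"""Monte-Carlo goodness-of-fit and BCa bootstrap confidence intervals.

Both procedures treat the stimulus values as fixed (exactly what an
adaptive design delivered) and are fully reproducible under a seed.

Goodness of fit follows the parametric-resampling logic: keep every
stimulus condition, resample responses from the fitted model, refit, and
build the reference distribution of deviances expected if the model were
the true generator.  The observed deviance is then ranked two-tailed
within that distribution.

Bootstrap intervals are non-parametric (trials resampled with
replacement) using the bias-corrected and accelerated (BCa) method, with
a leave-one-trial-out jackknife for the acceleration constant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .core import FitResult, ObserverParams
from .fitting import DualGrouped, GridSpec, SingleGrouped, _as_grouped, \
    fit_model, make_model

__all__ = [
    "GofResult", "BootstrapCI", "gof_monte_carlo", "bootstrap_bca_ci",
    "bca_interval", "simulate_responses_from_fit",
]


@dataclass
class GofResult:
    observed_deviance: float
    simulated_deviances: np.ndarray
    p_two_tailed: float
    n_sims: int
    n_missing: int
    seed: Optional[int]

    def __post_init__(self):
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p out of range")


@dataclass
class BootstrapCI:
    intervals: dict                 # name -> (low, high)
    point: dict                     # name -> point estimate
    level: float
    n_resamples: int
    method: str
    seed: Optional[int]
    n_skipped: int = 0
    flagged: bool = False
    flags: list = field(default_factory=list)


def _rng_from(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_responses_from_fit(fit: FitResult, grouped, rng):
    """New grouped data with the same stimulus conditions and trial counts,
    responses resampled from the fitted model."""
    p = fit.model.probs(fit.free_params, grouped)
    if isinstance(grouped, DualGrouped):
        k = rng.binomial(grouped.n.astype(int), np.clip(p, 0, 1)).astype(float)
        return DualGrouped(grouped.soa_std, grouped.soa_test,
                           grouped.standard_first, k, grouped.n)
    n = grouped.counts.sum(axis=1).astype(int)
    counts = np.empty_like(grouped.counts)
    if p.ndim == 1:                 # binomial single task
        k = rng.binomial(n, np.clip(p, 0, 1))
        counts[:, 1] = k
        counts[:, 0] = n - k
    else:
        for i in range(len(n)):
            counts[i] = rng.multinomial(n[i], np.clip(p[i], 0, None)
                                        / np.clip(p[i], 0, None).sum())
    return SingleGrouped(grouped.soa, counts, grouped.categories)


def gof_monte_carlo(fit: FitResult, data, n_sims: int = 1000,
                    seed: Optional[int] = None, rng=None,
                    refit_grid: Optional[GridSpec] = None) -> GofResult:
    """Monte-Carlo goodness of fit for a converged model fit.

    Each of ``n_sims`` replicates feeds the observed stimulus values into
    the fitted model, simulates responses, refits (warm-started at the
    fitted parameters by default) and records the refit deviance.  The
    two-tailed p ranks the observed deviance symmetrically:
    ``p = min(1, 2 * min(n_at_or_below, n_at_or_above) + 1) / (n_sims + 1)``.
    Replicates whose refit fails are retried once from the full grid and
    otherwise recorded as missing, never silently dropped.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    rng = _rng_from(seed, rng)
    grouped = _as_grouped(data, fit.model.task)
    grid = refit_grid or GridSpec.warm(fit.free_params)

    devs = np.full(n_sims, np.nan)
    for i in range(n_sims):
        sim = simulate_responses_from_fit(fit, grouped, rng)
        try:
            refit = fit_model(fit.model, sim, grid)
            if not refit.converged:
                raise RuntimeError("refit did not converge")
        except Exception:
            try:        # retry once from the original (full) grid
                refit = fit_model(fit.model, sim, fit.grid or GridSpec())
            except Exception:
                continue
        devs[i] = refit.deviance

    ok = np.isfinite(devs)
    n_missing = int(n_sims - ok.sum())
    if ok.sum() == 0:
        raise RuntimeError("all goodness-of-fit replicates failed")
    obs = fit.deviance
    n_below = int(np.sum(devs[ok] <= obs))
    n_above = int(np.sum(devs[ok] >= obs))
    denom = int(ok.sum()) + 1
    p = min(1.0, 2.0 * (min(n_below, n_above) + 1) / denom)
    return GofResult(observed_deviance=obs, simulated_deviances=devs,
                     p_two_tailed=p, n_sims=n_sims, n_missing=n_missing,
                     seed=seed)


# ---------------------------------------------------------------------------
# BCa machinery
# ---------------------------------------------------------------------------

def bca_interval(boot_vals, theta_hat, jack_vals, jack_weights=None,
                 level=0.95):
    """BCa endpoints from bootstrap replicates and jackknife values.

    Bias correction from the fraction of replicates below the point
    estimate; acceleration from the (weighted) jackknife skewness;
    endpoints are order statistics of the replicate distribution.
    """
    boot_vals = np.sort(np.asarray(boot_vals, dtype=float))
    B = len(boot_vals)
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    frac = np.mean(boot_vals < theta_hat)
    frac = np.clip(frac, 0.5 / B, 1.0 - 0.5 / B)
    z0 = ndtri(frac)

    jack_vals = np.asarray(jack_vals, dtype=float)
    w = np.ones_like(jack_vals) if jack_weights is None \
        else np.asarray(jack_weights, dtype=float)
    mean_j = np.sum(w * jack_vals) / w.sum()
    d = mean_j - jack_vals
    denom = np.sum(w * d * d) ** 1.5
    a = 0.0 if denom < 1e-300 else float(np.sum(w * d ** 3) / (6.0 * denom))

    alpha = 0.5 * (1.0 - level)
    out = []
    for z in (ndtri(alpha), ndtri(1.0 - alpha)):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        q = float(ndtr(adj))
        idx = int(np.clip(round(q * (B + 1)) - 1, 0, B - 1))
        out.append(float(boot_vals[idx]))
    return tuple(out)


def _default_params_of_interest(fit: FitResult) -> dict:
    if isinstance(fit.params, ObserverParams):
        p = fit.params
        out = {"pss": p.pss, "sigma": p.sigma}
        if p.bias_form != "none":
            out["bias"] = p.bias
        if p.crit_low is not None:
            out["crit_low"] = p.crit_low
            out["crit_high"] = p.crit_high
            out["pss"] = 0.5 * (p.crit_low + p.crit_high)
        return out
    return {f"g{i}": float(v) for i, v in enumerate(np.ravel(fit.params))}


def bootstrap_bca_ci(data, model, n_resamples: int = 1999, level: float = 0.95,
                     seed: Optional[int] = None, rng=None,
                     grid: Optional[GridSpec] = None,
                     fit_fn: Optional[Callable] = None,
                     params_fn: Optional[Callable] = None) -> BootstrapCI:
    """Non-parametric BCa bootstrap CIs on fitted model parameters.

    Trials are resampled with replacement and refitted (warm-started at the
    full-data optimum); the leave-one-trial-out jackknife supplies the
    acceleration, with identical trials deduplicated and weighted for
    speed.  Degenerate resamples (too few distinct conditions to identify
    the model, or a failed refit) are skipped and logged; more than 5%
    skipped flags the result.

    Parameters
    ----------
    model : str or model object
        Fitted via :func:`rovingsj.fitting.fit_model` unless ``fit_fn`` is
        given (a callable mapping a trial list to a FitResult).
    params_fn : callable, optional
        Maps a FitResult to a dict of named scalars; defaults to the
        model's natural report (pss, sigma, bias / criteria).
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    data = list(data)
    if not data:
        raise ValueError("no data")
    rng = _rng_from(seed, rng)
    params_fn = params_fn or _default_params_of_interest

    if fit_fn is None:
        model_obj = make_model(model) if isinstance(model, str) else model
        base_grid = grid or GridSpec()
        point_fit = fit_model(model_obj, data, base_grid)
        warm = GridSpec.warm(point_fit.free_params)

        def _refit(trials):
            return fit_model(model_obj, trials, warm)
        min_conditions = model_obj.n_params
        task = model_obj.task
    else:
        point_fit = fit_fn(data)
        _refit = fit_fn
        min_conditions = point_fit.n_params
        task = point_fit.model.task

    point = params_fn(point_fit)
    names = list(point)

    def _try_fit(trials):
        g = _as_grouped(trials, task)
        if g.n_conditions < min_conditions:
            return None
        try:
            f = _refit(g)
        except Exception:
            return None
        return params_fn(f)

    n = len(data)
    boot = {k: [] for k in names}
    n_skipped = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        vals = _try_fit([data[i] for i in idx])
        if vals is None:
            n_skipped += 1
            continue
        for k in names:
            boot[k].append(vals[k])

    # deduplicated leave-one-trial-out jackknife
    counter = Counter(data)
    uniq = list(counter)
    jack = {k: [] for k in names}
    weights = []
    for t in uniq:
        rest = list(data)
        rest.remove(t)
        vals = _try_fit(rest)
        if vals is None:
            continue
        weights.append(counter[t])
        for k in names:
            jack[k].append(vals[k])

    flags = []
    flagged = False
    if n_skipped > 0.05 * n_resamples:
        flagged = True
        flags.append(f"{n_skipped}/{n_resamples} resamples skipped")
    intervals = {}
    for k in names:
        lo, hi = bca_interval(boot[k], point[k], jack[k], weights, level)
        intervals[k] = (lo, hi)
        if not (lo <= point[k] <= hi):
            flagged = True
            flags.append(f"BCa interval for {k} excludes the point estimate")
    return BootstrapCI(intervals=intervals, point=point, level=level,
                       n_resamples=n_resamples, method="BCa", seed=seed,
                       n_skipped=n_skipped, flagged=flagged, flags=flags)
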