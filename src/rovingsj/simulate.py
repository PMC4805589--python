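"""Synthetic observers and session simulation.

The generative core mirrors the analytic observer model: each stimulus
pair's internal arrival-time difference is drawn from
``N(SOA + mu, sigma^2)``; the task's decision rule (single criterion for
order judgments, two criteria for simultaneity judgments, bias-thresholded
absolute comparison for dual presentations) is applied to the draw(s); a
lapse channel then replaces the response with a uniform guess at rate
``lapse``.  Response frequencies therefore match the analytic predictions
of :mod:`rovingsj.models` by construction, which is what the law-of-large-
numbers tests verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adaptive import Design, draw_soa, polya_urn_update, update_roving
from .core import DualTrial, ObserverParams, RTTrial, SingleTrial
from .fitting import LAPSE

__all__ = [
    "SyntheticObserver", "simulate_response", "simulate_session",
    "simulate_rt_dataset",
]


@dataclass(frozen=True)
class SyntheticObserver:
    """A parameterised observer able to perform every task.

    ``rt_mean``/``rt_sd`` give per-modality Gaussian reaction-time
    components (ms); defaults emulate a faster auditory than visual simple
    RT, the usual audiovisual pattern.
    """
    params: ObserverParams = field(default_factory=ObserverParams)
    rt_mean: dict = field(default_factory=lambda: {"light": 250.0,
                                                   "sound": 220.0})
    rt_sd: dict = field(default_factory=lambda: {"light": 40.0,
                                                 "sound": 35.0})
    cancel_prob: float = 0.0

    def __post_init__(self):
        if any(v <= 0 for v in self.rt_sd.values()):
            raise ValueError("RT SDs must be > 0")
        if not (0.0 <= self.cancel_prob < 1.0):
            raise ValueError("cancel_prob must be in [0, 1)")


def _internal_dt(observer, soa, rng, size=None):
    p = observer.params
    return rng.normal(soa + p.mu, p.sigma, size=size)


def _lapse_channel(response, options, lapse, rng):
    if rng.random() < lapse:
        return options[rng.integers(len(options))]
    return response


def _sj_decision(observer, dt, rng):
    """Two-criterion simultaneity decision on an internal response.

    Criteria live on the SOA axis (they absorb mu); with the four-parameter
    variant the criteria are themselves Gaussian (SD from the excess of the
    flank SDs over the latency noise).
    """
    p = observer.params
    if p.crit_low is None or p.crit_high is None:
        raise ValueError("observer lacks SJ criteria")
    c_low = p.crit_low + p.mu
    c_high = p.crit_high + p.mu
    for name, s in (("low", p.sigma_low), ("high", p.sigma_high)):
        if s is not None:
            if s < p.sigma:
                raise ValueError(f"sigma_{name} must be >= sigma for the "
                                 "generative criterion-noise decomposition")
            tau = np.sqrt(s**2 - p.sigma**2)
            if name == "low":
                c_low = rng.normal(c_low, tau) if tau > 0 else c_low
            else:
                c_high = rng.normal(c_high, tau) if tau > 0 else c_high
    if dt < c_low:
        return -1                   # first-named stimulus first
    if dt > c_high:
        return 1
    return 0


def simulate_response(observer: SyntheticObserver, task: str, stimulus,
                      rng: np.random.Generator):
    """Simulate one trial's response.

    ``stimulus`` is a single SOA for single-presentation tasks, or
    ``(soa_interval1, soa_interval2)`` for the dual task (response is the
    chosen interval, 1 or 2).
    """
    p = observer.params
    lapse = p.lapse if p.lapse is not None else LAPSE

    if task == "toj":
        if np.ndim(stimulus) != 0:
            raise ValueError("toj expects a single SOA")
        dt = _internal_dt(observer, float(stimulus), rng)
        resp = 1 if dt > 0 else 0   # 1 = positive-direction order response
        return _lapse_channel(resp, (0, 1), lapse, rng)

    if task == "sj":
        if np.ndim(stimulus) != 0:
            raise ValueError("sj expects a single SOA")
        dt = _internal_dt(observer, float(stimulus), rng)
        resp = 1 if _sj_decision(observer, dt, rng) == 0 else 0
        return _lapse_channel(resp, (0, 1), lapse, rng)

    if task == "ternary":
        if np.ndim(stimulus) != 0:
            raise ValueError("ternary expects a single SOA")
        dt = _internal_dt(observer, float(stimulus), rng)
        resp = _sj_decision(observer, dt, rng)
        return _lapse_channel(resp, (-1, 0, 1), lapse, rng)

    if task == "2xsj":
        if np.ndim(stimulus) != 1 or len(stimulus) != 2:
            raise ValueError("2xsj expects two SOAs")
        d1 = _internal_dt(observer, float(stimulus[0]), rng)
        d2 = _internal_dt(observer, float(stimulus[1]), rng)
        if p.bias_form == "proportional":
            pick1 = d1 * d1 < p.bias * d2 * d2
        elif p.bias_form == "constant":
            pick1 = abs(d1) - abs(d2) < p.bias
        else:
            pick1 = abs(d1) < abs(d2)
        resp = 1 if pick1 else 2
        return _lapse_channel(resp, (1, 2), lapse, rng)

    raise ValueError(f"unknown task {task!r}")


def _dual_schedule(design: Design, rng):
    """Balanced constant-stimuli schedule for one dual-task block: each SOA
    exactly ``reps_per_interval`` times in each interval, shuffled."""
    slots = [(soa, interval)
             for soa in design.constant_soas
             for interval in (1, 2)
             for _ in range(design.reps_per_interval)]
    rng.shuffle(slots)
    return slots


def simulate_session(observer: SyntheticObserver, design: Design,
                     rng: np.random.Generator):
    """Simulate a full session for a design template.

    Dual designs pair each constant-stimuli SOA with a draw from the roving
    distribution (updated from every simulated choice); single designs draw
    every SOA from the Polya urn.  Returns the trial list; combined designs
    return ``(dual_trials, sj_trials)`` with two SJ responses per dual
    trial, driven by the same internal arrival-time draws.
    """
    if design.task == "2xsj":
        return _simulate_dual_session(observer, design, rng)
    return _simulate_single_session(observer, design, rng)


def _simulate_dual_session(observer, design, rng):
    p = observer.params
    state = design.init_adaptive()
    duals, sjs = [], []

    def run_one(soa1, soa2):
        nonlocal state
        d1 = _internal_dt(observer, soa1, rng)
        d2 = _internal_dt(observer, soa2, rng)
        if design.combined_sj:
            for soa, dt in ((soa1, d1), (soa2, d2)):
                r = 1 if _sj_decision(observer, dt, rng) == 0 else 0
                r = _lapse_channel(r, (0, 1), p.lapse, rng)
                sjs.append(SingleTrial(soa, r))
        if p.bias_form == "proportional":
            pick1 = d1 * d1 < p.bias * d2 * d2
        elif p.bias_form == "constant":
            pick1 = abs(d1) - abs(d2) < p.bias
        else:
            pick1 = abs(d1) < abs(d2)
        choice = 1 if pick1 else 2
        choice = _lapse_channel(choice, (1, 2), p.lapse, rng)
        canceled = rng.random() < observer.cancel_prob
        duals.append(DualTrial(soa1, soa2, choice, canceled))
        if not canceled:
            state = update_roving(state, soa1 if choice == 1 else soa2)
        return canceled

    for _ in range(design.n_blocks):
        repeats = []
        for soa_const, interval in _dual_schedule(design, rng):
            soa_adapt = draw_soa(state, rng)
            pair = (soa_const, soa_adapt) if interval == 1 \
                else (soa_adapt, soa_const)
            if run_one(*pair):
                repeats.append(pair)
        for pair in repeats:        # canceled trials repeat at block end
            run_one(*pair)

    if design.combined_sj:
        return duals, sjs
    return duals


def _simulate_single_session(observer, design, rng):
    trials = []
    for _ in range(design.n_blocks):
        state = design.init_adaptive()      # urn is uniform at each block start
        k = state.rule_params.get("k", 8)
        for _ in range(design.trials_per_block):
            soa = draw_soa(state, rng)
            resp = simulate_response(observer, design.task, soa, rng)
            trials.append(SingleTrial(soa, resp))
            # urn updates need an order direction; a "simultaneous" ternary
            # response is followed by a forced order guess (not analysed)
            order = resp if design.task == "toj" else (
                1 if resp == 1 else 0 if resp == -1 else int(rng.integers(2)))
            state = polya_urn_update(state, soa, order, k)
    return trials


def simulate_rt_dataset(observer: SyntheticObserver, n_per_modality: int,
                        rng: np.random.Generator):
    """Simulate interleaved simple-RT trials: Gaussian per-modality RTs
    truncated at zero."""
    if n_per_modality < 1:
        raise ValueError("n_per_modality must be >= 1")
    trials = []
    for mod in observer.rt_mean:
        m, s = observer.rt_mean[mod], observer.rt_sd[mod]
        for _ in range(n_per_modality):
            rt = rng.normal(m, s)
            while rt <= 0:
                rt = rng.normal(m, s)
            trials.append(RTTrial(mod, float(rt)))
    idx = rng.permutation(len(trials))
    return [trials[i] for i in idx]
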