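"""Adaptive SOA-selection procedures and experiment design presets.

Two stateful samplers are provided:

* the *roving* distribution used for the second pair of a dual-presentation
  trial: a discrete distribution (20-ms steps by default) whose selection
  likelihood is boosted around whichever asynchrony was just judged most
  simultaneous, so sampled values concentrate near the observer's PSS
  without ever guaranteeing true synchrony;
* a generalized Polya-urn sampler for single-presentation (TOJ-style)
  trials: each accepted trial adds ``k`` balls displaced one grid step from
  the tested SOA, on the side indicated by the response, steering sampling
  toward the region where responses flip.

Both rules are deliberately simple count-based urns; the boost magnitude
and displacement kernel are documented defaults (the qualitative behaviour
— concentration near the point of subjective simultaneity, efficient
sampling of the psychometric function — is what is tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AdaptiveState

__all__ = [
    "init_roving", "update_roving", "init_polya_urn", "polya_urn_update",
    "draw_soa", "Design", "make_design", "DESIGN_PRESETS",
]

ROVING_BOOST_WINDOW = 40.0      # ms either side of the selected asynchrony


def _make_grid(lo, hi, step):
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def init_roving(step=20.0, span=60.0, hard_bound=300.0) -> AdaptiveState:
    """Initial roving distribution: uniform over ``[-span, +span]`` in
    ``step``-ms increments, with room to grow to ``+/-hard_bound``."""
    if step <= 0:
        raise ValueError("step must be > 0")
    for name, v in (("span", span), ("hard_bound", hard_bound)):
        if abs(round(v / step) * step - v) > 1e-9:
            raise ValueError(f"step must divide {name}")
    if span > hard_bound:
        raise ValueError("span exceeds hard bound")
    grid = _make_grid(-span, span, step)
    return AdaptiveState(grid=grid, counts=np.ones_like(grid),
                         hard_bounds=(-hard_bound, hard_bound),
                         rule="roving_2xsj", rule_params={"boost": 1.0})


def update_roving(state: AdaptiveState, selected_soa: float) -> AdaptiveState:
    """Boost all grid points within +/-40 ms of the asynchrony selected as
    most simultaneous (+1 count each), extending the support one step past
    any boosted boundary point (capped at the hard bounds).  Returns a new
    state."""
    lo, hi = state.hard_bounds
    if not (lo - 1e-9 <= selected_soa <= hi + 1e-9):
        raise ValueError(f"selected SOA {selected_soa} outside hard bounds")
    new = state.copy()
    boost = new.rule_params.get("boost", 1.0)
    near = np.abs(new.grid - selected_soa) <= ROVING_BOOST_WINDOW + 1e-9
    new.counts[near] += boost

    step = new.step
    if near[-1] and new.grid[-1] + step <= hi + 1e-9:
        new.grid = np.append(new.grid, new.grid[-1] + step)
        new.counts = np.append(new.counts, 1.0)
    if near[0] and new.grid[0] - step >= lo - 1e-9:
        new.grid = np.insert(new.grid, 0, new.grid[0] - step)
        new.counts = np.insert(new.counts, 0, 1.0)
    return new


def init_polya_urn(lo, hi, step, k, hard_bound, extreme_boost=1.0) -> AdaptiveState:
    """Uniform urn over ``[lo, hi]`` in ``step`` increments; ``extreme_boost``
    multiplies the initial count of the two endpoint SOAs (used by designs
    that over-sample the extremes)."""
    if step <= 0 or k < 0:
        raise ValueError("step must be > 0 and k >= 0")
    grid = _make_grid(lo, hi, step)
    counts = np.ones_like(grid)
    counts[0] *= extreme_boost
    counts[-1] *= extreme_boost
    return AdaptiveState(grid=grid, counts=counts,
                         hard_bounds=(-hard_bound, hard_bound),
                         rule="polya_urn", rule_params={"k": k})


def polya_urn_update(state: AdaptiveState, trial_soa: float, response: int,
                     k=None) -> AdaptiveState:
    """Add ``k`` balls one grid step from ``trial_soa`` on the side the
    response indicates (below for the positive-direction order response,
    above otherwise), expanding the support within the hard bounds when the
    target falls outside the current grid."""
    if response not in (0, 1):
        raise ValueError(f"response must be 0/1, got {response!r}")
    k = state.rule_params.get("k", 32) if k is None else k
    if k < 0:
        raise ValueError("k must be >= 0")
    new = state.copy()
    if k == 0:
        return new
    step = new.step
    idx = np.argmin(np.abs(new.grid - trial_soa))
    if abs(new.grid[idx] - trial_soa) > step / 2 + 1e-9:
        raise ValueError(f"trial SOA {trial_soa} not on grid")
    target = new.grid[idx] + (-step if response == 1 else step)
    lo, hi = new.hard_bounds
    target = min(max(target, lo), hi)
    if target < new.grid[0] - 1e-9:
        new.grid = np.insert(new.grid, 0, new.grid[0] - step)
        new.counts = np.insert(new.counts, 0, 0.0)
    elif target > new.grid[-1] + 1e-9:
        new.grid = np.append(new.grid, new.grid[-1] + step)
        new.counts = np.append(new.counts, 0.0)
    j = int(np.argmin(np.abs(new.grid - target)))
    new.counts[j] += k
    return new


def draw_soa(state: AdaptiveState, rng: np.random.Generator) -> float:
    """Sample one SOA from the state's categorical distribution."""
    return float(rng.choice(state.grid, p=state.weights))


# ---------------------------------------------------------------------------
# Experiment design presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Design:
    """A trial-schedule template.

    For dual tasks, each constant-stimuli SOA appears ``reps_per_interval``
    times in each interval per block, paired with a draw from the roving
    distribution.  For single tasks the urn supplies every SOA.
    """
    name: str
    task: str                                   # "2xsj", "toj", "ternary"
    constant_soas: tuple = ()
    reps_per_interval: int = 0
    n_blocks: int = 1
    trials_per_block: int = 0
    adaptive_init: dict = field(default_factory=dict)
    combined_sj: bool = False                   # SJ response after each pair

    @property
    def total_trials(self):
        return self.n_blocks * self.trials_per_block

    def init_adaptive(self) -> AdaptiveState:
        kind = self.adaptive_init["kind"]
        kw = {k: v for k, v in self.adaptive_init.items() if k != "kind"}
        if kind == "roving":
            return init_roving(**kw)
        return init_polya_urn(**kw)

    def to_dict(self):
        return {
            "name": self.name, "task": self.task,
            "constant_soas": list(self.constant_soas),
            "reps_per_interval": self.reps_per_interval,
            "n_blocks": self.n_blocks,
            "trials_per_block": self.trials_per_block,
            "adaptive_init": dict(self.adaptive_init),
            "combined_sj": self.combined_sj,
        }


_SOAS_WIDE = (-300, -260, -220, -180, -140, -100, -60, -40, -20, 0,
              20, 40, 60, 100, 140, 180, 220, 260, 300)
_SOAS_WIDER = (-375, -325, -275, -225, -175, -125, -75, -50, -25, 0,
               25, 50, 75, 125, 175, 225, 275, 325, 375)

_ROVING_STD = {"kind": "roving", "step": 20.0, "span": 60.0,
               "hard_bound": 300.0}


def _presets():
    d = {}
    d["exp1a_2xsj"] = Design(
        name="exp1a_2xsj", task="2xsj", constant_soas=_SOAS_WIDE,
        reps_per_interval=4, n_blocks=15, trials_per_block=152,
        adaptive_init=dict(_ROVING_STD))
    d["exp1b_2xsj"] = Design(
        name="exp1b_2xsj", task="2xsj", constant_soas=_SOAS_WIDE,
        reps_per_interval=4, n_blocks=1, trials_per_block=152,
        adaptive_init=dict(_ROVING_STD))
    d["exp1c_combined"] = Design(
        name="exp1c_combined", task="2xsj", constant_soas=_SOAS_WIDE,
        reps_per_interval=4, n_blocks=1, trials_per_block=152,
        adaptive_init=dict(_ROVING_STD), combined_sj=True)
    d["exp1_toj"] = Design(
        name="exp1_toj", task="toj", n_blocks=23, trials_per_block=100,
        adaptive_init={"kind": "urn", "lo": -225.0, "hi": 225.0, "step": 5.0,
                       "k": 32, "hard_bound": 450.0})
    d["exp1b_toj"] = Design(
        name="exp1b_toj", task="toj", n_blocks=1, trials_per_block=100,
        adaptive_init={"kind": "urn", "lo": -140.0, "hi": 140.0, "step": 20.0,
                       "k": 8, "hard_bound": 300.0})
    d["exp2_ternary"] = Design(
        name="exp2_ternary", task="ternary", n_blocks=1, trials_per_block=100,
        adaptive_init={"kind": "urn", "lo": -140.0, "hi": 140.0, "step": 20.0,
                       "k": 8, "hard_bound": 300.0})
    d["exp3_2xsj"] = Design(
        name="exp3_2xsj", task="2xsj", constant_soas=_SOAS_WIDER,
        reps_per_interval=5, n_blocks=1, trials_per_block=190,
        adaptive_init={"kind": "roving", "step": 25.0, "span": 75.0,
                       "hard_bound": 375.0})
    d["exp3_toj"] = Design(
        name="exp3_toj", task="toj", n_blocks=1, trials_per_block=152,
        adaptive_init={"kind": "urn", "lo": -450.0, "hi": 450.0, "step": 30.0,
                       "k": 8, "hard_bound": 450.0, "extreme_boost": 9.0})
    return d


DESIGN_PRESETS = _presets()


def make_design(preset: str) -> Design:
    """Return the trial-schedule template for a named experimental design."""
    try:
        return DESIGN_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown design preset {preset!r}; options: "
                         f"{sorted(DESIGN_PRESETS)}") from None
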