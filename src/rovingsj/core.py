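"""Domain data structures and coding conventions.

Units and signs
---------------
All stimulus onset asynchronies (SOAs) and model parameters are signed
milliseconds.  For an audiovisual pair, positive SOA means the second-named
stimulus trails the first (e.g. AV: beep follows flash).

The observer's internal arrival-time difference for a pair presented at a
given SOA is modelled as ``dt ~ N(SOA + mu, sigma^2)``.  Subjective
simultaneity (the SOA minimising E|dt|) therefore sits at ``-mu``; fitted
results report ``pss = -mu`` so that positive PSS retains the task's sign
convention (e.g. "simultaneity perceived when the beep trails the flash").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "DualTrial",
    "SingleTrial",
    "RTTrial",
    "ObserverParams",
    "FitResult",
    "AdaptiveState",
    "designate_standard",
]


@dataclass(frozen=True)
class DualTrial:
    """One dual-presentation (2xSJ) trial: two SOAs and the interval judged
    more simultaneous.

    Which pair is the *standard* (the SOA nearer zero) is derived via
    :func:`designate_standard`, never stored.
    """
    soa1: float
    soa2: float
    choice: int                 # 1 or 2: interval reported "more simultaneous"
    canceled: bool = False      # excluded from likelihoods, kept in files

    def __post_init__(self):
        if self.choice not in (1, 2):
            raise ValueError(f"choice must be 1 or 2, got {self.choice!r}")
        if not (math.isfinite(self.soa1) and math.isfinite(self.soa2)):
            raise ValueError("SOAs must be finite")


@dataclass(frozen=True)
class SingleTrial:
    """One single-presentation trial (TOJ, SJ or ternary).

    Response coding: TOJ 0/1 (1 = positive-direction order reported, e.g.
    "flash first" under the AV convention); SJ 0/1 (1 = "simultaneous");
    ternary -1/0/+1 (first-named first / simultaneous / second-named first).
    """
    soa: float
    response: int
    canceled: bool = False

    def __post_init__(self):
        if not math.isfinite(self.soa):
            raise ValueError("soa must be finite")
        if self.response not in (-1, 0, 1):
            raise ValueError(f"response must be in {{-1,0,1}}, got {self.response!r}")


@dataclass(frozen=True)
class RTTrial:
    """One simple reaction-time trial."""
    modality: str
    rt: float

    def __post_init__(self):
        if not (math.isfinite(self.rt) and self.rt > 0):
            raise ValueError("rt must be finite and > 0")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the detection-theoretic observer.

    Attributes
    ----------
    mu : float
        Internal subjective-asynchrony offset (ms): ``dt ~ N(SOA + mu,
        sigma^2)``.  The reported PSS is ``-mu`` (see :attr:`pss`).
    sigma : float
        Latency-noise SD of each dt distribution (ms); the "precision"
        measure.
    bias_form : {"none", "proportional", "constant"}
        Interval-bias family for dual-presentation decisions.
    bias : float
        beta (> 0, unitless threshold on the squared dt ratio) for
        proportional bias, or c (ms, threshold on the |dt| difference) for
        constant bias.  Ignored for ``bias_form="none"``.
    lapse : float
        Keyboard-error/lapse rate; fixed at 0.01 in fits.
    crit_low, crit_high : float, optional
        SJ decision criteria on the SOA axis (ms); "simultaneous" is
        reported when the internal response falls between them.
    sigma_low, sigma_high : float, optional
        Criterion-specific SDs for the four-parameter SJ variant (ms).
    """
    mu: float = 0.0
    sigma: float = 50.0
    bias_form: str = "none"
    bias: float = 0.0
    lapse: float = 0.01
    crit_low: Optional[float] = None
    crit_high: Optional[float] = None
    sigma_low: Optional[float] = None
    sigma_high: Optional[float] = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.bias_form not in ("none", "proportional", "constant"):
            raise ValueError(f"unknown bias_form {self.bias_form!r}")
        if self.bias_form == "proportional" and self.bias <= 0:
            raise ValueError("proportional bias beta must be > 0")
        if not (0.0 <= self.lapse < 1.0):
            raise ValueError("lapse must be in [0, 1)")
        if self.crit_low is not None and self.crit_high is not None:
            if self.crit_low > self.crit_high:
                raise ValueError("crit_low must be <= crit_high")
        for name in ("sigma_low", "sigma_high"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def pss(self) -> float:
        """Reported point of subjective simultaneity (ms) = ``-mu``."""
        return -self.mu

    @classmethod
    def from_pss(cls, pss: float, **kwargs) -> "ObserverParams":
        return cls(mu=-pss, **kwargs)

    def replace(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit.

    ``deviance`` is twice the log-likelihood shortfall relative to the
    saturated model (one free probability per unique stimulus condition).
    """
    model_id: str
    params: object                  # ObserverParams or guess-rate ndarray
    loglik: float
    deviance: float
    n_params: int
    converged: bool
    seed_grid: Optional[tuple] = None   # winning simplex start
    free_params: Optional[np.ndarray] = None
    nested_tests: list = field(default_factory=list)
    notes: list = field(default_factory=list)
    derived: dict = field(default_factory=dict)   # pss/precision/bias summary
    model: object = None                # fitted _Model (not serialized)
    grid: object = None                 # GridSpec used (not serialized)

    def __post_init__(self):
        if self.deviance < -1e-6:
            raise ValueError(f"negative deviance {self.deviance}")


@dataclass
class AdaptiveState:
    """Discrete SOA selection distribution for adaptive stimulus placement.

    ``counts`` is an integer-like count representation; ``weights`` derives
    from it by normalisation.  The grid has a constant step and lives inside
    ``hard_bounds``.
    """
    grid: np.ndarray
    counts: np.ndarray
    hard_bounds: tuple
    rule: str                       # "roving_2xsj" or "polya_urn"
    rule_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.grid.size < 2:
            raise ValueError("grid needs at least two points")
        steps = np.diff(self.grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError("grid step must be constant")
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts/grid shape mismatch")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("counts must be non-negative with positive sum")
        lo, hi = self.hard_bounds
        if self.grid[0] < lo - 1e-9 or self.grid[-1] > hi + 1e-9:
            raise ValueError("grid exceeds hard bounds")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def weights(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def copy(self) -> "AdaptiveState":
        return AdaptiveState(self.grid.copy(), self.counts.copy(),
                             tuple(self.hard_bounds), self.rule,
                             dict(self.rule_params))


def designate_standard(trial: DualTrial):
    """Split a dual trial into (standard, test): the standard is the SOA
    nearer zero; ties go to interval 1.

    Returns
    -------
    (soa_standard, soa_test, standard_first) : (float, float, bool)
        ``standard_first`` is True when the standard occupied interval 1.
    """
    if abs(trial.soa1) <= abs(trial.soa2):
        return trial.soa1, trial.soa2, True
    return trial.soa2, trial.soa1, False
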