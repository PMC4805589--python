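"""CSV reading/writing for trial-level data, and JSON report serialization.

Schemas (header row required, no extra or missing columns):

* dual trials:   ``soa1_ms,soa2_ms,choice``   (optional ``canceled``)
* single trials: ``soa_ms,response``          (optional ``canceled``)
* RT trials:     ``modality,rt_ms``
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .core import DualTrial, FitResult, ObserverParams, RTTrial, SingleTrial

__all__ = [
    "read_trials", "write_trials",
    "dual_trials_to_frame", "single_trials_to_frame", "rt_trials_to_frame",
    "fit_result_to_dict", "write_report",
]

_SCHEMAS = {
    "dual": ["soa1_ms", "soa2_ms", "choice"],
    "single": ["soa_ms", "response"],
    "rt": ["modality", "rt_ms"],
}
_TASK_KIND = {"2xsj": "dual", "dual": "dual",
              "toj": "single", "sj": "single", "ternary": "single",
              "single": "single", "rt": "rt"}


def _check_schema(df: pd.DataFrame, kind: str, path):
    expected = _SCHEMAS[kind]
    cols = [c for c in df.columns if c != "canceled"]
    if cols != expected:
        raise ValueError(
            f"{path}: expected columns {expected} (optional 'canceled'), "
            f"found {list(df.columns)}")


def read_trials(path, task: str):
    """Read and validate a trial CSV for the given task.

    Raises ``ValueError`` naming the offending row on any invalid record.
    """
    kind = _TASK_KIND.get(task)
    if kind is None:
        raise ValueError(f"unknown task {task!r}")
    df = pd.read_csv(path)
    _check_schema(df, kind, path)
    canceled = df["canceled"].astype(bool) if "canceled" in df else \
        pd.Series(False, index=df.index)

    trials = []
    for i, row in df.iterrows():
        try:
            if kind == "dual":
                trials.append(DualTrial(float(row["soa1_ms"]),
                                        float(row["soa2_ms"]),
                                        int(row["choice"]),
                                        bool(canceled[i])))
            elif kind == "single":
                resp = int(row["response"])
                if task == "toj" and resp not in (0, 1):
                    raise ValueError("TOJ response must be 0/1")
                if task == "sj" and resp not in (0, 1):
                    raise ValueError("SJ response must be 0/1")
                trials.append(SingleTrial(float(row["soa_ms"]), resp,
                                          bool(canceled[i])))
            else:
                trials.append(RTTrial(str(row["modality"]),
                                      float(row["rt_ms"])))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return trials


def dual_trials_to_frame(trials: Sequence[DualTrial]) -> pd.DataFrame:
    return pd.DataFrame({
        "soa1_ms": [t.soa1 for t in trials],
        "soa2_ms": [t.soa2 for t in trials],
        "choice": [t.choice for t in trials],
        "canceled": [t.canceled for t in trials],
    })


def single_trials_to_frame(trials: Sequence[SingleTrial]) -> pd.DataFrame:
    return pd.DataFrame({
        "soa_ms": [t.soa for t in trials],
        "response": [t.response for t in trials],
        "canceled": [t.canceled for t in trials],
    })


def rt_trials_to_frame(trials: Sequence[RTTrial]) -> pd.DataFrame:
    return pd.DataFrame({
        "modality": [t.modality for t in trials],
        "rt_ms": [t.rt for t in trials],
    })


def write_trials(trials, path):
    """Write trials to CSV; ``read_trials(write_trials(x)) == x``."""
    if not trials:
        raise ValueError("no trials to write")
    first = trials[0]
    if isinstance(first, DualTrial):
        df = dual_trials_to_frame(trials)
        if not df["canceled"].any():
            df = df.drop(columns="canceled")
    elif isinstance(first, SingleTrial):
        df = single_trials_to_frame(trials)
        if not df["canceled"].any():
            df = df.drop(columns="canceled")
    elif isinstance(first, RTTrial):
        df = rt_trials_to_frame(trials)
    else:
        raise TypeError(f"unsupported trial type {type(first)}")
    df.to_csv(path, index=False)


def _params_to_dict(params):
    if isinstance(params, ObserverParams):
        d = {k: v for k, v in asdict(params).items() if v is not None}
        d["pss"] = params.pss
        return d
    return {"guess_rates": np.asarray(params).tolist()}


def fit_result_to_dict(fit: FitResult) -> dict:
    d = {
        "model_id": fit.model_id,
        "params": _params_to_dict(fit.params),
        "loglik": fit.loglik,
        "deviance": fit.deviance,
        "n_params": fit.n_params,
        "converged": fit.converged,
        "seed_grid": list(fit.seed_grid) if fit.seed_grid is not None else None,
        "nested_tests": [dict(t) for t in fit.nested_tests],
        "notes": list(fit.notes),
        "derived": dict(fit.derived),
    }
    return d


def write_report(obj: dict, path):
    """Write a versioned JSON report; floats rounded to 6 decimals (well
    inside the 0.1-ms reporting resolution for ms quantities)."""
    def _round(o):
        if isinstance(o, float):
            return round(o, 6)
        if isinstance(o, dict):
            return {k: _round(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_round(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return _round(o.item())
        return o

    payload = {"schema_version": 1, **_round(obj)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
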