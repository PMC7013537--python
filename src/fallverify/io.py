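"""Readers, writers and canonical fixtures.

Two on-disk incident formats are supported:

* **CSV** (long format), one row per sample with columns
  ``incident_id, label, t_s, h_m`` — the interchange format the CLI uses;
* **JSONL**, one object per incident with ``id``, ``label`` and parallel
  ``t_s`` / ``h_m`` arrays.

Floats are written with 6 decimal places and a fixed column order, so
identical runs produce byte-identical files.  Fitted models round-trip
through plain JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import (
    CheckpointVoteClassifier,
    TotalTimeThresholdClassifier,
    midpoint_criterion,
)
from .incidents import Incident, IncidentError, NormalTimeModel
from .simulate import SimulationConfig, generate_dataset, simulate_bend, simulate_fall

__all__ = [
    "read_incidents",
    "write_incidents",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "make_fixtures",
]

logger = logging.getLogger(__name__)

_CSV_COLUMNS = ["incident_id", "label", "t_s", "h_m"]


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    raise ValueError(f"cannot infer format from {path!r}; pass format explicitly")


def read_incidents(
    path: Union[str, Path], format: Optional[str] = None
) -> List[Incident]:
    """Read and validate incidents from a CSV or JSONL file.

    Invariant violations are reported with the offending incident id.
    An empty file yields an empty list (with a warning).
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "csv":
        incidents = _read_csv(path)
    elif fmt == "jsonl":
        incidents = _read_jsonl(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not incidents:
        logger.warning("no incidents found in %s", path)
    return incidents


def _read_csv(path: Path) -> List[Incident]:
    try:
        frame = pd.read_csv(path, keep_default_na=False, dtype={"label": str})
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise IncidentError(f"{path}: missing columns {missing}")
    incidents = []
    for ident, group in frame.groupby("incident_id", sort=False):
        labels = set(group["label"])
        if len(labels) > 1:
            raise IncidentError(f"incident {ident!r}: inconsistent labels {labels}")
        label = labels.pop() or None
        incidents.append(
            Incident(
                id=str(ident),
                t=group["t_s"].to_numpy(float),
                h=group["h_m"].to_numpy(float),
                label=label,
            )
        )
    return incidents


def _read_jsonl(path: Path) -> List[Incident]:
    incidents = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise IncidentError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            incidents.append(
                Incident(
                    id=str(obj["id"]),
                    t=np.asarray(obj["t_s"], float),
                    h=np.asarray(obj["h_m"], float),
                    label=obj.get("label") or None,
                )
            )
    return incidents


def write_incidents(
    incidents: Sequence[Incident],
    path: Union[str, Path],
    format: Optional[str] = None,
) -> None:
    """Write incidents deterministically (fixed columns, 6-decimal floats)."""
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "csv":
        rows = []
        for inc in incidents:
            for t, h in zip(inc.t, inc.h):
                rows.append((inc.id, inc.label or "", t, h))
        frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        frame.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "jsonl":
        with open(path, "w") as handle:
            for inc in incidents:
                obj = {
                    "id": inc.id,
                    "label": inc.label,
                    "t_s": [round(float(v), 6) for v in inc.t],
                    "h_m": [round(float(v), 6) for v in inc.h],
                }
                handle.write(json.dumps(obj) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Model (de)serialization

def _time_model_to_dict(model: NormalTimeModel) -> dict:
    return {
        "mu": model.mu, "sigma": model.sigma,
        "lo": model.lo, "hi": model.hi, "n_obs": model.n_obs,
    }


def model_to_dict(model) -> dict:
    """Serialize a fitted classifier to a plain, diffable dict."""
    if isinstance(model, TotalTimeThresholdClassifier):
        return {
            "type": "cm1",
            "fall_model": _time_model_to_dict(model.fall_model_),
            "bend_model": _time_model_to_dict(model.bend_model_),
            "r": model.r_,
        }
    if isinstance(model, CheckpointVoteClassifier):
        return {
            "type": "cm2",
            "checkpoints": [float(v) for v in model.checkpoints_],
            "t_fall_ref": [float(v) for v in model.t_fall_ref_],
            "t_bend_ref": [float(v) for v in model.t_bend_ref_],
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(payload: dict):
    """Rebuild a fitted classifier from :func:`model_to_dict` output."""
    kind = payload.get("type")
    if kind == "cm1":
        model = TotalTimeThresholdClassifier()
        model.fall_model_ = NormalTimeModel(**payload["fall_model"])
        model.bend_model_ = NormalTimeModel(**payload["bend_model"])
        model.r_ = midpoint_criterion(model.fall_model_.mu, model.bend_model_.mu)
        model.classes_ = np.array(["BEND", "FALL"])
        return model
    if kind == "cm2":
        checkpoints = np.asarray(payload["checkpoints"], float)
        model = CheckpointVoteClassifier(n_checkpoints=len(checkpoints))
        model.checkpoints_ = checkpoints
        model.t_fall_ref_ = np.asarray(payload["t_fall_ref"], float)
        model.t_bend_ref_ = np.asarray(payload["t_bend_ref"], float)
        model.classes_ = np.array(["BEND", "FALL"])
        return model
    raise ValueError(f"unknown model type {kind!r}")


def save_model(model, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        json.dump(model_to_dict(model), handle, indent=2, sort_keys=True)
        handle.write("\n")


def load_model(path: Union[str, Path]):
    with open(path) as handle:
        return model_from_dict(json.load(handle))


# ---------------------------------------------------------------------------
# Canonical fixtures

#: Seed baked into the canonical fixture so regeneration is reproducible.
FIXTURE_SEED = 20200108


def make_fixtures(seed: int = FIXTURE_SEED) -> tuple[List[Incident], List[Incident]]:
    """The canonical small datasets the test suite exercises.

    Returns ``(dataset, mini)``: a seeded 86-incident dataset (41 falls,
    45 lean-overs) under the default study conditions, and a 10-incident
    noise-free mini-set whose trajectories follow the closed-form kinematic
    profiles exactly, for analytic tests.
    """
    dataset = generate_dataset(SimulationConfig(seed=seed))
    mini: List[Incident] = []
    fall_T = np.linspace(1.47, 2.25, 5)
    bend_T = np.linspace(2.66, 3.62, 5)
    for i, T in enumerate(fall_T):
        mini.append(simulate_fall(1.72, float(T), incident_id=f"mini_fall_{i}"))
    for i, T in enumerate(bend_T):
        mini.append(simulate_bend(1.72, float(T), incident_id=f"mini_bend_{i}"))
    return dataset, mini
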