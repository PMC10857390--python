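"""Readers and writers: CSV time series, JSON metadata, model bundles.

CSV schemas
-----------
Gait cycle:   ``time_s`` + the 12 kinematic channels in canonical order,
one file per cycle, with a JSON sidecar (subject_id, speed, sample_rate).
Force trace:  ``time_s,F_GM,F_RF,F_GAST,F_SOL`` in newtons.

All round trips preserve full double precision.  Malformed files raise
:class:`SchemaError` naming the offending column or line number.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from gaitforce.features import Normalizer
from gaitforce.gait import CHANNEL_NAMES, Anthropometrics, GaitCycle
from gaitforce.musculoskeletal import MuscleForceTrace
from gaitforce.model import MuscleForceModel, MuscleForceResults
from gaitforce.nn.network import ModelSpec, TrainConfig, build_model

GAIT_HEADER = ("time_s",) + CHANNEL_NAMES
FORCE_HEADER = ("time_s", "F_GM", "F_RF", "F_GAST", "F_SOL")


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _read_numeric_csv(path: Path, header: tuple) -> np.ndarray:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        raise SchemaError(f"{path}: file is empty")
    got = tuple(rows[0])
    if got != header:
        missing = set(header) - set(got)
        extra = set(got) - set(header)
        detail = []
        if missing:
            detail.append(f"missing columns {sorted(missing)}")
        if extra:
            detail.append(f"unexpected columns {sorted(extra)}")
        if not detail:
            detail.append("columns out of order")
        raise SchemaError(f"{path}: bad header ({'; '.join(detail)})")
    if len(rows) == 1:
        raise SchemaError(f"{path}: no data rows")
    data = np.empty((len(rows) - 1, len(header)))
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise SchemaError(
                f"{path}: line {ln}: expected {len(header)} fields, "
                f"got {len(row)}")
        try:
            data[ln - 2] = [float(v) for v in row]
        except ValueError as exc:
            raise SchemaError(f"{path}: line {ln}: non-numeric cell "
                              f"({exc})") from None
    return data


def write_gait_cycle_csv(cycle: GaitCycle, path) -> None:
    path = Path(path)
    table = np.column_stack([cycle.time, cycle.data])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GAIT_HEADER)
        for row in table:
            writer.writerow([repr(float(v)) for v in row])
    sidecar = {"subject_id": cycle.subject_id, "speed": cycle.speed,
               "sample_rate": cycle.sample_rate}
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_gait_cycle_csv(path) -> GaitCycle:
    path = Path(path)
    data = _read_numeric_csv(path, GAIT_HEADER)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:  # reconstruct the rate from the time column
        dt = np.diff(data[:, 0]).mean()
        meta = {"subject_id": "", "speed": float("nan"),
                "sample_rate": 1.0 / dt}
    return GaitCycle(subject_id=meta["subject_id"], speed=meta["speed"],
                     sample_rate=meta["sample_rate"], data=data[:, 1:])


def write_force_trace_csv(trace: MuscleForceTrace, time: np.ndarray,
                          path) -> None:
    path = Path(path)
    table = np.column_stack([time, trace.forces])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FORCE_HEADER)
        for row in table:
            writer.writerow([repr(float(v)) for v in row])


def read_force_trace_csv(path) -> MuscleForceTrace:
    data = _read_numeric_csv(Path(path), FORCE_HEADER)
    return MuscleForceTrace(forces=data[:, 1:])


def write_subjects_json(subjects: list, path) -> None:
    payload = [
        {"subject_id": s.subject_id, "height": s.height, "mass": s.mass,
         "thigh_length": s.thigh_length, "shank_length": s.shank_length,
         "cohort": s.cohort}
        for s in subjects
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_subjects_json(path) -> list:
    payload = json.loads(Path(path).read_text())
    try:
        return [Anthropometrics(**entry) for entry in payload]
    except TypeError as exc:
        raise SchemaError(f"{path}: bad subject record ({exc})") from None


def save_results(results: MuscleForceResults, out_dir) -> None:
    """Persist a fitted estimator: spec, config, normalizer, weights."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "spec": vars(results.spec) | {},
        "cfg": vars(results.cfg) | {},
        "n_timesteps": results.model.n_timesteps,
        "n_features": results.model.train_features[0].values.shape[1],
    }
    meta["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in meta["spec"].items()}
    (out_dir / "model.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))
    (out_dir / "normalizer.json").write_text(results.normalizer.to_json())
    state = {f"{li}.{name}": arr
             for (li, name), arr in results.network.get_state().items()}
    np.savez(out_dir / "weights.npz", **state)
    with open(out_dir / "history.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_mae", "val_mae"])
        val = results.history.get("val_mae", [])
        for i, tr in enumerate(results.history.get("train_mae", [])):
            writer.writerow([i, repr(tr),
                             repr(val[i]) if i < len(val) else ""])


def load_results(out_dir) -> MuscleForceResults:
    """Reload a persisted estimator for inference and evaluation."""
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "model.json").read_text())
    spec_kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in meta["spec"].items()}
    spec = ModelSpec(**spec_kwargs)
    cfg = TrainConfig(**meta["cfg"])
    normalizer = Normalizer.from_json(
        (out_dir / "normalizer.json").read_text())
    network = build_model(spec, meta["n_timesteps"], meta["n_features"],
                          seed=cfg.seed)
    with np.load(out_dir / "weights.npz") as npz:
        state = {}
        for key in npz.files:
            li, name = key.split(".", 1)
            state[(int(li), name)] = npz[key]
    network.set_state(state)

    model = MuscleForceModel.__new__(MuscleForceModel)
    model.spec = spec
    model.normalizer = normalizer
    model.n_timesteps = meta["n_timesteps"]
    model.train_features = []
    model.train_forces = []
    model.val_features = None
    model.val_forces = None
    history: dict = {"train_mae": [], "val_mae": []}
    hist_path = out_dir / "history.csv"
    if hist_path.exists():
        with open(hist_path, newline="") as fh:
            for row in list(csv.reader(fh))[1:]:
                history["train_mae"].append(float(row[1]))
                if len(row) > 2 and row[2]:
                    history["val_mae"].append(float(row[2]))
    return MuscleForceResults(model=model, network=network, cfg=cfg,
                              history=history)
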