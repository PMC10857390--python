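"""Evaluation metrics and the benchmark experiment protocols.

Two metrics compare an estimated force series y against the reference x:

* percentage root-mean-square error,
  RMSE% = sqrt(sum (x_i - y_i)^2) / sqrt(sum x_i^2) * 100, and
* Pearson's product-moment correlation r.

Metrics are computed per gait cycle and then averaged across cycles
(concatenation mode available for sensitivity checks).  Report averages
over the four target muscles are always recomputed as arithmetic means
of the per-muscle entries, never copied from a free-standing value.

Protocols:

* ``run_training_validation`` — per walking speed, train each estimator
  on the training split and score the held-out validation split.
* ``run_intrasession``       — fuse all speeds into one dataset, train
  on the fused training split, score the fused remainder.
* ``run_intersession``       — score an intrasession-trained estimator,
  without retraining, on cycles from unseen subjects at the training
  speeds and at unseen speeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from gaitforce.gait import ExperimentDesign, sample_subject, \
    synthesize_gait_cycle
from gaitforce.features import assemble_features
from gaitforce.model import MuscleForceModel, MuscleForceResults, \
    supervised_pairs
from gaitforce.musculoskeletal import TARGET_MUSCLES, reference_forces
from gaitforce.nn.network import ModelSpec, TrainConfig
from gaitforce import gait as _gait


def rmse_percent(x: np.ndarray, y: np.ndarray) -> float:
    """Percentage RMSE of estimate y against reference x."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    denom = np.sum(x ** 2)
    if denom == 0:
        raise ValueError("RMSE%% undefined for an all-zero reference")
    return float(np.sqrt(np.sum((x - y) ** 2) / denom) * 100.0)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("correlation needs at least two samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc ** 2))
    sy = np.sqrt(np.sum(yc ** 2))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.sum(xc * yc) / (sx * sy))


def metrics_over_cycles(references: list, predictions: list,
                        mode: str = "per_cycle") -> dict:
    """Per-muscle r and RMSE% over matched (T, 4) force arrays.

    ``per_cycle`` computes both metrics on each cycle and averages
    across cycles; ``concatenate`` joins all cycles first.
    """
    if not references or len(references) != len(predictions):
        raise ValueError("need matching, nonempty reference/prediction "
                         "lists")
    out: dict = {}
    for mi, muscle in enumerate(TARGET_MUSCLES):
        if mode == "concatenate":
            ref = np.concatenate([r[:, mi] for r in references])
            pred = np.concatenate([p[:, mi] for p in predictions])
            out[muscle] = {"r": pearson_r(ref, pred),
                           "rmse_percent": rmse_percent(ref, pred)}
        elif mode == "per_cycle":
            rs, es = [], []
            for ref, pred in zip(references, predictions):
                rs.append(pearson_r(ref[:, mi], pred[:, mi]))
                es.append(rmse_percent(ref[:, mi], pred[:, mi]))
            out[muscle] = {"r": float(np.mean(rs)),
                           "rmse_percent": float(np.mean(es))}
        else:
            raise ValueError(f"unknown metric mode {mode!r}")
    return out


def four_muscle_average(values) -> float:
    """Arithmetic mean over the four per-muscle metric values."""
    values = [float(v) for v in values]
    if len(values) != len(TARGET_MUSCLES):
        raise ValueError(
            f"expected {len(TARGET_MUSCLES)} per-muscle values, "
            f"got {len(values)}")
    return float(np.mean(values))


@dataclass
class EvaluationReport:
    """Nested per-(model, group, muscle) metric table.

    ``metrics[model][group][muscle] = {"r": .., "rmse_percent": ..}``
    where ``group`` is a speed label or a protocol dataset label.  The
    four-muscle "Average" rows are recomputed on access.
    """

    metrics: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def set_entry(self, model: str, group: str, per_muscle: dict) -> None:
        self.metrics.setdefault(model, {})[group] = {
            m: {"r": float(per_muscle[m]["r"]),
                "rmse_percent": float(per_muscle[m]["rmse_percent"])}
            for m in TARGET_MUSCLES
        }

    def average(self, model: str, group: str, metric: str = "r") -> float:
        cell = self.metrics[model][group]
        return four_muscle_average(cell[m][metric]
                                   for m in TARGET_MUSCLES)

    def to_dict(self) -> dict:
        out: dict = {"meta": self.meta, "metrics": {}}
        for model, groups in self.metrics.items():
            out["metrics"][model] = {}
            for group, cell in groups.items():
                entry = {m: dict(cell[m]) for m in TARGET_MUSCLES}
                entry["Average"] = {
                    "r": self.average(model, group, "r"),
                    "rmse_percent": self.average(model, group,
                                                 "rmse_percent"),
                }
                out["metrics"][model][group] = entry
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self, metric: str = "r") -> str:
        """Aligned table: rows muscles + Average, columns models."""
        models = sorted(self.metrics)
        groups: list = []
        for m in models:
            for g in self.metrics[m]:
                if g not in groups:
                    groups.append(g)
        fmt = ".4f" if metric == "r" else ".2f"
        lines = [f"{'Group':<14}{'Muscle':<10}"
                 + "".join(f"{m:>12}" for m in models)]
        for g in groups:
            for muscle in TARGET_MUSCLES + ("Average",):
                row = f"{g:<14}{muscle:<10}"
                for model in models:
                    if g not in self.metrics.get(model, {}):
                        row += f"{'-':>12}"
                    elif muscle == "Average":
                        row += f"{self.average(model, g, metric):>12{fmt}}"
                    else:
                        val = self.metrics[model][g][muscle][metric]
                        row += f"{val:>12{fmt}}"
                lines.append(row)
        return "\n".join(lines)


def evaluate_model(results: MuscleForceResults, features: list,
                   forces: list, mode: str = "per_cycle") -> dict:
    """Score a fitted estimator against reference forces."""
    if not features:
        raise ValueError("evaluation subset is empty")
    preds = [results.predict(f) for f in features]
    refs = [tr.forces for tr in forces]
    return metrics_over_cycles(refs, preds, mode=mode)


def _single_speed_design(design: ExperimentDesign,
                         speed: float) -> ExperimentDesign:
    return ExperimentDesign(
        n_young=design.n_young, n_elderly=design.n_elderly,
        cycles_per_subject_per_speed=design.cycles_per_subject_per_speed,
        speeds=(speed,),
        train_cycles_per_subject=design.train_cycles_per_subject,
        n_samples=design.n_samples, seed=design.seed)


def run_training_validation(design: ExperimentDesign,
                            kinds=("cnn", "lstm", "cnn_lstm"),
                            cfg: TrainConfig | None = None,
                            muscles: list | None = None
                            ) -> EvaluationReport:
    """Per-speed training/validation protocol.

    For each walking speed: build the dataset, train each estimator kind
    on the training split and evaluate on the held-out validation split.
    """
    cfg = cfg or TrainConfig()
    report = EvaluationReport(meta={"protocol": "training_validation",
                                    "seed": cfg.seed})
    for speed in design.speeds:
        ds = _gait.build_dataset(_single_speed_design(design, speed))
        for kind in kinds:
            model = MuscleForceModel.from_dataset(
                ds, spec=ModelSpec(kind=kind), muscles=muscles)
            res = model.fit(cfg)
            met = res.evaluate(model.val_features, model.val_forces)
            report.set_entry(kind, f"{speed:.1f} m/s", met)
    return report


def run_intrasession(design: ExperimentDesign,
                     kinds=("cnn", "lstm", "cnn_lstm"),
                     cfg: TrainConfig | None = None,
                     muscles: list | None = None,
                     return_models: bool = False):
    """Fused-speed protocol: one model per kind across all speeds.

    The per-subject train/validation split is applied at every speed, so
    the paper-default design fuses 1200 cycles into 960 training and 240
    validation cycles.
    """
    cfg = cfg or TrainConfig()
    ds = _gait.build_dataset(design)
    report = EvaluationReport(meta={"protocol": "intrasession",
                                    "seed": cfg.seed,
                                    "n_cycles": len(ds.cycles),
                                    "n_train": len(ds.split("train"))})
    fitted = {}
    for kind in kinds:
        model = MuscleForceModel.from_dataset(
            ds, spec=ModelSpec(kind=kind), muscles=muscles)
        res = model.fit(cfg)
        met = res.evaluate(model.val_features, model.val_forces)
        report.set_entry(kind, "fused", met)
        fitted[kind] = res
    if return_models:
        return report, fitted
    return report


def _external_cycles(design: ExperimentDesign, speeds, n_young: int,
                     n_elderly: int, cycles_per_subject_per_speed: int,
                     seed: int,
                     angle_noise_sd: float = _gait.DEFAULT_ANGLE_NOISE_SD,
                     velocity_noise_sd: float =
                     _gait.DEFAULT_VELOCITY_NOISE_SD):
    """Generate unseen-subject evaluation cycles with their subjects."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_young):
        subjects.append(sample_subject(int(rng.integers(2**31)), "young",
                                       subject_id=f"XY{i:02d}"))
    for i in range(n_elderly):
        subjects.append(sample_subject(int(rng.integers(2**31)),
                                       "elderly",
                                       subject_id=f"XE{i:02d}"))
    pairs = []
    for speed in speeds:
        for subject in subjects:
            for _ in range(cycles_per_subject_per_speed):
                clean = synthesize_gait_cycle(
                    subject, speed, design.n_samples,
                    seed=int(rng.integers(2**31)))
                observed = clean
                if angle_noise_sd > 0 or velocity_noise_sd > 0:
                    observed = _gait.add_sensor_noise(
                        clean, angle_noise_sd, velocity_noise_sd,
                        seed=int(rng.integers(2**31)))
                pairs.append((observed, clean, subject))
    return pairs


def run_intersession(design: ExperimentDesign,
                     trained: MuscleForceResults,
                     cfg: TrainConfig | None = None,
                     n_unseen_young: int = 3, n_unseen_elderly: int = 3,
                     cycles_per_subject_per_speed: int = 2,
                     unseen_speeds=(1.1, 1.6),
                     muscles: list | None = None) -> EvaluationReport:
    """Unseen-subject / unseen-speed generalization protocol.

    Dataset 1: unseen subjects walking at the training speeds (defaults:
    2 cycles x 3 speeds x 6 subjects = 36 cycles).  Dataset 2: the same
    subjects at speeds absent from training (2 x 2 x 6 = 24 cycles).
    The trained estimator is scored without retraining.
    """
    cfg = cfg or trained.cfg
    report = EvaluationReport(meta={"protocol": "intersession",
                                    "seed": cfg.seed,
                                    "unseen_speeds": list(unseen_speeds)})
    for label, speeds in (("seen_speeds", design.speeds),
                          ("unseen_speeds", tuple(unseen_speeds))):
        pairs = _external_cycles(design, speeds, n_unseen_young,
                                 n_unseen_elderly,
                                 cycles_per_subject_per_speed,
                                 seed=design.seed + 7919)
        feats = [assemble_features(obs, s) for obs, _, s in pairs]
        forces = [reference_forces(clean, s, muscles)
                  for _, clean, s in pairs]
        met = evaluate_model(trained, feats, forces)
        report.set_entry(trained.spec.kind, label, met)
        report.meta[f"n_cycles_{label}"] = len(pairs)
    return report
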