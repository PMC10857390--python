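"""Input assembly and min-max normalization for the estimators.

The network input is a T x 16 sequence: the 12 kinematic channels of a
gait cycle plus four anthropometric constants (height, mass, thigh length,
shank length) broadcast over time.  Normalization maps each channel to
[-1, 1] by its training-set extrema,

    x_tilde = 2 * (x - x_min) / (x_max - x_min) - 1,

and is fitted on the training split only; validation/test values may fall
outside [-1, 1].  Target forces are scaled to [0, 1] by training-set
per-muscle maxima before loss computation and unscaled for reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from gaitforce.gait import CHANNEL_NAMES, Anthropometrics, GaitCycle
from gaitforce.musculoskeletal import TARGET_MUSCLES, MuscleForceTrace

ANTHRO_CHANNELS = ("height", "mass", "thigh_length", "shank_length")
FEATURE_NAMES = CHANNEL_NAMES + ANTHRO_CHANNELS
N_FEATURES = len(FEATURE_NAMES)  # 16


@dataclass
class FeatureSequence:
    """T x 16 network input, optionally normalized."""

    values: np.ndarray
    channel_names: tuple = FEATURE_NAMES
    normalized: bool = False
    subject_id: str = ""
    speed: float = float("nan")

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must be (T, {N_FEATURES}), "
                f"got {self.values.shape}")


@dataclass
class Normalizer:
    """Per-channel min/max for inputs plus per-muscle force scales."""

    x_min: np.ndarray = field(default=None)
    x_max: np.ndarray = field(default=None)
    force_scale: np.ndarray = field(default=None)  # (4,) training maxima, N

    @property
    def fitted(self) -> bool:
        return self.x_min is not None and self.x_max is not None

    def to_json(self) -> str:
        return json.dumps({
            "channel_names": list(FEATURE_NAMES),
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "force_scale": (self.force_scale.tolist()
                            if self.force_scale is not None else None),
            "muscles": list(TARGET_MUSCLES),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        obj = json.loads(text)
        fs = obj.get("force_scale")
        return cls(x_min=np.asarray(obj["x_min"], dtype=float),
                   x_max=np.asarray(obj["x_max"], dtype=float),
                   force_scale=None if fs is None
                   else np.asarray(fs, dtype=float))


def assemble_features(cycle: GaitCycle,
                      subject: Anthropometrics) -> FeatureSequence:
    """Stack kinematic channels with broadcast anthropometric constants."""
    if cycle.subject_id and cycle.subject_id != subject.subject_id:
        raise ValueError(
            f"cycle belongs to {cycle.subject_id!r}, not "
            f"{subject.subject_id!r}")
    T = cycle.n_samples
    anthro = np.array([subject.height, subject.mass,
                       subject.thigh_length, subject.shank_length])
    values = np.hstack([cycle.data, np.tile(anthro, (T, 1))])
    return FeatureSequence(values=values, subject_id=subject.subject_id,
                           speed=cycle.speed)


def fit_normalizer(train_features: list,
                   train_forces: list | None = None) -> Normalizer:
    """Per-channel extrema over the training split only."""
    if not train_features:
        raise ValueError("cannot fit a normalizer on an empty training set")
    stacked = np.vstack([f.values for f in train_features])
    norm = Normalizer(x_min=stacked.min(axis=0), x_max=stacked.max(axis=0))
    if train_forces:
        all_forces = np.vstack([tr.forces for tr in train_forces])
        scale = all_forces.max(axis=0)
        scale[scale == 0] = 1.0  # a muscle silent in training stays silent
        norm.force_scale = scale
    return norm


def normalize(features: FeatureSequence, norm: Normalizer) -> FeatureSequence:
    """Map each channel to [-1, 1] by the fitted training extrema.

    Degenerate channels (x_max == x_min) map to 0.  Out-of-range values
    (validation/test data beyond the training extrema) pass through the
    affine map untouched and may fall outside [-1, 1].
    """
    if not norm.fitted:
        raise ValueError("normalizer has not been fitted")
    span = norm.x_max - norm.x_min
    ok = span > 0
    values = np.zeros_like(features.values)
    values[:, ok] = (2.0 * (features.values[:, ok] - norm.x_min[ok])
                     / span[ok] - 1.0)
    return FeatureSequence(values=values, normalized=True,
                           subject_id=features.subject_id,
                           speed=features.speed)


def denormalize(features: FeatureSequence,
                norm: Normalizer) -> FeatureSequence:
    """Inverse of :func:`normalize` on non-degenerate channels."""
    if not norm.fitted:
        raise ValueError("normalizer has not been fitted")
    span = norm.x_max - norm.x_min
    ok = span > 0
    values = np.tile(norm.x_min, (features.values.shape[0], 1))
    values[:, ok] = ((features.values[:, ok] + 1.0) / 2.0 * span[ok]
                     + norm.x_min[ok])
    return FeatureSequence(values=values, normalized=False,
                           subject_id=features.subject_id,
                           speed=features.speed)


def scale_forces(trace: MuscleForceTrace, norm: Normalizer) -> np.ndarray:
    """Scale target forces to [0, 1] by training-set per-muscle maxima."""
    if norm.force_scale is None:
        raise ValueError("normalizer has no force scales")
    return trace.forces / norm.force_scale[None, :]


def unscale_forces(scaled: np.ndarray, norm: Normalizer) -> np.ndarray:
    """Back to newtons, clipped at 0 (muscle forces are nonnegative)."""
    if norm.force_scale is None:
        raise ValueError("normalizer has no force scales")
    return np.clip(scaled * norm.force_scale[None, :], 0.0, None)


def reshape_for_cnn(features: FeatureSequence) -> np.ndarray:
    """View the T x 16 sequence as a single-channel rectangle image.

    Shape (1, T, 16): rows are time, columns are features, no permutation;
    the round trip through :func:`inverse_reshape` is lossless.
    """
    return features.values[None, :, :]


def inverse_reshape(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[0] != 1:
        raise ValueError("expected a (1, T, C) image")
    return image[0]
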