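"""Synthetic lower-limb gait kinematics.

Generates per-subject anthropometrics and sagittal-plane hip/knee/ankle
angle and angular-velocity trajectories for one gait cycle at a given
walking speed.  Each joint angle is a truncated 4-harmonic Fourier series
over the cycle phase; angular velocities are the analytic time derivatives
of the same series, so noiseless cycles satisfy the derivative and
periodicity invariants exactly.  Harmonic amplitudes grow smoothly with
walking speed, cycle duration shrinks linearly with speed, and all
randomness (anthropometrics, per-cycle amplitude jitter, sensor noise,
dataset splits) is driven by explicit integer seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

#: Canonical channel ordering shared with the CSV layout and the feature
#: pipeline: six angles (rad) then six angular velocities (rad/s).
CHANNEL_NAMES = (
    "l_hip_ang", "l_knee_ang", "l_ankle_ang",
    "r_hip_ang", "r_knee_ang", "r_ankle_ang",
    "l_hip_vel", "l_knee_vel", "l_ankle_vel",
    "r_hip_vel", "r_knee_vel", "r_ankle_vel",
)

JOINTS = ("hip", "knee", "ankle")

#: Cohort anthropometric distributions: mean/SD of body mass (kg) and
#: height (m) for young and elderly adults.
COHORTS = {
    "young": {"mass": (61.4, 11.3), "height": (1.672, 0.125)},
    "elderly": {"mass": (58.7, 10.7), "height": (1.658, 0.095)},
}

#: Segment lengths as standard fractions of standing height.
THIGH_FRACTION = 0.245
SHANK_FRACTION = 0.246

# 4-harmonic joint-angle templates (rad): mean, cosine and sine
# coefficients of harmonics 1..4 of the gait-cycle phase.  Shapes follow
# normative level-walking ranges: hip flexion/extension ~ +-0.35 rad,
# knee flexion 0..1.1 rad, ankle ~ +-0.3 rad.
_TEMPLATES = {
    "hip": {
        "a0": 0.08,
        "cos": np.array([0.30, 0.05, 0.015, 0.005]),
        "sin": np.array([0.12, -0.04, 0.010, -0.003]),
    },
    "knee": {
        "a0": 0.55,
        "cos": np.array([-0.25, -0.18, 0.03, 0.010]),
        "sin": np.array([-0.35, 0.10, -0.02, 0.005]),
    },
    "ankle": {
        "a0": -0.02,
        "cos": np.array([0.10, -0.12, 0.03, -0.010]),
        "sin": np.array([-0.22, 0.06, 0.02, 0.004]),
    },
}

#: Harmonic amplitudes scale by 1 + _SPEED_GAIN * (v - 1.5 m/s).
_SPEED_GAIN = 0.25
#: Elderly subjects walk with slightly reduced joint excursions.
_ELDERLY_AMPLITUDE = 0.95
#: Cycle duration (s) decreases linearly with speed:
#: 1.15 s at 1.2 m/s down to 0.95 s at 1.8 m/s.
_DURATION_INTERCEPT = 1.55
_DURATION_SLOPE = -1.0 / 3.0


@dataclass(frozen=True)
class Anthropometrics:
    """Per-subject scalars that scale kinematics and the force model."""

    subject_id: str
    height: float          # m
    mass: float            # kg
    thigh_length: float    # m
    shank_length: float    # m
    cohort: str            # "young" | "elderly"

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        for name in ("height", "mass", "thigh_length", "shank_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.thigh_length >= self.height or self.shank_length >= self.height:
            raise ValueError("segment lengths must be shorter than height")


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle of 12-channel sagittal kinematics.

    ``data`` has shape (T, 12) in :data:`CHANNEL_NAMES` order.  The cycle
    spans heel strike to ipsilateral heel strike: sample 0 and sample T-1
    are the same phase point, so noiseless angle channels wrap exactly.
    """

    subject_id: str
    speed: float           # m/s
    sample_rate: float     # Hz
    data: np.ndarray       # (T, 12)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Cycle duration in seconds (first to last sample)."""
        return (self.n_samples - 1) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNEL_NAMES.index(name)]

    def left_angles(self) -> np.ndarray:
        """(T, 3) left hip/knee/ankle angles in radians."""
        return self.data[:, 0:3]

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNEL_NAMES):
            raise ValueError(
                f"cycle data must be (T, {len(CHANNEL_NAMES)}), "
                f"got {self.data.shape}"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """Counts and speeds defining a synthetic data-collection campaign."""

    n_young: int = 20
    n_elderly: int = 20
    cycles_per_subject_per_speed: int = 10
    speeds: tuple = (1.2, 1.5, 1.8)
    train_cycles_per_subject: int = 8
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.speeds) == 0:
            raise ValueError("speeds must be nonempty")
        if self.train_cycles_per_subject > self.cycles_per_subject_per_speed:
            raise ValueError(
                "train_cycles_per_subject cannot exceed "
                "cycles_per_subject_per_speed"
            )
        if self.n_young < 0 or self.n_elderly < 0:
            raise ValueError("subject counts must be nonnegative")
        if self.n_young + self.n_elderly == 0:
            raise ValueError("design needs at least one subject")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_elderly

    @property
    def cycles_per_speed(self) -> int:
        return self.n_subjects * self.cycles_per_subject_per_speed

    @property
    def total_cycles(self) -> int:
        return self.cycles_per_speed * len(self.speeds)


#: Default sensor-noise magnitudes emulating IMU error relative to an
#: optical reference (angles in rad, angular velocities in rad/s).
DEFAULT_ANGLE_NOISE_SD = 0.02
DEFAULT_VELOCITY_NOISE_SD = 0.1


@dataclass(frozen=True)
class LabelledCycle:
    """A sensor-observed cycle with its split label and clean truth.

    ``cycle`` is what the estimator sees (possibly noisy); ``truth`` is
    the noiseless kinematics the reference forces are derived from, as
    in a lab where the optical system, not the IMUs, drives the
    musculoskeletal analysis.  ``truth`` is ``cycle`` itself when no
    noise was added.
    """

    cycle: GaitCycle
    split: str  # "train" | "validation" | "test"
    truth: GaitCycle | None = None

    @property
    def clean(self) -> GaitCycle:
        return self.truth if self.truth is not None else self.cycle


@dataclass
class GaitDataset:
    subjects: list = field(default_factory=list)
    cycles: list = field(default_factory=list)  # list[LabelledCycle]
    design: ExperimentDesign | None = None

    def split(self, label: str) -> list:
        return [lc.cycle for lc in self.cycles if lc.split == label]

    def labelled(self, label: str) -> list:
        return [lc for lc in self.cycles if lc.split == label]

    def at_speed(self, speed: float, split: str | None = None) -> list:
        out = []
        for lc in self.cycles:
            if not np.isclose(lc.cycle.speed, speed):
                continue
            if split is not None and lc.split != split:
                continue
            out.append(lc.cycle)
        return out

    def subject(self, subject_id: str) -> Anthropometrics:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def cycle_duration(speed: float) -> float:
    """Gait-cycle duration (s) at a given walking speed (m/s)."""
    return _DURATION_INTERCEPT + _DURATION_SLOPE * speed


def sample_subject(seed: int, cohort: str, subject_id: str | None = None,
                   mass_sd: float | None = None,
                   height_sd: float | None = None) -> Anthropometrics:
    """Draw one subject from a cohort's anthropometric distribution.

    Mass and height come from Gaussians truncated at +-3 SD (and at zero),
    with the cohort's published mean and SD; thigh and shank lengths are
    fixed fractions of height.  Passing ``mass_sd=0`` / ``height_sd=0``
    returns the cohort means exactly.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    rng = np.random.default_rng(seed)
    params = COHORTS[cohort]
    m_mu, m_sd = params["mass"]
    h_mu, h_sd = params["height"]
    if mass_sd is not None:
        m_sd = mass_sd
    if height_sd is not None:
        h_sd = height_sd

    def draw(mu: float, sd: float) -> float:
        if sd == 0:
            return mu
        lo = max(-3.0, -mu / sd)  # truncate at 3 SD and at zero
        return float(stats.truncnorm.rvs(lo, 3.0, loc=mu, scale=sd,
                                         random_state=rng))

    mass = draw(m_mu, m_sd)
    height = draw(h_mu, h_sd)
    if subject_id is None:
        subject_id = f"{cohort}-{seed}"
    return Anthropometrics(
        subject_id=subject_id,
        height=height,
        mass=mass,
        thigh_length=THIGH_FRACTION * height,
        shank_length=SHANK_FRACTION * height,
        cohort=cohort,
    )


def _subject_scale(subject: Anthropometrics) -> float:
    """Stable per-subject amplitude factor derived from the subject id."""
    h = zlib.crc32(subject.subject_id.encode())
    base = 1.0 + 0.04 * ((h % 1000) / 999.0 - 0.5)  # +-2% spread
    if subject.cohort == "elderly":
        base *= _ELDERLY_AMPLITUDE
    return base


def _evaluate_series(a0: float, cos_c: np.ndarray, sin_c: np.ndarray,
                     phase: np.ndarray, duration: float):
    """Evaluate a Fourier series and its time derivative on a phase grid."""
    k = np.arange(1, len(cos_c) + 1)
    arg = 2.0 * np.pi * np.outer(phase, k)  # (T, 4)
    angle = a0 + np.cos(arg) @ cos_c + np.sin(arg) @ sin_c
    # d/dt = d/dphase * (1/duration)
    dphase = (-np.sin(arg) * (2.0 * np.pi * k)) @ cos_c \
        + (np.cos(arg) * (2.0 * np.pi * k)) @ sin_c
    return angle, dphase / duration


def synthesize_gait_cycle(subject: Anthropometrics, speed: float,
                          n_samples: int = 100, seed: int = 0,
                          harmonic_jitter_sd: float = 0.05) -> GaitCycle:
    """Generate one noiseless gait cycle for a subject at a walking speed.

    The right-leg channels are the left-leg series phase-shifted by half a
    cycle.  ``harmonic_jitter_sd`` is the SD of a multiplicative jitter on
    each harmonic amplitude (per cycle, seeded); set 0 for the template.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if n_samples < 16:
        raise ValueError("n_samples must be at least 16")
    if harmonic_jitter_sd < 0:
        raise ValueError("harmonic_jitter_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    duration = cycle_duration(speed)
    amp = (1.0 + _SPEED_GAIN * (speed - 1.5)) * _subject_scale(subject)
    # phase grid includes both endpoints so the cycle wraps exactly;
    # every cycle is heel-strike aligned (phase 0 at sample 0)
    phase = np.linspace(0.0, 1.0, n_samples)

    data = np.empty((n_samples, 12))
    for j, joint in enumerate(JOINTS):
        tpl = _TEMPLATES[joint]
        jitter_c = 1.0 + harmonic_jitter_sd * rng.standard_normal(4)
        jitter_s = 1.0 + harmonic_jitter_sd * rng.standard_normal(4)
        cos_c = amp * tpl["cos"] * jitter_c
        sin_c = amp * tpl["sin"] * jitter_s
        for leg, shift in (("left", 0.0), ("right", 0.5)):
            ang, vel = _evaluate_series(
                tpl["a0"], cos_c, sin_c,
                np.mod(phase + shift, 1.0), duration)
            col = j if leg == "left" else 3 + j
            data[:, col] = ang
            data[:, 6 + col] = vel

    return GaitCycle(
        subject_id=subject.subject_id,
        speed=speed,
        sample_rate=(n_samples - 1) / duration,
        data=data,
    )


def add_sensor_noise(cycle: GaitCycle, angle_sd: float = 0.02,
                     velocity_sd: float = 0.1, seed: int = 0) -> GaitCycle:
    """Return a copy of a cycle with IMU-like Gaussian noise added.

    ``angle_sd`` (rad) applies to the six angle channels, ``velocity_sd``
    (rad/s) to the six angular-velocity channels.  The input is unmodified.
    """
    if angle_sd < 0 or velocity_sd < 0:
        raise ValueError("noise SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    data = cycle.data.copy()
    if angle_sd > 0:
        data[:, 0:6] += rng.normal(0.0, angle_sd, size=data[:, 0:6].shape)
    if velocity_sd > 0:
        data[:, 6:12] += rng.normal(0.0, velocity_sd,
                                    size=data[:, 6:12].shape)
    return replace(cycle, data=data)


def build_dataset(design: ExperimentDesign,
                  angle_noise_sd: float = DEFAULT_ANGLE_NOISE_SD,
                  velocity_noise_sd: float = DEFAULT_VELOCITY_NOISE_SD,
                  harmonic_jitter_sd: float = 0.05) -> GaitDataset:
    """Generate a full dataset with per-subject train/validation splits.

    Per subject and speed, ``design.train_cycles_per_subject`` cycles are
    labelled ``train`` and the remainder ``validation`` (seeded random
    selection).  Sensor noise is added to the observed cycles only; each
    :class:`LabelledCycle` keeps the clean kinematics as ``truth`` for
    the reference-force pathway.  Pass zero SDs for a noiseless dataset.
    """
    rng = np.random.default_rng(design.seed)
    subjects = []
    for i in range(design.n_young):
        subjects.append(sample_subject(int(rng.integers(2**31)), "young",
                                       subject_id=f"Y{i:03d}"))
    for i in range(design.n_elderly):
        subjects.append(sample_subject(int(rng.integers(2**31)), "elderly",
                                       subject_id=f"E{i:03d}"))

    cycles = []
    for speed in design.speeds:
        for subject in subjects:
            n = design.cycles_per_subject_per_speed
            order = rng.permutation(n)
            train_idx = set(order[: design.train_cycles_per_subject].tolist())
            for c in range(n):
                clean = synthesize_gait_cycle(
                    subject, speed, design.n_samples,
                    seed=int(rng.integers(2**31)),
                    harmonic_jitter_sd=harmonic_jitter_sd)
                observed, truth = clean, None
                if angle_noise_sd > 0 or velocity_noise_sd > 0:
                    observed = add_sensor_noise(
                        clean, angle_noise_sd, velocity_noise_sd,
                        seed=int(rng.integers(2**31)))
                    truth = clean
                label = "train" if c in train_idx else "validation"
                cycles.append(LabelledCycle(cycle=observed, split=label,
                                            truth=truth))
    return GaitDataset(subjects=subjects, cycles=cycles, design=design)
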