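"""Planar musculoskeletal reference model and static optimization.

Reference ("ground truth") muscle forces are computed from kinematics and
anthropometrics in three steps, per time sample:

1. a smooth joint-torque template over the gait cycle, scaled linearly by
   body mass and affinely by walking speed;
2. angle-dependent moment arms r(theta) = c0 + c1*cos(theta) for an
   8-muscle planar muscle set spanning hip, knee and ankle;
3. static optimization (SO): minimise the sum of squared activations
   subject to joint-torque equilibrium R diag(f_max) a = tau with
   0 <= a_i <= 1, solved exactly by an active-set quadratic program.

The four target muscles are gluteus maximus (GM), rectus femoris (RF),
gastrocnemius (GAST) and soleus (SOL); iliopsoas (ILIO), hamstrings (HAM),
vasti (VAS) and tibialis anterior (TA) complete agonist/antagonist pairs
so the muscle-redundancy problem is nontrivial.  Muscle force is
activation times maximum isometric force (ideal force generator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from gaitforce.gait import Anthropometrics, GaitCycle

#: Output muscle ordering used throughout the package.
TARGET_MUSCLES = ("GM", "RF", "GAST", "SOL")

#: Sign convention for sagittal joint torques: positive = hip flexion,
#: knee extension, ankle dorsiflexion.
JOINT_INDEX = {"hip": 0, "knee": 1, "ankle": 2}


@dataclass(frozen=True)
class MuscleModel:
    """One planar muscle: name, strength and per-joint moment arms.

    ``arms`` maps joint name -> (c0, c1, sign) with moment arm magnitude
    r(theta) = c0 + c1*cos(theta) in metres and sign giving the torque
    direction at that joint.  Joints not listed are not spanned.
    """

    name: str
    f_max: float                     # N
    arms: tuple                      # ((joint, c0, c1, sign), ...)

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise ValueError("f_max must be positive")
        if len(self.arms) == 0:
            raise ValueError("muscle must span at least one joint")
        for joint, c0, c1, sign in self.arms:
            if joint not in JOINT_INDEX:
                raise ValueError(f"unknown joint {joint!r}")
            if abs(c0) + abs(c1) > 0.08:
                raise ValueError("moment arm exceeds 0.08 m")
            if sign not in (-1, 0, 1):
                raise ValueError("action sign must be -1, 0 or +1")


#: Maximum isometric force per kilogram of body mass (N/kg).
F_MAX_PER_KG = {
    "GM": 30.0, "RF": 20.0, "GAST": 25.0, "SOL": 45.0,
    "ILIO": 25.0, "HAM": 30.0, "VAS": 40.0, "TA": 15.0,
}

# (joint, c0 [m], c1 [m], sign) per muscle.
_ARM_TABLE = {
    "ILIO": (("hip", 0.045, 0.008, +1),),
    "GM": (("hip", 0.055, 0.010, -1),),
    "RF": (("hip", 0.040, 0.006, +1), ("knee", 0.045, 0.008, +1)),
    "HAM": (("hip", 0.050, 0.008, -1), ("knee", 0.035, 0.006, -1)),
    "VAS": (("knee", 0.045, 0.009, +1),),
    "GAST": (("knee", 0.030, 0.005, -1), ("ankle", 0.050, 0.006, -1)),
    "SOL": (("ankle", 0.045, 0.007, -1),),
    "TA": (("ankle", 0.040, 0.005, +1),),
}


def default_muscles(mass: float) -> list:
    """The default 8-muscle planar set, strengths scaled by body mass."""
    if not mass > 0:
        raise ValueError("mass must be positive")
    return [
        MuscleModel(name=name, f_max=F_MAX_PER_KG[name] * mass,
                    arms=_ARM_TABLE[name])
        for name in ("GM", "RF", "GAST", "SOL", "ILIO", "HAM", "VAS", "TA")
    ]


def muscle_config() -> dict:
    """The default muscle parameters as a plain dict (YAML/JSON ready).

    Per muscle: maximum isometric force per kg of body mass, and per
    spanned joint the moment-arm coefficients (c0, c1, metres) of
    r(theta) = c0 + c1*cos(theta) plus the torque direction sign.
    """
    return {
        name: {
            "f_max_per_kg": F_MAX_PER_KG[name],
            "arms": [{"joint": joint, "c0": c0, "c1": c1, "sign": sign}
                     for joint, c0, c1, sign in _ARM_TABLE[name]],
        }
        for name in ("GM", "RF", "GAST", "SOL", "ILIO", "HAM", "VAS",
                     "TA")
    }


def muscles_from_config(config: dict, mass: float) -> list:
    """Build a muscle set from a :func:`muscle_config`-shaped mapping.

    The four target muscles (GM, RF, GAST, SOL) must be present; any
    number of additional muscles is allowed.
    """
    if not mass > 0:
        raise ValueError("mass must be positive")
    missing = set(TARGET_MUSCLES) - set(config)
    if missing:
        raise ValueError(f"muscle config missing targets {sorted(missing)}")
    names = list(TARGET_MUSCLES) + [n for n in config
                                    if n not in TARGET_MUSCLES]
    return [
        MuscleModel(
            name=name,
            f_max=float(config[name]["f_max_per_kg"]) * mass,
            arms=tuple((a["joint"], float(a["c0"]), float(a["c1"]),
                        int(a["sign"]))
                       for a in config[name]["arms"]),
        )
        for name in names
    ]


@dataclass(frozen=True)
class JointTorqueTrace:
    """Sagittal joint torques (N*m) over a gait cycle, shape (T, 3)."""

    torques: np.ndarray  # (T, 3): hip, knee, ankle

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.torques)):
            raise ValueError("torques must be finite")


@dataclass(frozen=True)
class ActivationSolution:
    """Static-optimization result for one time sample."""

    activations: np.ndarray   # (n_muscles,), each in [0, 1]
    objective: float          # sum of squared activations
    residual: float           # ||R diag(f_max) a - tau||


@dataclass(frozen=True)
class MuscleForceTrace:
    """Forces (N) of the four target muscles, shape (T, 4): GM RF GAST SOL."""

    forces: np.ndarray
    subject_id: str = ""
    speed: float = float("nan")

    def __post_init__(self) -> None:
        if self.forces.ndim != 2 or self.forces.shape[1] != 4:
            raise ValueError("forces must have shape (T, 4)")


class InfeasibleTorqueError(RuntimeError):
    """Raised when no activation in [0, 1]^n can reproduce the torques."""

    def __init__(self, message: str, sample_index: int | None = None):
        super().__init__(message)
        self.sample_index = sample_index


# Joint-torque templates in N*m per kg body mass as functions of cycle
# phase.  Early-stance hip extension (GM), stance knee extension
# (VAS/RF), a stance plantarflexion burst (GAST/SOL) and swing-phase hip
# flexion / ankle dorsiflexion give each muscle a distinct duty cycle.
def _torque_shapes(phase: np.ndarray) -> np.ndarray:
    two_pi = 2.0 * np.pi
    hip = (-0.40 * np.cos(two_pi * phase)
           - 0.10 * np.sin(two_pi * phase)
           - 0.05 * np.cos(2 * two_pi * phase))
    knee = (0.05 + 0.30 * np.cos(two_pi * phase)
            + 0.10 * np.sin(2 * two_pi * phase))
    ankle = (-0.30 - 0.30 * np.sin(two_pi * phase)
             + 0.08 * np.cos(two_pi * phase)
             - 0.05 * np.cos(2 * two_pi * phase))
    return np.stack([hip, knee, ankle], axis=-1)


#: Torque amplitude scales affinely with walking speed.
_TORQUE_SPEED_INTERCEPT = 0.7
_TORQUE_SPEED_SLOPE = 0.2


def joint_torque_template(cycle: GaitCycle,
                          subject: Anthropometrics) -> JointTorqueTrace:
    """Smooth per-joint torque curves over one gait cycle.

    Torques scale exactly linearly with body mass and affinely with
    walking speed; the phase grid matches the cycle's samples, so the
    output length equals ``cycle.n_samples``.
    """
    phase = np.linspace(0.0, 1.0, cycle.n_samples)
    scale = subject.mass * (_TORQUE_SPEED_INTERCEPT
                            + _TORQUE_SPEED_SLOPE * cycle.speed)
    return JointTorqueTrace(torques=scale * _torque_shapes(phase))


def moment_arm_matrix(angles: np.ndarray, muscles: list) -> np.ndarray:
    """Signed moment-arm matrix R (3 x n_muscles, metres).

    ``R[j, i] = sign * (c0 + c1*cos(theta_j))`` for muscle i at joint j;
    exactly zero where the muscle does not span the joint.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (3,) or not np.all(np.isfinite(angles)):
        raise ValueError("angles must be a finite 3-vector")
    R = np.zeros((3, len(muscles)))
    for i, m in enumerate(muscles):
        for joint, c0, c1, sign in m.arms:
            j = JOINT_INDEX[joint]
            R[j, i] = sign * (c0 + c1 * np.cos(angles[j]))
    return R


def _min_norm_solve(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimum-norm solution of G a = b (underdetermined least squares)."""
    return np.linalg.lstsq(G, b, rcond=None)[0]


def solve_static_optimization(tau: np.ndarray, R: np.ndarray,
                              f_max: np.ndarray,
                              tol: float = 1e-9,
                              max_iter: int = 200) -> ActivationSolution:
    """Solve min sum(a^2) s.t. R diag(f_max) a = tau, 0 <= a <= 1.

    Active-set method: start from the minimum-norm equality-constrained
    solution, clamp bound violations one at a time, and release clamped
    variables whose KKT multiplier has the wrong sign.  Exact for this
    convex QP class.  Infeasible torques (outside the polytope spanned at
    a = 1) raise :class:`InfeasibleTorqueError` rather than being clipped.
    """
    tau = np.asarray(tau, dtype=float).reshape(-1)
    R = np.asarray(R, dtype=float)
    f_max = np.asarray(f_max, dtype=float).reshape(-1)
    if R.ndim != 2 or R.shape != (tau.size, f_max.size):
        raise ValueError("R must be (n_joints, n_muscles)")
    if not np.all(np.isfinite(R)) or not np.all(np.isfinite(tau)):
        raise ValueError("inputs must be finite")
    if not np.all(f_max > 0):
        raise ValueError("f_max must be strictly positive")

    G = R * f_max[None, :]  # torque produced at full activation
    n = f_max.size
    res_tol = 1e-6 * (1.0 + np.linalg.norm(tau))

    # Fast path: the unclamped minimum-norm solution is optimal whenever
    # it already lies inside the box.
    a0 = _min_norm_solve(G, tau)
    if np.all(a0 >= -tol) and np.all(a0 <= 1.0 + tol):
        a0 = np.clip(a0, 0.0, 1.0)
        residual = float(np.linalg.norm(G @ a0 - tau))
        if residual <= res_tol:
            return ActivationSolution(activations=a0,
                                      objective=float(np.sum(a0 ** 2)),
                                      residual=residual)

    # Feasibility certificate: bounded least squares over the box.
    cert = optimize.lsq_linear(G, tau, bounds=(0.0, 1.0))
    if np.linalg.norm(G @ cert.x - tau) > res_tol:
        raise InfeasibleTorqueError(
            f"torque {tau} unreachable with activations in [0, 1]; "
            f"best residual {np.linalg.norm(G @ cert.x - tau):.3g}")

    a = np.zeros(n)
    fixed = np.full(n, -1)  # -1 free, 0 at lower bound, 1 at upper bound
    for _ in range(max_iter):
        free = fixed < 0
        b = tau - G[:, ~free] @ a[~free]
        if free.any():
            a_free = _min_norm_solve(G[:, free], b)
            a[free] = a_free
        # clamp the single worst bound violation and re-solve
        lo_viol = np.where(free & (a < -tol))[0]
        hi_viol = np.where(free & (a > 1.0 + tol))[0]
        if lo_viol.size or hi_viol.size:
            cands = [(-a[i], i, 0) for i in lo_viol]
            cands += [(a[i] - 1.0, i, 1) for i in hi_viol]
            _, idx, bound = max(cands)
            fixed[idx] = bound
            a[idx] = float(bound)
            continue
        a = np.clip(a, 0.0, 1.0)
        # KKT check for clamped variables: stationarity 2a = G^T mu + lam,
        # with lam >= 0 at the lower bound and lam <= 0 at the upper.
        if not (fixed >= 0).any():
            break
        if free.any():
            mu = np.linalg.lstsq(G[:, free].T, 2.0 * a[free], rcond=None)[0]
        else:
            mu = np.zeros(tau.size)
        grad = G.T @ mu  # = 2a - lam at clamped entries
        release = None
        worst = tol
        for i in np.where(fixed >= 0)[0]:
            if fixed[i] == 0 and grad[i] > worst:       # lam = -grad < 0
                release, worst = i, grad[i]
            elif fixed[i] == 1 and 2.0 - grad[i] > worst:  # lam > 0 wrong side
                release, worst = i, 2.0 - grad[i]
        if release is None:
            break
        fixed[release] = -1
    else:
        a = _enumerate_active_sets(G, tau, tol)

    residual = float(np.linalg.norm(G @ a - tau))
    if residual > res_tol:
        # the greedy clamping order painted itself into a corner; fall
        # back to exhaustive active-set enumeration (exact, small n)
        a = _enumerate_active_sets(G, tau, tol)
        residual = float(np.linalg.norm(G @ a - tau))
        if residual > res_tol:
            raise InfeasibleTorqueError(
                f"solver residual {residual:.3g} exceeds "
                f"tolerance {res_tol:.3g}")
    return ActivationSolution(activations=a,
                              objective=float(np.sum(a ** 2)),
                              residual=residual)


def _enumerate_active_sets(G: np.ndarray, tau: np.ndarray,
                           tol: float) -> np.ndarray:
    """Exact QP solve by enumerating every {free, lo, hi} assignment.

    At the optimum the free block is the minimum-norm solution of its
    reduced equality system, so checking all 3^n assignments and keeping
    the feasible one with the smallest objective is exact.  Used only as
    a safeguard; cost is exponential in the muscle count.
    """
    from itertools import product

    n = G.shape[1]
    res_tol = 1e-6 * (1.0 + np.linalg.norm(tau))
    best, best_obj = None, np.inf
    for assign in product((-1, 0, 1), repeat=n):
        assign = np.array(assign)
        a = np.where(assign == 1, 1.0, 0.0)
        free = assign == -1
        b = tau - G[:, ~free] @ a[~free]
        if free.any():
            a[free] = _min_norm_solve(G[:, free], b)
        if np.any(a < -tol) or np.any(a > 1.0 + tol):
            continue
        if np.linalg.norm(G @ a - tau) > res_tol:
            continue
        obj = float(np.sum(np.clip(a, 0.0, 1.0) ** 2))
        if obj < best_obj:
            best, best_obj = np.clip(a, 0.0, 1.0), obj
    if best is None:
        raise InfeasibleTorqueError(
            f"torque {tau} unreachable with activations in [0, 1]")
    return best


def reference_forces(cycle: GaitCycle, subject: Anthropometrics,
                     muscles: list | None = None) -> MuscleForceTrace:
    """Reference muscle forces for GM, RF, GAST, SOL over one gait cycle.

    Per sample: evaluate the torque template, build the moment-arm matrix
    at the left-leg joint angles, solve static optimization, and report
    force = activation * f_max for the four target muscles.
    """
    if muscles is None:
        muscles = default_muscles(subject.mass)
    names = [m.name for m in muscles]
    target_idx = [names.index(n) for n in TARGET_MUSCLES]
    f_max = np.array([m.f_max for m in muscles])

    torques = joint_torque_template(cycle, subject).torques
    angles = cycle.left_angles()
    forces = np.empty((cycle.n_samples, 4))
    for t in range(cycle.n_samples):
        R = moment_arm_matrix(angles[t], muscles)
        try:
            sol = solve_static_optimization(torques[t], R, f_max)
        except InfeasibleTorqueError as exc:
            raise InfeasibleTorqueError(str(exc), sample_index=t) from exc
        forces[t] = sol.activations[target_idx] * f_max[target_idx]
    return MuscleForceTrace(forces=forces, subject_id=subject.subject_id,
                            speed=cycle.speed)
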