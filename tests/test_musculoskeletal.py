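"""Static-optimization reference model against closed forms and oracles."""

import numpy as np
import pytest

from gaitforce import (
    InfeasibleTorqueError,
    MuscleModel,
    default_muscles,
    joint_torque_template,
    moment_arm_matrix,
    reference_forces,
    solve_static_optimization,
    synthesize_gait_cycle,
)
from gaitforce.gait import Anthropometrics
from gaitforce.musculoskeletal import TARGET_MUSCLES


def grid_oracle(G, tau, step=1e-3):
    """Independent brute-force oracle for min sum(a^2) s.t. G a = tau.

    Enumerates a grid over n - n_joints free coordinates and solves the
    remaining square linear system from the equality constraint, keeping
    the best feasible candidate.  Exact up to O(step^2) in objective.
    """
    G = np.asarray(G, float)
    tau = np.asarray(tau, float).reshape(-1)
    n_j, n_m = G.shape
    n_free = n_m - n_j
    best = None
    best_obj = np.inf
    if n_free == 0:
        a = np.linalg.solve(G, tau)
        if np.all(a >= -1e-9) and np.all(a <= 1 + 1e-9):
            return np.clip(a, 0, 1)
        return None
    grids = np.meshgrid(*[np.arange(0.0, 1.0 + step / 2, step)] * n_free,
                        indexing="ij")
    free_vals = np.stack([g.ravel() for g in grids], axis=1)
    free_idx = list(range(n_free))
    dep_idx = list(range(n_free, n_m))
    Gd = G[:, dep_idx]
    rhs = tau[None, :] - free_vals @ G[:, free_idx].T
    dep = np.linalg.solve(Gd, rhs.T).T  # (n_grid, n_j)
    ok = np.all((dep >= -1e-9) & (dep <= 1 + 1e-9), axis=1)
    if not ok.any():
        return None
    cand_free = free_vals[ok]
    cand_dep = dep[ok]
    obj = (cand_free ** 2).sum(axis=1) + (cand_dep ** 2).sum(axis=1)
    i = int(np.argmin(obj))
    a = np.empty(n_m)
    a[free_idx] = cand_free[i]
    a[dep_idx] = cand_dep[i]
    return a


def random_feasible_problem(rng, n_joints, n_muscles):
    """A random SO problem guaranteed feasible (tau from a known a)."""
    G = rng.uniform(-1.0, 1.0, size=(n_joints, n_muscles))
    G[np.abs(G) < 0.2] += np.sign(G[np.abs(G) < 0.2] + 1e-9) * 0.2
    a_true = rng.uniform(0.0, 1.0, size=n_muscles)
    tau = G @ a_true
    return G, tau


class TestMomentArms:
    def test_constant_arm_when_c1_zero(self):
        m = MuscleModel(name="GM", f_max=100.0,
                        arms=(("hip", 0.05, 0.0, -1),))
        r1 = moment_arm_matrix(np.array([0.0, 0.0, 0.0]), [m])
        r2 = moment_arm_matrix(np.array([0.7, -0.2, 0.3]), [m])
        assert np.array_equal(r1, r2)

    def test_direct_evaluation_at_zero_angle(self):
        m = MuscleModel(name="VAS", f_max=100.0,
                        arms=(("knee", 0.05, 0.01, +1),))
        R = moment_arm_matrix(np.zeros(3), [m])
        assert R[1, 0] == pytest.approx(0.06)

    def test_non_spanned_joints_are_exactly_zero(self):
        muscles = default_muscles(70.0)
        R = moment_arm_matrix(np.array([0.1, 0.5, -0.1]), muscles)
        soleus = [m.name for m in muscles].index("SOL")
        assert R[0, soleus] == 0.0 and R[1, soleus] == 0.0
        assert R[2, soleus] != 0.0

    def test_arm_magnitudes_physiological(self):
        muscles = default_muscles(70.0)
        for theta in np.linspace(-1.0, 1.5, 11):
            R = moment_arm_matrix(np.array([theta] * 3), muscles)
            assert np.abs(R).max() <= 0.08


class TestTorqueTemplate:
    def test_doubling_mass_doubles_every_torque(self, clean_cycle,
                                                young_subject):
        heavy = Anthropometrics(
            subject_id=young_subject.subject_id,
            height=young_subject.height, mass=2 * young_subject.mass,
            thigh_length=young_subject.thigh_length,
            shank_length=young_subject.shank_length,
            cohort=young_subject.cohort)
        t1 = joint_torque_template(clean_cycle, young_subject).torques
        t2 = joint_torque_template(clean_cycle, heavy).torques
        assert np.allclose(t2, 2.0 * t1, rtol=0, atol=1e-12)

    def test_output_length_matches_cycle(self, clean_cycle,
                                         young_subject):
        t = joint_torque_template(clean_cycle, young_subject).torques
        assert t.shape == (clean_cycle.n_samples, 3)

    def test_peak_hip_torque_increases_with_speed(self, young_subject):
        peaks = []
        for v in (1.2, 1.8):
            cyc = synthesize_gait_cycle(young_subject, v, 100, seed=0)
            t = joint_torque_template(cyc, young_subject).torques
            peaks.append(np.abs(t[:, 0]).max())
        assert peaks[1] > peaks[0]


class TestStaticOptimization:
    def test_two_identical_muscles_share_load_equally(self):
        R = np.array([[0.05, 0.05]])
        f_max = np.array([1000.0, 1000.0])
        tau = np.array([0.05 * 1000.0])  # both at full would overshoot
        sol = solve_static_optimization(tau, R, f_max)
        assert np.allclose(sol.activations, [0.5, 0.5], atol=1e-9)

    def test_single_muscle_single_joint(self):
        R = np.array([[0.04]])
        f_max = np.array([500.0])
        tau = np.array([0.5 * 0.04 * 500.0])
        sol = solve_static_optimization(tau, R, f_max)
        assert sol.activations[0] == pytest.approx(0.5, abs=1e-9)

    def test_interior_two_muscle_solution_matches_lagrange_form(self):
        # interior optimum of min a1^2+a2^2 s.t. g1 a1 + g2 a2 = tau is
        # a_i = tau * g_i / (g1^2 + g2^2)
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = rng.uniform(10.0, 100.0, size=2)
            tau = np.array([rng.uniform(0.05, 0.45) * g.sum()])
            expected = tau[0] * g / (g @ g)
            if np.any(expected > 1.0):
                continue
            sol = solve_static_optimization(
                tau, (g / np.array([50.0, 80.0]))[None, :],
                np.array([50.0, 80.0]))
            assert np.allclose(sol.activations, expected, atol=1e-8)

    def test_matches_grid_oracle_on_random_problems(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            n_j = int(rng.integers(1, 3))
            n_m = int(rng.integers(n_j + 1, 4))
            G, tau = random_feasible_problem(rng, n_j, n_m)
            oracle = grid_oracle(G, tau, step=1e-3)
            if oracle is None:
                continue
            f_max = rng.uniform(10.0, 100.0, size=n_m)
            sol = solve_static_optimization(tau, G / f_max[None, :],
                                            f_max)
            gap = sol.objective - float(np.sum(oracle ** 2))
            assert gap <= 1e-4, (G, tau, sol.activations, oracle)
            checked += 1

    def test_nullspace_perturbation_never_improves_objective(self):
        rng = np.random.default_rng(7)
        muscles = default_muscles(70.0)
        f_max = np.array([m.f_max for m in muscles])
        R = moment_arm_matrix(np.array([0.2, 0.4, -0.1]), muscles)
        tau = np.array([30.0, -20.0, -40.0])
        sol = solve_static_optimization(tau, R, f_max)
        G = R * f_max[None, :]
        from scipy.linalg import null_space
        Z = null_space(G)
        for _ in range(50):
            direction = Z @ rng.standard_normal(Z.shape[1])
            for eps in (1e-4, 1e-3, 1e-2):
                cand = sol.activations + eps * direction
                if np.all(cand >= 0) and np.all(cand <= 1):
                    assert np.sum(cand ** 2) >= sol.objective - 1e-12

    def test_infeasible_torque_raises_explicitly(self):
        R = np.array([[0.05]])
        f_max = np.array([100.0])
        tau = np.array([100.0])  # far beyond r * f_max = 5 N*m
        with pytest.raises(InfeasibleTorqueError):
            solve_static_optimization(tau, R, f_max)

    def test_matches_slsqp_on_default_muscle_problems(self):
        # independent general-purpose NLP solver as a cross-check
        from scipy.optimize import minimize
        muscles = default_muscles(65.0)
        f_max = np.array([m.f_max for m in muscles])
        rng = np.random.default_rng(3)
        for _ in range(10):
            angles = rng.uniform(-0.5, 1.0, size=3)
            R = moment_arm_matrix(angles, muscles)
            G = R * f_max[None, :]
            a_true = rng.uniform(0.0, 0.6, size=len(muscles))
            tau = G @ a_true
            sol = solve_static_optimization(tau, R, f_max)
            ref = minimize(lambda a: np.sum(a ** 2), x0=a_true,
                           jac=lambda a: 2 * a,
                           bounds=[(0.0, 1.0)] * len(muscles),
                           constraints={"type": "eq",
                                        "fun": lambda a: G @ a - tau},
                           method="SLSQP",
                           options={"ftol": 1e-12, "maxiter": 200})
            assert sol.objective <= ref.fun + 1e-6


class TestReferenceForces:
    def test_forces_within_activation_bounds(self, clean_cycle,
                                             young_subject):
        muscles = default_muscles(young_subject.mass)
        trace = reference_forces(clean_cycle, young_subject, muscles)
        f_max = {m.name: m.f_max for m in muscles}
        assert np.all(trace.forces >= 0)
        for i, name in enumerate(TARGET_MUSCLES):
            assert np.all(trace.forces[:, i] <= f_max[name] + 1e-9)

    def test_reconstructed_torques_match_template(self, clean_cycle,
                                                  young_subject):
        muscles = default_muscles(young_subject.mass)
        f_max = np.array([m.f_max for m in muscles])
        torques = joint_torque_template(clean_cycle,
                                        young_subject).torques
        for t in range(0, clean_cycle.n_samples, 10):
            R = moment_arm_matrix(clean_cycle.left_angles()[t], muscles)
            sol = solve_static_optimization(torques[t], R, f_max)
            recon = (R * f_max[None, :]) @ sol.activations
            assert np.linalg.norm(recon - torques[t]) <= \
                1e-6 * (1 + np.linalg.norm(torques[t]))

    def test_heavier_subject_produces_pointwise_larger_forces(
            self, clean_cycle):
        base = dict(subject_id="s", height=1.70,
                    thigh_length=0.42, shank_length=0.42, cohort="young")
        light = Anthropometrics(mass=60.0, **base)
        heavy = Anthropometrics(mass=75.0, **base)
        f_light = reference_forces(clean_cycle, light).forces
        f_heavy = reference_forces(clean_cycle, heavy).forces
        assert np.all(f_heavy >= f_light - 1e-9)

    def test_deterministic(self, clean_cycle, young_subject):
        a = reference_forces(clean_cycle, young_subject).forces
        b = reference_forces(clean_cycle, young_subject).forces
        assert np.array_equal(a, b)


class TestMuscleConfig:
    def test_config_round_trip_equals_defaults(self):
        from gaitforce.musculoskeletal import (muscle_config,
                                               muscles_from_config)
        mass = 68.0
        rebuilt = muscles_from_config(muscle_config(), mass)
        assert rebuilt == default_muscles(mass)

    def test_missing_target_muscle_rejected(self):
        from gaitforce.musculoskeletal import (muscle_config,
                                               muscles_from_config)
        cfg = muscle_config()
        del cfg["SOL"]
        with pytest.raises(ValueError, match="SOL"):
            muscles_from_config(cfg, 70.0)
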