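"""Manipulator kinematics, Euler-Lagrange dynamics and PD+ regulation."""

import numpy as np
import pytest

import myohmi as m

L1, L2, L3 = m.RobotParams().l
STATE_POINTS = [np.asarray(s.output) for s in m.MOTION_STATES]


def _random_reachable_points(rob, n, rng):
    lo, hi = rob.params.reach
    pts = []
    while len(pts) < n:
        q = rng.uniform([-np.pi, -np.pi / 2, -np.pi], [np.pi, np.pi / 2, np.pi])
        p = rob.forward_kinematics(q)
        if np.hypot(p[0], p[1]) > 1e-6:  # avoid the base singularity
            pts.append(p)
    return pts


class TestForwardKinematics:
    @pytest.mark.parametrize("q,expected", [
        ((0, 0, 0), (L2 + L3, 0, L1)),
        ((np.pi / 2, 0, 0), (0, L2 + L3, L1)),
        ((0, np.pi / 2, 0), (0, 0, L1 + L2 + L3)),
    ])
    def test_canonical_poses(self, robot, q, expected):
        np.testing.assert_allclose(robot.forward_kinematics(q), expected,
                                   atol=1e-12)


class TestInverseKinematics:
    def test_stretched_arm_inversion(self, robot):
        q = robot.inverse_kinematics(np.array([L2 + L3, 0.0, L1]))
        np.testing.assert_allclose(q, 0.0, atol=1e-7)

    def test_beyond_reach_rejected(self, robot):
        with pytest.raises(m.WorkspaceError):
            robot.inverse_kinematics(np.array([0.0, 0.0, L1 + L2 + L3 + 0.1]))

    def test_base_singularity_warns(self, robot):
        with pytest.warns(UserWarning, match="singular"):
            q = robot.inverse_kinematics(np.array([0.0, 0.0, L1 + 0.3]))
        assert q[0] == 0.0

    def test_roundtrip_on_state_setpoints(self, robot):
        for p in STATE_POINTS:
            for elbow in (1, -1):
                q = robot.inverse_kinematics(p, elbow=elbow)
                assert np.linalg.norm(robot.forward_kinematics(q) - p) < 1e-9

    def test_roundtrip_on_random_points_both_branches(self, robot, rng):
        for p in _random_reachable_points(robot, 1000, rng):
            for elbow in (1, -1):
                q = robot.inverse_kinematics(p, elbow=elbow)
                assert np.linalg.norm(robot.forward_kinematics(q) - p) < 1e-9


class TestDynamics:
    def test_inertia_symmetric_positive_definite(self, robot, rng):
        for _ in range(100):
            q = rng.uniform(-np.pi, np.pi, 3)
            M = robot.inertia_matrix(q)
            np.testing.assert_array_equal(M, M.T)
            assert np.linalg.eigvalsh(M).min() > 0

    def test_m33_constant(self, robot, rng):
        p = robot.params
        expected = p.I[2] + p.m[2] * p.lc[2] ** 2
        for _ in range(20):
            q = rng.uniform(-np.pi, np.pi, 3)
            assert robot.inertia_matrix(q)[2, 2] == pytest.approx(expected,
                                                                  abs=1e-15)

    def test_m22_m23_closed_forms(self, robot, rng):
        p = robot.params
        _, l2, _ = p.l
        _, lc2, lc3 = p.lc
        _, m2, m3 = p.m
        for _ in range(20):
            q = rng.uniform(-np.pi, np.pi, 3)
            c3 = np.cos(q[2])
            M = robot.inertia_matrix(q)
            assert M[1, 1] == pytest.approx(
                p.I[1] + p.I[2] + lc2**2 * m2
                + (l2**2 + lc3**2 + 2 * l2 * lc3 * c3) * m3, abs=1e-12)
            assert M[1, 2] == pytest.approx(
                p.I[2] + lc3**2 * m3 + l2 * lc3 * m3 * c3, abs=1e-12)

    def test_coriolis_vanishes_at_rest_and_is_homogeneous(self, robot, rng):
        for _ in range(10):
            q = rng.uniform(-np.pi, np.pi, 3)
            qd = rng.uniform(-2, 2, 3)
            np.testing.assert_allclose(robot.coriolis_matrix(q, np.zeros(3)),
                                       0.0, atol=1e-15)
            np.testing.assert_allclose(robot.coriolis_matrix(q, 3.0 * qd),
                                       3.0 * robot.coriolis_matrix(q, qd),
                                       atol=1e-12)

    def test_mdot_minus_2c_skew_symmetric(self, robot, rng):
        h = 1e-6
        eye = np.eye(3)
        for _ in range(50):
            q = rng.uniform(-np.pi, np.pi, 3)
            qd = rng.uniform(-2, 2, 3)
            Mdot = sum(
                (robot.inertia_matrix(q + h * eye[i])
                 - robot.inertia_matrix(q - h * eye[i])) / (2 * h) * qd[i]
                for i in range(3))
            S = Mdot - 2 * robot.coriolis_matrix(q, qd)
            assert np.max(np.abs(S + S.T)) < 1e-8

    def test_gravity_is_potential_gradient(self, robot, rng):
        h = 1e-6
        eye = np.eye(3)
        for _ in range(50):
            q = rng.uniform(-np.pi, np.pi, 3)
            g_fd = np.array([
                (robot.potential_energy(q + h * eye[i])
                 - robot.potential_energy(q - h * eye[i])) / (2 * h)
                for i in range(3)])
            np.testing.assert_allclose(robot.gravity_vector(q), g_fd, atol=1e-8)
            assert robot.gravity_vector(q)[0] == 0.0

    def test_vertical_arm_feels_no_gravity(self, robot):
        # q2 = pi/2, q3 = 0: both links vertical, every cosine term vanishes
        np.testing.assert_allclose(
            robot.gravity_vector([0.3, np.pi / 2, 0.0]), 0.0, atol=1e-15)

    def test_static_equilibrium(self, robot, rng):
        for _ in range(10):
            q = rng.uniform(-np.pi, np.pi, 3)
            acc = robot.dynamics_rhs(q, np.zeros(3), robot.gravity_vector(q))
            np.testing.assert_allclose(acc, 0.0, atol=1e-12)

    def test_energy_conserved_without_gravity_friction_torque(self):
        rob = m.Manipulator(m.RobotParams(B=(0, 0, 0), g=0.0))
        sim = rob.simulate(np.array([0.1, 0.3, -0.5]), np.zeros(3),
                           qdot0=np.array([0.5, 0.5, 0.5]), dt=1e-3,
                           duration=5.0,
                           torque_fn=lambda t, q, v: np.zeros(3))
        E = np.array([rob.kinetic_energy(q, v)
                      for q, v in zip(sim.q, sim.qdot)])
        assert np.max(np.abs(E - E[0])) / E[0] < 1e-6

    def test_friction_dissipates_kinetic_energy(self):
        rob = m.Manipulator(m.RobotParams(g=0.0))
        sim = rob.simulate(np.zeros(3), np.zeros(3),
                           qdot0=np.array([1.0, 1.0, 1.0]), dt=1e-3,
                           duration=2.0,
                           torque_fn=lambda t, q, v: np.zeros(3))
        E = np.array([rob.kinetic_energy(q, v)
                      for q, v in zip(sim.q, sim.qdot)])
        assert np.all(np.diff(E) <= 1e-12)


class TestPdPlusControl:
    def test_pure_gravity_compensation_at_target(self, robot):
        qd = np.array([0.2, 0.5, -0.4])
        tau = robot.pdplus_torque(qd, np.zeros(3), qd)
        np.testing.assert_allclose(tau, robot.gravity_vector(qd), atol=1e-12)

    def test_kp_term_linear_in_error(self, robot):
        q = np.array([0.1, 0.2, 0.3])
        qd1 = q + np.array([0.05, -0.02, 0.01])
        qd2 = q + 2 * (qd1 - q)
        tau1 = robot.pdplus_torque(q, np.zeros(3), qd1)
        tau2 = robot.pdplus_torque(q, np.zeros(3), qd2)
        base = robot.gravity_vector(q)
        np.testing.assert_allclose(tau2 - base, 2 * (tau1 - base), atol=1e-10)

    def test_zero_gains_zero_gravity_at_rest_is_stationary(self):
        rob = m.Manipulator(m.RobotParams(B=(0, 0, 0), g=0.0))
        q0 = np.array([0.3, 0.2, 0.1])
        sim = rob.simulate(q0, q0, dt=1e-3, duration=1.0,
                           torque_fn=lambda t, q, v: np.zeros(3))
        np.testing.assert_allclose(sim.q[-1], q0, atol=1e-12)
        np.testing.assert_allclose(sim.qdot[-1], 0.0, atol=1e-12)

    def test_regulation_to_all_state_setpoints(self, robot):
        """Joint error < 1e-3 rad beyond 5 s and Cartesian error < 1 mm."""
        q0 = np.array([0.0, np.pi / 4, -np.pi / 4])
        for p in STATE_POINTS:
            qd = robot.inverse_kinematics(p)
            sim = robot.simulate(q0, qd, dt=1e-3, duration=6.0)
            assert sim.error_inf_after(5.0) < 1e-3
            assert np.linalg.norm(robot.forward_kinematics(sim.q[-1]) - p) < 1e-3
            # error shrinks over the run, tendency-to-zero
            early = np.max(np.abs(sim.error[sim.t <= 0.5]))
            late = np.max(np.abs(sim.error[sim.t >= 5.0]))
            assert late < early

    def test_dt_halving_changes_final_state_negligibly(self, robot):
        qd = robot.inverse_kinematics(np.asarray(m.MachineState.S2.output))
        q0 = np.array([0.0, np.pi / 4, -np.pi / 4])
        a = robot.simulate(q0, qd, dt=1e-3, duration=2.0)
        b = robot.simulate(q0, qd, dt=5e-4, duration=2.0)
        assert np.max(np.abs(a.q[-1] - b.q[-1])) < 1e-6

    def test_divergence_aborts(self):
        rob = m.Manipulator(m.RobotParams(B=(0, 0, 0), g=0.0))
        with pytest.raises(RuntimeError, match="diverged"):
            rob.simulate(np.zeros(3), np.zeros(3), dt=1e-3, duration=2.0,
                         torque_fn=lambda t, q, v: np.array([500.0, 0, 0]))

    def test_indefinite_gains_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            m.ControlGains(Kp=np.diag([1.0, -1.0, 1.0]))

    def test_oversized_timestep_rejected(self, robot):
        with pytest.raises(ValueError):
            robot.simulate(np.zeros(3), np.zeros(3), dt=0.01, duration=1.0)
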