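"""3-DOF anthropomorphic manipulator: kinematics, dynamics, PD+ control.

The arm is a rotary base (q1, about the vertical axis) carrying a planar
two-link arm (q2, q3) — the usual anthropomorphic waist/shoulder/elbow
chain.  With link lengths l2, l3 and base height l1 the end effector sits
at

    px = cos q1 (l2 cos q2 + l3 cos(q2+q3))
    py = sin q1 (l2 cos q2 + l3 cos(q2+q3))
    pz = l1 + l2 sin q2 + l3 sin(q2+q3)

The dynamics follow the Euler–Lagrange form

    tau = M(q) q'' + C(q, q') q' + g(q) + B q'

with the inertia matrix assembled from the kinetic energy of the chain,
the Coriolis matrix built from the Christoffel symbols of M (which makes
dM/dt - 2C skew-symmetric by construction), gravity as the gradient of the
potential energy, and diagonal viscous friction B.

Set-point regulation uses the PD+ law

    tau = Kp (qd - q) + Kv (qd' - q') + M(q) qd'' + C(q, q') qd' + B qd' + g(q)

which for constant targets reduces to PD feedback with exact gravity
compensation; the closed loop drives both the position and velocity error
to zero.  Integration is fixed-step classical Runge-Kutta (RK4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RobotParams:
    """Geometric and inertial parameters of the three links.

    Lengths in meters, masses in kg, link inertias in kg m^2 (about the
    center of mass, perpendicular to the motion plane), viscous friction
    in N m s/rad.
    """

    l: tuple = (0.30, 0.25, 0.25)
    lc: tuple = (0.15, 0.125, 0.125)
    m: tuple = (1.0, 1.0, 0.8)
    I: tuple = (0.01, 0.01, 0.01)
    B: tuple = (0.1, 0.1, 0.1)
    g: float = 9.81

    def __post_init__(self):
        for name in ("l", "lc", "m", "I", "B"):
            vals = getattr(self, name)
            if len(vals) != 3:
                raise ValueError(f"{name} must have 3 entries")
        if any(v <= 0 for v in self.l + self.m):
            raise ValueError("link lengths and masses must be positive")
        if any(not 0 < c <= li for c, li in zip(self.lc, self.l)):
            raise ValueError("center-of-mass distances must satisfy 0 < lc <= l")
        if any(b < 0 for b in self.B):
            raise ValueError("viscous friction must be non-negative")

    @property
    def reach(self) -> tuple[float, float]:
        """(min, max) radial distance of the wrist from the shoulder."""
        return abs(self.l[1] - self.l[2]), self.l[1] + self.l[2]

    @classmethod
    def from_json(cls, path=None) -> "RobotParams":
        if path is None:
            text = (resources.files("myohmi") / "data/robot_params.json").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        obj = json.loads(text)
        return cls(
            l=tuple(obj["l"]), lc=tuple(obj["lc"]), m=tuple(obj["m"]),
            I=tuple(obj["I"]), B=tuple(obj["B"]), g=float(obj["g"]),
        )


@dataclass(frozen=True)
class ControlGains:
    """Positive-definite proportional and derivative gain matrices."""

    Kp: np.ndarray = field(default_factory=lambda: np.diag([100.0, 100.0, 100.0]))
    Kv: np.ndarray = field(default_factory=lambda: np.diag([20.0, 20.0, 20.0]))

    def __post_init__(self):
        for name, K in (("Kp", self.Kp), ("Kv", self.Kv)):
            K = np.asarray(K, dtype=float)
            if K.shape != (3, 3) or not np.allclose(K, K.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            try:
                np.linalg.cholesky(K)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"{name} must be positive definite") from exc
            object.__setattr__(self, name, K)


class WorkspaceError(ValueError):
    """Requested Cartesian point is outside the reachable workspace."""


class Manipulator:
    """The arm model: kinematics, dynamics and closed-loop simulation."""

    def __init__(self, params: RobotParams | None = None,
                 gains: ControlGains | None = None):
        self.params = params if params is not None else RobotParams()
        self.gains = gains if gains is not None else ControlGains()

    # -- kinematics ---------------------------------------------------------

    def forward_kinematics(self, q) -> np.ndarray:
        """End-effector position (px, py, pz) for joint angles q (rad)."""
        q1, q2, q3 = np.asarray(q, dtype=float)
        _, l2, l3 = self.params.l
        r = l2 * np.cos(q2) + l3 * np.cos(q2 + q3)
        return np.array([
            np.cos(q1) * r,
            np.sin(q1) * r,
            self.params.l[0] + l2 * np.sin(q2) + l3 * np.sin(q2 + q3),
        ])

    def inverse_kinematics(self, p, elbow: int = 1) -> np.ndarray:
        """Joint angles reaching Cartesian point p; ``elbow`` = +1 or -1 branch.

        q1 = atan2(py, px); q2 from the half-angle solution of
        a cos q2 + b sin q2 = c with a = 2 l2 r, b = 2 l2 u,
        c = r^2 + u^2 + l2^2 - l3^2 (r: radial, u: vertical wrist offset);
        q3 closes the chain exactly, so FK(IK(p)) = p to round-off.
        """
        px, py, pz = np.asarray(p, dtype=float)
        l1, l2, l3 = self.params.l
        if px == 0.0 and py == 0.0:
            import warnings

            warnings.warn("px = py = 0: base angle is singular, using q1 = 0",
                          stacklevel=2)
            q1 = 0.0
        else:
            q1 = float(np.arctan2(py, px))
        r = px * np.cos(q1) + py * np.sin(q1)
        u = pz - l1
        d = float(np.hypot(r, u))
        lo, hi = self.params.reach
        if not lo - 1e-12 <= d <= hi + 1e-12:
            raise WorkspaceError(
                f"point {tuple(np.round(p, 4))} at wrist distance {d:.4f} m is "
                f"outside the reachable annulus [{lo:.4f}, {hi:.4f}] m"
            )
        a = 2.0 * l2 * r
        b = 2.0 * l2 * u
        c = r * r + u * u + l2 * l2 - l3 * l3
        disc = max(a * a + b * b - c * c, 0.0)
        s = 1 if elbow >= 0 else -1
        q2 = 2.0 * float(np.arctan2(b + s * np.sqrt(disc), a + c))
        # elbow angle from the wrist residual: exact closure
        q23 = float(np.arctan2(u - l2 * np.sin(q2), r - l2 * np.cos(q2)))
        q3 = float(np.arctan2(np.sin(q23 - q2), np.cos(q23 - q2)))
        return np.array([q1, q2, q3])

    # -- dynamics -----------------------------------------------------------

    def inertia_matrix(self, q) -> np.ndarray:
        """Symmetric positive-definite inertia matrix M(q)."""
        _, q2, q3 = np.asarray(q, dtype=float)
        _, l2, _ = self.params.l
        _, lc2, lc3 = self.params.lc
        _, m2, m3 = self.params.m
        I1, I2, I3 = self.params.I
        c2, c23, c3 = np.cos(q2), np.cos(q2 + q3), np.cos(q3)
        A = l2 * c2 + lc3 * c23  # COM-3 horizontal reach
        M = np.zeros((3, 3))
        M[0, 0] = I1 + I2 + I3 + m2 * (lc2 * c2) ** 2 + m3 * A**2
        M[1, 1] = I2 + I3 + m2 * lc2**2 + m3 * (l2**2 + lc3**2 + 2 * l2 * lc3 * c3)
        M[1, 2] = M[2, 1] = I3 + m3 * (lc3**2 + l2 * lc3 * c3)
        M[2, 2] = I3 + m3 * lc3**2
        return M

    def _dM_dq(self, q) -> np.ndarray:
        """Analytic partials dM/dq_i, shape (3, 3, 3); M depends on q2, q3 only."""
        _, q2, q3 = np.asarray(q, dtype=float)
        _, l2, _ = self.params.l
        _, lc2, lc3 = self.params.lc
        _, m2, m3 = self.params.m
        c2, s2 = np.cos(q2), np.sin(q2)
        c23, s23 = np.cos(q2 + q3), np.sin(q2 + q3)
        s3 = np.sin(q3)
        A = l2 * c2 + lc3 * c23
        dM = np.zeros((3, 3, 3))
        # dM/dq2
        dM[1, 0, 0] = -2 * m2 * lc2**2 * c2 * s2 - 2 * m3 * A * (l2 * s2 + lc3 * s23)
        # dM/dq3
        dM[2, 0, 0] = -2 * m3 * A * lc3 * s23
        dM[2, 1, 1] = -2 * m3 * l2 * lc3 * s3
        dM[2, 1, 2] = dM[2, 2, 1] = -m3 * l2 * lc3 * s3
        return dM

    def coriolis_matrix(self, q, qdot) -> np.ndarray:
        """C(q, q') from the Christoffel symbols of M(q).

        C_kj = sum_i 1/2 (dM_kj/dq_i + dM_ki/dq_j - dM_ij/dq_k) q'_i, which
        guarantees dM/dt - 2C is skew-symmetric.
        """
        qdot = np.asarray(qdot, dtype=float)
        dM = self._dM_dq(q)
        # C_kj = 1/2 sum_i (dM[i,k,j] + dM[j,k,i] - dM[k,i,j]) qdot_i
        return 0.5 * (
            np.einsum("ikj,i->kj", dM, qdot)
            + np.einsum("jki,i->kj", dM, qdot)
            - np.einsum("kij,i->kj", dM, qdot)
        )

    def potential_energy(self, q) -> float:
        """Gravitational potential of links 2 and 3 above the shoulder."""
        _, q2, q3 = np.asarray(q, dtype=float)
        _, l2, _ = self.params.l
        _, lc2, lc3 = self.params.lc
        _, m2, m3 = self.params.m
        return self.params.g * (
            m2 * lc2 * np.sin(q2) + m3 * (l2 * np.sin(q2) + lc3 * np.sin(q2 + q3))
        )

    def gravity_vector(self, q) -> np.ndarray:
        """g(q) = dU/dq; the base joint never feels gravity (g1 = 0)."""
        _, q2, q3 = np.asarray(q, dtype=float)
        _, l2, _ = self.params.l
        _, lc2, lc3 = self.params.lc
        _, m2, m3 = self.params.m
        g = self.params.g
        c2, c23 = np.cos(q2), np.cos(q2 + q3)
        return np.array([
            0.0,
            g * ((m2 * lc2 + m3 * l2) * c2 + m3 * lc3 * c23),
            g * m3 * lc3 * c23,
        ])

    def kinetic_energy(self, q, qdot) -> float:
        qdot = np.asarray(qdot, dtype=float)
        return 0.5 * float(qdot @ self.inertia_matrix(q) @ qdot)

    def dynamics_rhs(self, q, qdot, tau) -> np.ndarray:
        """Joint accelerations q'' = M^{-1} (tau - C q' - g - B q')."""
        qdot = np.asarray(qdot, dtype=float)
        M = self.inertia_matrix(q)
        C = self.coriolis_matrix(q, qdot)
        rhs = (np.asarray(tau, dtype=float) - C @ qdot - self.gravity_vector(q)
               - np.asarray(self.params.B) * qdot)
        return np.linalg.solve(M, rhs)

    # -- control ------------------------------------------------------------

    def pdplus_torque(self, q, qdot, qd, qd_dot=None, qd_ddot=None,
                      gains: ControlGains | None = None) -> np.ndarray:
        """PD feedback plus full-model feedforward (PD+)."""
        gains = gains if gains is not None else self.gains
        q = np.asarray(q, dtype=float)
        qdot = np.asarray(qdot, dtype=float)
        qd = np.asarray(qd, dtype=float)
        qd_dot = np.zeros(3) if qd_dot is None else np.asarray(qd_dot, dtype=float)
        qd_ddot = np.zeros(3) if qd_ddot is None else np.asarray(qd_ddot, dtype=float)
        e = qd - q
        edot = qd_dot - qdot
        return (gains.Kp @ e + gains.Kv @ edot
                + self.inertia_matrix(q) @ qd_ddot
                + self.coriolis_matrix(q, qdot) @ qd_dot
                + np.asarray(self.params.B) * qd_dot
                + self.gravity_vector(q))

    # -- closed-loop simulation --------------------------------------------

    def simulate(
        self,
        q0,
        qd,
        qdot0=None,
        qd_dot=None,
        qd_ddot=None,
        gains: ControlGains | None = None,
        dt: float = 1e-3,
        duration: float = 8.0,
        torque_fn=None,
    ) -> "SimulationResults":
        """Fixed-step RK4 integration of the closed loop.

        ``qd`` (and optionally ``qd_dot``, ``qd_ddot``) may be constant
        vectors or callables of time; ``torque_fn(t, q, qdot)`` overrides
        the PD+ law entirely (e.g. zero torque for energy checks).
        """
        if dt > 2e-3 or dt <= 0:
            raise ValueError(f"dt must lie in (0, 0.002] s, got {dt}")
        if duration <= 0:
            raise ValueError("duration must be positive")
        gains = gains if gains is not None else self.gains

        def as_fn(v, default):
            if v is None:
                return lambda t: default
            if callable(v):
                return v
            arr = np.asarray(v, dtype=float)
            return lambda t: arr

        qd_f = as_fn(qd, np.zeros(3))
        qd_dot_f = as_fn(qd_dot, np.zeros(3))
        qd_ddot_f = as_fn(qd_ddot, np.zeros(3))
        if torque_fn is None:
            def torque_fn(t, q, v):
                return self.pdplus_torque(q, v, qd_f(t), qd_dot_f(t),
                                          qd_ddot_f(t), gains)

        n_steps = int(round(duration / dt))
        t_grid = np.arange(n_steps + 1) * dt
        q = np.asarray(q0, dtype=float).copy()
        v = np.zeros(3) if qdot0 is None else np.asarray(qdot0, dtype=float).copy()
        Q = np.empty((n_steps + 1, 3))
        V = np.empty((n_steps + 1, 3))
        TAU = np.empty((n_steps + 1, 3))
        Q[0], V[0] = q, v
        TAU[0] = torque_fn(0.0, q, v)

        def deriv(t, q, v):
            tau = torque_fn(t, q, v)
            return v, self.dynamics_rhs(q, v, tau), tau

        for i in range(n_steps):
            t = t_grid[i]
            k1q, k1v, tau = deriv(t, q, v)
            k2q, k2v, _ = deriv(t + dt / 2, q + dt / 2 * k1q, v + dt / 2 * k1v)
            k3q, k3v, _ = deriv(t + dt / 2, q + dt / 2 * k2q, v + dt / 2 * k2v)
            k4q, k4v, _ = deriv(t + dt, q + dt * k3q, v + dt * k3v)
            q = q + dt / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
            v = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
            if np.linalg.norm(v) > 1e3:
                raise RuntimeError(
                    f"simulation diverged at t = {t + dt:.3f} s "
                    f"(|qdot| = {np.linalg.norm(v):.1f} rad/s)"
                )
            Q[i + 1], V[i + 1] = q, v
            TAU[i + 1] = torque_fn(t_grid[i + 1], q, v)

        QD = np.vstack([qd_f(t) for t in t_grid])
        QD_DOT = np.vstack([qd_dot_f(t) for t in t_grid])
        return SimulationResults(self, t_grid, Q, V, TAU, QD, QD_DOT)


class SimulationResults:
    """Closed-loop trajectory: states, torques and tracking errors."""

    def __init__(self, model, t, q, qdot, tau, qd, qd_dot):
        self.model = model
        self.t = t
        self.q = q
        self.qdot = qdot
        self.tau = tau
        self.qd = qd
        self.qd_dot = qd_dot

    @property
    def error(self) -> np.ndarray:
        """Position tracking error qd(t) - q(t), per joint."""
        return self.qd - self.q

    @property
    def error_rate(self) -> np.ndarray:
        return self.qd_dot - self.qdot

    @property
    def final_error_inf(self) -> float:
        return float(np.max(np.abs(self.error[-1])))

    def error_inf_after(self, t_from: float) -> float:
        """sup-norm of the joint error over t >= t_from."""
        mask = self.t >= t_from
        return float(np.max(np.abs(self.error[mask])))

    def cartesian_error_m(self) -> float:
        """Final end-effector distance from the desired point, meters."""
        p = self.model.forward_kinematics(self.q[-1])
        p_des = self.model.forward_kinematics(self.qd[-1])
        return float(np.linalg.norm(p - p_des))

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for j in range(3):
            cols[f"q{j + 1}"] = self.q[:, j]
            cols[f"e{j + 1}"] = self.error[:, j]
            cols[f"tau{j + 1}"] = self.tau[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        e = self.error
        lines = [
            "PD+ closed-loop simulation",
            "=" * 40,
            f"duration: {self.t[-1]:.3f} s   steps: {self.t.size - 1}   "
            f"dt: {self.t[1] - self.t[0]:.4g} s",
            f"target q_d (rad): {np.round(self.qd[-1], 4)}",
            f"final joint error (rad): {np.round(e[-1], 6)}",
            f"final |error|_inf: {self.final_error_inf:.2e} rad",
            f"final Cartesian error: {self.cartesian_error_m() * 1e3:.4f} mm",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Joint tracking errors over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j in range(3):
            ax.plot(self.t, self.error[:, j], label=f"$\\tilde q_{j + 1}$")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("joint error (rad)")
        ax.legend()
        return ax
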