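"""Seven-DOF serial-chain arm: kinematics, dynamics, joint limits.

The arm is modelled as a serial chain anchored at the right shoulder:
three shoulder DOFs (elevation-plane angle, shoulder elevation, humeral
rotation), elbow flexion, forearm pronation/supination, wrist deviation
and wrist flexion.  The end-effector is the tip of the index finger.
Coordinate frame: right-handed, origin at the shoulder, +x to the
subject's right, +y up, +z forward.  At the reference posture (all
angles zero) the arm hangs straight down along -y.

Dynamics are plain rigid-body mechanics of three segments (upper arm,
forearm, hand) driven by joint torques and gravity, integrated with a
semi-implicit Euler scheme at a small substep.  The chain sits behind a
small backend interface (`DynamicsBackend`) so that an external physics
engine could be substituted; everything downstream talks to the
interface only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEG = np.pi / 180.0

__all__ = [
    "JointSpec",
    "ArmConfig",
    "ArmState",
    "InvalidStateError",
    "NumericalFailureError",
    "default_arm_config",
    "forward_kinematics",
    "forward_dynamics",
    "enforce_joint_limits",
    "jacobian",
    "SerialChainBackend",
    "solve_ik",
]


class InvalidStateError(ValueError):
    """A joint angle lies outside its configured range."""


class NumericalFailureError(RuntimeError):
    """The integrator produced a non-finite state."""


@dataclass(frozen=True)
class JointSpec:
    """One actuated degree of freedom.

    Parameters
    ----------
    name : str
        Human-readable DOF name.
    angle_min, angle_max : float
        Joint range in radians, ``angle_min < angle_max``.
    torque_scale : float
        Magnitude ``g`` of the torque range limit in N·m; the torque
        applied at this DOF is ``g * activation``.
    """

    name: str
    angle_min: float
    angle_max: float
    torque_scale: float

    def __post_init__(self) -> None:
        if not self.angle_min < self.angle_max:
            raise ValueError(f"{self.name}: angle_min must be < angle_max")
        if not self.torque_scale > 0:
            raise ValueError(f"{self.name}: torque_scale must be positive")


#: Joint ranges (deg) and maximum voluntary torques (N·m) per DOF, in
#: chain order.  These are the model's defaults; angles are stored in
#: radians on the JointSpec.
DEFAULT_JOINT_TABLE = (
    ("elevation_angle", -90.0, 130.0, 36.01),
    ("shoulder_elevation", 0.0, 180.0, 60.97),
    ("shoulder_rotation", -90.0, 20.0, 19.37),
    ("elbow_flexion", 0.0, 130.0, 12.57),
    ("pronation_supination", -90.0, 90.0, 1.03),
    ("wrist_deviation", -10.0, 25.0, 2.14),
    ("wrist_flexion", -70.0, 70.0, 1.53),
)


@dataclass(frozen=True)
class ArmConfig:
    """Full arm description: joints, segments, gravity, frame origin.

    Segment lengths/masses are configurable stand-ins for a specific
    subject; defaults are generic adult anthropometrics (upper arm,
    forearm, hand measured shoulder->elbow, elbow->wrist,
    wrist->fingertip).
    """

    joints: tuple[JointSpec, ...]
    segment_lengths: tuple[float, float, float] = (0.34, 0.28, 0.20)
    segment_masses: tuple[float, float, float] = (2.0, 1.2, 0.5)
    # rod-like transverse inertia fractions are derived from length and
    # mass; segment_inertias stores the axial (long-axis) inertias.
    segment_inertias: tuple[float, float, float] = (2e-3, 1e-3, 5e-4)
    # reflected rotor/soft-tissue inertia added to every diagonal entry of
    # the mass matrix.  At aligned-axis postures (the hanging arm brings
    # the elevation-plane and humeral-rotation axes into line) the rigid
    # chain's mass matrix is exactly singular; the armature term bounds
    # its smallest eigenvalue away from zero.
    joint_armature: float = 1e-4
    gravity: tuple[float, float, float] = (0.0, -9.81, 0.0)
    shoulder_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.joints) != 7:
            raise ValueError("ArmConfig requires exactly 7 joints")
        if any(l <= 0 for l in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if any(m <= 0 for m in self.segment_masses):
            raise ValueError("segment masses must be positive")
        if self.joint_armature <= 0:
            raise ValueError("joint_armature must be positive")

    @property
    def torque_scales(self) -> np.ndarray:
        return np.array([j.torque_scale for j in self.joints])

    @property
    def angle_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([j.angle_min for j in self.joints])
        hi = np.array([j.angle_max for j in self.joints])
        return lo, hi


def default_arm_config(**overrides) -> ArmConfig:
    joints = tuple(
        JointSpec(name, lo * DEG, hi * DEG, g)
        for name, lo, hi, g in DEFAULT_JOINT_TABLE
    )
    return ArmConfig(joints=joints, **overrides)


@dataclass
class ArmState:
    """Joint angles (rad) and velocities (rad/s)."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != (7,) or self.qdot.shape != (7,):
            raise ValueError("ArmState requires 7 angles and 7 velocities")

    def copy(self) -> "ArmState":
        return ArmState(self.q.copy(), self.qdot.copy())


# -- chain geometry ---------------------------------------------------------

# Rotation axis of each joint in its local (parent) frame.
_AXES = np.array(
    [
        [0.0, 1.0, 0.0],   # elevation-plane angle: about vertical
        [-1.0, 0.0, 0.0],  # shoulder elevation: lifts the arm forward/up
        [0.0, -1.0, 0.0],  # humeral internal/external rotation
        [-1.0, 0.0, 0.0],  # elbow flexion: curls the hand up/forward
        [0.0, -1.0, 0.0],  # pronation/supination about the forearm axis
        [0.0, 0.0, 1.0],   # wrist radial/ulnar deviation
        [1.0, 0.0, 0.0],   # wrist flexion
    ]
)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _joint_offsets(config: ArmConfig) -> np.ndarray:
    """Translation from the previous joint frame to each joint, local frame."""
    l_ua, l_fa, _ = config.segment_lengths
    t = np.zeros((7, 3))
    t[3] = (0.0, -l_ua, 0.0)  # shoulder -> elbow
    t[5] = (0.0, -l_fa, 0.0)  # elbow -> wrist
    return t


def _chain_pass(config: ArmConfig, q: np.ndarray):
    """Forward pass: world joint positions, world axes, frame rotations."""
    offsets = _joint_offsets(config)
    R = np.eye(3)
    p = np.asarray(config.shoulder_origin, dtype=float)
    positions = np.empty((7, 3))
    axes = np.empty((7, 3))
    rotations = []
    for k in range(7):
        p = p + R @ offsets[k]
        axes[k] = R @ _AXES[k]
        R = R @ _axis_rotation(_AXES[k], q[k])
        positions[k] = p
        rotations.append(R)
    return positions, axes, rotations


def _check_state(config: ArmConfig, state: ArmState, tol: float = 1e-9) -> None:
    lo, hi = config.angle_bounds
    if not (np.all(np.isfinite(state.q)) and np.all(np.isfinite(state.qdot))):
        bad = int(np.argmax(~(np.isfinite(state.q) & np.isfinite(state.qdot))))
        raise NumericalFailureError(
            f"non-finite state at DOF '{config.joints[bad].name}'"
        )
    if np.any(state.q < lo - tol) or np.any(state.q > hi + tol):
        bad = int(np.argmax((state.q < lo - tol) | (state.q > hi + tol)))
        raise InvalidStateError(
            f"joint '{config.joints[bad].name}' angle {state.q[bad]:.4f} rad "
            f"outside [{lo[bad]:.4f}, {hi[bad]:.4f}]"
        )


def forward_kinematics(config: ArmConfig, state: ArmState) -> np.ndarray:
    """Fingertip position (m) in the shoulder-anchored world frame."""
    _check_state(config, state)
    positions, _, rotations = _chain_pass(config, state.q)
    l_hand = config.segment_lengths[2]
    return positions[6] + rotations[6] @ np.array([0.0, -l_hand, 0.0])


def jacobian(config: ArmConfig, state: ArmState) -> np.ndarray:
    """3x7 linear-velocity Jacobian of the fingertip."""
    positions, axes, rotations = _chain_pass(config, state.q)
    tip = positions[6] + rotations[6] @ np.array([0.0, -config.segment_lengths[2], 0.0])
    return np.cross(axes, tip - positions).T


def enforce_joint_limits(config: ArmConfig, state: ArmState) -> ArmState:
    """Clip angles to their ranges; zero the velocity of clipped DOFs."""
    lo, hi = config.angle_bounds
    q = np.clip(state.q, lo, hi)
    clipped = q != state.q
    qdot = np.where(clipped, 0.0, state.qdot)
    return ArmState(q, qdot)


class SerialChainBackend:
    """Built-in rigid-body dynamics of the three-segment chain.

    Mass matrix from body Jacobians; bias (Coriolis, centrifugal and
    gravity) from a velocity/acceleration propagation with the base
    linear acceleration set to -g, which folds gravity into the
    inertial forces.
    """

    #: chain frame index each segment is rigidly attached to
    _BODY_FRAME = (2, 4, 6)

    def __init__(self, config: ArmConfig, use_fast: bool = True):
        self.config = config
        m = config.segment_masses
        L = config.segment_lengths
        ax = config.segment_inertias
        # thin-rod transverse inertia about the COM, long axis along -y
        self._inertia_local = [
            np.diag([m[i] * L[i] ** 2 / 12.0, ax[i], m[i] * L[i] ** 2 / 12.0])
            for i in range(3)
        ]
        self._com_local = [np.array([0.0, -L[i] / 2.0, 0.0]) for i in range(3)]
        # constant arrays for the compiled inner loop
        from . import _fastdyn

        self._fast = _fastdyn if (use_fast and _fastdyn.HAVE_NUMBA) else None
        self._offsets = _joint_offsets(config)
        self._axes_local = _AXES.copy()
        self._body_frame = np.array(self._BODY_FRAME, dtype=np.int64)
        self._com_local_arr = np.array(self._com_local)
        self._inertia_diag = np.array(
            [np.diag(I) for I in self._inertia_local]
        )
        self._masses = np.array(config.segment_masses, dtype=float)
        self._gravity = np.array(config.gravity, dtype=float)
        lo, hi = config.angle_bounds
        self._lo, self._hi = lo, hi

    # -- quantities exposed for tests and energy accounting ------------

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        positions, axes, rotations = _chain_pass(self.config, q)
        M = np.zeros((7, 7))
        for b, frame in enumerate(self._BODY_FRAME):
            R = rotations[frame]
            com = positions[frame] + R @ self._com_local[b]
            k = frame + 1
            Jv = np.zeros((3, 7))
            Jw = np.zeros((3, 7))
            Jv[:, :k] = np.cross(axes[:k], com - positions[:k]).T
            Jw[:, :k] = axes[:k].T
            Iw = R @ self._inertia_local[b] @ R.T
            m = self.config.segment_masses[b]
            M += m * Jv.T @ Jv + Jw.T @ Iw @ Jw
        M += self.config.joint_armature * np.eye(7)
        return M

    def bias_forces(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        """Generalized Coriolis/centrifugal + gravity forces Q(q, qdot)."""
        cfg = self.config
        positions, axes, rotations = _chain_pass(cfg, q)
        g = np.asarray(cfg.gravity)
        # propagate angular velocity/acceleration and linear acceleration
        # of the joint origins with qddot = 0 and base accel = -g
        omega = np.zeros((8, 3))
        alpha = np.zeros((8, 3))
        acc = np.zeros((8, 3))
        acc[0] = -g
        prev_p = np.asarray(cfg.shoulder_origin, dtype=float)
        for k in range(7):
            r = positions[k] - prev_p
            acc[k + 1] = acc[k] + np.cross(alpha[k], r) + np.cross(
                omega[k], np.cross(omega[k], r)
            )
            alpha[k + 1] = alpha[k] + np.cross(omega[k], axes[k]) * qdot[k]
            omega[k + 1] = omega[k] + axes[k] * qdot[k]
            prev_p = positions[k]
        Q = np.zeros(7)
        for b, frame in enumerate(self._BODY_FRAME):
            R = rotations[frame]
            com = positions[frame] + R @ self._com_local[b]
            w = omega[frame + 1]
            al = alpha[frame + 1]
            r = com - positions[frame]
            a_com = acc[frame + 1] + np.cross(al, r) + np.cross(w, np.cross(w, r))
            Iw = R @ self._inertia_local[b] @ R.T
            f = self.config.segment_masses[b] * a_com
            n = Iw @ al + np.cross(w, Iw @ w)
            k = frame + 1
            Jv = np.cross(axes[:k], com - positions[:k]).T
            Jw = axes[:k].T
            Q[:k] += Jv.T @ f + Jw.T @ n
        return Q

    def com_positions(self, q: np.ndarray) -> np.ndarray:
        positions, _, rotations = _chain_pass(self.config, q)
        return np.array(
            [
                positions[f] + rotations[f] @ self._com_local[b]
                for b, f in enumerate(self._BODY_FRAME)
            ]
        )

    def mechanical_energy(self, state: ArmState) -> float:
        """Kinetic + gravitational potential energy of the chain."""
        M = self.mass_matrix(state.q)
        ke = 0.5 * state.qdot @ M @ state.qdot
        g = np.asarray(self.config.gravity)
        coms = self.com_positions(state.q)
        pe = -sum(
            m * (g @ c) for m, c in zip(self.config.segment_masses, coms)
        )
        return ke + pe

    # -- stepping -------------------------------------------------------

    def fk_and_jacobian(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fingertip position and linear Jacobian (fast path if compiled)."""
        if self._fast is not None:
            tip, J = self._fast.fk_jac(
                q, self._offsets, self._axes_local,
                self.config.segment_lengths[2],
            )
            return tip + np.asarray(self.config.shoulder_origin), J
        st = ArmState(q, np.zeros(7))
        return forward_kinematics(self.config, st), jacobian(self.config, st)

    def step(
        self,
        state: ArmState,
        torques: np.ndarray,
        dt: float,
        locked: np.ndarray | None = None,
    ) -> ArmState:
        """One semi-implicit Euler substep under applied joint torques."""
        if self._fast is not None:
            lock = (
                np.zeros(7, dtype=np.bool_) if locked is None
                else locked.astype(np.bool_)
            )
            q_new, qdot_new = self._fast.substep(
                state.q, state.qdot, np.asarray(torques, dtype=float), dt,
                self._offsets, self._axes_local, self._body_frame,
                self._com_local_arr, self._inertia_diag, self._masses,
                self._gravity, self.config.joint_armature,
                self._lo, self._hi, lock,
            )
            if not (np.all(np.isfinite(q_new)) and np.all(np.isfinite(qdot_new))):
                bad = int(np.argmax(~(np.isfinite(q_new) & np.isfinite(qdot_new))))
                raise NumericalFailureError(
                    f"integration diverged at DOF "
                    f"'{self.config.joints[bad].name}'"
                )
            return ArmState(q_new, qdot_new)
        return self.step_reference(state, torques, dt, locked=locked)

    def step_reference(
        self,
        state: ArmState,
        torques: np.ndarray,
        dt: float,
        locked: np.ndarray | None = None,
    ) -> ArmState:
        """Reference numpy substep (the backend-contract baseline)."""
        q, qdot = state.q, state.qdot
        M = self.mass_matrix(q)
        Q = self.bias_forces(q, qdot)
        if locked is not None and locked.any():
            free = ~locked
            qddot = np.zeros(7)
            Mff = M[np.ix_(free, free)]
            qddot[free] = np.linalg.solve(Mff, (torques - Q)[free])
        else:
            qddot = np.linalg.solve(M, torques - Q)
        qdot_new = qdot + dt * qddot
        if locked is not None:
            qdot_new = np.where(locked, 0.0, qdot_new)
        q_new = q + dt * qdot_new
        new = ArmState(q_new, qdot_new)
        if not (np.all(np.isfinite(q_new)) and np.all(np.isfinite(qdot_new))):
            bad = int(np.argmax(~(np.isfinite(q_new) & np.isfinite(qdot_new))))
            raise NumericalFailureError(
                f"integration diverged at DOF '{self.config.joints[bad].name}'"
            )
        return enforce_joint_limits(self.config, new)


def forward_dynamics(
    config: ArmConfig,
    state: ArmState,
    torques: np.ndarray,
    dt: float,
    backend: SerialChainBackend | None = None,
    locked: np.ndarray | None = None,
) -> ArmState:
    """Advance the arm one substep of length ``dt`` under joint torques."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    torques = np.asarray(torques, dtype=float)
    if not np.all(np.isfinite(torques)):
        raise ValueError("torques must be finite")
    if backend is None:
        backend = SerialChainBackend(config)
    return backend.step(state, torques, dt, locked=locked)


def solve_ik(
    config: ArmConfig,
    target: np.ndarray,
    q0: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter: int = 500,
    damping: float = 0.05,
    free_dofs: np.ndarray | None = None,
) -> np.ndarray:
    """Damped-least-squares inverse kinematics for the fingertip.

    Deterministic given the config and start posture.  ``free_dofs``
    optionally restricts the solve to a boolean subset of joints (the
    others keep their ``q0`` values).  Raises ``ValueError`` if the
    target cannot be approached within ``tol``.
    """
    lo, hi = config.angle_bounds
    if free_dofs is None:
        free = np.ones(7, dtype=bool)
    else:
        free = np.asarray(free_dofs, dtype=bool)
    target = np.asarray(target, dtype=float)

    if q0 is not None:
        starts = [np.asarray(q0, dtype=float).copy()]
    else:
        # deterministic restart postures: the nominal start plus a
        # small grid over the three DOFs that move the hand the most,
        # to escape joint-limit local minima of the damped iteration
        starts = [np.array([0.0, 45 * DEG, 0.0, 45 * DEG, 0.0, 0.0, 0.0])]
        for elev_plane in (0.0, 90.0, -45.0, 45.0):
            for elev in (30.0, 90.0, 150.0):
                for elbow in (10.0, 70.0, 120.0):
                    s = np.zeros(7)
                    s[0], s[1], s[3] = (
                        elev_plane * DEG, elev * DEG, elbow * DEG
                    )
                    starts.append(s)

    best_err = np.inf
    for start in starts:
        q = np.clip(start, lo, hi)
        for _ in range(max_iter):
            st = ArmState(q, np.zeros(7))
            err = target - forward_kinematics(config, st)
            if np.linalg.norm(err) < tol:
                return q
            J = jacobian(config, st) * free
            JJt = J @ J.T + damping**2 * np.eye(3)
            dq = J.T @ np.linalg.solve(JJt, err)
            q = np.clip(q + np.clip(dq, -0.2, 0.2), lo, hi)
        best_err = min(
            best_err,
            float(np.linalg.norm(
                target - forward_kinematics(config, ArmState(q, np.zeros(7)))
            )),
        )
    raise ValueError(
        f"IK did not converge: residual {best_err:.4f} m for target {target}"
    )
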