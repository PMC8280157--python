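"""Reaching environment: targets, initial postures, observations, stepping.

One episode is one aimed movement: a spherical target is sampled in a
cuboid workspace in front of the body, the arm starts from a random
posture, and every 10 ms control step the policy's 7-dim action in
[-1, 1] is corrupted by motor noise, integrated through the activation
dynamics and the rigid-body chain (five 2 ms substeps), and rewarded
with -1.  The episode ends successfully when the fingertip has stayed
inside the target for 100 ms (10 consecutive control steps), or
unsuccessfully after 1.5 s (150 steps).  Maximizing return is
therefore exactly minimizing movement time.

The observation is a fixed 48-component layout: joint angles (7),
joint velocities (7), activations (7), excitations (7), end-effector
position (3), target position (3), end-effector velocity (3), target
velocity (3, zero here), end-effector acceleration (3), target minus
end-effector difference vector (3), the projection of the end-effector
velocity onto the unit difference vector (1), and the target radius
(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actuation import (
    ActivationState,
    ControlSignal,
    MuscleParams,
    NoiseParams,
    apply_noise,
    compute_torque,
    step_activation,
)
from .arm import (
    ArmConfig,
    ArmState,
    SerialChainBackend,
    enforce_joint_limits,
    forward_kinematics,
    jacobian,
    solve_ik,
)
from .curriculum import CurriculumState, sample_target_diameter

OBS_DIM = 48

#: Fixed per-component observation scaling (divisors) that brings every
#: block to O(1) magnitude: angles (rad), velocities (rad/s),
#: activations, excitations (1/s), positions (m), linear velocities
#: (m/s), accelerations (m/s^2), difference vector (m), velocity
#: projection (m/s), radius (m).  Optional: policies can be trained on
#: raw or scaled observations; analyses always use physical units.
DEFAULT_OBS_SCALE = np.concatenate(
    [
        np.full(7, 1.0),    # q
        np.full(7, 10.0),   # qdot
        np.full(7, 1.0),    # sigma
        np.full(7, 10.0),   # sigma_dot
        np.full(3, 1.0),    # ee position
        np.full(3, 1.0),    # target position
        np.full(3, 5.0),    # ee velocity
        np.full(3, 5.0),    # target velocity
        np.full(3, 200.0),  # ee acceleration
        np.full(3, 1.0),    # difference vector
        [5.0],              # velocity projection
        [1.0],              # target radius
    ]
)

__all__ = [
    "OBS_DIM",
    "Target",
    "Workspace",
    "EpisodeConfig",
    "EpisodeRecord",
    "sample_target",
    "HullPostureSampler",
    "UniformPostureSampler",
    "assemble_observation",
    "ReachEnv",
]


@dataclass(frozen=True)
class Target:
    """Spherical target: center (m) and radius (m)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float)
        )
        if not self.radius > 0:
            raise ValueError("target radius must be positive")


@dataclass(frozen=True)
class Workspace:
    """Axis-aligned target-sampling cuboid in the shoulder frame.

    Default: 40 cm wide (x), 70 cm high (y), 30 cm deep (z), centered
    50 cm in front of and 10 cm to the right of the shoulder, at
    shoulder height.
    """

    center: tuple[float, float, float] = (0.10, 0.0, 0.50)
    size: tuple[float, float, float] = (0.40, 0.70, 0.30)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        h = np.asarray(self.size) / 2.0
        return c - h, c + h

    def edge_midpoints(self) -> np.ndarray:
        """The 12 edge midpoints of the cuboid (anchor-target layout)."""
        lo, hi = self.bounds
        c = np.asarray(self.center)
        pts = []
        for free in range(3):
            others = [ax for ax in range(3) if ax != free]
            for s0 in (lo, hi):
                for s1 in (lo, hi):
                    p = c.copy()
                    p[others[0]] = s0[others[0]]
                    p[others[1]] = s1[others[1]]
                    pts.append(p)
        return np.array(pts)


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode timing: N = 150 control steps of 10 ms, 100 ms dwell."""

    max_steps: int = 150
    control_dt: float = 0.010
    time_limit: float = 1.5
    dwell_time: float = 0.100
    reward_per_step: float = -1.0

    def __post_init__(self) -> None:
        if abs(self.max_steps * self.control_dt - self.time_limit) > 1e-9:
            raise ValueError(
                f"max_steps * control_dt = "
                f"{self.max_steps * self.control_dt} != time_limit = "
                f"{self.time_limit}"
            )
        ratio = self.dwell_time / self.control_dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dwell_time must be a multiple of control_dt")

    @property
    def dwell_steps(self) -> int:
        return int(round(self.dwell_time / self.control_dt))


def sample_target(
    curriculum_diameter: float,
    rng: np.random.Generator,
    workspace: Workspace | None = None,
) -> Target:
    """Uniform target center in the workspace cuboid; radius = diameter/2."""
    if not 0.001 <= curriculum_diameter <= 0.60:
        raise ValueError("target diameter must lie in [0.001, 0.60] m")
    ws = workspace or Workspace()
    lo, hi = ws.bounds
    center = rng.uniform(lo, hi)
    return Target(center, curriculum_diameter / 2.0)


class HullPostureSampler:
    """Initial postures from the convex hull of 12 anchor postures.

    The anchors are deterministic damped-least-squares IK solutions
    that put the fingertip at each of the 12 edge midpoints of the
    workspace cuboid; samples are convex combinations with flat-simplex
    (Dirichlet(1)) weights, which approximates (but is not identical
    to) a uniform draw over the hull volume.
    """

    def __init__(self, config: ArmConfig, workspace: Workspace | None = None):
        self.config = config
        ws = workspace or Workspace()
        anchors = []
        for point in ws.edge_midpoints():
            anchors.append(solve_ik(config, point))  # raises if unreachable
        self.anchor_postures = np.array(anchors)

    def __call__(self, rng: np.random.Generator) -> np.ndarray:
        w = rng.dirichlet(np.ones(len(self.anchor_postures)))
        return w @ self.anchor_postures


class UniformPostureSampler:
    """Uniform per-DOF posture sampler (used by reduced-DOF configs)."""

    def __init__(self, q_lo: np.ndarray, q_hi: np.ndarray):
        self.q_lo = np.asarray(q_lo, dtype=float)
        self.q_hi = np.asarray(q_hi, dtype=float)

    def __call__(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.q_lo, self.q_hi)


def sample_initial_state(
    config: ArmConfig,
    rng: np.random.Generator,
    posture_sampler,
    qdot_max: float = 0.005,
) -> tuple[ArmState, ActivationState]:
    """Random start: hull posture, tiny joint velocities, zero activation."""
    q = posture_sampler(rng)
    qdot = rng.uniform(-qdot_max, qdot_max, size=7)
    state = enforce_joint_limits(config, ArmState(q, qdot))
    return state, ActivationState.zeros(7)


def assemble_observation(
    arm: ArmState,
    act: ActivationState,
    ee_pos: np.ndarray,
    ee_vel: np.ndarray,
    ee_acc: np.ndarray,
    target: Target,
) -> np.ndarray:
    """Pack the 48-component observation in its fixed layout."""
    diff = target.center - ee_pos
    dist = np.linalg.norm(diff)
    proj = float(ee_vel @ (diff / dist)) if dist > 0 else 0.0
    return np.concatenate(
        [
            arm.q,
            arm.qdot,
            act.sigma,
            act.sigma_dot,
            ee_pos,
            target.center,
            ee_vel,
            np.zeros(3),  # target velocity (static targets)
            ee_acc,
            diff,
            [proj],
            [target.radius],
        ]
    )


@dataclass
class EpisodeRecord:
    """One reaching movement: time series, target and outcome."""

    time: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    sigma: np.ndarray
    sigma_dot: np.ndarray
    ee_pos: np.ndarray
    ee_vel: np.ndarray
    ee_acc: np.ndarray
    action: np.ndarray
    control: np.ndarray
    reward: np.ndarray
    dist: np.ndarray
    in_target: np.ndarray
    target: Target
    success: bool
    movement_time: float
    total_time: float
    termination: str
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.time)

    def to_dataframe(self):
        import pandas as pd

        cols = {"step": np.arange(1, self.n_steps + 1), "time_s": self.time}
        for name, arr in [
            ("q", self.q),
            ("qd", self.qdot),
            ("sig", self.sigma),
            ("sigd", self.sigma_dot),
        ]:
            for i in range(7):
                cols[f"{name}{i + 1}"] = arr[:, i]
        for name, arr in [
            ("ee_", self.ee_pos),
            ("ee_v", self.ee_vel),
            ("ee_a", self.ee_acc),
        ]:
            for i, ax in enumerate("xyz"):
                cols[f"{name}{ax}"] = arr[:, i]
        for name, arr in [("act", self.action), ("ctrl", self.control)]:
            for i in range(7):
                cols[f"{name}{i + 1}"] = arr[:, i]
        cols["reward"] = self.reward
        cols["dist_to_target"] = self.dist
        cols["in_target"] = self.in_target.astype(int)
        return pd.DataFrame(cols)

    def sidecar(self) -> dict:
        return {
            "target_center": self.target.center.tolist(),
            "target_radius": float(self.target.radius),
            "success": bool(self.success),
            "movement_time_s": float(self.movement_time),
            "total_time_s": float(self.total_time),
            "termination": self.termination,
            **self.meta,
        }


class _RecordBuffer:
    def __init__(self) -> None:
        self.rows: list[dict] = []

    def append(self, **kw) -> None:
        self.rows.append(kw)

    def build(
        self, target, success, movement_time, total_time, termination, meta
    ) -> EpisodeRecord:
        def stack(key):
            return np.array([r[key] for r in self.rows])

        return EpisodeRecord(
            time=stack("time"),
            q=stack("q"),
            qdot=stack("qdot"),
            sigma=stack("sigma"),
            sigma_dot=stack("sigma_dot"),
            ee_pos=stack("ee_pos"),
            ee_vel=stack("ee_vel"),
            ee_acc=stack("ee_acc"),
            action=stack("action"),
            control=stack("control"),
            reward=stack("reward"),
            dist=stack("dist"),
            in_target=stack("in_target"),
            target=target,
            success=success,
            movement_time=movement_time,
            total_time=total_time,
            termination=termination,
            meta=meta or {},
        )


class ReachEnv:
    """Gym-style reaching environment over the arm + actuator models."""

    def __init__(
        self,
        arm_config: ArmConfig,
        muscle: MuscleParams | None = None,
        noise: NoiseParams | None = None,
        episode: EpisodeConfig | None = None,
        workspace: Workspace | None = None,
        rng: np.random.Generator | None = None,
        posture_sampler=None,
        controlled_dofs: np.ndarray | None = None,
        record: bool = False,
        obs_scale: np.ndarray | None = None,
    ):
        self.arm_config = arm_config
        self.muscle = muscle or MuscleParams()
        self.noise = noise or NoiseParams()
        self.episode = episode or EpisodeConfig()
        self.workspace = workspace or Workspace()
        self.rng = rng or np.random.default_rng()
        self.backend = SerialChainBackend(arm_config)
        self.record = record
        if controlled_dofs is None:
            self.locked = np.zeros(7, dtype=bool)
        else:
            self.locked = ~np.asarray(controlled_dofs, dtype=bool)
        self.posture_sampler = posture_sampler or HullPostureSampler(
            arm_config, self.workspace
        )
        self.obs_scale = (
            None if obs_scale is None else np.asarray(obs_scale, dtype=float)
        )
        self._arm: ArmState | None = None
        self._act: ActivationState | None = None
        self._buffer: _RecordBuffer | None = None
        self.last_record: EpisodeRecord | None = None

    # -- episode control -------------------------------------------------

    def reset(
        self,
        diameter: float | None = None,
        target: Target | None = None,
        keep_arm_state: bool = False,
    ) -> np.ndarray:
        """Start a new movement; returns the initial observation."""
        if target is None:
            if diameter is None:
                raise ValueError("reset needs a target or a diameter")
            target = sample_target(diameter, self.rng, self.workspace)
        self.target = target
        if not keep_arm_state or self._arm is None:
            arm, act = sample_initial_state(
                self.arm_config, self.rng, self.posture_sampler
            )
            if self.locked.any():
                arm.qdot[self.locked] = 0.0
            self._arm, self._act = arm, act
        self._steps = 0
        self._dwell = 0
        self._done = False
        self._ee_pos, J = self.backend.fk_and_jacobian(self._arm.q)
        self._ee_vel = J @ self._arm.qdot
        self._ee_acc = np.zeros(3)
        self._buffer = _RecordBuffer() if self.record else None
        return self._observe()

    def reset_with_curriculum(
        self, curriculum: CurriculumState, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Episode start as used in training: epsilon-mixed diameter."""
        d = sample_target_diameter(curriculum, rng or self.rng)
        return self.reset(diameter=d)

    def set_target(self, target: Target) -> None:
        """Swap the active target mid-episode (via-point tasks)."""
        self.target = target
        self._dwell = 0

    def _observe(self) -> np.ndarray:
        obs = assemble_observation(
            self._arm, self._act, self._ee_pos, self._ee_vel, self._ee_acc,
            self.target,
        )
        return obs if self.obs_scale is None else obs / self.obs_scale

    @property
    def arm_state(self) -> ArmState:
        return self._arm.copy()

    @property
    def activation_state(self) -> ActivationState:
        return self._act.copy()

    def step(self, action: np.ndarray):
        """One 10 ms control step; returns (obs, reward, done, info)."""
        if self._done:
            raise RuntimeError("episode finished; call reset()")
        action = np.asarray(action, dtype=float)
        clipped = bool(np.any(np.abs(action) > 1.0))
        action = np.clip(action, -1.0, 1.0)
        control = apply_noise(action, self.noise, self.rng)
        arm, act = self._arm, self._act
        for _ in range(self.muscle.n_substeps):
            act = step_activation(act, control, self.muscle)
            tau = compute_torque(act, self.arm_config.joints)
            if self.locked.any():
                tau = np.where(self.locked, 0.0, tau)
            arm = self.backend.step(
                arm, tau, self.muscle.substep_dt, locked=self.locked
            )
        self._arm, self._act = arm, act
        prev_vel = self._ee_vel
        self._ee_pos, J = self.backend.fk_and_jacobian(arm.q)
        self._ee_vel = J @ arm.qdot
        self._ee_acc = (self._ee_vel - prev_vel) / self.episode.control_dt

        self._steps += 1
        dist = float(np.linalg.norm(self.target.center - self._ee_pos))
        inside = dist < self.target.radius
        self._dwell = self._dwell + 1 if inside else 0
        reward = self.episode.reward_per_step

        success = self._dwell >= self.episode.dwell_steps
        timeout = self._steps >= self.episode.max_steps
        done = success or timeout
        info = {
            "distance": dist,
            "dwell": self._dwell,
            "in_target": inside,
            "action_clipped": clipped,
            "success": success,
        }
        if self._buffer is not None:
            self._buffer.append(
                time=self._steps * self.episode.control_dt,
                q=arm.q.copy(),
                qdot=arm.qdot.copy(),
                sigma=act.sigma.copy(),
                sigma_dot=act.sigma_dot.copy(),
                ee_pos=self._ee_pos.copy(),
                ee_vel=self._ee_vel.copy(),
                ee_acc=self._ee_acc.copy(),
                action=action,
                control=control.c.copy(),
                reward=reward,
                dist=dist,
                in_target=inside,
            )
        if done:
            self._done = True
            dt = self.episode.control_dt
            total_time = self._steps * dt
            if success:
                movement_time = (self._steps - self.episode.dwell_steps) * dt
                termination = "success"
            else:
                movement_time = total_time
                termination = "timeout"
            info["movement_time"] = movement_time
            info["total_time"] = total_time
            if self._buffer is not None:
                self.last_record = self._buffer.build(
                    self.target, success, movement_time, total_time,
                    termination, None,
                )
        return self._observe(), reward, done, info
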