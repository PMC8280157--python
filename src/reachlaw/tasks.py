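"""Evaluation protocols and movement-law analyses.

Two protocols probe a trained policy:

* A discrete aimed-movement task following the ISO 9241-9 layout: 13
  equidistant targets on a circle in the frontal plane 50 cm in front
  of and 10 cm to the right of the shoulder, visited in the standard
  across-the-circle order.  Task difficulty is the Shannon index of
  difficulty ID = log2(D/W + 1); conditions sample ID and the
  inter-target distance D independently, and W = D / (2^ID - 1).
  Movement times against ID give the Fitts' Law regression MT = a + b ID.

* A via-point task that elicits rhythmic elliptic movement: targets
  advance along an arc-length-parameterized ellipse in 10 % increments,
  switching as soon as the movement has covered half of the current
  increment.  The speed-curvature relation v = k rho^(1-beta) is then
  fit by log-log regression at 100 Hz.

Also provided: centroid projection of a movement onto its start-target
axis, with phasespace (v vs x) and Hooke (a vs x) pairings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arm import ArmState, solve_ik
from .environment import EpisodeConfig, EpisodeRecord, ReachEnv, Target

__all__ = [
    "FittsCondition",
    "FittsFit",
    "PowerLawFit",
    "EllipseSpec",
    "EllipseGeometry",
    "IsoSchedule",
    "DEFAULT_CONDITION_TABLE",
    "make_iso_conditions",
    "run_iso_task",
    "fitts_fit",
    "run_ellipse_task",
    "curvature_velocity_series",
    "powerlaw_fit",
    "project_trajectory",
]

#: across-the-circle step between consecutive ISO targets (13 targets)
ISO_STEP = 6


@dataclass(frozen=True)
class FittsCondition:
    """One task condition: index of difficulty, distance, width."""

    ID: float
    D: float
    W: float

    def __post_init__(self) -> None:
        if abs(self.ID - math.log2(self.D / self.W + 1.0)) > 1e-9:
            raise ValueError("ID, D, W inconsistent with ID = log2(D/W + 1)")


@dataclass(frozen=True)
class FittsFit:
    """Linear fit MT = a + b * ID."""

    a: float
    b: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class PowerLawFit:
    """Speed-curvature power law v = k * rho^(1-beta)."""

    beta: float
    k: float
    r: float
    r_squared: float
    n_used: int = 0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if abs(self.r_squared - self.r**2) > 1e-9:
            raise ValueError("r_squared must equal r**2")


#: Default condition table: 10 conditions, IDs spanning [1, 4] with
#: distances chosen independently ("form and scale" sampling).
def _default_conditions() -> tuple[FittsCondition, ...]:
    ids = np.linspace(1.0, 4.0, 10)
    dists = [0.15, 0.25, 0.35, 0.15, 0.25, 0.35, 0.15, 0.25, 0.35, 0.35]
    return tuple(
        FittsCondition(float(i), float(d), float(d / (2.0**i - 1.0)))
        for i, d in zip(ids, dists)
    )


DEFAULT_CONDITION_TABLE = _default_conditions()


@dataclass(frozen=True)
class IsoMovement:
    condition: FittsCondition
    rep: int
    direction: int  # index of the movement within the across-circle cycle
    from_index: int
    to_index: int
    target: Target


@dataclass(frozen=True)
class IsoSchedule:
    movements: tuple[IsoMovement, ...]
    layouts: dict  # condition -> (13, 3) target centers

    def __len__(self) -> int:
        return len(self.movements)


def _circle_layout(
    D: float, n_targets: int, center: np.ndarray, e1: np.ndarray,
    e2: np.ndarray,
) -> np.ndarray:
    """Target centers so consecutive across-circle movements span D."""
    radius = D / (2.0 * math.sin(ISO_STEP * math.pi / n_targets))
    angles = 2.0 * math.pi * np.arange(n_targets) / n_targets
    return (
        center
        + radius * np.cos(angles)[:, None] * e1
        + radius * np.sin(angles)[:, None] * e2
    )


def make_iso_conditions(
    condition_table=None,
    n_targets: int = 13,
    reps: int = 50,
    center=(0.10, 0.0, 0.50),
    e1=(1.0, 0.0, 0.0),
    e2=(0.0, 1.0, 0.0),
) -> IsoSchedule:
    """Build the full movement schedule of the ISO aimed-movement task.

    The defaults enumerate 10 conditions x 13 directions x 50 reps =
    6500 movements on a circle in the frontal plane.
    """
    conditions = tuple(condition_table or DEFAULT_CONDITION_TABLE)
    for c in conditions:
        if not 1.0 - 1e-9 <= c.ID <= 4.0 + 1e-9:
            raise ValueError(f"ID {c.ID} outside [1, 4]")
        if c.W < 0.001:
            raise ValueError(
                f"condition ID={c.ID}, D={c.D}: width {c.W:.4f} m < 1 mm"
            )
    center = np.asarray(center, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    movements = []
    layouts = {}
    for cond in conditions:
        layout = _circle_layout(cond.D, n_targets, center, e1, e2)
        layouts[cond] = layout
        for rep in range(reps):
            idx = 0
            for direction in range(n_targets):
                nxt = (idx + ISO_STEP) % n_targets
                movements.append(
                    IsoMovement(
                        condition=cond,
                        rep=rep,
                        direction=direction,
                        from_index=idx,
                        to_index=nxt,
                        target=Target(layout[nxt], cond.W / 2.0),
                    )
                )
                idx = nxt
    return IsoSchedule(tuple(movements), layouts)


def run_iso_task(policy, env: ReachEnv, schedule: IsoSchedule):
    """Execute the scheduled movements sequentially with the greedy policy.

    Each movement starts where the previous one ended (no posture
    reset); whenever a movement's start target differs from the
    previous end (new condition or rep), the arm is placed at the
    posture reaching the start target.
    """
    from .training import greedy_action

    from .actuation import ActivationState

    env.record = True  # the protocol is pointless without trajectories
    records = []
    prev_end: int | None = None
    prev_cond = None
    for mv in schedule.movements:
        new_chain = (
            prev_cond is not mv.condition or prev_end != mv.from_index
        )
        if new_chain:
            start_center = schedule.layouts[mv.condition][mv.from_index]
            free = ~env.locked if env.locked.any() else None
            q = solve_ik(env.arm_config, start_center, free_dofs=free)
            env._arm = ArmState(q, np.zeros(7))
            env._act = ActivationState.zeros(7)
            env.reset(target=mv.target, keep_arm_state=True)
        else:
            env.reset(target=mv.target, keep_arm_state=True)
        obs = env._observe()
        done = False
        while not done:
            obs, _, done, info = env.step(greedy_action(policy, obs))
        rec = env.last_record
        rec.meta.update(
            ID=mv.condition.ID,
            D=mv.condition.D,
            W=mv.condition.W,
            rep=mv.rep,
            direction=mv.direction,
            from_index=mv.from_index,
            to_index=mv.to_index,
        )
        records.append(rec)
        prev_end, prev_cond = mv.to_index, mv.condition
    return records


def records_to_table(records) -> pd.DataFrame:
    """Per-movement table (ID, D, W, movement_time, success, ...)."""
    rows = []
    for r in records:
        rows.append(
            {
                "ID": r.meta.get("ID"),
                "D": r.meta.get("D"),
                "W": r.meta.get("W"),
                "direction": r.meta.get("direction"),
                "rep": r.meta.get("rep"),
                "movement_time": r.movement_time,
                "total_time": r.total_time,
                "success": r.success,
            }
        )
    return pd.DataFrame(rows)


def fitts_fit(data, on: str = "medians") -> FittsFit:
    """Fit MT = a + b * ID.

    ``data`` is either a list of episode records carrying ID metadata
    or a DataFrame with columns ``ID`` and ``movement_time``.  With
    ``on="medians"`` (default) the regression runs on the per-ID median
    movement times; ``on="all"`` uses every movement.
    """
    if not isinstance(data, pd.DataFrame):
        data = records_to_table(data)
    if data["ID"].nunique() < 2:
        raise ValueError("fitts_fit needs at least two distinct IDs")
    if on == "medians":
        grouped = data.groupby("ID")["movement_time"].median()
        x = grouped.index.to_numpy(dtype=float)
        y = grouped.to_numpy(dtype=float)
    elif on == "all":
        x = data["ID"].to_numpy(dtype=float)
        y = data["movement_time"].to_numpy(dtype=float)
    else:
        raise ValueError("on must be 'medians' or 'all'")
    res = stats.linregress(x, y)
    # zero variance in movement time (e.g. every movement timed out)
    # gives an undefined correlation: report no explained variance
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):
        r2 = 0.0
    return FittsFit(
        a=float(res.intercept), b=float(res.slope),
        r_squared=min(r2, 1.0),
    )


# -- elliptic via-point task ------------------------------------------------


@dataclass(frozen=True)
class EllipseSpec:
    """Ellipse traced in the via-point task.

    Default: semi-axes 7.5 cm (horizontal) x 3 cm (vertical), center
    55 cm in front of, 10 cm above and 10 cm to the right of the
    shoulder, lying in the frontal (x-y) plane.
    """

    center: tuple[float, float, float] = (0.10, 0.10, 0.55)
    semi_axis_h: float = 0.075
    semi_axis_v: float = 0.03
    e1: tuple[float, float, float] = (1.0, 0.0, 0.0)
    e2: tuple[float, float, float] = (0.0, 1.0, 0.0)
    via_fraction: float = 0.10
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.semi_axis_h <= 0 or self.semi_axis_v <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0.0 < self.via_fraction <= 0.5:
            raise ValueError("via_fraction must lie in (0, 0.5]")


class EllipseGeometry:
    """Arc-length parameterization of the ellipse, clockwise from the
    leftmost point (which rises first, like a clock hand at 9)."""

    def __init__(self, spec: EllipseSpec, n_grid: int = 4096):
        self.spec = spec
        self.c = np.asarray(spec.center, dtype=float)
        self.e1 = np.asarray(spec.e1, dtype=float)
        self.e2 = np.asarray(spec.e2, dtype=float)
        A, B = spec.semi_axis_h, spec.semi_axis_v
        # phi decreasing from pi: leftmost -> top -> rightmost -> bottom
        phi = np.pi - np.linspace(0.0, 2.0 * np.pi, n_grid + 1)
        self.phi = phi
        speed = np.sqrt(A**2 * np.sin(phi) ** 2 + B**2 * np.cos(phi) ** 2)
        dphi = 2.0 * np.pi / n_grid
        # cumulative arc length along the traversal direction
        mid = 0.5 * (speed[1:] + speed[:-1])
        self.s = np.concatenate([[0.0], np.cumsum(mid) * dphi])
        self.perimeter = float(self.s[-1])
        self.points = (
            self.c
            + A * np.cos(phi)[:, None] * self.e1
            + B * np.sin(phi)[:, None] * self.e2
        )

    def point_at_arc(self, s: float | np.ndarray) -> np.ndarray:
        s = np.mod(s, self.perimeter)
        phi = np.interp(s, self.s, self.phi)
        A, B = self.spec.semi_axis_h, self.spec.semi_axis_v
        return (
            self.c
            + A * np.cos(phi) * self.e1
            + B * np.sin(phi) * self.e2
        )

    def nearest_arc(self, point: np.ndarray) -> float:
        """Arc coordinate of the ellipse point nearest to ``point``."""
        d = np.linalg.norm(self.points - point, axis=1)
        return float(self.s[int(np.argmin(d))])

    def via_arcs(self) -> np.ndarray:
        """Arc coordinates of the via-points over one lap."""
        n = int(round(1.0 / self.spec.via_fraction))
        return self.perimeter * self.spec.via_fraction * np.arange(1, n + 1)


def run_ellipse_task(
    policy,
    env: ReachEnv,
    spec: EllipseSpec | None = None,
    via_radius: float = 0.01,
) -> EpisodeRecord:
    """Trace the ellipse with moving via-point targets for ``duration`` s.

    The first target sits 10 % of the perimeter clockwise from the
    leftmost point; the target advances by one via-point as soon as the
    projection of the movement onto the ellipse has covered more than
    half of the current increment.
    """
    from .training import greedy_action
    from .actuation import ActivationState

    spec = spec or EllipseSpec()
    geom = EllipseGeometry(spec)
    env.record = True  # the analysis needs the traced trajectory
    dt = env.episode.control_dt
    n_steps = int(round(spec.duration / dt))
    # episode config that never terminates before the duration is up
    env.episode = EpisodeConfig(
        max_steps=n_steps,
        control_dt=dt,
        time_limit=n_steps * dt,
        dwell_time=(n_steps + 10) * dt,
    )
    start_point = geom.point_at_arc(0.0)
    free = ~env.locked if env.locked.any() else None
    q = solve_ik(env.arm_config, start_point, free_dofs=free)
    env._arm = ArmState(q, np.zeros(7))
    env._act = ActivationState.zeros(7)

    seg = geom.perimeter * spec.via_fraction
    via_idx = 0
    target_arc = seg  # first via-point: 10% of the curve
    prev_arc = 0.0
    placements = 1
    env.reset(
        target=Target(geom.point_at_arc(target_arc), via_radius),
        keep_arm_state=True,
    )
    obs = env._observe()
    done = False
    while not done:
        obs, _, done, info = env.step(greedy_action(policy, obs))
        ee_arc = geom.nearest_arc(env._ee_pos)
        covered = (ee_arc - prev_arc) % geom.perimeter
        if covered > seg / 2.0 and covered < geom.perimeter / 2.0:
            via_idx += 1
            prev_arc = (prev_arc + seg) % geom.perimeter
            target_arc = (target_arc + seg) % geom.perimeter
            env.set_target(
                Target(geom.point_at_arc(target_arc), via_radius)
            )
            placements += 1
    record = env.last_record
    record.meta.update(
        task="ellipse",
        via_placements=placements,
        perimeter=geom.perimeter,
    )
    return record


def curvature_velocity_series(
    positions: np.ndarray,
    dt: float = 0.01,
    plane_origin=None,
    e1=(1.0, 0.0, 0.0),
    e2=(0.0, 1.0, 0.0),
    v_floor: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Radius of curvature and tangential speed of a planar trajectory.

    Positions are projected onto the plane spanned by (e1, e2);
    velocity and acceleration come from central finite differences.
    Samples with speed below ``v_floor`` (default 1 mm/s) or non-finite
    curvature are dropped; the number of exclusions is returned.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 5:
        raise ValueError("need at least 5 samples")
    origin = (
        np.zeros(3) if plane_origin is None else np.asarray(plane_origin)
    )
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    u = (positions - origin) @ e1
    w = (positions - origin) @ e2
    du = (u[2:] - u[:-2]) / (2.0 * dt)
    dw = (w[2:] - w[:-2]) / (2.0 * dt)
    ddu = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / dt**2
    ddw = (w[2:] - 2.0 * w[1:-1] + w[:-2]) / dt**2
    v = np.hypot(du, dw)
    cross = du * ddw - dw * ddu
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = v**3 / np.abs(cross)
    keep = (v >= v_floor) & np.isfinite(rho) & (rho > 0)
    n_excluded = int(np.size(v) - np.count_nonzero(keep))
    if np.count_nonzero(keep) < 5:
        raise ValueError("fewer than 5 valid curvature samples")
    return rho[keep], v[keep], n_excluded


def powerlaw_fit(rho: np.ndarray, v: np.ndarray) -> PowerLawFit:
    """Log-log regression of speed on radius of curvature."""
    rho = np.asarray(rho, dtype=float)
    v = np.asarray(v, dtype=float)
    if rho.shape != v.shape:
        raise ValueError("rho and v must have equal length")
    bad = np.flatnonzero((rho <= 0) | (v <= 0))
    if bad.size:
        raise ValueError(f"non-positive entries at indices {bad.tolist()[:10]}")
    res = stats.linregress(np.log(rho), np.log(v))
    r = float(res.rvalue)
    if not np.isfinite(r):  # degenerate (constant) input
        r = 0.0
    return PowerLawFit(
        beta=float(1.0 - res.slope),
        k=float(np.exp(res.intercept)),
        r=r,
        r_squared=r**2,
        n_used=len(rho),
    )


def project_trajectory(
    positions: np.ndarray,
    start: np.ndarray,
    target: np.ndarray,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Centroid projection onto the start-target axis.

    Returns per-sample scalar position, velocity and acceleration
    (central differences, one-sided at the ends), plus the phasespace
    (velocity vs position) and Hooke (acceleration vs position)
    pairings as columns.
    """
    positions = np.asarray(positions, dtype=float)
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    axis = target - start
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("start and target coincide")
    unit = axis / norm
    x = (positions - start) @ unit
    v = np.gradient(x, dt)
    a = np.gradient(v, dt)
    return pd.DataFrame(
        {
            "time_s": np.arange(len(x)) * dt,
            "position": x,
            "velocity": v,
            "acceleration": a,
            "phasespace_x": x,
            "phasespace_v": v,
            "hooke_x": x,
            "hooke_a": a,
        }
    )
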