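"""Scaled-down study setup: two controlled DOFs, 10 cm minimum targets.

The reduced condition locks every DOF except shoulder elevation and
elbow flexion, so the fingertip moves in the vertical plane through
the shoulder, and samples targets from a planar slab of the workspace
inside that plane.  The curriculum bottoms out at 10 cm diameters and
training runs for a few tens of thousands of steps with small (64, 64)
networks.  This is the package's desk-scale end-to-end condition: the
same code path as the full run, at a problem size a laptop can check.
"""

from __future__ import annotations

import numpy as np

from .arm import DEG, default_arm_config
from .curriculum import CurriculumState
from .environment import (
    DEFAULT_OBS_SCALE,
    ReachEnv,
    UniformPostureSampler,
    Workspace,
)
from .training import SACConfig

__all__ = [
    "SMOKE_CONTROLLED_DOFS",
    "smoke_workspace",
    "smoke_curriculum",
    "smoke_sac_config",
    "make_smoke_env",
    "smoke_iso_geometry",
    "smoke_iso_schedule",
]

#: shoulder elevation + elbow flexion
SMOKE_CONTROLLED_DOFS = np.array([False, True, False, True, False, False,
                                  False])


def smoke_workspace() -> Workspace:
    # zero-width slab in the arm's movement plane (x = 0).  With the
    # elevation-plane angle locked at zero, positive shoulder elevation
    # sweeps the arm toward +z, so the slab sits in front, placed
    # so that every point of it lies within about a millimetre of the
    # locus the two controlled DOFs can reach (checked against the
    # two-link workspace of the shoulder-elevation/elbow pair).
    return Workspace(center=(0.0, 0.05, 0.60), size=(0.0, 0.40, 0.30))


def smoke_curriculum() -> CurriculumState:
    return CurriculumState(
        diameter=0.60,
        d_min=0.09,
        d_max=0.60,
        step=0.03,
        stop_diameter=0.10,
        eval_period=1_000,
        eval_episodes=15,
    )


def smoke_sac_config(seed: int, max_env_steps: int = 100_000) -> SACConfig:
    return SACConfig(
        hidden_layers=(64, 64),
        initial_collect_steps=2_000,
        eval_period=1_000,
        eval_episodes=15,
        # two effective action dimensions -> entropy target -2
        target_entropy=-2.0,
        max_env_steps=max_env_steps,
        seed=seed,
    )


def make_smoke_env(rng: np.random.Generator, record: bool = False) -> ReachEnv:
    config = default_arm_config()
    lo = np.zeros(7)
    hi = np.zeros(7)
    lo[1], hi[1] = 30 * DEG, 150 * DEG   # shoulder elevation
    lo[3], hi[3] = 10 * DEG, 120 * DEG   # elbow flexion
    return ReachEnv(
        config,
        workspace=smoke_workspace(),
        rng=rng,
        posture_sampler=UniformPostureSampler(lo, hi),
        controlled_dofs=SMOKE_CONTROLLED_DOFS,
        record=record,
        obs_scale=DEFAULT_OBS_SCALE,
    )


def smoke_iso_geometry() -> dict:
    """ISO circle placed in the reduced arm's movement plane."""
    return {
        "center": (0.0, 0.05, 0.60),
        "e1": (0.0, 1.0, 0.0),
        "e2": (0.0, 0.0, 1.0),
    }


def smoke_iso_schedule(reps: int = 5):
    """Reduced aimed-movement protocol: 3 difficulty indices, few reps."""
    from .tasks import FittsCondition, make_iso_conditions

    D = 0.30
    conditions = tuple(
        FittsCondition(i, D, D / (2.0**i - 1.0)) for i in (1.0, 1.5, 2.0)
    )
    return make_iso_conditions(
        condition_table=conditions, reps=reps, **smoke_iso_geometry()
    )
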