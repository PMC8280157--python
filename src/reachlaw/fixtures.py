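"""Synthetic trajectory generators: ground-truth oracles for the analyses.

These fixtures let every analysis operation be exercised without a
training run: a quintic minimum-jerk reach (symmetric bell-shaped
speed profile, peak 1.875 D/MT), an ellipse traversed at constant
equi-affine speed (v = k rho^(1/3), i.e. the two-thirds power law
holds exactly), and a linear Fitts movement-time table MT = a + b ID
with optional Gaussian noise.  All emit the same trajectory schema as
recorded episodes, so analysis code cannot tell simulated from
synthetic input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .tasks import EllipseGeometry, EllipseSpec, FittsCondition

__all__ = [
    "min_jerk_trajectory",
    "affine_velocity_ellipse",
    "synthetic_fitts_dataset",
]


def min_jerk_trajectory(
    start: np.ndarray, end: np.ndarray, MT: float, dt: float = 0.01
) -> pd.DataFrame:
    """Quintic minimum-jerk straight reach from start to end in MT seconds.

    Boundary velocity and acceleration are zero; peak speed is
    1.875 * ||end - start|| / MT at t = MT/2.
    """
    if MT <= 0:
        raise ValueError("MT must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.arange(0.0, MT + dt / 2.0, dt)
    t[-1] = min(t[-1], MT)
    tau = t / MT
    s = 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5
    sdot = (30.0 * tau**2 - 60.0 * tau**3 + 30.0 * tau**4) / MT
    pos = start + s[:, None] * (end - start)
    vel = sdot[:, None] * (end - start)
    df = pd.DataFrame({"time_s": t})
    for i, ax in enumerate("xyz"):
        df[f"ee_{ax}"] = pos[:, i]
    for i, ax in enumerate("xyz"):
        df[f"ee_v{ax}"] = vel[:, i]
    return df


def affine_velocity_ellipse(
    spec: EllipseSpec | None = None,
    gain: float = 0.5,
    dt: float = 0.01,
    duration: float = 60.0,
    phase: float = 0.0,
) -> pd.DataFrame:
    """Ellipse traversal at constant equi-affine speed.

    The tangential speed is v(s) = gain * rho(s)^(1/3), which is
    exactly the two-thirds power law with beta = 2/3 and k = gain.
    ``phase`` offsets the starting arc position (fraction of the
    perimeter).
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    spec = spec or EllipseSpec()
    geom = EllipseGeometry(spec, n_grid=8192)
    A, B = spec.semi_axis_h, spec.semi_axis_v

    def rho_at_arc(s):
        phi = np.interp(np.mod(s, geom.perimeter), geom.s, geom.phi)
        return (A**2 * np.sin(phi) ** 2 + B**2 * np.cos(phi) ** 2) ** 1.5 / (
            A * B
        )

    t_eval = np.arange(0.0, duration + dt / 2.0, dt)

    def speed(t, s):
        return gain * rho_at_arc(s[0]) ** (1.0 / 3.0)

    sol = solve_ivp(
        speed,
        (0.0, t_eval[-1]),
        [phase * geom.perimeter],
        t_eval=t_eval,
        max_step=dt,
        rtol=1e-8,
        atol=1e-10,
    )
    arcs = sol.y[0]
    pts = np.array([geom.point_at_arc(s) for s in arcs])
    df = pd.DataFrame({"time_s": t_eval})
    for i, ax in enumerate("xyz"):
        df[f"ee_{ax}"] = pts[:, i]
    return df


def synthetic_fitts_dataset(
    a: float,
    b: float,
    conditions=None,
    reps: int = 50,
    n_directions: int = 13,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Movement-time table MT = a + b ID + noise, truncated at zero."""
    from .tasks import DEFAULT_CONDITION_TABLE

    if reps < 1:
        raise ValueError("reps must be >= 1")
    conditions = tuple(conditions or DEFAULT_CONDITION_TABLE)
    rng = rng or np.random.default_rng()
    rows = []
    for cond in conditions:
        for direction in range(n_directions):
            for rep in range(reps):
                mt = a + b * cond.ID
                if noise_sd > 0:
                    mt += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "ID": cond.ID,
                        "D": cond.D,
                        "W": cond.W,
                        "direction": direction,
                        "rep": rep,
                        "movement_time": max(mt, 0.0),
                        "success": True,
                    }
                )
    return pd.DataFrame(rows)
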