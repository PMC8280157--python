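"""Evaluation protocols and movement-law analyses against oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from reachlaw.environment import ReachEnv
from reachlaw.tasks import (
    DEFAULT_CONDITION_TABLE,
    ISO_STEP,
    EllipseGeometry,
    EllipseSpec,
    FittsCondition,
    FittsFit,
    PowerLawFit,
    curvature_velocity_series,
    fitts_fit,
    make_iso_conditions,
    powerlaw_fit,
    project_trajectory,
    records_to_table,
    run_iso_task,
)

# -- conditions and schedule -------------------------------------------------


def test_default_schedule_counts():
    schedule = make_iso_conditions()
    assert len(schedule) == 10 * 13 * 50 == 6500
    assert len(DEFAULT_CONDITION_TABLE) == 10
    per_condition = {}
    for mv in schedule.movements:
        per_condition[mv.condition] = per_condition.get(mv.condition, 0) + 1
    assert all(n == 650 for n in per_condition.values())


def test_width_from_difficulty():
    cond = FittsCondition(4.0, 0.35, 0.35 / (2.0**4 - 1.0))
    assert cond.W == pytest.approx(0.0233333, abs=1e-6)
    with pytest.raises(ValueError):
        FittsCondition(4.0, 0.35, 0.05)


@settings(max_examples=200, deadline=None)
@given(
    ID=st.floats(min_value=1.0, max_value=4.0),
    D=st.floats(min_value=0.05, max_value=0.60),
)
def test_difficulty_width_round_trip(ID, D):
    W = D / (2.0**ID - 1.0)
    assert math.log2(D / W + 1.0) == pytest.approx(ID, abs=1e-9)
    FittsCondition(ID, D, W)  # consistency invariant holds


def test_circle_layout_spacing():
    schedule = make_iso_conditions()
    for cond, layout in schedule.layouts.items():
        assert layout.shape == (13, 3)
        # consecutive across-circle movements span exactly D
        for i in range(13):
            j = (i + ISO_STEP) % 13
            assert np.linalg.norm(layout[j] - layout[i]) == pytest.approx(
                cond.D, abs=1e-9
            )


def test_movement_sequence_visits_all_targets():
    schedule = make_iso_conditions(reps=1)
    first = schedule.movements[:13]
    visited = [mv.to_index for mv in first]
    assert sorted(visited) == list(range(13))
    for prev, mv in zip(first, first[1:]):
        assert mv.from_index == prev.to_index


def test_condition_validation():
    with pytest.raises(ValueError, match="outside"):
        make_iso_conditions(
            condition_table=[FittsCondition(0.5, 0.15, 0.15 / (2**0.5 - 1))]
        )
    # a width below 1 mm is rejected (in-range ID, tiny distance)
    with pytest.raises(ValueError, match="width"):
        make_iso_conditions(
            condition_table=[FittsCondition(4.0, 0.014, 0.014 / 15.0)]
        )
    with pytest.raises(ValueError, match="outside"):
        make_iso_conditions(
            condition_table=[FittsCondition(9.0, 0.15, 0.15 / (2**9 - 1))]
        )


# -- Fitts regression --------------------------------------------------------


def test_fitts_fit_exact_on_linear_data():
    from reachlaw.fixtures import synthetic_fitts_dataset

    data = synthetic_fitts_dataset(a=0.2, b=0.3, reps=5)
    for on in ("medians", "all"):
        fit = fitts_fit(data, on=on)
        assert fit.a == pytest.approx(0.2, abs=1e-12)
        assert fit.b == pytest.approx(0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fitts_fit_matches_normal_equations():
    from reachlaw.fixtures import synthetic_fitts_dataset

    rng = np.random.default_rng(30)
    data = synthetic_fitts_dataset(a=0.25, b=0.28, reps=10, noise_sd=0.05,
                                   rng=rng)
    fit = fitts_fit(data, on="all")
    x = data["ID"].to_numpy()
    y = data["movement_time"].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert fit.a == pytest.approx(coef[0], abs=1e-10)
    assert fit.b == pytest.approx(coef[1], abs=1e-10)
    resid = y - X @ coef
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    assert fit.r_squared == pytest.approx(r2, abs=1e-10)


def test_fitts_fit_validation():
    df = pd.DataFrame({"ID": [2.0, 2.0], "movement_time": [0.5, 0.6]})
    with pytest.raises(ValueError, match="two distinct"):
        fitts_fit(df)
    good = pd.DataFrame({"ID": [1.0, 2.0], "movement_time": [0.5, 0.6]})
    with pytest.raises(ValueError, match="medians"):
        fitts_fit(good, on="nope")
    with pytest.raises(ValueError):
        FittsFit(0.1, 0.2, 1.5)


# -- power law ---------------------------------------------------------------


def test_powerlaw_fit_exact_recovery():
    rho = np.logspace(-3, 0, 200)
    v = 0.5 * rho**0.35
    fit = powerlaw_fit(rho, v)
    assert fit.beta == pytest.approx(0.65, abs=1e-12)
    assert fit.k == pytest.approx(0.5, abs=1e-12)
    assert fit.r == pytest.approx(1.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(fit.r**2, abs=1e-12)
    assert fit.n_used == 200


def test_powerlaw_fit_validation():
    with pytest.raises(ValueError, match="non-positive"):
        powerlaw_fit(np.array([1.0, -1.0, 2.0]), np.array([1.0, 1.0, 1.0]))
    with pytest.raises(ValueError, match="equal length"):
        powerlaw_fit(np.ones(3), np.ones(4))
    with pytest.raises(ValueError):
        PowerLawFit(beta=0.6, k=0.5, r=0.9, r_squared=0.5)


# -- curvature / velocity extraction -----------------------------------------


def test_circle_curvature_equals_radius():
    r, omega, dt = 0.1, 0.2, 0.01
    t = np.arange(0.0, 5.0, dt)
    pos = np.column_stack(
        [r * np.cos(omega * t), r * np.sin(omega * t), np.zeros_like(t)]
    )
    rho, v, n_excl = curvature_velocity_series(pos, dt=dt)
    np.testing.assert_allclose(rho, r, atol=1e-6)
    np.testing.assert_allclose(v, r * omega, rtol=1e-5)
    assert n_excl == 0


def test_straight_line_rejected():
    t = np.arange(0.0, 1.0, 0.01)
    pos = np.column_stack([t, 2.0 * t, np.zeros_like(t)])
    with pytest.raises(ValueError, match="valid curvature"):
        curvature_velocity_series(pos, dt=0.01)


def test_slow_samples_are_excluded():
    r, dt = 0.1, 0.01
    t = np.arange(0.0, 4.0, dt)
    omega = 0.5 * (1.0 + np.cos(2 * np.pi * t / 4.0))  # stalls mid-way
    theta = np.cumsum(omega) * dt
    pos = np.column_stack(
        [r * np.cos(theta), r * np.sin(theta), np.zeros_like(t)]
    )
    _, v, n_excl = curvature_velocity_series(pos, dt=dt, v_floor=0.01)
    assert n_excl > 0
    assert np.all(v >= 0.01)


def test_needs_five_samples():
    with pytest.raises(ValueError, match="at least 5"):
        curvature_velocity_series(np.zeros((4, 3)))


# -- ellipse geometry --------------------------------------------------------


def test_ellipse_perimeter_matches_quadrature():
    spec = EllipseSpec()
    geom = EllipseGeometry(spec)
    a, b = spec.semi_axis_h, spec.semi_axis_v
    ecc2 = 1.0 - (b / a) ** 2
    exact = 4.0 * a * special.ellipe(ecc2)
    assert geom.perimeter == pytest.approx(exact, abs=1e-6)


def test_ellipse_starts_at_leftmost_point_and_rises():
    spec = EllipseSpec()
    geom = EllipseGeometry(spec)
    left = np.asarray(spec.center) - spec.semi_axis_h * np.asarray(spec.e1)
    np.testing.assert_allclose(geom.point_at_arc(0.0), left, atol=1e-9)
    soon = geom.point_at_arc(0.01 * geom.perimeter)
    assert (soon - left) @ np.asarray(spec.e2) > 0  # clockwise: rises first


def test_ellipse_arc_round_trip():
    geom = EllipseGeometry(EllipseSpec())
    for s in np.linspace(0.0, geom.perimeter * 0.999, 25):
        p = geom.point_at_arc(s)
        assert geom.nearest_arc(p) == pytest.approx(
            s, abs=geom.perimeter / 1000
        )


def test_via_points_divide_perimeter():
    geom = EllipseGeometry(EllipseSpec())
    arcs = geom.via_arcs()
    assert len(arcs) == 10
    np.testing.assert_allclose(np.diff(arcs), geom.perimeter * 0.1, atol=1e-9)
    assert arcs[-1] == pytest.approx(geom.perimeter, abs=1e-9)


def test_ellipse_curvature_closed_form():
    """Curvature extracted from sampled ellipse positions matches
    rho(phi) = (a^2 sin^2 + b^2 cos^2)^(3/2) / (a b)."""
    a, b, dt = 0.075, 0.03, 0.01
    t = np.arange(0.0, 20.0, dt)
    phi = 0.1 * t  # slow constant-phase traversal
    pos = np.column_stack(
        [a * np.cos(phi), b * np.sin(phi), np.zeros_like(t)]
    )
    rho, _, _ = curvature_velocity_series(pos, dt=dt)
    expected = (a**2 * np.sin(phi) ** 2 + b**2 * np.cos(phi) ** 2) ** 1.5 / (
        a * b
    )
    np.testing.assert_allclose(rho, expected[1:-1], rtol=1e-3)


# -- projection --------------------------------------------------------------


def test_projection_of_straight_movement():
    start = np.array([0.0, 0.0, 0.5])
    target = np.array([0.3, 0.4, 0.5])
    t = np.linspace(0.0, 1.0, 101)
    pos = start + t[:, None] * (target - start)
    df = project_trajectory(pos, start, target, dt=0.01)
    D = np.linalg.norm(target - start)
    np.testing.assert_allclose(df["position"], t * D, atol=1e-12)
    np.testing.assert_allclose(df["velocity"], D, atol=1e-9)
    np.testing.assert_allclose(
        df["acceleration"][1:-1], 0.0, atol=1e-6
    )
    np.testing.assert_array_equal(df["phasespace_x"], df["position"])
    np.testing.assert_array_equal(df["hooke_a"], df["acceleration"])
    with pytest.raises(ValueError, match="coincide"):
        project_trajectory(pos, start, start)


def test_projection_ignores_orthogonal_component():
    start = np.zeros(3)
    target = np.array([1.0, 0.0, 0.0])
    rng = np.random.default_rng(31)
    wiggle = rng.normal(size=50)
    pos = np.column_stack(
        [np.linspace(0, 1, 50), wiggle, np.zeros(50)]
    )
    df = project_trajectory(pos, start, target, dt=0.01)
    np.testing.assert_allclose(df["position"], np.linspace(0, 1, 50),
                               atol=1e-12)


# -- task execution ----------------------------------------------------------


class _ZeroPolicy:
    def heads(self, obs):
        obs = np.atleast_2d(obs)
        return np.zeros((len(obs), 7)), np.zeros((len(obs), 7))


def test_run_iso_task_records_and_metadata(arm_config):
    schedule = make_iso_conditions(
        condition_table=[FittsCondition(1.0, 0.15, 0.15)], reps=1
    )
    env = ReachEnv(arm_config, rng=np.random.default_rng(32), record=True)
    records = run_iso_task(_ZeroPolicy(), env, schedule)
    assert len(records) == 13
    table = records_to_table(records)
    assert set(table.columns) >= {
        "ID", "D", "W", "direction", "rep", "movement_time", "success",
    }
    assert (table["ID"] == 1.0).all()
    # movements chain: each record carries the scheduled indices
    for rec, mv in zip(records, schedule.movements):
        assert rec.meta["from_index"] == mv.from_index
        assert rec.meta["to_index"] == mv.to_index
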