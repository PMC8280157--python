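"""Per-DOF actuator: second-order activation dynamics, motor noise, torque.

Each degree of freedom is driven by a simplified second-order muscle
model aggregating agonist/antagonist action.  The continuous dynamics

    t_e * t_a * sigma'' + (t_e + t_a) * sigma' + sigma = c

with excitation time constant ``t_e`` and activation time constant
``t_a`` are discretized with a forward Euler substep::

    [sigma, sigma_dot]' = A [sigma, sigma_dot] + B c

    A = [[1, dt], [-dt/(t_e t_a), 1 - dt (t_e+t_a)/(t_e t_a)]]
    B = [0, dt/(t_e t_a)]

The control ``c`` is the policy action corrupted by signal-dependent
and constant Gaussian noise, c = (1 + eta) a + eps, drawn once per
control step and held constant over the substeps.  Activation is
signed (actions span [-1, 1]); the torque g * sigma is hard-clipped to
the +-g voluntary-torque range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm import JointSpec

__all__ = [
    "MuscleParams",
    "NoiseParams",
    "ActivationState",
    "ControlSignal",
    "apply_noise",
    "step_activation",
    "activation_matrices",
    "compute_torque",
]


@dataclass(frozen=True)
class MuscleParams:
    """Time constants and stepping cadence of the actuator dynamics.

    Defaults: t_e = 30 ms, t_a = 40 ms, 10 ms control step split into
    five 2 ms substeps.
    """

    t_e: float = 0.030
    t_a: float = 0.040
    control_dt: float = 0.010
    n_substeps: int = 5
    substep_dt: float = 0.002

    def __post_init__(self) -> None:
        if min(self.t_e, self.t_a, self.control_dt, self.substep_dt) <= 0:
            raise ValueError("all muscle time parameters must be positive")
        if self.n_substeps <= 0:
            raise ValueError("n_substeps must be positive")
        if abs(self.n_substeps * self.substep_dt - self.control_dt) > 1e-12:
            raise ValueError(
                f"n_substeps * substep_dt = "
                f"{self.n_substeps * self.substep_dt} != control_dt = "
                f"{self.control_dt}"
            )


@dataclass(frozen=True)
class NoiseParams:
    """Standard deviations of signal-dependent and constant motor noise."""

    sd_signal: float = 0.103
    sd_constant: float = 0.185

    def __post_init__(self) -> None:
        if self.sd_signal < 0 or self.sd_constant < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class ActivationState:
    """Activation sigma and excitation sigma_dot per DOF."""

    sigma: np.ndarray
    sigma_dot: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.sigma_dot = np.asarray(self.sigma_dot, dtype=float)

    @classmethod
    def zeros(cls, n: int = 7) -> "ActivationState":
        return cls(np.zeros(n), np.zeros(n))

    def copy(self) -> "ActivationState":
        return ActivationState(self.sigma.copy(), self.sigma_dot.copy())


@dataclass
class ControlSignal:
    """Noisy control per DOF; deliberately NOT clipped to [-1, 1]."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if not np.all(np.isfinite(self.c)):
            raise ValueError("control signal must be finite")


def apply_noise(
    action: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> ControlSignal:
    """Corrupt an action with signal-dependent and constant noise.

    c = (1 + eta) * a + eps, with eta ~ N(0, sd_signal) and
    eps ~ N(0, sd_constant) drawn independently per DOF, once per
    control step.
    """
    action = np.asarray(action, dtype=float)
    eta = rng.normal(0.0, noise.sd_signal, size=action.shape)
    eps = rng.normal(0.0, noise.sd_constant, size=action.shape)
    return ControlSignal((1.0 + eta) * action + eps)


def activation_matrices(params: MuscleParams) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-time (A, B) of one activation substep."""
    dt = params.substep_dt
    te_ta = params.t_e * params.t_a
    A = np.array(
        [[1.0, dt], [-dt / te_ta, 1.0 - dt * (params.t_e + params.t_a) / te_ta]]
    )
    B = np.array([0.0, dt / te_ta])
    return A, B


def step_activation(
    state: ActivationState, control: ControlSignal, params: MuscleParams
) -> ActivationState:
    """One forward-Euler substep of the activation dynamics (per DOF)."""
    A, B = activation_matrices(params)
    sigma = A[0, 0] * state.sigma + A[0, 1] * state.sigma_dot + B[0] * control.c
    sigma_dot = (
        A[1, 0] * state.sigma + A[1, 1] * state.sigma_dot + B[1] * control.c
    )
    return ActivationState(sigma, sigma_dot)


def compute_torque(
    state: ActivationState, joints: tuple[JointSpec, ...] | list[JointSpec]
) -> np.ndarray:
    """Joint torques tau = g * sigma, clipped to the +-g voluntary range."""
    g = np.array([j.torque_scale for j in joints])
    return np.clip(g * state.sigma, -g, g)
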