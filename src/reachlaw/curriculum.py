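"""Adaptive target-diameter curriculum.

During training the target diameter starts large (60 cm) and is
adapted every evaluation period from the measured greedy success rate:
below 70 % success the diameter grows by 1 cm, above 90 % it shrinks
by 1 cm, and it is always clipped to [0.1 cm, 60 cm].  Threshold
comparisons are strict ("falls below" / "exceeds"): a rate of exactly
0.70 or 0.90 leaves the diameter unchanged.  At episode start the
diameter is the curriculum value with probability 1 - epsilon and
uniform on the full range otherwise, so small and large targets keep
occurring throughout training.  Training stops once the curriculum
diameter falls below ``stop_diameter`` (1 cm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CurriculumState", "update_curriculum", "sample_target_diameter"]


@dataclass(frozen=True)
class CurriculumState:
    diameter: float = 0.60
    d_min: float = 0.001
    d_max: float = 0.60
    step: float = 0.01
    low_threshold: float = 0.70
    high_threshold: float = 0.90
    epsilon: float = 0.10
    eval_period: int = 10_000
    eval_episodes: int = 30
    stop_diameter: float = 0.01

    def __post_init__(self) -> None:
        if not self.d_min <= self.diameter <= self.d_max:
            raise ValueError("diameter must lie in [d_min, d_max]")
        if not 0.0 <= self.low_threshold < self.high_threshold <= 1.0:
            raise ValueError("need 0 <= low_threshold < high_threshold <= 1")

    @property
    def done(self) -> bool:
        return self.diameter < self.stop_diameter


def update_curriculum(
    state: CurriculumState, success_rate: float
) -> CurriculumState:
    """Adapt the diameter from the latest greedy success rate."""
    if not 0.0 <= success_rate <= 1.0:
        raise ValueError("success_rate must lie in [0, 1]")
    d = state.diameter
    if success_rate < state.low_threshold:
        d += state.step
    elif success_rate > state.high_threshold:
        d -= state.step
    d = float(np.clip(d, state.d_min, state.d_max))
    return replace(state, diameter=d)


def sample_target_diameter(
    state: CurriculumState, rng: np.random.Generator
) -> float:
    """Diameter for the next episode: curriculum value or uniform draw."""
    if rng.random() < state.epsilon:
        return float(rng.uniform(state.d_min, state.d_max))
    return state.diameter
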