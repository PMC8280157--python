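"""Shared fixtures for the test suite."""

import numpy as np
import pytest

from reachlaw.arm import (
    ArmConfig,
    JointSpec,
    SerialChainBackend,
    default_arm_config,
)


@pytest.fixture(scope="session")
def arm_config():
    return default_arm_config()


@pytest.fixture(scope="session")
def backend(arm_config):
    return SerialChainBackend(arm_config)


@pytest.fixture(scope="session")
def wide_config():
    """Arm with very wide joint ranges: no limit clipping interferes
    with conservation/closed-form checks."""
    joints = tuple(
        JointSpec(f"j{i}", -2.0 * np.pi, 2.0 * np.pi, 10.0) for i in range(7)
    )
    return ArmConfig(joints=joints)


def random_states(config, n, rng, qdot_scale=1.0):
    """Random in-range joint states."""
    lo, hi = config.angle_bounds
    q = rng.uniform(lo, hi, size=(n, 7))
    qdot = rng.uniform(-qdot_scale, qdot_scale, size=(n, 7))
    return q, qdot
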