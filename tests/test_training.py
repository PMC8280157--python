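"""Soft actor-critic machinery: buffer, gradients, evaluation, loop."""

import dataclasses

import numpy as np
import pytest

from reachlaw.arm import forward_kinematics
from reachlaw.environment import Target
from reachlaw.nets import MLP, Adam
from reachlaw.smoke import make_smoke_env, smoke_sac_config
from reachlaw.curriculum import CurriculumState
from reachlaw.training import (
    PolicySpec,
    ReplayBuffer,
    SACAgent,
    SACConfig,
    evaluate_policy,
    greedy_action,
    load_policy,
    sac_train,
    save_policy,
)


def tiny_agent(obs_dim=6, act_dim=3, seed=0, **overrides):
    cfg = SACConfig(hidden_layers=(8, 8), batch_size=4, seed=seed, **overrides)
    return SACAgent(obs_dim, act_dim, cfg, np.random.default_rng(seed))


# -- networks ----------------------------------------------------------------


def test_mlp_gradients_match_finite_differences():
    rng = np.random.default_rng(1)
    net = MLP([5, 7, 4], rng)
    x = rng.normal(size=(3, 5))
    w = rng.normal(size=(3, 4))  # fixed linear readout weights

    def loss_fn():
        return float(np.sum(w * net.forward(x)))

    cache = []
    net.forward(x, cache)
    grads, dx = net.backward(cache, w)
    h = 1e-6
    for p, g in zip(net.params, grads):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 5)):
            idx = it.multi_index
            old = p[idx]
            p[idx] = old + h
            up = loss_fn()
            p[idx] = old - h
            dn = loss_fn()
            p[idx] = old
            assert g[idx] == pytest.approx((up - dn) / (2 * h), abs=1e-4)
            it.iternext()
    # input gradient
    for i in range(3):
        for j in range(5):
            old = x[i, j]
            x[i, j] = old + h
            up = loss_fn()
            x[i, j] = old - h
            dn = loss_fn()
            x[i, j] = old
            assert dx[i, j] == pytest.approx((up - dn) / (2 * h), abs=1e-4)


def test_adam_descends_quadratic():
    p = np.array([5.0])
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        opt.step([p], [2.0 * p])
    assert abs(p[0]) < 0.1


# -- replay buffer -----------------------------------------------------------


def test_replay_buffer_fifo_eviction():
    buf = ReplayBuffer(capacity=3, obs_dim=2, act_dim=1)
    for i in range(5):
        buf.add([i, i], [i], float(i), [i + 1, i + 1], False)
    assert buf.size == 3
    # oldest two transitions (0, 1) were overwritten by (3, 4)
    stored = sorted(buf.rew.tolist())
    assert stored == [2.0, 3.0, 4.0]
    obs, act, rew, nxt, done = buf.sample(8, np.random.default_rng(0))
    assert obs.shape == (8, 2) and act.shape == (8, 1)
    assert set(rew.tolist()) <= {2.0, 3.0, 4.0}


# -- policy heads ------------------------------------------------------------


def test_greedy_action_is_tanh_mean_and_deterministic():
    agent = tiny_agent()
    obs = np.random.default_rng(3).normal(size=6)
    a1 = greedy_action(agent.policy, obs)
    a2 = greedy_action(agent.policy, obs)
    np.testing.assert_array_equal(a1, a2)
    mu, _ = agent.policy.heads(obs)
    np.testing.assert_allclose(a1, np.tanh(mu[0]), atol=1e-12)
    assert np.all(np.abs(a1) < 1.0)


def test_sampled_actions_bounded_and_centered_on_mean():
    agent = tiny_agent()
    obs = np.random.default_rng(4).normal(size=6)
    rng = np.random.default_rng(5)
    samples = np.array([agent.policy.sample(obs, rng) for _ in range(3000)])
    assert np.all(np.abs(samples) < 1.0)
    # tanh is monotone: the sample median estimates tanh(mu)
    np.testing.assert_allclose(
        np.median(samples, axis=0), greedy_action(agent.policy, obs),
        atol=0.08,
    )


def test_policy_save_load_round_trip(tmp_path):
    agent = tiny_agent()
    path = tmp_path / "policy.json"
    save_policy(agent.policy, path)
    restored = load_policy(path)
    obs = np.random.default_rng(6).normal(size=(5, 6))
    np.testing.assert_array_equal(
        greedy_action(agent.policy, obs), greedy_action(restored, obs)
    )
    bad = tmp_path / "bad.json"
    bad.write_text('{"format": "something-else"}')
    with pytest.raises(ValueError):
        load_policy(bad)


# -- SAC update mathematics --------------------------------------------------


def _constant_critic(net, value):
    for w in net.W:
        w[:] = 0.0
    for b in net.b:
        b[:] = 0.0
    net.b[-1][:] = value


def test_critic_targets_use_minimum_and_entropy_bonus():
    agent = tiny_agent()
    _constant_critic(agent.q1_target, -3.0)
    _constant_critic(agent.q2_target, -8.0)
    rng = np.random.default_rng(7)
    B = 4
    next_obs = rng.normal(size=(B, 6))
    rew = np.full(B, -1.0)
    done = np.array([0.0, 0.0, 1.0, 0.0])
    zeta = rng.standard_normal((B, 3))
    y = agent.critic_targets(rew, next_obs, done, zeta)
    _, log_prob, _, _, _ = agent._actor_forward(next_obs, zeta)
    expected = rew + agent.cfg.discount * (1.0 - done) * (
        -8.0 - agent.alpha * log_prob
    )
    np.testing.assert_allclose(y, expected, atol=1e-10)
    assert y[2] == -1.0  # terminal transition does not bootstrap


def test_critic_gradients_match_finite_differences():
    agent = tiny_agent(seed=2)
    rng = np.random.default_rng(8)
    obs = rng.normal(size=(4, 6))
    act = rng.uniform(-1, 1, size=(4, 3))
    y = rng.normal(size=4)
    loss, grads, _ = agent.critic_loss_and_grads(agent.q1, obs, act, y)
    h = 1e-6
    for p, g in zip(agent.q1.params, grads):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 4)):
            idx = it.multi_index
            old = p[idx]
            p[idx] = old + h
            up, _, _ = agent.critic_loss_and_grads(agent.q1, obs, act, y)
            p[idx] = old - h
            dn, _, _ = agent.critic_loss_and_grads(agent.q1, obs, act, y)
            p[idx] = old
            assert g[idx] == pytest.approx((up - dn) / (2 * h), abs=1e-6)
            it.iternext()


def test_actor_gradients_match_finite_differences():
    agent = tiny_agent(seed=3)
    rng = np.random.default_rng(9)
    obs = rng.normal(size=(4, 6))
    zeta = rng.standard_normal((4, 3))
    loss, grads, _ = agent.actor_loss_and_grads(obs, zeta)
    h = 1e-6
    for p, g in zip(agent.actor.params, grads):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 4)):
            idx = it.multi_index
            old = p[idx]
            p[idx] = old + h
            up, _, _ = agent.actor_loss_and_grads(obs, zeta)
            p[idx] = old - h
            dn, _, _ = agent.actor_loss_and_grads(obs, zeta)
            p[idx] = old
            assert g[idx] == pytest.approx((up - dn) / (2 * h), abs=5e-5)
            it.iternext()


def test_temperature_moves_toward_target_entropy():
    # entropy of the fresh policy is far above a very low target:
    # temperature must fall; far below a very high target: must rise
    rng = np.random.default_rng(10)
    batch = (
        rng.normal(size=(4, 6)),
        rng.uniform(-1, 1, size=(4, 3)),
        np.full(4, -1.0),
        rng.normal(size=(4, 6)),
        np.zeros(4),
    )
    low = tiny_agent(seed=4, target_entropy=-50.0)
    low.update(batch, np.random.default_rng(0))
    assert low.log_alpha[0] < 0.0
    high = tiny_agent(seed=4, target_entropy=50.0)
    high.update(batch, np.random.default_rng(0))
    assert high.log_alpha[0] > 0.0


def test_polyak_target_update():
    agent = tiny_agent(seed=5)
    before = [p.copy() for p in agent.q1_target.params]
    online = [p.copy() for p in agent.q1.params]
    rng = np.random.default_rng(11)
    batch = (
        rng.normal(size=(4, 6)),
        rng.uniform(-1, 1, size=(4, 3)),
        np.full(4, -1.0),
        rng.normal(size=(4, 6)),
        np.zeros(4),
    )
    agent.update(batch, rng)
    tau = agent.cfg.target_smoothing
    for pt, b, o_new in zip(
        agent.q1_target.params, before, agent.q1.params
    ):
        np.testing.assert_allclose(
            pt, (1 - tau) * b + tau * o_new, atol=1e-10
        )


# -- evaluation --------------------------------------------------------------


class _AlwaysInTargetEnv:
    """Wrapper placing every target on the fingertip with a huge radius."""

    def __init__(self, env):
        self._env = env

    def __getattr__(self, name):
        return getattr(self._env, name)

    def reset(self, diameter=None, **kw):
        self._env.reset(diameter=0.5)
        tip = forward_kinematics(self._env.arm_config, self._env.arm_state)
        return self._env.reset(target=Target(tip, 5.0), keep_arm_state=True)


def test_evaluate_policy_perfect_environment():
    env = _AlwaysInTargetEnv(make_smoke_env(np.random.default_rng(20)))
    agent = tiny_agent(obs_dim=48, act_dim=7, seed=6)
    stats, _ = evaluate_policy(agent.policy, env, 5, diameter=0.3)
    assert stats["success_rate"] == 1.0
    assert stats["mean_movement_time"] == pytest.approx(0.0)
    assert stats["mean_return"] == pytest.approx(-10.0)


def test_untrained_policy_fails_tiny_targets():
    env = make_smoke_env(np.random.default_rng(21))
    agent = tiny_agent(obs_dim=48, act_dim=7, seed=7)
    stats, _ = evaluate_policy(agent.policy, env, 10, diameter=0.01)
    assert stats["success_rate"] < 0.1
    with pytest.raises(ValueError):
        evaluate_policy(agent.policy, env, 0, diameter=0.01)


def test_sac_train_loop_runs_and_logs():
    env = make_smoke_env(np.random.default_rng(22))
    eval_env = make_smoke_env(np.random.default_rng(23))
    cfg = dataclasses.replace(
        smoke_sac_config(seed=1, max_env_steps=600),
        hidden_layers=(16, 16),
        batch_size=32,
        initial_collect_steps=200,
        eval_period=300,
        eval_episodes=2,
    )
    curriculum = CurriculumState(
        diameter=0.50, d_min=0.09, d_max=0.60, step=0.03,
        stop_diameter=0.05, eval_period=300, eval_episodes=2,
    )
    policy, log = sac_train(env, curriculum, cfg, eval_env=eval_env)
    assert len(log) == 2
    for col in (
        "global_step", "diameter_m", "success_rate", "critic1_loss",
        "actor_loss", "alpha",
    ):
        assert col in log.columns
    assert list(log["global_step"]) == [300, 600]
    assert np.isfinite(log["critic1_loss"]).all()
    a = greedy_action(policy, env.reset(diameter=0.3))
    assert a.shape == (7,) and np.all(np.abs(a) < 1.0)
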