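"""Soft actor-critic training with twin critics and automatic temperature.

The agent is a tanh-squashed Gaussian policy over the 7-dim action
space with twin Q critics (the target value uses the elementwise
minimum of the two target-critic outputs), polyak-averaged target
networks, a uniform replay buffer, and dual-gradient-descent
adaptation of the entropy temperature alpha toward a target entropy.

Training alternates one environment step with one gradient update on a
sampled mini-batch (after an initial collection phase), evaluates the
greedy policy periodically on complete episodes at the current
curriculum diameter, updates the curriculum from the measured success
rate, and stops once the curriculum diameter falls below its stopping
value or a hard step cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curriculum import CurriculumState, update_curriculum
from .environment import ReachEnv
from .nets import MLP, Adam

LOG_STD_MIN, LOG_STD_MAX = -20.0, 2.0
_TANH_EPS = 1e-6

__all__ = [
    "SACConfig",
    "PolicySpec",
    "ReplayBuffer",
    "SACAgent",
    "greedy_action",
    "evaluate_policy",
    "sac_train",
    "save_policy",
    "load_policy",
]


@dataclass(frozen=True)
class SACConfig:
    hidden_layers: tuple[int, ...] = (256, 256)
    discount: float = 0.99
    replay_capacity: int = 1_000_000
    batch_size: int = 256
    initial_collect_steps: int = 10_000
    updates_per_env_step: int = 1
    eval_period: int = 10_000
    eval_episodes: int = 30
    learning_rate: float = 3e-4
    target_smoothing: float = 0.005
    target_entropy: float = -7.0
    max_env_steps: int = 3_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.discount <= 1.0:
            raise ValueError("discount must lie in (0, 1]")
        if min(self.replay_capacity, self.batch_size, self.eval_period) <= 0:
            raise ValueError("capacities and periods must be positive")


@dataclass
class PolicySpec:
    """Trained actor: MLP trunk emitting per-dimension mean and log-std."""

    net: MLP
    act_dim: int = 7

    def heads(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = self.net.forward(np.atleast_2d(obs))
        mu = out[:, : self.act_dim]
        log_std = np.clip(
            out[:, self.act_dim :], LOG_STD_MIN, LOG_STD_MAX
        )
        return mu, log_std

    def sample(
        self, obs: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        mu, log_std = self.heads(obs)
        z = mu + np.exp(log_std) * rng.standard_normal(mu.shape)
        return np.tanh(z)[0] if np.ndim(obs) == 1 else np.tanh(z)


def save_policy(policy: PolicySpec, path) -> None:
    """Write actor weights to a JSON checkpoint."""
    import json

    payload = {
        "format": "reachlaw-policy-v1",
        "sizes": policy.net.sizes,
        "act_dim": policy.act_dim,
        "W": [w.tolist() for w in policy.net.W],
        "b": [b.tolist() for b in policy.net.b],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_policy(path) -> PolicySpec:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "reachlaw-policy-v1":
        raise ValueError("unrecognized policy checkpoint format")
    net = MLP.__new__(MLP)
    net.sizes = payload["sizes"]
    net.W = [np.array(w) for w in payload["W"]]
    net.b = [np.array(b) for b in payload["b"]]
    return PolicySpec(net, payload["act_dim"])


def greedy_action(policy: PolicySpec, obs: np.ndarray) -> np.ndarray:
    """Deterministic action: tanh of the Gaussian mean."""
    mu, _ = policy.heads(obs)
    a = np.tanh(mu)
    return a[0] if np.ndim(obs) == 1 else a


class ReplayBuffer:
    """Fixed-capacity FIFO transition store with uniform sampling."""

    def __init__(self, capacity: int, obs_dim: int, act_dim: int):
        self.capacity = capacity
        self.obs = np.zeros((capacity, obs_dim))
        self.act = np.zeros((capacity, act_dim))
        self.rew = np.zeros(capacity)
        self.next_obs = np.zeros((capacity, obs_dim))
        self.done = np.zeros(capacity)
        self.idx = 0
        self.size = 0

    def add(self, obs, act, rew, next_obs, done) -> None:
        i = self.idx
        self.obs[i] = obs
        self.act[i] = act
        self.rew[i] = rew
        self.next_obs[i] = next_obs
        self.done[i] = float(done)
        self.idx = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, self.size, size=batch_size)
        return (
            self.obs[idx],
            self.act[idx],
            self.rew[idx],
            self.next_obs[idx],
            self.done[idx],
        )


class SACAgent:
    """Twin-critic SAC learner over numpy MLPs."""

    def __init__(self, obs_dim: int, act_dim: int, cfg: SACConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        hid = list(cfg.hidden_layers)
        self.actor = MLP([obs_dim] + hid + [2 * act_dim], rng)
        self.q1 = MLP([obs_dim + act_dim] + hid + [1], rng)
        self.q2 = MLP([obs_dim + act_dim] + hid + [1], rng)
        self.q1_target = self.q1.copy()
        self.q2_target = self.q2.copy()
        lr = cfg.learning_rate
        self.actor_opt = Adam(self.actor.params, lr=lr)
        self.q1_opt = Adam(self.q1.params, lr=lr)
        self.q2_opt = Adam(self.q2.params, lr=lr)
        self.log_alpha = np.zeros(1)
        self.alpha_opt = Adam([self.log_alpha], lr=lr)

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha[0]))

    @property
    def policy(self) -> PolicySpec:
        return PolicySpec(self.actor, self.act_dim)

    # -- pieces shared by update() and the gradient-check tests ----------

    def _actor_forward(self, obs, zeta, cache=None):
        out = self.actor.forward(obs, cache)
        mu = out[:, : self.act_dim]
        log_std_raw = out[:, self.act_dim :]
        log_std = np.clip(log_std_raw, LOG_STD_MIN, LOG_STD_MAX)
        std = np.exp(log_std)
        z = mu + std * zeta
        a = np.tanh(z)
        log_prob = (
            -0.5 * zeta**2
            - log_std
            - 0.5 * np.log(2 * np.pi)
            - np.log(1.0 - a**2 + _TANH_EPS)
        ).sum(axis=1)
        clip_mask = (log_std_raw > LOG_STD_MIN) & (log_std_raw < LOG_STD_MAX)
        return a, log_prob, z, std, clip_mask

    def critic_targets(self, rew, next_obs, done, zeta):
        """y = r + gamma (1-d) (min_i Qt_i(s', a') - alpha log pi(a'|s'))."""
        a_next, log_prob, _, _, _ = self._actor_forward(next_obs, zeta)
        xa = np.concatenate([next_obs, a_next], axis=1)
        qt1 = self.q1_target.forward(xa)[:, 0]
        qt2 = self.q2_target.forward(xa)[:, 0]
        qt = np.minimum(qt1, qt2) - self.alpha * log_prob
        return rew + self.cfg.discount * (1.0 - done) * qt

    def critic_loss_and_grads(self, critic, obs, act, y):
        xa = np.concatenate([obs, act], axis=1)
        cache: list = []
        q = critic.forward(xa, cache)[:, 0]
        err = q - y
        loss = float(np.mean(err**2))
        dout = (2.0 * err / len(err))[:, None]
        grads, _ = critic.backward(cache, dout)
        return loss, grads, q

    def actor_loss_and_grads(self, obs, zeta):
        """L = mean(alpha log pi - min_i Q_i(s, a)) with reparametrized a."""
        cache: list = []
        a, log_prob, z, std, clip_mask = self._actor_forward(
            obs, zeta, cache
        )
        B = len(obs)
        xa = np.concatenate([obs, a], axis=1)
        c1: list = []
        c2: list = []
        q1 = self.q1.forward(xa, c1)[:, 0]
        q2 = self.q2.forward(xa, c2)[:, 0]
        use1 = q1 <= q2
        loss = float(np.mean(self.alpha * log_prob - np.minimum(q1, q2)))
        # dQmin/da through whichever critic is the minimum, per sample
        d1 = np.where(use1, 1.0, 0.0)[:, None] / B
        d2 = np.where(use1, 0.0, 1.0)[:, None] / B
        _, dx1 = self.q1.backward(c1, d1)
        _, dx2 = self.q2.backward(c2, d2)
        dq_da = (dx1 + dx2)[:, self.obs_dim :]
        one_m_a2 = 1.0 - a**2
        dlogp_dz = 2.0 * a * one_m_a2 / (one_m_a2 + _TANH_EPS)
        dL_dz = (self.alpha / B) * dlogp_dz - dq_da * one_m_a2
        dL_dmu = dL_dz
        dL_dlogstd = dL_dz * std * zeta - self.alpha / B  # (z - mu) = std*zeta
        dL_dlogstd = dL_dlogstd * clip_mask
        dout = np.concatenate([dL_dmu, dL_dlogstd], axis=1)
        grads, _ = self.actor.backward(cache, dout)
        return loss, grads, log_prob

    def update(self, batch, rng: np.random.Generator) -> dict:
        obs, act, rew, next_obs, done = batch
        B = len(obs)
        zeta_next = rng.standard_normal((B, self.act_dim))
        y = self.critic_targets(rew, next_obs, done, zeta_next)
        l1, g1, _ = self.critic_loss_and_grads(self.q1, obs, act, y)
        l2, g2, _ = self.critic_loss_and_grads(self.q2, obs, act, y)
        self.q1_opt.step(self.q1.params, g1)
        self.q2_opt.step(self.q2.params, g2)

        zeta = rng.standard_normal((B, self.act_dim))
        la, ga, log_prob = self.actor_loss_and_grads(obs, zeta)
        self.actor_opt.step(self.actor.params, ga)

        # temperature: d/dlog_alpha of -log_alpha*(log_prob + H_target)
        dlog_alpha = -float(np.mean(log_prob + self.cfg.target_entropy))
        self.alpha_opt.step([self.log_alpha], [np.array([dlog_alpha])])

        tau = self.cfg.target_smoothing
        for net, tgt in ((self.q1, self.q1_target), (self.q2, self.q2_target)):
            for p, pt in zip(net.params, tgt.params):
                pt *= 1.0 - tau
                pt += tau * p
        return {
            "critic1_loss": l1,
            "critic2_loss": l2,
            "actor_loss": la,
            "alpha": self.alpha,
            "entropy_estimate": float(-np.mean(log_prob)),
        }


def evaluate_policy(
    policy: PolicySpec,
    env: ReachEnv,
    n_episodes: int,
    diameter: float,
    collect_records: bool = False,
):
    """Greedy rollouts at a fixed target diameter (no epsilon mixing)."""
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    successes = 0
    movement_times = []
    returns = []
    records = []
    for _ in range(n_episodes):
        obs = env.reset(diameter=diameter)
        total = 0.0
        done = False
        while not done:
            obs, reward, done, info = env.step(greedy_action(policy, obs))
            total += reward
        returns.append(total)
        if info["success"]:
            successes += 1
            movement_times.append(info["movement_time"])
        if collect_records and env.record:
            records.append(env.last_record)
    success_rate = successes / n_episodes
    mean_mt = float(np.mean(movement_times)) if movement_times else float("nan")
    out = {
        "success_rate": success_rate,
        "mean_movement_time": mean_mt,
        "mean_return": float(np.mean(returns)),
    }
    return (out, records) if collect_records else (out, [])


def sac_train(
    env: ReachEnv,
    curriculum: CurriculumState,
    cfg: SACConfig,
    eval_env: ReachEnv | None = None,
    callback=None,
) -> tuple[PolicySpec, pd.DataFrame]:
    """Run the alternating sample/update loop until the curriculum stops.

    Returns the latest policy and a per-evaluation log (global step,
    losses, temperature, success rate, diameter, mean movement time).
    """
    rng = np.random.default_rng(cfg.seed)
    obs = env.reset_with_curriculum(curriculum)
    agent = SACAgent(obs.shape[0], 7, cfg, rng)
    buffer = ReplayBuffer(cfg.replay_capacity, agent.obs_dim, 7)
    eval_env = eval_env or env

    # Only successful termination is a true terminal state (no further
    # time cost); hitting the step cap is a truncation, so the critic
    # bootstraps through it.
    for _ in range(cfg.initial_collect_steps):
        a = agent.policy.sample(obs, rng)
        next_obs, r, done, info = env.step(a)
        buffer.add(obs, a, r, next_obs, info["success"])
        obs = env.reset_with_curriculum(curriculum) if done else next_obs

    log_rows = []
    diag = {}
    step = 0
    while step < cfg.max_env_steps and not curriculum.done:
        a = agent.policy.sample(obs, rng)
        next_obs, r, done, info = env.step(a)
        buffer.add(obs, a, r, next_obs, info["success"])
        obs = env.reset_with_curriculum(curriculum) if done else next_obs
        for _ in range(cfg.updates_per_env_step):
            diag = agent.update(buffer.sample(cfg.batch_size, rng), rng)
        if not np.isfinite(diag.get("critic1_loss", 0.0)):
            raise RuntimeError("training diverged: non-finite critic loss")
        step += 1
        if step % cfg.eval_period == 0:
            stats, _ = evaluate_policy(
                agent.policy, eval_env, cfg.eval_episodes, curriculum.diameter
            )
            curriculum = update_curriculum(curriculum, stats["success_rate"])
            row = {
                "global_step": step,
                "diameter_m": curriculum.diameter,
                "success_rate": stats["success_rate"],
                "mean_movement_time_s": stats["mean_movement_time"],
                "mean_return": stats["mean_return"],
                **diag,
            }
            log_rows.append(row)
            if callback is not None:
                callback(row, agent)
            # continuing episodes under a changed curriculum is fine;
            # the new diameter applies from the next reset onward
    return agent.policy, pd.DataFrame(log_rows)
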