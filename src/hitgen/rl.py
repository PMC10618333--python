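"""REINFORCE fine-tuning of the generator against the scalarized reward.

Each sampled SMILES is one episode: the tokens are the actions, the
scalar reward (shaped pIC50 and SAS combined by the current weights) is
terminal, and per-step returns follow R_t = sum_k gamma^k r_{t+k+1}.
The surrogate loss

    L = -(1/B) sum_molecules sum_t gamma^t R_t ln pi(A_t | S_t)

is minimized by gradient descent, which realizes the policy-gradient
ascent theta <- theta + alpha gamma^t R_t grad ln pi.  Invalid samples
receive zero reward on both objectives, preserving pressure toward
syntactic validity.  A moving-average baseline (optional) reduces
gradient variance without changing the expected direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .chem import canonicalize, sas_score
from .generator import SmilesGenerator
from .nn import Tensor
from .predictor import Pic50Predictor
from .rewards import PIC50_SHAPE, SAS_SHAPE, RewardShape, ScalarizationState
from .tokenizer import pad_encode, tokenize


@dataclass
class RLConfig:
    epochs: int = 90
    batch_size: int = 64
    learning_rate: float = 5e-4
    gamma: float = 1.0
    temperature: float = 0.80
    use_baseline: bool = False
    baseline_decay: float = 0.9
    pic50_shape: RewardShape = field(default_factory=lambda: PIC50_SHAPE)
    sas_shape: RewardShape = field(default_factory=lambda: SAS_SHAPE)

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class Trajectory:
    """One sampled episode: encoded actions, terminal reward, returns."""

    actions: np.ndarray          # token indices after GO, incl. EOS
    terminal_reward: float
    returns: np.ndarray          # per-step discounted returns

    def __post_init__(self):
        if len(self.actions) != len(self.returns):
            raise ValueError("actions and returns must have equal length")


def discounted_returns(rewards, gamma: float) -> np.ndarray:
    """R_t = sum_k gamma^k r_{t+k+1} computed right-to-left."""
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    rewards = np.asarray(rewards, dtype=float)
    if not np.all(np.isfinite(rewards)):
        raise ValueError("rewards must be finite")
    out = np.empty_like(rewards)
    acc = 0.0
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


def terminal_trajectory(actions: np.ndarray, reward: float,
                        gamma: float) -> Trajectory:
    """Episode with a single terminal reward spread back by discounting."""
    T = len(actions)
    rewards = np.zeros(T)
    rewards[-1] = reward
    return Trajectory(actions=np.asarray(actions),
                      terminal_reward=float(reward),
                      returns=discounted_returns(rewards, gamma))


def reinforce_loss(generator: SmilesGenerator, trajectories: list[Trajectory],
                   gamma: float = 1.0) -> Tensor:
    """Batch REINFORCE surrogate loss (differentiable through the policy)."""
    if not trajectories:
        raise ValueError("empty trajectory batch")
    B = len(trajectories)
    L = max(len(t.actions) for t in trajectories) + 1
    go = generator.vocab.go_idx
    pad = generator.vocab.pad_idx
    enc = np.full((B, L), pad, dtype=np.int64)
    weights = np.zeros((B, L - 1))
    for i, traj in enumerate(trajectories):
        T = len(traj.actions)
        enc[i, 0] = go
        enc[i, 1:T + 1] = traj.actions
        weights[i, :T] = (gamma ** np.arange(T)) * traj.returns
    log_probs = generator.step_log_probs(enc)
    return -(log_probs * Tensor(weights / B)).sum()


class CategoricalPolicy:
    """Softmax policy over ``k`` arms (single-step bandit).

    Minimal testbed for the score-function (REINFORCE) gradient: the
    policy is pi = softmax(logits) and an episode is one arm pull with
    reward r_a.
    """

    def __init__(self, k: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.logits = Tensor(rng.normal(0, 0.1, size=k), requires_grad=True)

    def probs(self) -> np.ndarray:
        with nn.no_grad():
            return nn.softmax(self.logits.reshape(1, -1)).data[0]

    def expected_reward(self, rewards) -> float:
        return float(np.dot(self.probs(), np.asarray(rewards, dtype=float)))

    def expected_policy_gradient(self, rewards) -> np.ndarray:
        """E[r * grad ln pi] computed exactly by enumerating the arms."""
        rewards = np.asarray(rewards, dtype=float)
        probs = self.probs()
        grad = np.zeros_like(self.logits.data)
        for a, (p, r) in enumerate(zip(probs, rewards)):
            self.logits.grad = None
            lp = nn.log_softmax(self.logits.reshape(1, -1))[(np.array([0]), np.array([a]))]
            lp.sum().backward()
            grad += p * r * self.logits.grad.reshape(-1)
        self.logits.grad = None
        return grad

    def train(self, rewards, steps: int = 2000, lr: float = 0.1,
              seed: int = 0) -> np.ndarray:
        """Sampled REINFORCE updates; returns the final arm probabilities."""
        rewards = np.asarray(rewards, dtype=float)
        rng = np.random.default_rng(seed)
        opt = nn.Adam([self.logits], lr=lr)
        for _ in range(steps):
            probs = self.probs()
            a = rng.choice(len(rewards), p=probs)
            lp = nn.log_softmax(self.logits.reshape(1, -1))[(np.array([0]), np.array([a]))]
            loss = -(lp.sum() * rewards[a])
            opt.zero_grad()
            loss.backward()
            opt.step()
        return self.probs()


@dataclass
class EpochReport:
    epoch: int
    validity: float
    mean_reward: float
    mean_r_pic50: float
    mean_r_sas: float
    mean_pic50: float
    mean_sas: float
    w1: float
    w2: float


def _score_batch(smiles: list[str], predictor: Pic50Predictor,
                 config: RLConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shaped rewards (r1=pIC50, r2=SAS) per molecule; invalid get 0/0."""
    n = len(smiles)
    r1 = np.zeros(n)
    r2 = np.zeros(n)
    pic50 = np.full(n, np.nan)
    sas = np.full(n, np.nan)
    valid_idx = []
    valid_smiles = []
    for i, s in enumerate(smiles):
        if not s:
            continue
        rec = canonicalize(s)
        if rec.valid:
            valid_idx.append(i)
            valid_smiles.append(rec.smiles_canonical)
    if valid_idx:
        preds, flags = predictor.predict(valid_smiles)
        for j, i in enumerate(valid_idx):
            if not flags[j]:
                continue
            p = float(preds[j])
            s_val = sas_score(valid_smiles[j])
            pic50[i] = p
            sas[i] = s_val
            r1[i] = config.pic50_shape(p)
            r2[i] = config.sas_shape(s_val)
    return r1, r2, pic50, sas


class ReinforceOptimizer:
    """Drives the sample -> score -> adapt-weights -> update loop."""

    def __init__(self, generator: SmilesGenerator, predictor: Pic50Predictor,
                 state: ScalarizationState | None = None,
                 config: RLConfig | None = None):
        self.generator = generator
        self.predictor = predictor
        self.state = state or ScalarizationState()
        self.config = config or RLConfig()
        self._opt = nn.Adam(generator.parameters(),
                            lr=self.config.learning_rate, clip_norm=5.0)
        self._baseline = 0.0
        self._baseline_initialized = False

    def rl_epoch(self, epoch: int, seed: int = 0) -> EpochReport:
        """One batch of sampling, reward shaping, weight update, gradient step."""
        cfg = self.config
        gen = self.generator
        smiles = gen.sample(cfg.batch_size, temperature=cfg.temperature, seed=seed)
        r1, r2, pic50, sas = _score_batch(smiles, self.predictor, cfg)
        valid = ~np.isnan(pic50)
        # one self-adaptive weight update per batch, before the gradient step
        f1 = float(r1[valid].mean()) if valid.any() else 0.0
        f2 = float(r2[valid].mean()) if valid.any() else 0.0
        self.state.record(f1, f2)
        self.state.update_weights()
        rewards = self.state.scalarize(r1, r2)
        report = EpochReport(
            epoch=epoch,
            validity=float(valid.mean()),
            mean_reward=float(rewards.mean()),
            mean_r_pic50=f1,
            mean_r_sas=f2,
            mean_pic50=float(pic50[valid].mean()) if valid.any() else float("nan"),
            mean_sas=float(sas[valid].mean()) if valid.any() else float("nan"),
            w1=self.state.w1,
            w2=self.state.w2,
        )
        if not valid.any():
            return report  # nothing to learn from an all-invalid batch
        if cfg.use_baseline:
            batch_mean = float(rewards.mean())
            if not self._baseline_initialized:
                self._baseline = batch_mean
                self._baseline_initialized = True
            else:
                self._baseline = (cfg.baseline_decay * self._baseline
                                  + (1 - cfg.baseline_decay) * batch_mean)
            advantages = rewards - self._baseline
        else:
            advantages = rewards
        trajectories = []
        for s, adv in zip(smiles, advantages):
            tokens = tokenize(s, gen.vocab) if s else []
            if len(tokens) + 1 > gen.config.max_len + 1:
                continue
            actions = [gen.vocab.index_of.get(t, gen.vocab.unk_idx) for t in tokens]
            actions.append(gen.vocab.eos_idx)
            trajectories.append(terminal_trajectory(np.asarray(actions), adv,
                                                    cfg.gamma))
        if not trajectories:
            return report
        loss = reinforce_loss(gen, trajectories, gamma=cfg.gamma)
        self._opt.zero_grad()
        loss.backward()
        self._opt.step()
        return report

    def run(self, epochs: int | None = None, seed: int = 0,
            verbose: bool = False) -> pd.DataFrame:
        """Loop rl_epoch; returns the per-epoch log as a DataFrame."""
        epochs = self.config.epochs if epochs is None else epochs
        rows = []
        for epoch in range(epochs):
            rep = self.rl_epoch(epoch + 1, seed=seed * 100003 + epoch)
            rows.append(rep.__dict__)
            if verbose:
                print(f"epoch {rep.epoch}: reward {rep.mean_reward:.3f} "
                      f"validity {rep.validity:.2f} w=({rep.w1:.2f},{rep.w2:.2f})")
        return pd.DataFrame(rows)


def run_optimization(generator: SmilesGenerator, predictor: Pic50Predictor,
                     config: RLConfig | None = None,
                     state: ScalarizationState | None = None,
                     seed: int = 0, verbose: bool = False
                     ) -> tuple[SmilesGenerator, pd.DataFrame]:
    """Clone the generator, bias it by REINFORCE, return (biased, log)."""
    biased = generator.clone()
    opt = ReinforceOptimizer(biased, predictor, state=state, config=config)
    log = opt.run(seed=seed, verbose=verbose)
    return biased, log
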