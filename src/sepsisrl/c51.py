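"""Categorical distributional Q-learning (C51) on the transition dataset.

The return distribution for each (state, action) is a categorical
distribution over 51 equally spaced atoms on a fixed support
[V_min, V_max].  The distributional Bellman backup shifts the atoms by
r + γ·z, clips to the support and redistributes mass linearly between the
two nearest atoms; the loss is the cross-entropy between the projected
target and the online network's prediction.  Terminal transitions back up
the point mass at the terminal reward (±15).

Training samples batches by weighted (multinomial, with-replacement)
experience replay: terminal death states, near-death states (non-survivor
transitions close to the time of death) and terminal surviving states are
upweighted; weights are calibrated so a default batch of 100 contains on
average one terminal survival and one terminal death record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cohort import TransitionDataset

__all__ = [
    "AgentConfig",
    "C51Net",
    "QView",
    "project",
    "td_update",
    "replay_probabilities",
    "weighted_sample",
    "train_agent",
    "q_view",
    "value_iteration",
]


@dataclass
class AgentConfig:
    state_dim: int = 41
    n_actions: int = 9
    n_atoms: int = 51
    v_min: float = -16.0
    v_max: float = 16.0
    gamma: float = 0.99
    lr: float = 5e-4
    batch_size: int = 100
    target_update: int = 1000
    n_steps: int = 8000
    hidden: tuple[int, ...] = (128, 128)
    seed: int = 0
    # replay weighting: near-death horizon and relative near-death weight
    near_death_h: int = 24
    w_neardeath_rel: float = 5.0
    weighted_replay: bool = True

    def __post_init__(self):
        if not self.v_min < self.v_max:
            raise ValueError("require v_min < v_max")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")

    @property
    def atoms(self) -> np.ndarray:
        return np.linspace(self.v_min, self.v_max, self.n_atoms)


class C51Net(nn.Module):
    """MLP from state to per-action atom log-probabilities."""

    def __init__(self, config: AgentConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        sizes = [config.state_dim, *config.hidden,
                 config.n_actions * config.n_atoms]
        self.body = nn.MLP(sizes, rng)

    def log_probs(self, states: nn.Tensor) -> nn.Tensor:
        """(B, S) -> (B, A, N) log-probabilities (softmax per action)."""
        B = states.data.shape[0]
        logits = self.body(states).reshape(
            B, self.config.n_actions, self.config.n_atoms)
        return logits.log_softmax(axis=-1)

    def probs(self, states: np.ndarray, chunk: int = 8192) -> np.ndarray:
        """Plain ndarray forward: (B, S) -> (B, A, N) probabilities.

        Evaluated in chunks so large state blocks stay memory-bounded.
        """
        states = np.atleast_2d(np.asarray(states, dtype=float))
        out = [np.exp(self.log_probs(nn.Tensor(states[i:i + chunk])).data)
               for i in range(0, states.shape[0], chunk)]
        return out[0] if len(out) == 1 else np.concatenate(out)

    def q_values(self, states: np.ndarray) -> np.ndarray:
        """(B, S) -> (B, A) expected values Σ z_i p_i."""
        return self.probs(states) @ self.config.atoms

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, config: AgentConfig) -> "C51Net":
        z = np.load(path)
        net = cls(config)
        net.load_state_dict({k: z[k] for k in z.files})
        return net

    def clone(self) -> "C51Net":
        other = C51Net(self.config)
        other.load_state_dict(self.state_dict())
        return other


@dataclass(frozen=True)
class QView:
    """Expected values, greedy action and entropies for one state."""

    q: np.ndarray         # (A,)
    probs: np.ndarray     # (A, N)
    greedy: int
    entropy: np.ndarray   # (A,) Shannon entropy in nats


def project(shifted_atoms: np.ndarray, probs: np.ndarray,
            atoms: np.ndarray) -> np.ndarray:
    """Project mass at arbitrary support points back onto the fixed atoms.

    Each shifted value is clipped to [V_min, V_max] and its probability is
    split linearly between the two nearest atoms.  Vectorized over leading
    batch dimensions; conserves total mass exactly.
    """
    shifted_atoms = np.atleast_2d(shifted_atoms)
    probs = np.atleast_2d(probs)
    v_min, v_max = atoms[0], atoms[-1]
    dz = atoms[1] - atoms[0]
    n = atoms.size
    tz = np.clip(shifted_atoms, v_min, v_max)
    b = (tz - v_min) / dz
    lo = np.floor(b).astype(int)
    hi = np.ceil(b).astype(int)
    # when b is integral lo == hi: give all mass to lo
    frac_hi = b - lo
    frac_lo = 1.0 - frac_hi
    out = np.zeros((shifted_atoms.shape[0], n))
    rows = np.repeat(np.arange(out.shape[0]), shifted_atoms.shape[1])
    np.add.at(out, (rows, lo.ravel()), (probs * frac_lo).ravel())
    np.add.at(out, (rows, np.minimum(hi, n - 1).ravel()),
              (probs * frac_hi).ravel())
    return out


def _target_distribution(batch: dict, online: C51Net, target: C51Net,
                         config: AgentConfig) -> np.ndarray:
    """Projected distributional Bellman target (no gradients).

    Double-DQN style: the online net picks argmax_a' at s', the target net
    supplies its distribution.  Terminal records use the point mass at r.
    """
    atoms = config.atoms
    B = len(batch["rewards"])
    out = np.empty((B, config.n_atoms))
    nonterm = batch["terminal_type"] == 0
    if np.any(nonterm):
        s2 = batch["next_states"][nonterm]
        p_online = online.probs(s2)
        a_star = (p_online @ atoms).argmax(axis=1)
        p_tgt = target.probs(s2)[np.arange(s2.shape[0]), a_star]
        shifted = batch["rewards"][nonterm, None] + config.gamma * atoms[None, :]
        out[nonterm] = project(shifted, p_tgt, atoms)
    if np.any(~nonterm):
        r = batch["rewards"][~nonterm, None]
        point = np.ones((r.shape[0], 1))
        out[~nonterm] = project(r, point, atoms)
    return out


def td_update(batch: dict, online: C51Net, target: C51Net,
              config: AgentConfig, opt: nn.Adam) -> float:
    """One gradient step on the cross-entropy to the projected target."""
    m = _target_distribution(batch, online, target, config)
    states = nn.Tensor(batch["states"])
    logp = online.log_probs(states)
    B = batch["states"].shape[0]
    taken = logp[np.arange(B), batch["actions"], :]  # (B, N)
    loss = -(nn.Tensor(m) * taken).sum() * (1.0 / B)
    if not np.isfinite(loss.data):
        raise RuntimeError("NaN/inf distributional TD loss")
    opt.zero_grad()
    loss.backward()
    opt.step()
    return float(loss.data)


def transition_classes(dataset: TransitionDataset, near_death_h: int = 24
                       ) -> np.ndarray:
    """0 base, 1 near-death, 2 terminal survival, 3 terminal death."""
    cls = np.zeros(len(dataset), dtype=int)
    near = ((dataset.terminal_type == 0)
            & (dataset.outcome == "nonsurvivor")
            & (dataset.time_to_event <= near_death_h))
    cls[near] = 1
    cls[dataset.terminal_type == 1] = 2
    cls[dataset.terminal_type == 2] = 3
    return cls


def replay_probabilities(dataset: TransitionDataset, config: AgentConfig
                         ) -> np.ndarray:
    """Per-transition sampling probabilities for weighted replay.

    Calibrated so that a batch of ``batch_size`` contains on average one
    terminal survival and one terminal death record; the remaining mass is
    split over near-death and base transitions with near-death records
    upweighted by ``w_neardeath_rel``.
    """
    cls = transition_classes(dataset, config.near_death_h)
    n = np.bincount(cls, minlength=4).astype(float)
    p = np.zeros(len(dataset))
    mass_terminal = 1.0 / config.batch_size
    mass = np.zeros(4)
    for c in (2, 3):
        mass[c] = mass_terminal if n[c] > 0 else 0.0
    rest = 1.0 - mass.sum()
    denom = n[0] + config.w_neardeath_rel * n[1]
    if denom > 0:
        mass[0] = rest * n[0] / denom
        mass[1] = rest * config.w_neardeath_rel * n[1] / denom
    for c in range(4):
        if n[c] > 0:
            p[cls == c] = mass[c] / n[c]
    return p / p.sum()


def weighted_sample(dataset: TransitionDataset, config: AgentConfig,
                    rng: np.random.Generator,
                    probs: np.ndarray | None = None) -> dict:
    """Draw a replay batch (multinomial, with replacement)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if probs is None:
        probs = (replay_probabilities(dataset, config)
                 if config.weighted_replay else None)
    idx = rng.choice(len(dataset), size=config.batch_size, p=probs)
    return {
        "states": dataset.states[idx],
        "actions": dataset.actions[idx],
        "rewards": dataset.rewards[idx],
        "next_states": dataset.next_states[idx],
        "terminal_type": dataset.terminal_type[idx],
    }


def train_agent(dataset: TransitionDataset, config: AgentConfig,
                net: C51Net | None = None) -> tuple[C51Net, dict]:
    """Offline C51 training loop with a hard-updated target network."""
    rng = np.random.default_rng(config.seed)
    online = net if net is not None else C51Net(config)
    target = online.clone()
    opt = nn.Adam(online.parameters(), lr=config.lr)
    probs = (replay_probabilities(dataset, config)
             if config.weighted_replay else None)
    log = {"step": [], "loss": [], "mean_q": []}
    for step in range(config.n_steps):
        batch = weighted_sample(dataset, config, rng, probs=probs)
        loss = td_update(batch, online, target, config, opt)
        if (step + 1) % config.target_update == 0:
            target = online.clone()
        if step % 200 == 0 or step == config.n_steps - 1:
            log["step"].append(step)
            log["loss"].append(loss)
            log["mean_q"].append(float(online.q_values(batch["states"]).mean()))
    return online, log


def q_view(net: C51Net, state: np.ndarray) -> QView:
    """Expected values, greedy action (ties -> lowest index), entropies."""
    p = net.probs(np.atleast_2d(state))[0]  # (A, N)
    q = p @ net.config.atoms
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    return QView(q=q, probs=p, greedy=int(q.argmax()), entropy=ent)


def value_iteration(P: np.ndarray, R: np.ndarray, terminal: np.ndarray,
                    gamma: float, tol: float = 1e-10) -> np.ndarray:
    """Tabular Q value iteration oracle for toy MDP checks.

    P: (S, A, S) transition probabilities; R: (S, A) expected rewards;
    terminal: (S,) bool — a terminal state's Q is exactly its reward (the
    episode ends there and no bootstrap target is formed), but its
    predecessors do bootstrap through it, matching how terminal records
    enter the offline dataset.  Returns Q (S, A).
    """
    S, A = R.shape
    Q = np.zeros((S, A))
    while True:
        V = Q.max(axis=1)
        Q_new = R + gamma * P @ V
        Q_new[terminal] = R[terminal]
        if np.max(np.abs(Q_new - Q)) < tol:
            return Q_new
        Q = Q_new
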