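"""Behavior cloning and the uncertainty-aware action preference score.

The behavior cloner G(s, ·) is a feed-forward classifier approximating the
average clinician policy from the observed state-action pairs.  The
preference score combines three signals:

    P(s, a) = β · softmax(Q̃(s, ·))_a + (1 − β) · G(s, a) − λ · u(s, a)

where Q̃ is the Q function of the ensembled value distributions, u is the
bootstrap model uncertainty and β ∈ [0, 1], λ ≥ 0 are user-chosen.  β = 1,
λ = 0 recovers the pure expected-value criterion; β = 0, λ = 0 the pure
behavior cloner.  The recommended action is argmax_a P(s, a) with ties
broken toward the lowest action index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cohort import TransitionDataset

__all__ = [
    "ClonerConfig",
    "ClonerModel",
    "train_cloner",
    "Recommendation",
    "preference_score",
    "recommend_trajectory",
]


@dataclass
class ClonerConfig:
    state_dim: int = 41
    n_actions: int = 9
    hidden: tuple[int, ...] = (128, 128)
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 10
    batch_size: int = 256
    seed: int = 0


class ClonerModel(nn.Module):
    """Multinomial classifier from state to clinician action probabilities."""

    def __init__(self, config: ClonerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.body = nn.MLP(
            [config.state_dim, *config.hidden, config.n_actions], rng)
        self.loss_trace: list[float] = []

    def log_proba(self, states: nn.Tensor) -> nn.Tensor:
        return self.body(states).log_softmax(axis=-1)

    def predict_proba(self, states: np.ndarray) -> np.ndarray:
        """(B, S) -> (B, A) action probabilities (a simplex per row)."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        return np.exp(self.log_proba(nn.Tensor(states)).data)

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path: str | Path, config: ClonerConfig) -> "ClonerModel":
        z = np.load(path)
        model = cls(config)
        model.load_state_dict({k: z[k] for k in z.files})
        return model


def train_cloner(dataset: TransitionDataset, config: ClonerConfig
                 ) -> tuple[ClonerModel, dict]:
    """Minimize the negative log-likelihood with weight-decay regularization."""
    model = ClonerModel(config)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay)
    X, y = dataset.states, dataset.actions
    history = {"train_nll": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logp = model.log_proba(nn.Tensor(X[idx]))
            nll = -logp[np.arange(len(idx)), y[idx]].mean()
            if not np.isfinite(nll.data):
                raise RuntimeError(f"NaN/inf cloner loss at epoch {epoch}")
            opt.zero_grad()
            nll.backward()
            opt.step()
            losses.append(float(nll.data))
        history["train_nll"].append(float(np.mean(losses)))
    model.loss_trace = history["train_nll"]
    return model, history


@dataclass(frozen=True)
class Recommendation:
    """Per-action preference scores and the components they combine."""

    P: np.ndarray            # (A,) preference scores
    action: int
    softmax_q: np.ndarray    # (A,)
    G: np.ndarray            # (A,)
    u: np.ndarray            # (A,)
    beta: float
    lam: float


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def preference_score(q_values: np.ndarray, G: np.ndarray, u: np.ndarray,
                     beta: float, lam: float) -> Recommendation:
    """Combine ensemble Q, cloner probabilities and uncertainty into P(s, ·)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    if lam < 0.0:
        raise ValueError("lambda must be >= 0")
    q_values = np.asarray(q_values, dtype=float)
    G = np.asarray(G, dtype=float)
    u = np.asarray(u, dtype=float)
    sq = _softmax(q_values)
    P = beta * sq + (1.0 - beta) * G - lam * u
    return Recommendation(P=P, action=int(P.argmax()), softmax_q=sq, G=G,
                          u=u, beta=beta, lam=lam)


def recommend_trajectory(states: np.ndarray, members, cloner: ClonerModel,
                         beta: float, lam: float,
                         uncertainty_reference: str = "ensemble_mean"
                         ) -> list[Recommendation]:
    """Hourly recommendations for a (T, 41) trajectory of assembled states."""
    from .uncertainty import ensemble_q, model_uncertainty

    states = np.atleast_2d(states)
    q = ensemble_q(members, states)            # (T, A)
    u = model_uncertainty(members, states, reference=uncertainty_reference)
    g = cloner.predict_proba(states)           # (T, A)
    return [preference_score(q[t], g[t], u[t], beta, lam)
            for t in range(states.shape[0])]
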