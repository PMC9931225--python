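"""Denoising stacked-GRU autoencoder for lab history.

Labs are drawn roughly every 12 hours and forward-filled, so the hourly
lab table is highly redundant; a recurrent representation of the history
is more informative than the carried-forward snapshot.  Three GRU layers
with decreasing widths are stacked; the final 10-dimensional hidden state
is the lab-history representation.  Training reconstructs the full
12-channel input (in standardized units) from corrupted input, with the
corruption probability ramped linearly from 0 to 50% over training;
inference always uses uncorrupted input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .physio_encoder import corrupt
from .synthetic_cohort import LAB_COLUMNS

__all__ = ["LabConfig", "LabEncoder", "train_lab_autoencoder", "encode_labs"]


@dataclass
class LabConfig:
    widths: tuple[int, ...] = (64, 32, 10)  # must be decreasing; last = rep dim
    lr: float = 3e-3
    epochs: int = 15
    batch_patients: int = 64
    max_corruption: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if list(self.widths) != sorted(self.widths, reverse=True):
            raise ValueError("stacked GRU widths must be decreasing")
        if self.widths[-1] != 10:
            raise ValueError("representation dimension is fixed at 10")


class LabEncoder(nn.Module):
    def __init__(self, config: LabConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = [12] + list(config.widths)
        self.cells = [nn.GRUCell(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.head = nn.Linear(config.widths[-1], 12, rng)
        self.in_mean = np.zeros(12)
        self.in_std = np.ones(12)
        self.loss_trace: list[float] = []

    def _run(self, x_scaled: np.ndarray) -> tuple[list[nn.Tensor], list[nn.Tensor]]:
        """(B, T, 12) scaled input -> per-hour rep tensors and reconstructions."""
        B, T, _ = x_scaled.shape
        hs = [c.init_state(B) for c in self.cells]
        reps, recons = [], []
        for t in range(T):
            inp = nn.Tensor(x_scaled[:, t, :])
            for k, cell in enumerate(self.cells):
                hs[k] = cell(inp, hs[k])
                inp = hs[k]
            reps.append(hs[-1])
            recons.append(self.head(hs[-1]))
        return reps, recons

    def encode(self, labs: np.ndarray) -> np.ndarray:
        """(T, 12) lab history -> (T, 10) representation (deterministic)."""
        labs = np.asarray(labs, dtype=float)
        if labs.ndim != 2 or labs.shape[1] != 12:
            raise ValueError("expected a (T, 12) lab history")
        xs = (labs - self.in_mean) / self.in_std
        reps, _ = self._run(xs[None])
        return np.stack([r.data[0] for r in reps])

    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        state.update(in_mean=self.in_mean, in_std=self.in_std)
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path, config: LabConfig) -> "LabEncoder":
        z = np.load(path)
        model = cls(config)
        model.load_state_dict({k: z[k] for k in z.files if k.startswith("p")})
        model.in_mean, model.in_std = z["in_mean"], z["in_std"]
        return model


def _patient_lab_arrays(labs: pd.DataFrame):
    return [
        df.sort_values("hour")[LAB_COLUMNS].to_numpy(dtype=float)
        for _, df in labs.groupby("patient_id", sort=True)
    ]


def _batch_loss(model: LabEncoder, x_corrupt: np.ndarray, target: np.ndarray,
                mask: np.ndarray) -> nn.Tensor:
    _, recons = model._run(x_corrupt)
    total = None
    for t, r in enumerate(recons):
        err = r - nn.Tensor(target[:, t, :])
        se = (err * err).sum(axis=1) * nn.Tensor(mask[:, t])
        total = se.sum() if total is None else total + se.sum()
    return total * (1.0 / (mask.sum() * 12.0))


def train_lab_autoencoder(labs: pd.DataFrame, config: LabConfig
                          ) -> tuple[LabEncoder, dict]:
    """Train with the corruption probability ramped 0 -> max over epochs."""
    if len(labs) == 0:
        raise ValueError("empty lab table")
    model = LabEncoder(config)
    arrays = _patient_lab_arrays(labs)
    rng = np.random.default_rng(config.seed)

    flat = np.concatenate(arrays)
    model.in_mean = flat.mean(axis=0)
    model.in_std = np.maximum(flat.std(axis=0), 1e-6)
    scaled = [(a - model.in_mean) / model.in_std for a in arrays]

    opt = nn.Adam(model.parameters(), lr=config.lr)
    history = {"train_loss": [], "corruption": []}
    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        p = config.max_corruption * frac
        order = rng.permutation(len(scaled))
        losses = []
        for i in range(0, len(order), config.batch_patients):
            batch = [scaled[j] for j in order[i:i + config.batch_patients]]
            B = len(batch)
            T = max(len(a) for a in batch)
            X = np.zeros((B, T, 12))
            M = np.zeros((B, T))
            for k, a in enumerate(batch):
                X[k, :len(a)] = a
                M[k, :len(a)] = 1.0
            Xc = corrupt(X, p, rng=rng) if p > 0 else X
            loss = _batch_loss(model, Xc, X, M)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf lab reconstruction loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        history["corruption"].append(p)
    model.loss_trace = history["train_loss"]
    return model, history


def encode_labs(model: LabEncoder, history: np.ndarray) -> np.ndarray:
    """Module-level convenience wrapper around :meth:`LabEncoder.encode`."""
    return model.encode(history)
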