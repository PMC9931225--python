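"""Physiology-driven denoising recurrent autoencoder.

The encoder ``g`` maps a (corrupted) patient history to a sequence of
latent cardiovascular states; the decoder ``f`` is the *fixed*,
parameter-free Windkessel pressure map (`windkessel.decode`).  Three
networks compose ``g``:

* a patient encoder: demographics -> initial cardiovascular state estimate;
* a single-layer GRU summarizing the vitals/scores history up to and
  including the current hour;
* a transition network: (previous cardiovascular state, current action,
  history summary) -> new cardiovascular state estimate.

Training minimizes the unnormalized mean squared reconstruction error of
the four observables (P_sys, P_dias, P_MAP, F) per time step, with inputs
randomly zeroed (corruption probability drawn from 10–25% per batch) so
the network cannot memorize the current observation and must integrate
history and treatments.  Latent states are parameterized as positive
softplus transforms of (baseline + learned deviation), so inferred states
always satisfy the Windkessel positivity constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .windkessel import BASELINE

__all__ = [
    "PhysioConfig",
    "PhysioEncoder",
    "corrupt",
    "train_autoencoder",
    "evaluate_mse",
]

_INPUT_COLUMNS = ["hr", "sbp", "dbp", "map", "temp", "spo2", "rr",
                  "sofa", "liver", "renal", "cns", "cardio"]
_TARGET_COLUMNS = ["sbp", "dbp", "map", "hr"]  # order matches decoder output
_DEMO_COLUMNS = ["age", "gender", "weight"]

# softplus(1) = 1.3133...; deviation 0 maps each parameter to its baseline
_SP_SHIFT = 1.0
_SP_AT_SHIFT = float(np.log1p(np.exp(_SP_SHIFT)))
_BASE = np.array([BASELINE["R"], BASELINE["C"], BASELINE["SV"],
                  60.0 / BASELINE["F"]])  # (R, C, SV, T)
_SCALES = _BASE / _SP_AT_SHIFT


def corrupt(history: np.ndarray, prob: float, seed: int | None = None,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Zero each element of `history` independently with probability `prob`."""
    if not 0.0 <= prob < 1.0:
        raise ValueError("corruption probability must be in [0, 1)")
    if prob == 0.0:
        return np.array(history, dtype=float, copy=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random(np.shape(history)) >= prob
    return np.asarray(history, dtype=float) * mask


@dataclass
class PhysioConfig:
    hidden: int = 64          # GRU hidden width
    pe_width: int = 64        # patient-encoder hidden width
    trans_width: int = 64     # transition-network hidden width
    lr: float = 3e-3
    lr_decay: float = 0.3     # lr multiplier applied after 2/3 of the epochs
    epochs: int = 45
    batch_patients: int = 64
    corruption: tuple[float, float] = (0.10, 0.25)
    val_frac: float = 0.2
    seed: int = 0


class PhysioEncoder(nn.Module):
    """Encoder g plus the fixed Windkessel decoder f."""

    def __init__(self, config: PhysioConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.patient_encoder = nn.MLP([3, config.pe_width, config.pe_width, 4], rng)
        self.gru = nn.GRUCell(12, config.hidden, rng)
        self.transition = nn.MLP(
            [4 + 9 + config.hidden, config.trans_width, config.trans_width, 4], rng)
        # input/demographic scalers, fitted by the trainer
        self.in_mean = np.zeros(12)
        self.in_std = np.ones(12)
        self.demo_mean = np.zeros(3)
        self.demo_std = np.ones(3)
        self.loss_trace: list[float] = []

    # -- core forward ------------------------------------------------------
    def _latent_sequence(self, x_scaled: nn.Tensor, actions: np.ndarray,
                         demo_scaled: nn.Tensor) -> list[nn.Tensor]:
        """Deviations -> positive (R, C, SV, T) tensors, one (B, 4) per hour."""
        B, T, _ = x_scaled.data.shape
        a_onehot = np.eye(9)[actions]  # (B, T, 9)
        h = self.gru.init_state(B)
        dev = self.patient_encoder(demo_scaled)  # initial state estimate
        params = []
        for t in range(T):
            xt = x_scaled[:, t, :]
            h = self.gru(xt, h)
            dev = self.transition(
                nn.concat([dev, nn.Tensor(a_onehot[:, t, :]), h], axis=-1))
            raw = dev + _SP_SHIFT
            params.append(raw.softplus() * nn.Tensor(_SCALES))
        return params

    @staticmethod
    def _decode(params: nn.Tensor) -> nn.Tensor:
        """Differentiable Windkessel decode: (B,4) params -> (B,4) vitals."""
        R, C, SV, T = (params[:, [i]] for i in range(4))
        x = T / (R * C)
        emx = (-1.0 * x).exp()
        denom = 1.0 - emx
        pulse = SV / C
        psys = pulse / denom
        pdias = psys * emx
        pmap = SV * R / T
        f = 60.0 / T
        return nn.concat([psys, pdias, pmap, f], axis=-1)

    def forward(self, x: np.ndarray, actions: np.ndarray, demo: np.ndarray
                ) -> tuple[list[nn.Tensor], list[nn.Tensor]]:
        """Scaled forward pass on (possibly corrupted) raw inputs.

        Returns per-hour latent parameter tensors and reconstruction
        tensors, each (B, 4).
        """
        xs = (x - self.in_mean) / self.in_std
        ds = (demo - self.demo_mean) / self.demo_std
        params = self._latent_sequence(nn.Tensor(xs), actions, nn.Tensor(ds))
        recon = [self._decode(p) for p in params]
        return params, recon

    # -- inference ---------------------------------------------------------
    def infer_states(self, vitals_scores: np.ndarray, actions: np.ndarray,
                     demographics: np.ndarray) -> np.ndarray:
        """Uncorrupted inference: (T, 12) history -> (T, 4) = (R, C, SV, T)."""
        vitals_scores = np.asarray(vitals_scores, dtype=float)
        if vitals_scores.ndim != 2 or vitals_scores.shape[1] != 12:
            raise ValueError("expected a (T, 12) vitals/scores history")
        if len(actions) != len(vitals_scores):
            raise ValueError("actions misaligned with history")
        x = vitals_scores[None]  # batch of one
        params, _ = self.forward(x, np.asarray(actions, dtype=int)[None],
                                 np.asarray(demographics, dtype=float)[None])
        return np.stack([p.data[0] for p in params])

    def reconstruct(self, vitals_scores, actions, demographics) -> np.ndarray:
        """(T, 12) history -> (T, 4) predicted (Psys, Pdias, Pmap, F)."""
        x = np.asarray(vitals_scores, dtype=float)[None]
        _, recon = self.forward(x, np.asarray(actions, dtype=int)[None],
                                np.asarray(demographics, dtype=float)[None])
        return np.stack([r.data[0] for r in recon])

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        state.update(in_mean=self.in_mean, in_std=self.in_std,
                     demo_mean=self.demo_mean, demo_std=self.demo_std,
                     hidden=np.array(self.config.hidden))
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path, config: PhysioConfig) -> "PhysioEncoder":
        z = np.load(path)
        model = cls(config)
        model.load_state_dict(
            {k: z[k] for k in z.files if k.startswith("p")})
        model.in_mean, model.in_std = z["in_mean"], z["in_std"]
        model.demo_mean, model.demo_std = z["demo_mean"], z["demo_std"]
        return model


def _patient_arrays(vitals: pd.DataFrame):
    """Split the cohort table into per-patient (inputs, targets, actions, demo)."""
    out = []
    for pid, df in vitals.groupby("patient_id", sort=True):
        df = df.sort_values("hour")
        out.append((
            pid,
            df[_INPUT_COLUMNS].to_numpy(dtype=float),
            df[_TARGET_COLUMNS].to_numpy(dtype=float),
            df["action"].to_numpy(dtype=int),
            df[_DEMO_COLUMNS].iloc[0].to_numpy(dtype=float),
        ))
    return out


def _pad_batch(items):
    """Pad variable-length patients into (B,T,·) arrays plus a mask."""
    B = len(items)
    T = max(len(x) for _, x, _, _, _ in items)
    X = np.zeros((B, T, 12))
    Y = np.zeros((B, T, 4))
    A = np.zeros((B, T), dtype=int)
    D = np.zeros((B, 3))
    M = np.zeros((B, T))
    for i, (_, x, y, a, d) in enumerate(items):
        L = len(x)
        X[i, :L] = x
        Y[i, :L] = y
        A[i, :L] = a
        D[i] = d
        M[i, :L] = 1.0
    return X, Y, A, D, M


def _masked_mse(model: PhysioEncoder, X, Y, A, D, M) -> nn.Tensor:
    """Sum over the 4 outputs of squared error, averaged per observed hour."""
    _, recon = model.forward(X, A, D)
    total = None
    for t, r in enumerate(recon):
        err = r - nn.Tensor(Y[:, t, :])
        se = (err * err).sum(axis=1) * nn.Tensor(M[:, t])
        total = se.sum() if total is None else total + se.sum()
    return total * (1.0 / M.sum())


def evaluate_mse(model: PhysioEncoder, vitals: pd.DataFrame,
                 corruption: float = 0.0, seed: int = 0) -> float:
    """Reconstruction MSE per time step at a given eval-time corruption."""
    rng = np.random.default_rng(seed)
    items = _patient_arrays(vitals)
    total, n = 0.0, 0.0
    for i in range(0, len(items), 64):
        X, Y, A, D, M = _pad_batch(items[i:i + 64])
        Xc = corrupt(X, corruption, rng=rng) if corruption > 0 else X
        loss = _masked_mse(model, Xc, Y, A, D, M)
        total += float(loss.data) * M.sum()
        n += M.sum()
    return total / n


def train_autoencoder(vitals: pd.DataFrame, config: PhysioConfig
                      ) -> tuple[PhysioEncoder, dict]:
    """Train the autoencoder on a cohort table; returns (model, history).

    History records per-epoch mean training loss and validation MSE on
    uncorrupted inputs; the train/validation split is by patient.
    """
    if len(vitals) == 0:
        raise ValueError("empty cohort")
    model = PhysioEncoder(config)
    items = _patient_arrays(vitals)
    rng = np.random.default_rng(config.seed)

    ids = np.array([it[0] for it in items])
    perm = rng.permutation(len(items))
    n_val = int(round(config.val_frac * len(items)))
    val_idx = set(perm[:n_val].tolist()) if n_val else set()
    train_items = [it for i, it in enumerate(items) if i not in val_idx]
    val_items = [it for i, it in enumerate(items) if i in val_idx]

    all_x = np.concatenate([x for _, x, _, _, _ in train_items])
    model.in_mean = all_x.mean(axis=0)
    model.in_std = np.maximum(all_x.std(axis=0), 1e-6)
    all_d = np.stack([d for _, _, _, _, d in train_items])
    model.demo_mean = all_d.mean(axis=0)
    model.demo_std = np.maximum(all_d.std(axis=0), 1e-6)

    opt = nn.Adam(model.parameters(), lr=config.lr)
    history = {"train_loss": [], "val_mse": [], "val_patient_ids":
               [it[0] for it in val_items]}
    lo, hi = config.corruption
    for epoch in range(config.epochs):
        if epoch == (2 * config.epochs) // 3:
            opt.lr *= config.lr_decay
        order = rng.permutation(len(train_items))
        losses = []
        for i in range(0, len(order), config.batch_patients):
            batch = [train_items[j] for j in order[i:i + config.batch_patients]]
            X, Y, A, D, M = _pad_batch(batch)
            p = rng.uniform(lo, hi) if hi > 0 else 0.0
            Xc = corrupt(X, p, rng=rng) if p > 0 else X
            loss = _masked_mse(model, Xc, Y, A, D, M)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf reconstruction loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if val_items:
            df_val = vitals[vitals["patient_id"].isin(
                [it[0] for it in val_items])]
            history["val_mse"].append(evaluate_mse(model, df_val))
    model.loss_trace = history["train_loss"]
    return model, history
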