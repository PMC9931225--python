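"""POMDP assembly: preprocessing, action discretization, rewards, states.

Turns hourly patient tables into a transition dataset for offline RL:

* actions — hourly fluid volume and peak norepinephrine-equivalent
  vasopressor rate, each discretized into 3 bins (0 / low / high) with
  cutoffs 500 mL and 0.15 mcg/kg/min, giving 9 joint actions with
  ``index = 3·vaso_bin + fluid_bin``;
* rewards — SOFA-based intermediate rewards plus ±15 terminal rewards
  (survival/death): for non-terminal steps
  ``r = −0.025·1[SOFA unchanged and > 0] − 0.125·(ΔSOFA)``;
* states — 41-dim vectors: demographics(3) + vitals(7) + scores(5) +
  labs(12) + cardiovascular latents(4: R, C, SV, T) + lab history
  representation(10), z-scored with moments fitted on the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FLUID_CUTOFF_ML",
    "VASO_CUTOFF_RATE",
    "ActionIndex",
    "discretize_action",
    "reward",
    "preprocess",
    "split_patients",
    "TransitionDataset",
    "assemble_states",
    "VITAL_COLUMNS",
    "SCORE_COLUMNS",
    "DEMO_COLUMNS",
    "STATE_FEATURE_NAMES",
]

FLUID_CUTOFF_ML = 500.0        # within-hour total fluid volume
VASO_CUTOFF_RATE = 0.15        # mcg/kg/min norepinephrine equivalent

DEMO_COLUMNS = ["age", "gender", "weight"]
VITAL_COLUMNS = ["hr", "sbp", "dbp", "map", "temp", "spo2", "rr"]
SCORE_COLUMNS = ["sofa", "liver", "renal", "cns", "cardio"]

from .synthetic_cohort import LAB_COLUMNS  # single source for channel order

STATE_FEATURE_NAMES = (
    DEMO_COLUMNS + VITAL_COLUMNS + SCORE_COLUMNS + LAB_COLUMNS
    + ["cv_R", "cv_C", "cv_SV", "cv_T"]
    + [f"lab_rep_{k}" for k in range(10)]
)
STATE_DIM = len(STATE_FEATURE_NAMES)
assert STATE_DIM == 41


@dataclass(frozen=True)
class ActionIndex:
    fluid_bin: int
    vaso_bin: int

    def __post_init__(self):
        if self.fluid_bin not in (0, 1, 2) or self.vaso_bin not in (0, 1, 2):
            raise ValueError("bins must be in {0, 1, 2}")

    @property
    def index(self) -> int:
        return 3 * self.vaso_bin + self.fluid_bin

    @classmethod
    def from_index(cls, index: int) -> "ActionIndex":
        if not 0 <= index <= 8:
            raise ValueError("action index must be in 0..8")
        return cls(fluid_bin=index % 3, vaso_bin=index // 3)


def _bin_dose(dose: float, cutoff: float) -> int:
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0:
        return 0
    return 1 if dose <= cutoff else 2


def discretize_action(fluid_ml_per_h: float, vaso_rate: float) -> ActionIndex:
    """Map hourly doses to the 9-way joint action."""
    return ActionIndex(
        fluid_bin=_bin_dose(fluid_ml_per_h, FLUID_CUTOFF_ML),
        vaso_bin=_bin_dose(vaso_rate, VASO_CUTOFF_RATE),
    )


def reward(sofa_t: int, sofa_next: int, terminal_type: str = "none") -> float:
    """SOFA-shaped intermediate reward with ±15 terminal rewards."""
    if terminal_type == "survival":
        return 15.0
    if terminal_type == "death":
        return -15.0
    if terminal_type != "none":
        raise ValueError(f"unknown terminal_type {terminal_type!r}")
    for v in (sofa_t, sofa_next):
        if not 0 <= v <= 24:
            raise ValueError("SOFA must be in 0..24")
    r = 0.0
    if sofa_next == sofa_t and sofa_next > 0:
        r -= 0.025
    r -= 0.125 * (sofa_next - sofa_t)
    return r


def preprocess(
    vitals: pd.DataFrame,
    labs: pd.DataFrame,
    outcomes: pd.DataFrame,
    max_missing_frac: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Filter and impute raw hourly trajectories.

    Forward-fills missing vitals and labs within each patient (last value
    carried forward); excludes patients whose pre-fill vitals missingness
    exceeds ``max_missing_frac``, patients without a recorded weight, and
    patients flagged as dying in hospital after ICU discharge.
    """
    vitals = vitals.sort_values(["patient_id", "hour"]).copy()
    labs = labs.sort_values(["patient_id", "hour"]).copy()

    missing = (
        vitals[VITAL_COLUMNS].isna().groupby(vitals["patient_id"]).mean().mean(axis=1)
    )
    no_weight = vitals.groupby("patient_id")["weight"].apply(
        lambda s: s.isna().any()
    )
    excluded_outcome = set(
        outcomes.loc[outcomes["outcome"] == "excluded_hospital_death", "patient_id"]
    )
    keep = [
        pid
        for pid in missing.index
        if missing[pid] <= max_missing_frac
        and not no_weight[pid]
        and pid not in excluded_outcome
    ]
    if not keep:
        raise ValueError("no patients remain after filtering")
    keep_set = set(keep)
    vitals = vitals[vitals["patient_id"].isin(keep_set)].copy()
    labs = labs[labs["patient_id"].isin(keep_set)].copy()
    outcomes = outcomes[outcomes["patient_id"].isin(keep_set)].copy()

    g = vitals.groupby("patient_id", sort=False)
    vitals[VITAL_COLUMNS] = g[VITAL_COLUMNS].ffill()
    # leading NaNs (no prior value to carry): fall back to column median
    vitals[VITAL_COLUMNS] = vitals[VITAL_COLUMNS].fillna(
        vitals[VITAL_COLUMNS].median()
    )
    gl = labs.groupby("patient_id", sort=False)
    labs[LAB_COLUMNS] = gl[LAB_COLUMNS].ffill()
    labs[LAB_COLUMNS] = labs[LAB_COLUMNS].fillna(labs[LAB_COLUMNS].median())
    return vitals, labs, outcomes


def split_patients(
    patient_ids, train_frac: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded patient-level train/validation split."""
    ids = np.unique(np.asarray(list(patient_ids)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_train = int(round(train_frac * len(ids)))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class TransitionDataset:
    """Flat (s, a, r, s', terminal) arrays plus bookkeeping columns.

    ``next_states`` rows for terminal transitions are zero-filled and must
    never be used as bootstrap targets (mask with ``terminal_type > 0``).
    ``terminal_type``: 0 none, 1 survival, 2 death.
    """

    states: np.ndarray        # (N, 41) z-scored
    actions: np.ndarray       # (N,) int 0..8
    rewards: np.ndarray       # (N,)
    next_states: np.ndarray   # (N, 41)
    terminal_type: np.ndarray  # (N,) int
    time_to_event: np.ndarray  # (N,) hours until death/discharge
    patient_id: np.ndarray    # (N,)
    hour: np.ndarray          # (N,)
    outcome: np.ndarray       # (N,) str per transition
    scaler_mean: np.ndarray   # (41,)
    scaler_std: np.ndarray    # (41,)
    train_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    val_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    feature_names: list = field(default_factory=lambda: list(STATE_FEATURE_NAMES))

    def __len__(self) -> int:
        return len(self.actions)

    def subset(self, mask: np.ndarray) -> "TransitionDataset":
        return TransitionDataset(
            states=self.states[mask], actions=self.actions[mask],
            rewards=self.rewards[mask], next_states=self.next_states[mask],
            terminal_type=self.terminal_type[mask],
            time_to_event=self.time_to_event[mask],
            patient_id=self.patient_id[mask], hour=self.hour[mask],
            outcome=self.outcome[mask],
            scaler_mean=self.scaler_mean, scaler_std=self.scaler_std,
            train_ids=self.train_ids, val_ids=self.val_ids,
            feature_names=self.feature_names,
        )

    def for_patients(self, ids) -> "TransitionDataset":
        return self.subset(np.isin(self.patient_id, np.asarray(list(ids))))

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            **{k: getattr(self, k) for k in (
                "states", "actions", "rewards", "next_states", "terminal_type",
                "time_to_event", "patient_id", "hour", "scaler_mean",
                "scaler_std", "train_ids", "val_ids")},
            outcome=self.outcome.astype(str),
            feature_names=np.array(self.feature_names),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TransitionDataset":
        z = np.load(path, allow_pickle=False)
        return cls(
            states=z["states"], actions=z["actions"], rewards=z["rewards"],
            next_states=z["next_states"], terminal_type=z["terminal_type"],
            time_to_event=z["time_to_event"], patient_id=z["patient_id"],
            hour=z["hour"], outcome=z["outcome"],
            scaler_mean=z["scaler_mean"], scaler_std=z["scaler_std"],
            train_ids=z["train_ids"], val_ids=z["val_ids"],
            feature_names=list(z["feature_names"]),
        )


def assemble_states(
    vitals: pd.DataFrame,
    labs: pd.DataFrame,
    outcomes: pd.DataFrame,
    physio_model,
    lab_model,
    train_frac: float = 0.8,
    seed: int = 0,
) -> TransitionDataset:
    """Build the 41-dim transition dataset from preprocessed tables.

    ``physio_model`` must expose ``infer_states(vitals_scores, actions,
    demographics) -> (T, 4)`` returning (R, C, SV, T) per hour and
    ``lab_model`` must expose ``encode(labs) -> (T, 10)``.  Feature
    scaling (z-score) is fitted on the training-split states only.
    """
    outcome_by_pid = outcomes.set_index("patient_id")["outcome"].to_dict()
    rows, next_rows, acts, rews, terms, ttes, pids, hours, outs = (
        [], [], [], [], [], [], [], [], [])

    for pid, vdf in vitals.groupby("patient_id", sort=True):
        vdf = vdf.sort_values("hour")
        ldf = labs[labs["patient_id"] == pid].sort_values("hour")
        if len(ldf) != len(vdf):
            raise ValueError(f"labs misaligned with vitals for patient {pid}")
        L = len(vdf)
        outcome = outcome_by_pid.get(pid, "survivor")
        vs = vdf[VITAL_COLUMNS + SCORE_COLUMNS].to_numpy(dtype=float)
        demo = vdf[DEMO_COLUMNS].iloc[0].to_numpy(dtype=float)
        actions = vdf["action"].to_numpy(dtype=int)
        latents = np.asarray(physio_model.infer_states(vs, actions, demo))
        lab_arr = ldf[LAB_COLUMNS].to_numpy(dtype=float)
        lab_rep = np.asarray(lab_model.encode(lab_arr))
        if latents.shape != (L, 4) or lab_rep.shape != (L, 10):
            raise ValueError("representation model output has wrong shape")
        demo_block = np.broadcast_to(demo, (L, 3))
        state_block = np.concatenate(
            [demo_block, vs, lab_arr, latents, lab_rep], axis=1)
        if state_block.shape[1] != STATE_DIM:
            raise ValueError(
                f"assembled state has dimension {state_block.shape[1]}, want {STATE_DIM}")
        if not np.all(np.isfinite(state_block)):
            raise ValueError(f"non-finite state entries for patient {pid}")

        sofa = vdf["sofa"].to_numpy(dtype=int)
        for t in range(L):
            rows.append(state_block[t])
            acts.append(actions[t])
            pids.append(pid)
            hours.append(int(vdf["hour"].iloc[t]))
            outs.append(outcome)
            ttes.append(L - 1 - t)
            if t < L - 1:
                next_rows.append(state_block[t + 1])
                rews.append(reward(sofa[t], sofa[t + 1]))
                terms.append(0)
            else:
                next_rows.append(np.zeros(STATE_DIM))
                if outcome == "nonsurvivor":
                    rews.append(reward(0, 0, "death"))
                    terms.append(2)
                else:
                    rews.append(reward(0, 0, "survival"))
                    terms.append(1)

    states = np.asarray(rows)
    next_states = np.asarray(next_rows)
    terminal_type = np.asarray(terms, dtype=int)
    patient_id = np.asarray(pids)
    train_ids, val_ids = split_patients(patient_id, train_frac, seed)

    train_mask = np.isin(patient_id, train_ids)
    mean = states[train_mask].mean(axis=0)
    std = states[train_mask].std(axis=0)
    std[std < 1e-8] = 1.0
    states = (states - mean) / std
    next_states = (next_states - mean) / std
    next_states[terminal_type > 0] = 0.0

    return TransitionDataset(
        states=states, actions=np.asarray(acts, dtype=int),
        rewards=np.asarray(rews, dtype=float), next_states=next_states,
        terminal_type=terminal_type,
        time_to_event=np.asarray(ttes, dtype=int),
        patient_id=patient_id, hour=np.asarray(hours, dtype=int),
        outcome=np.asarray(outs, dtype=object).astype(str),
        scaler_mean=mean, scaler_std=std,
        train_ids=train_ids, val_ids=val_ids,
    )
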