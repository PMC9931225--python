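"""Analysis procedures over trained agents and cohorts.

Outcome-stratified statistics versus time to death/discharge, feature
permutation importance of the Q function, Gaussian-mixture density versus
model uncertainty, and vasopressor-policy comparison curves.  All
statistics are computed from states only — the outcome and time-to-event
labels are used solely to group states, never as model input.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .cohort import TransitionDataset

__all__ = [
    "stratify_by_time_to_event",
    "mean_distribution_by_offset",
    "permutation_importance",
    "permutation_importance_ranking",
    "density_vs_uncertainty",
    "policy_comparison_report",
    "binned_vaso_curve",
]

logger = logging.getLogger(__name__)


def stratify_by_time_to_event(dataset: TransitionDataset,
                              statistic_fn: Callable[[np.ndarray], np.ndarray],
                              max_hours: int = 48) -> pd.DataFrame:
    """Group-mean curves of a per-state statistic vs hours to death/discharge.

    ``statistic_fn`` maps a (B, 41) state block to (B,) values (e.g. the
    greedy expected value, entropy, or model uncertainty).  Returns a tidy
    frame with columns (hours_to_event, outcome, mean, n).  Empty strata
    are omitted with a log entry.
    """
    rows = []
    for outcome in ("survivor", "nonsurvivor"):
        mask_o = dataset.outcome == outcome
        for h in range(max_hours + 1):
            mask = mask_o & (dataset.time_to_event == h)
            if not np.any(mask):
                logger.info("empty stratum: outcome=%s offset=%d", outcome, h)
                continue
            vals = np.asarray(statistic_fn(dataset.states[mask]))
            rows.append({"hours_to_event": h, "outcome": outcome,
                         "mean": float(np.mean(vals)), "n": int(mask.sum())})
    return pd.DataFrame(rows)


def mean_distribution_by_offset(dataset: TransitionDataset, net,
                                offsets=(48, 24, 1)) -> dict:
    """Mean per-action value distributions at given hours-to-event offsets."""
    out = {}
    for outcome in ("survivor", "nonsurvivor"):
        for h in offsets:
            mask = (dataset.outcome == outcome) & (dataset.time_to_event == h)
            if not np.any(mask):
                logger.info("empty stratum: outcome=%s offset=%d", outcome, h)
                continue
            out[(outcome, h)] = net.probs(dataset.states[mask]).mean(axis=0)
    return out


def permutation_importance(q_fn: Callable[[np.ndarray], np.ndarray],
                           states: np.ndarray, feature_index: int,
                           rng: np.random.Generator) -> float:
    """Mean |ΔQ| across states and actions after permuting one feature."""
    states = np.atleast_2d(states)
    if states.shape[0] < 2:
        raise ValueError("need at least 2 states to permute")
    if not 0 <= feature_index < states.shape[1]:
        raise ValueError("feature index out of range")
    q0 = np.asarray(q_fn(states))
    perm = states.copy()
    perm[:, feature_index] = perm[rng.permutation(states.shape[0]),
                                  feature_index]
    q1 = np.asarray(q_fn(perm))
    return float(np.mean(np.abs(q1 - q0)))


def permutation_importance_ranking(q_fn, dataset: TransitionDataset,
                                   seed: int = 0,
                                   max_patients: int | None = None
                                   ) -> pd.DataFrame:
    """Per-patient importance scores averaged over the cohort, ranked."""
    rng = np.random.default_rng(seed)
    pids = np.unique(dataset.patient_id)
    if max_patients is not None:
        pids = pids[:max_patients]
    n_feat = dataset.states.shape[1]
    scores = np.zeros(n_feat)
    counts = np.zeros(n_feat)
    for pid in pids:
        s = dataset.states[dataset.patient_id == pid]
        if s.shape[0] < 2:
            continue
        for j in range(n_feat):
            scores[j] += permutation_importance(q_fn, s, j, rng)
            counts[j] += 1
    counts[counts == 0] = 1
    df = pd.DataFrame({"feature": dataset.feature_names,
                       "importance": scores / counts})
    return df.sort_values("importance", ascending=False).reset_index(drop=True)


def density_vs_uncertainty(states: np.ndarray, uncertainties: np.ndarray,
                           n_components: int = 10,
                           percentiles=(5, 10, 25, 50, 75, 100),
                           seed: int = 0) -> pd.DataFrame:
    """Mean uncertainty of states in the low-density tail of a GMM fit.

    Fits a Gaussian mixture to the states; for each percentile p reports
    the mean of ``uncertainties`` over states whose log-likelihood falls
    below the p-th percentile.  A singular fit is retried with a stronger
    covariance ridge.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    states = np.atleast_2d(states)
    u = np.asarray(uncertainties, dtype=float)
    for reg in (1e-6, 1e-3, 1e-1):
        try:
            gmm = GaussianMixture(n_components=n_components,
                                  covariance_type="full", reg_covar=reg,
                                  random_state=seed).fit(states)
            ll = gmm.score_samples(states)
            if np.all(np.isfinite(ll)):
                break
            raise ValueError("non-finite likelihoods")
        except ValueError:
            logger.warning("GMM fit unstable at reg_covar=%g; retrying", reg)
    rows = []
    for p in percentiles:
        cut = np.percentile(ll, p)
        mask = ll <= cut
        rows.append({"percentile": p, "mean_u": float(u[mask].mean()),
                     "n": int(mask.sum())})
    return pd.DataFrame(rows)


def _vaso_given(actions: np.ndarray) -> np.ndarray:
    return np.asarray(actions) // 3 > 0


def policy_comparison_report(policies: dict[str, Callable[[np.ndarray], np.ndarray]],
                             dataset: TransitionDataset,
                             max_hours: int = 48) -> pd.DataFrame:
    """% of non-survivor states with vasopressors selected, per policy,
    binned by time to eventual death.

    Each policy maps a (B, 41) state block to (B,) action indices; the
    clinician column uses the recorded actions.  Returns a tidy frame with
    columns (hours_to_death, policy, vaso_pct, n).
    """
    rows = []
    mask_ns = dataset.outcome == "nonsurvivor"
    for h in range(max_hours + 1):
        mask = mask_ns & (dataset.time_to_event == h)
        n = int(mask.sum())
        if n == 0:
            continue
        s = dataset.states[mask]
        for name, pol in policies.items():
            acts = np.asarray(pol(s))
            rows.append({"hours_to_death": h, "policy": name,
                         "vaso_pct": 100.0 * _vaso_given(acts).mean(), "n": n})
        rows.append({"hours_to_death": h, "policy": "clinician",
                     "vaso_pct": 100.0 * _vaso_given(
                         dataset.actions[mask]).mean(), "n": n})
    return pd.DataFrame(rows)


def binned_vaso_curve(policy: Callable[[np.ndarray], np.ndarray],
                      dataset: TransitionDataset, covariate: np.ndarray,
                      n_bins: int = 8) -> pd.DataFrame:
    """% vasopressors selected per quantile bin of a per-state covariate
    (e.g. true mean pressure, SOFA, or (SV)·R)."""
    covariate = np.asarray(covariate, dtype=float)
    edges = np.quantile(covariate, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    which = np.clip(np.digitize(covariate, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not np.any(mask):
            continue
        acts = np.asarray(policy(dataset.states[mask]))
        rows.append({"bin": b, "bin_center":
                     float((edges[b] + edges[b + 1]) / 2),
                     "vaso_pct": 100.0 * _vaso_given(acts).mean(),
                     "n": int(mask.sum())})
    return pd.DataFrame(rows)
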