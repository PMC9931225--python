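"""Bootstrap-ensemble model (epistemic) uncertainty for value distributions.

An ensemble of C51 agents is trained on patient-level bootstrap resamples
of the transition dataset, each substantially smaller than the full
training set.  Model uncertainty for a state-action pair is the
Monte-Carlo estimate

    u(s, a) = (1/M) Σ_m KL( θ_m(s,a) ‖ θ̄(s,a) )

where θ_m are member value distributions and the reference θ̄ is either
the ensemble mean distribution or the distribution of a model trained on
the full dataset.  The ensemble also yields derived agents: a
patient-weighted mixture agent and a voting agent that prescribes
vasopressors only when at least p% of members agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .c51 import AgentConfig, C51Net, train_agent
from .cohort import TransitionDataset

__all__ = [
    "EnsembleMember",
    "train_ensemble",
    "model_uncertainty",
    "ensemble_probs",
    "ensemble_q",
    "voting_vaso_policy",
]

_EPS = 1e-8


@dataclass
class EnsembleMember:
    net: C51Net
    member_id: int
    seed: int
    n_patients: int  # distinct patients in the bootstrap resample


def patient_bootstrap(dataset: TransitionDataset, fraction: float,
                      rng: np.random.Generator,
                      max_retries: int = 20) -> tuple[TransitionDataset, int]:
    """Patient-level bootstrap resample covering both terminal classes.

    All of a patient's transitions travel together (transition-level
    resampling would leak trajectories across members).  Resamples missing
    a terminal class are redrawn with a warning.
    """
    ids = np.unique(dataset.patient_id)
    n_draw = max(2, int(round(fraction * len(ids))))
    for attempt in range(max_retries):
        draw = rng.choice(ids, size=n_draw, replace=True)
        uniq = np.unique(draw)
        sub = dataset.for_patients(uniq)
        if {1, 2} <= set(np.unique(sub.terminal_type[sub.terminal_type > 0])):
            return sub, len(uniq)
        warnings.warn("bootstrap resample missing a terminal class; redrawing")
    return sub, len(uniq)


def train_ensemble(dataset: TransitionDataset, n_members: int = 25,
                   fraction: float = 0.3,
                   config: AgentConfig | None = None,
                   seed: int = 0) -> list[EnsembleMember]:
    """Train ``n_members`` identical C51 agents on bootstrap resamples."""
    if n_members < 2:
        raise ValueError("need at least 2 members to estimate spread")
    if not 0.0 < fraction < 1.0:
        raise ValueError("subsample fraction must be in (0, 1)")
    config = config if config is not None else AgentConfig()
    members = []
    rng = np.random.default_rng(seed)
    for m in range(n_members):
        sub, n_patients = patient_bootstrap(dataset, fraction, rng)
        member_seed = int(rng.integers(0, 2**31 - 1))
        cfg_m = replace(config, seed=member_seed)
        net, _ = train_agent(sub, cfg_m)
        members.append(EnsembleMember(net=net, member_id=m,
                                      seed=member_seed, n_patients=n_patients))
    return members


def _member_probs(members: list[EnsembleMember], states: np.ndarray
                  ) -> np.ndarray:
    """(M, B, A, N) member distributions."""
    states = np.atleast_2d(states)
    return np.stack([m.net.probs(states) for m in members])


def ensemble_probs(members: list[EnsembleMember], states: np.ndarray,
                   patient_weighted: bool = True) -> np.ndarray:
    """Mixture distribution (B, A, N); weights ∝ n_patients if requested."""
    p = _member_probs(members, states)
    if patient_weighted:
        w = np.array([m.n_patients for m in members], dtype=float)
    else:
        w = np.ones(len(members))
    w = w / w.sum()
    return np.einsum("m,mban->ban", w, p)


def model_uncertainty(members: list[EnsembleMember], states: np.ndarray,
                      reference: str = "ensemble_mean",
                      full_model: C51Net | None = None) -> np.ndarray:
    """u(s, a) per state-action: mean KL of members from the reference.

    ``reference`` is "ensemble_mean" (unweighted mean of member
    distributions) or "full_model" (requires ``full_model``).  KL is in
    nats, with an epsilon floor on probabilities.  Returns (B, A).
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    p = _member_probs(members, states)  # (M, B, A, N)
    if reference == "ensemble_mean":
        ref = p.mean(axis=0)
    elif reference == "full_model":
        if full_model is None:
            raise ValueError("reference='full_model' requires full_model")
        ref = full_model.probs(np.atleast_2d(states))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    p = np.clip(p, _EPS, None)
    p = p / p.sum(axis=-1, keepdims=True)
    ref = np.clip(ref, _EPS, None)
    ref = ref / ref.sum(axis=-1, keepdims=True)
    kl = np.sum(p * (np.log(p) - np.log(ref[None])), axis=-1)  # (M, B, A)
    return kl.mean(axis=0)


def ensemble_q(members: list[EnsembleMember], states: np.ndarray
               ) -> np.ndarray:
    """(B, A) expected values of the patient-weighted mixture distribution."""
    atoms = members[0].net.config.atoms
    return ensemble_probs(members, states) @ atoms


def voting_vaso_policy(members: list[EnsembleMember], state: np.ndarray,
                       threshold_pct: float) -> int:
    """Prescribe a vasopressor action only on sufficient member agreement.

    If at least ``threshold_pct`` percent of members' greedy actions
    contain a vasopressor (vaso_bin > 0), return the mixture-greedy action
    among vasopressor actions; otherwise the mixture-greedy among
    vaso_bin = 0 actions.
    """
    if not 0.0 < threshold_pct <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    state = np.atleast_2d(state)
    greedy = np.array([m.net.q_values(state)[0].argmax() for m in members])
    vaso_frac = np.mean(greedy // 3 > 0)
    q_mix = ensemble_q(members, state)[0]
    actions = np.arange(q_mix.size)
    if vaso_frac * 100.0 >= threshold_pct:
        allowed = actions[actions // 3 > 0]
    else:
        allowed = actions[actions // 3 == 0]
    return int(allowed[q_mix[allowed].argmax()])
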