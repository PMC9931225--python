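"""End-to-end study runner on the synthetic cohort.

Chains the full method: cohort simulation -> preprocessing -> physiology
autoencoder -> lab autoencoder -> 41-dim transition dataset -> C51 agent
(weighted replay) -> bootstrap uncertainty ensemble.  Used by the test
suite and the reproduction script so both exercise the identical path.

Problem sizes follow the study conditions: 2000 patients over a 72-hour
horizon; the distributional agent trains for 10k batches of 100; the
uncertainty ensemble holds 5 members on 30% patient bootstraps (a
desk-scale stand-in for the 25-member production setting, which is a
config change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .c51 import AgentConfig, C51Net, train_agent
from .cohort import TransitionDataset, assemble_states, preprocess
from .lab_encoder import LabConfig, LabEncoder, train_lab_autoencoder
from .physio_encoder import PhysioConfig, PhysioEncoder, evaluate_mse, train_autoencoder
from .synthetic_cohort import SimulationConfig, SyntheticCohort, generate_cohort
from .uncertainty import EnsembleMember, train_ensemble

__all__ = ["StudyArtifacts", "run_study", "recovery_correlations",
           "corruption_mse_curve", "policy_trend_metrics"]

_INPUT_COLS = ["hr", "sbp", "dbp", "map", "temp", "spo2", "rr",
               "sofa", "liver", "renal", "cns", "cardio"]


@dataclass
class StudyArtifacts:
    cohort: SyntheticCohort
    vitals: pd.DataFrame
    labs: pd.DataFrame
    outcomes: pd.DataFrame
    physio: PhysioEncoder
    physio_history: dict
    lab_model: LabEncoder
    lab_history: dict
    dataset: TransitionDataset
    agent: C51Net
    agent_log: dict
    members: list[EnsembleMember] | None


def run_study(seed: int = 0, n_patients: int = 2000,
              with_ensemble: bool = True,
              agent_steps: int = 10_000,
              ensemble_steps: int = 2_500,
              n_members: int = 5) -> StudyArtifacts:
    """Run the full pipeline at the study conditions, seeded throughout."""
    seed = int(seed) % (2**28)
    sim_cfg = SimulationConfig(n_patients=n_patients, seed=11 + seed)
    cohort = generate_cohort(sim_cfg)
    vitals, labs, outcomes = preprocess(cohort.vitals, cohort.labs,
                                        cohort.outcomes)

    physio, physio_hist = train_autoencoder(vitals, PhysioConfig(seed=seed))
    lab_model, lab_hist = train_lab_autoencoder(
        labs, LabConfig(widths=(32, 16, 10), epochs=10, seed=seed))

    dataset = assemble_states(vitals, labs, outcomes, physio, lab_model,
                              seed=seed)
    agent_cfg = AgentConfig(n_steps=agent_steps, seed=seed)
    agent, agent_log = train_agent(dataset.for_patients(dataset.train_ids),
                                   agent_cfg)
    members = None
    if with_ensemble:
        members = train_ensemble(
            dataset.for_patients(dataset.train_ids), n_members=n_members,
            fraction=0.3,
            config=AgentConfig(n_steps=ensemble_steps, seed=seed),
            seed=seed + 1)
    return StudyArtifacts(cohort=cohort, vitals=vitals, labs=labs,
                          outcomes=outcomes, physio=physio,
                          physio_history=physio_hist, lab_model=lab_model,
                          lab_history=lab_hist, dataset=dataset, agent=agent,
                          agent_log=agent_log, members=members)


def recovery_correlations(study: StudyArtifacts) -> dict[str, float]:
    """Held-out correlation between inferred and true identifiable combos.

    Evaluated on the autoencoder's validation patients; predictions use
    uncorrupted input, truth is the generator's pre-noise hidden state.
    """
    val_ids = study.physio_history["val_patient_ids"]
    truth = study.cohort.truth
    pred_svc, true_svc, pred_svr, true_svr = [], [], [], []
    for pid in val_ids:
        df = study.vitals[study.vitals.patient_id == pid].sort_values("hour")
        lat = study.physio.infer_states(
            df[_INPUT_COLS].to_numpy(float),
            df["action"].to_numpy(int),
            df[["age", "gender", "weight"]].iloc[0].to_numpy(float))
        tt = truth[truth.patient_id == pid].sort_values("hour")
        pred_svc.append(lat[:, 2] / lat[:, 1])
        true_svc.append(tt.SV_over_C.to_numpy())
        pred_svr.append(lat[:, 2] * lat[:, 0])
        true_svr.append(tt.SV_times_R.to_numpy())
    pred_svc, true_svc = np.concatenate(pred_svc), np.concatenate(true_svc)
    pred_svr, true_svr = np.concatenate(pred_svr), np.concatenate(true_svr)
    return {
        "corr_sv_over_c": float(np.corrcoef(pred_svc, true_svc)[0, 1]),
        "corr_sv_times_r": float(np.corrcoef(pred_svr, true_svr)[0, 1]),
    }


def corruption_mse_curve(study: StudyArtifacts,
                         levels=(0.0, 0.25, 0.5), seed: int = 5
                         ) -> dict[float, float]:
    """Validation reconstruction MSE per time step vs eval-time corruption."""
    val_ids = study.physio_history["val_patient_ids"]
    val_df = study.vitals[study.vitals.patient_id.isin(val_ids)]
    return {p: evaluate_mse(study.physio, val_df, corruption=p, seed=seed)
            for p in levels}


def policy_trend_metrics(study: StudyArtifacts) -> dict[str, float]:
    """Vasopressor-policy trends of the trained greedy agent.

    * `q_gap_low_pmap`: mean (best vasopressor Q − no-treatment Q) over
      states whose true mean pressure is below 65 mmHg;
    * `vaso_pct_near` / `vaso_pct_far`: % of non-survivor states where
      the greedy action contains a vasopressor, within 6 h of death vs at
      24–48 h before death;
    * `vaso_margin_near` / `vaso_margin_far`: mean of
      (best vasopressor Q − best non-vasopressor Q) over the same groups —
      the continuous version of the preference, far less sensitive to
      argmax ties in states where actions barely matter;
    * `vaso_pct_by_pmap_bin`: greedy vasopressor % in true-MAP bins
      (<55, 55–65, 65–75 mmHg) — rises as pressure falls.
    """
    ds = study.dataset
    truth_ix = study.cohort.truth.set_index(["patient_id", "hour"]).Pmap
    pmap = np.array([truth_ix.get((p, h), np.nan)
                     for p, h in zip(ds.patient_id, ds.hour)])
    q = study.agent.q_values(ds.states)
    low = pmap < 65.0
    q_low = q[low]
    ns = ds.outcome == "nonsurvivor"
    greedy = q.argmax(axis=1)
    margin = q[:, 3:].max(axis=1) - q[:, :3].max(axis=1)
    near = ns & (ds.time_to_event < 6)
    far = ns & (ds.time_to_event >= 24) & (ds.time_to_event < 48)
    bins = [(0.0, 55.0), (55.0, 65.0), (65.0, 75.0)]
    pct_by_bin = [
        float(100.0 * (greedy[(pmap >= lo) & (pmap < hi)] // 3 > 0).mean())
        for lo, hi in bins]
    n_by_bin = [int(((pmap >= lo) & (pmap < hi)).sum()) for lo, hi in bins]
    return {
        "n_low_pmap": int(low.sum()),
        "q_no_treatment_low_pmap": float(q_low[:, 0].mean()),
        "q_best_vaso_low_pmap": float(q_low[:, 3:].max(axis=1).mean()),
        "q_gap_low_pmap": float(
            (q_low[:, 3:].max(axis=1) - q_low[:, 0]).mean()),
        "vaso_pct_near": float(100.0 * (greedy[near] // 3 > 0).mean()),
        "vaso_pct_far": float(100.0 * (greedy[far] // 3 > 0).mean()),
        "vaso_margin_near": float(margin[near].mean()),
        "vaso_margin_far": float(margin[far].mean()),
        "vaso_pct_by_pmap_bin": pct_by_bin,
        "n_by_pmap_bin": n_by_bin,
        "n_near": int(near.sum()),
        "n_far": int(far.sum()),
    }
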