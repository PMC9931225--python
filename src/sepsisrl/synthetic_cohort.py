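"""Seeded synthetic ICU cohort generator with Windkessel ground truth.

Emulates the structure of an hourly sepsis cohort: each patient carries a
hidden cardiovascular state (R, C, SV, F) whose deviations from a personal
baseline are driven by a latent severity process; observed vitals are the
Windkessel decoder output plus measurement noise; SOFA components follow
integer random walks biased by perfusion deficit and severity; labs are
drawn 12-hourly and forward-filled; vasopressors raise R (and mildly F)
within the hour and fluids raise SV; death fires through a hazard
increasing in SOFA and mean-pressure deficit, discharge when the patient
stays well.  A clinician-like behavior policy administers vasopressors
with probability increasing in SOFA.

Because the hidden state is known exactly, the cohort provides ground
truth for representation-recovery tests that a real ICU dataset cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .windkessel import BASELINE, decode_arrays

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "ground_truth_export",
    "LAB_COLUMNS",
]

LAB_COLUMNS = [
    "anion_gap", "bicarbonate", "creatinine", "chloride", "glucose",
    "hematocrit", "hemoglobin", "platelet", "potassium", "sodium",
    "bun", "wbc",
]

# (healthy mean, sd, severity coefficient) per lab channel
_LAB_MODEL = {
    "anion_gap": (10.0, 2.0, 4.0),
    "bicarbonate": (24.0, 2.0, -6.0),
    "creatinine": (1.0, 0.2, 1.5),
    "chloride": (102.0, 3.0, 2.0),
    "glucose": (110.0, 20.0, 40.0),
    "hematocrit": (38.0, 4.0, -4.0),
    "hemoglobin": (12.5, 1.5, -1.5),
    "platelet": (250.0, 60.0, -80.0),
    "potassium": (4.0, 0.4, 0.5),
    "sodium": (139.0, 3.0, 2.0),
    "bun": (18.0, 6.0, 20.0),
    "wbc": (9.0, 3.0, 8.0),
}

COHORT_COLUMNS = [
    "patient_id", "hour", "hr", "sbp", "dbp", "map", "temp", "spo2", "rr",
    "sofa", "liver", "renal", "cns", "cardio", "action",
    "age", "gender", "weight", "fluid_ml", "vaso_rate",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a sepsis-like ICU population: 2000 patients, 72-hour
    horizon, roughly 20% mortality, pressure noise 3 mmHg and heart-rate
    noise 2 bpm.
    """

    n_patients: int = 2000
    horizon_h: int = 72
    seed: int = 0

    # treatment effects, applied within the administration hour
    vaso_dR: tuple[float, float, float] = (0.0, 0.20, 0.40)   # mmHg·s/mL per bin
    vaso_dF: tuple[float, float, float] = (0.0, 3.0, 6.0)     # bpm per bin
    fluid_dSV: tuple[float, float, float] = (0.0, 4.0, 8.0)   # mL per bin
    # severity relief per mmHg of perfusion deficit removed by treatment:
    # restoring pressure in shock aids organ recovery; treatment of a
    # normotensive patient confers no benefit
    treat_relief: float = 0.02

    # observation noise SDs
    noise_pressure: float = 3.0  # mmHg, each of sbp/dbp/map
    noise_hr: float = 2.0        # bpm

    # hidden-state variability
    baseline_sd: dict = field(default_factory=lambda: {
        "R": 0.10, "C": 0.25, "SV": 10.0, "F": 6.0})
    severity_init_mean: float = 0.5
    severity_init_sd: float = 1.0
    severity_drift_mean: float = -0.05
    severity_drift_sd: float = 0.06
    severity_step_sd: float = 0.15
    severity_scale: float = 1.0   # coupling of severity into R/SV/F
    sev_coef_R: float = 0.50      # fractional R loss at full severity (vasoplegia)
    sev_coef_SV: float = 0.25     # fractional SV loss at full severity
    sev_coef_F: float = 0.20      # fractional F gain at full severity (tachycardia)
    ou_phi: float = 0.9
    ou_sd: dict = field(default_factory=lambda: {
        "R": 0.03, "C": 0.02, "SV": 0.04, "F": 0.02})

    # outcome processes
    hazard_scale: float = 1.0
    hazard_intercept: float = -6.0
    hazard_sofa: float = 0.05
    hazard_deficit: float = 0.30  # per mmHg of MAP below 65
    discharge_sofa: int = 3
    discharge_sev: float = 0.30
    discharge_hours: int = 4

    # data quirks
    missing_rate: float = 0.05        # per-cell NaN rate on vitals
    missing_weight_frac: float = 0.01
    hospital_death_frac: float = 0.02  # discharged alive, died later in hospital
    lab_period_h: int = 12

    # behavior policy logits
    policy_vaso_intercept: float = -2.4
    policy_vaso_sofa: float = 0.30
    policy_fluid_intercept: float = -1.6
    policy_fluid_sofa: float = 0.20
    policy_persistence: float = 1.0

    def __post_init__(self):
        if self.horizon_h < 2:
            raise ValueError("horizon_h must be >= 2")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for r in (self.missing_rate, self.missing_weight_frac,
                  self.hospital_death_frac):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """Generated cohort: observation tables plus the hidden truth."""

    vitals: pd.DataFrame    # COHORT_COLUMNS schema
    labs: pd.DataFrame      # patient_id, hour, 12 lab channels
    outcomes: pd.DataFrame  # patient_id, outcome
    truth: pd.DataFrame     # hidden state per patient-hour
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.vitals.to_csv(outdir / "cohort.csv", index=False)
        self.labs.to_csv(outdir / "labs.csv", index=False)
        self.outcomes.to_csv(outdir / "outcomes.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        with open(outdir / "config.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_patient(cfg: SimulationConfig, pid: int, policy=None):
    """Simulate one patient; returns (vitals rows, lab rows, truth rows, outcome)."""
    rng_phys = np.random.default_rng([cfg.seed % (2**31), pid, 0])
    rng_pol = np.random.default_rng([cfg.seed % (2**31), pid, 1])
    rng_obs = np.random.default_rng([cfg.seed % (2**31), pid, 2])

    age = float(np.clip(rng_phys.normal(65.0, 15.0), 18.0, 95.0))
    gender = int(rng_phys.random() < 0.45)
    weight = float(np.clip(rng_phys.normal(80.0, 15.0), 40.0, 150.0))
    if rng_phys.random() < cfg.missing_weight_frac:
        weight = np.nan

    base = {
        k: max(v + rng_phys.normal(0.0, cfg.baseline_sd[k]), 0.2 * v)
        for k, v in BASELINE.items()
    }
    renal_frail = int(rng_phys.random() < 0.5)

    z = rng_phys.normal(cfg.severity_init_mean, cfg.severity_init_sd)
    drift = rng_phys.normal(cfg.severity_drift_mean, cfg.severity_drift_sd)
    ou = {k: 0.0 for k in ("R", "C", "SV", "F")}
    # six SOFA components (resp & coag unreported), each 0..4
    comp = np.zeros(6, dtype=int)
    sev0 = _sigmoid(z - 1.0) * cfg.severity_scale
    comp[:] = np.minimum(4, rng_phys.poisson(2.0 * sev0, size=6))

    vit_rows, lab_rows, truth_rows = [], [], []
    prev_action = 0
    well_streak = 0
    outcome = "survivor"
    lab_vals = None

    for hour in range(cfg.horizon_h):
        sev = _sigmoid(z - 1.0) * cfg.severity_scale
        for k in ou:
            ou[k] = cfg.ou_phi * ou[k] + rng_phys.normal(0.0, cfg.ou_sd[k])
        R = base["R"] * (1.0 - cfg.sev_coef_R * sev) * np.exp(ou["R"])
        C = base["C"] * np.exp(ou["C"])
        SV = base["SV"] * (1.0 - cfg.sev_coef_SV * sev) * np.exp(ou["SV"])
        F = base["F"] * (1.0 + cfg.sev_coef_F * sev) * np.exp(ou["F"])

        # behavior policy (or override) chooses this hour's action
        sofa = int(comp.sum())
        if policy is not None:
            action = int(policy(hour, sofa))
        else:
            persist_v = cfg.policy_persistence * (prev_action // 3 > 0)
            persist_f = cfg.policy_persistence * (prev_action % 3 > 0)
            p_vaso = _sigmoid(cfg.policy_vaso_intercept
                              + cfg.policy_vaso_sofa * sofa + persist_v)
            p_fluid = _sigmoid(cfg.policy_fluid_intercept
                               + cfg.policy_fluid_sofa * sofa + persist_f)
            vaso_bin = 0
            if rng_pol.random() < p_vaso:
                vaso_bin = 2 if rng_pol.random() < _sigmoid(-1.5 + 0.25 * sofa) else 1
            fluid_bin = 0
            if rng_pol.random() < p_fluid:
                fluid_bin = 2 if rng_pol.random() < 0.35 else 1
            action = 3 * vaso_bin + fluid_bin
        vaso_bin, fluid_bin = action // 3, action % 3

        # doses consistent with the bin cutoffs (500 mL, 0.15 mcg/kg/min)
        u1, u2 = rng_pol.random(), rng_pol.random()
        fluid_ml = (0.0, 100 + 400 * u1, 500 + 1500 * u1)[fluid_bin]
        vaso_rate = (0.0, 0.01 + 0.14 * u2, 0.15 + 0.45 * u2)[vaso_bin]

        # within-hour treatment effect on the effective cardiovascular state
        R_eff = R + cfg.vaso_dR[vaso_bin]
        F_eff = F + cfg.vaso_dF[vaso_bin]
        SV_eff = SV + cfg.fluid_dSV[fluid_bin]
        T_eff = 60.0 / F_eff
        psys, pdias, pmap, _ = decode_arrays(R_eff, C, SV_eff, T_eff)
        deficit = max(0.0, 65.0 - float(pmap))
        # perfusion deficit had the patient gone untreated this hour
        pmap_untreated = SV * R * F / 60.0
        deficit_untreated = max(0.0, 65.0 - float(pmap_untreated))

        obs = {
            "hr": F_eff + rng_obs.normal(0.0, cfg.noise_hr),
            "sbp": psys + rng_obs.normal(0.0, cfg.noise_pressure),
            "dbp": pdias + rng_obs.normal(0.0, cfg.noise_pressure),
            "map": pmap + rng_obs.normal(0.0, cfg.noise_pressure),
            "temp": 36.8 + 0.8 * sev + rng_obs.normal(0.0, 0.3),
            "spo2": min(100.0, 97.0 - 4.0 * sev + rng_obs.normal(0.0, 1.0)),
            "rr": 16.0 + 6.0 * sev + rng_obs.normal(0.0, 1.5),
        }
        # inject missingness on vitals (never on hour 0, so LOCF is defined)
        if hour > 0 and cfg.missing_rate > 0:
            for k in obs:
                if rng_obs.random() < cfg.missing_rate:
                    obs[k] = np.nan

        if hour % cfg.lab_period_h == 0 or lab_vals is None:
            lab_vals = {}
            for name, (mu, sd, coef) in _LAB_MODEL.items():
                c = coef
                if name in ("creatinine", "bun") and renal_frail:
                    c = coef * 2.5
                lab_vals[name] = mu + c * sev + rng_obs.normal(0.0, sd)
        lab_rows.append({"patient_id": pid, "hour": hour, **lab_vals})

        vit_rows.append({
            "patient_id": pid, "hour": hour, **obs,
            "sofa": sofa, "liver": int(comp[0]), "renal": int(comp[1]),
            "cns": int(comp[2]), "cardio": int(comp[3]),
            "action": action, "age": age, "gender": gender, "weight": weight,
            "fluid_ml": fluid_ml, "vaso_rate": vaso_rate,
        })
        truth_rows.append({
            "patient_id": pid, "hour": hour,
            "R": float(R_eff), "C": float(C), "SV": float(SV_eff),
            "F": float(F_eff), "T": float(T_eff),
            "severity": float(sev), "renal_frail": renal_frail,
            "Psys": float(psys), "Pdias": float(pdias), "Pmap": float(pmap),
            "SV_over_C": float(SV_eff / C),
            "SV_times_R": float(SV_eff * R_eff),
            "CO": float(SV_eff * F_eff),
        })

        # terminal events (after at least 2 recorded hours)
        p_death = cfg.hazard_scale * _sigmoid(
            cfg.hazard_intercept + cfg.hazard_sofa * sofa
            + cfg.hazard_deficit * deficit)
        death_u = rng_phys.random()
        if hour >= 1 and death_u < p_death:
            outcome = "nonsurvivor"
            break
        well = sofa <= cfg.discharge_sofa and sev < cfg.discharge_sev
        well_streak = well_streak + 1 if well else 0
        if hour >= 1 and well_streak >= cfg.discharge_hours:
            break

        # severity evolution, relieved in proportion to the perfusion
        # deficit this hour's treatment removed
        relief = cfg.treat_relief * (deficit_untreated - deficit)
        z = z + drift - relief + rng_phys.normal(0.0, cfg.severity_step_sd)
        z = float(np.clip(z, -4.0, 5.0))
        # SOFA component walks: cardio tracks perfusion, others track severity
        for j in range(6):
            pressure = deficit / 25.0 if j == 3 else sev
            p_up = 0.02 + 0.28 * pressure
            p_dn = 0.15 * (1.0 - min(pressure, 1.0))
            u = rng_phys.random()
            if u < p_up:
                comp[j] = min(4, comp[j] + 1)
            elif u > 1.0 - p_dn:
                comp[j] = max(0, comp[j] - 1)
        prev_action = action

    return vit_rows, lab_rows, truth_rows, outcome


def generate_cohort(config: SimulationConfig, policy=None) -> SyntheticCohort:
    """Simulate the full cohort.

    `policy`, if given, overrides the clinician behavior policy; it is
    called as ``policy(hour, sofa) -> action index`` and enables paired
    treated-vs-control experiments (patient-level random streams are
    independent of the action sequence).
    """
    all_v, all_l, all_t, out_rows = [], [], [], []
    rng_outcome = np.random.default_rng([config.seed % (2**31), 999_999])
    for pid in range(config.n_patients):
        v, l, t, outcome = _simulate_patient(config, pid, policy=policy)
        if outcome == "survivor" and rng_outcome.random() < config.hospital_death_frac:
            outcome = "excluded_hospital_death"
        all_v.extend(v)
        all_l.extend(l)
        all_t.extend(t)
        out_rows.append({"patient_id": pid, "outcome": outcome})
    vitals = pd.DataFrame(all_v, columns=COHORT_COLUMNS)
    labs = pd.DataFrame(all_l, columns=["patient_id", "hour"] + LAB_COLUMNS)
    outcomes = pd.DataFrame(out_rows)
    truth = pd.DataFrame(all_t)
    return SyntheticCohort(vitals=vitals, labs=labs, outcomes=outcomes,
                           truth=truth, config=config)


def ground_truth_export(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-hour hidden CardioState and identifiable combinations.

    The table is hour-aligned with the vitals table; `SV_over_C` is the
    true (pre-noise) pulse pressure and `SV_times_R` equals Pmap·T.
    """
    t = cohort.truth
    if len(t) != len(cohort.vitals):
        raise AssertionError("truth misaligned with vitals")
    return t.copy()
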