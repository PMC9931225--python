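"""Shared fixtures.

The `study` fixture runs the full pipeline once per session at the study
conditions (2000 synthetic patients); it backs the end-to-end acceptance
tests.  Small fixtures build tiny cohorts/datasets for unit tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sepsisrl.cohort import TransitionDataset, preprocess

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")
from sepsisrl.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def study():
    from sepsisrl.pipeline import run_study

    return run_study(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient cohort for cheap integration tests."""
    return generate_cohort(SimulationConfig(n_patients=200, seed=42))


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return preprocess(small_cohort.vitals, small_cohort.labs,
                      small_cohort.outcomes)


def make_transition_dataset(n: int, n_death: int, n_survive: int,
                            state_dim: int = 8, seed: int = 0,
                            near_death: int = 0) -> TransitionDataset:
    """Synthetic flat transition dataset with prescribed terminal counts."""
    rng = np.random.default_rng(seed)
    states = rng.normal(size=(n, state_dim))
    terminal = np.zeros(n, dtype=int)
    terminal[:n_death] = 2
    terminal[n_death:n_death + n_survive] = 1
    outcome = np.array(["survivor"] * n, dtype=object)
    outcome[:n_death] = "nonsurvivor"
    tte = rng.integers(0, 72, size=n)
    if near_death:
        sl = slice(n_death + n_survive, n_death + n_survive + near_death)
        outcome[sl] = "nonsurvivor"
        tte[sl] = rng.integers(0, 24, size=near_death)
    nxt = rng.normal(size=(n, state_dim))
    nxt[terminal > 0] = 0.0
    return TransitionDataset(
        states=states, actions=rng.integers(0, 9, size=n),
        rewards=np.where(terminal == 2, -15.0,
                         np.where(terminal == 1, 15.0,
                                  rng.uniform(-1, 1, size=n))),
        next_states=nxt, terminal_type=terminal,
        time_to_event=tte.astype(int),
        patient_id=np.arange(n) // 10, hour=np.arange(n) % 10,
        outcome=outcome.astype(str),
        scaler_mean=np.zeros(state_dim), scaler_std=np.ones(state_dim),
        feature_names=[f"f{i}" for i in range(state_dim)])
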