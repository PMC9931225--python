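"""Action discretization, rewards, preprocessing and state assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sepsisrl.cohort import (
    ActionIndex,
    assemble_states,
    discretize_action,
    preprocess,
    reward,
    split_patients,
)
from sepsisrl.synthetic_cohort import LAB_COLUMNS


class TestDiscretizeAction:
    @pytest.mark.parametrize("fluid,vaso,index", [
        (0.0, 0.0, 0),            # no treatment
        (500.0, 0.0, 1),          # at the fluid cutoff -> low bin
        (800.0, 0.2, 8),          # both above cutoff -> high/high
        (0.0, 0.15, 3),           # at the vaso cutoff -> low bin
        (100.0, 0.5, 7),          # low fluid, high vaso
        (501.0, 0.0, 2),
    ])
    def test_bin_assignment(self, fluid, vaso, index):
        assert discretize_action(fluid, vaso).index == index

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            discretize_action(-1.0, 0.0)

    def test_index_convention_is_vaso_major(self):
        a = ActionIndex(fluid_bin=1, vaso_bin=2)
        assert a.index == 7
        assert ActionIndex.from_index(7) == a

    @given(st.floats(0, 5000), st.floats(0, 2))
    @settings(max_examples=100, deadline=None)
    def test_bins_partition_doses(self, fluid, vaso):
        a = discretize_action(fluid, vaso)
        assert 0 <= a.index <= 8
        assert (a.fluid_bin == 0) == (fluid == 0)
        assert (a.vaso_bin == 0) == (vaso == 0)


class TestReward:
    @pytest.mark.parametrize("sofa_t,sofa_next,terminal,expected", [
        (5, 3, "survival", 15.0),
        (20, 24, "death", -15.0),
        (10, 10, "none", -0.025),   # unchanged and positive
        (8, 10, "none", -0.25),     # worsening by 2
        (0, 0, "none", 0.0),        # healthy steady state
        (10, 7, "none", 0.375),     # improvement rewarded
    ])
    def test_values(self, sofa_t, sofa_next, terminal, expected):
        assert reward(sofa_t, sofa_next, terminal) == pytest.approx(expected)

    def test_rejects_out_of_range_sofa(self):
        with pytest.raises(ValueError):
            reward(25, 3)
        with pytest.raises(ValueError):
            reward(3, -1)

    @given(st.integers(0, 24), st.integers(0, 24))
    @settings(max_examples=200, deadline=None)
    def test_nonterminal_bound(self, a, b):
        assert abs(reward(a, b)) <= 0.125 * 24 + 0.025


def _toy_tables(lengths, missing_hours=None, weight_nan=None,
                outcomes=None):
    rows, lab_rows, out_rows = [], [], []
    for pid, L in enumerate(lengths):
        for h in range(L):
            row = dict(patient_id=pid, hour=h, hr=80.0, sbp=110.0, dbp=70.0,
                       map=85.0, temp=37.0, spo2=97.0, rr=16.0, sofa=4,
                       liver=1, renal=1, cns=1, cardio=1, action=0,
                       age=60.0, gender=1,
                       weight=np.nan if weight_nan == pid else 75.0)
            if missing_hours and (pid, h) in missing_hours:
                for k in ("hr", "sbp", "dbp", "map", "temp", "spo2", "rr"):
                    row[k] = np.nan
            rows.append(row)
            lab_rows.append({"patient_id": pid, "hour": h,
                             **{c: 1.0 for c in LAB_COLUMNS}})
        out_rows.append({"patient_id": pid,
                         "outcome": (outcomes or {}).get(pid, "survivor")})
    return (pd.DataFrame(rows), pd.DataFrame(lab_rows),
            pd.DataFrame(out_rows))


class TestPreprocess:
    def test_fully_observed_patient_unchanged(self):
        v, l, o = _toy_tables([4])
        v2, l2, o2 = preprocess(v, l, o)
        pd.testing.assert_frame_equal(
            v2.reset_index(drop=True), v.reset_index(drop=True))

    def test_drops_high_missingness_patient(self):
        missing = {(0, h) for h in range(1, 3)}  # 2 of 6 rows fully missing
        v, l, o = _toy_tables([6, 6], missing_hours=missing)
        v2, _, _ = preprocess(v, l, o)
        assert set(v2.patient_id) == {1}

    def test_drops_patient_without_weight(self):
        v, l, o = _toy_tables([4, 4], weight_nan=0)
        v2, _, _ = preprocess(v, l, o)
        assert set(v2.patient_id) == {1}

    def test_drops_post_discharge_hospital_death(self):
        v, l, o = _toy_tables([4, 4],
                              outcomes={0: "excluded_hospital_death"})
        v2, _, o2 = preprocess(v, l, o)
        assert set(v2.patient_id) == {1}
        assert set(o2.patient_id) == {1}

    def test_forward_fill_counts(self):
        v, l, o = _toy_tables([8])
        v.loc[v.hour.isin([2, 3, 4]), "sbp"] = np.nan  # 3-hour gap
        v2, _, _ = preprocess(v, l, o)
        assert (v2.sbp == 110.0).all()
        assert v2.sbp.notna().all()

    def test_empty_cohort_raises(self):
        v, l, o = _toy_tables([4], weight_nan=0)
        with pytest.raises(ValueError):
            preprocess(v, l, o)


class _IdentityPhysio:
    def infer_states(self, vs, actions, demo):
        return np.tile([1.0, 2.0, 70.0, 0.8], (len(vs), 1))


class _IdentityLab:
    def encode(self, labs):
        return np.zeros((len(labs), 10))


class TestAssembleStates:
    def test_transition_counts_and_dimension(self):
        v, l, o = _toy_tables([5, 7, 9], outcomes={1: "nonsurvivor"})
        ds = assemble_states(v, l, o, _IdentityPhysio(), _IdentityLab(),
                             train_frac=0.67, seed=0)
        assert len(ds) == 21
        assert ds.states.shape == (21, 41)
        assert (ds.terminal_type > 0).sum() == 3
        assert (ds.terminal_type == 2).sum() == 1  # the non-survivor

    def test_two_hour_trajectory_split(self):
        v, l, o = _toy_tables([2])
        ds = assemble_states(v, l, o, _IdentityPhysio(), _IdentityLab(),
                             train_frac=1.0, seed=0)
        assert len(ds) == 2
        assert list(ds.terminal_type) == [0, 1]
        assert ds.rewards[1] == 15.0

    def test_time_to_event_counts_down(self):
        v, l, o = _toy_tables([4], outcomes={0: "nonsurvivor"})
        ds = assemble_states(v, l, o, _IdentityPhysio(), _IdentityLab(),
                             train_frac=1.0, seed=0)
        assert list(ds.time_to_event) == [3, 2, 1, 0]
        assert ds.rewards[-1] == -15.0

    def test_terminal_next_states_zeroed(self):
        v, l, o = _toy_tables([3, 3])
        ds = assemble_states(v, l, o, _IdentityPhysio(), _IdentityLab(),
                             train_frac=1.0, seed=0)
        assert np.all(ds.next_states[ds.terminal_type > 0] == 0.0)

    def test_save_load_roundtrip(self, tmp_path):
        v, l, o = _toy_tables([3, 4])
        ds = assemble_states(v, l, o, _IdentityPhysio(), _IdentityLab(),
                             train_frac=0.5, seed=1)
        path = tmp_path / "ds.npz"
        ds.save(path)
        ds2 = ds.load(path)
        assert np.allclose(ds.states, ds2.states)
        assert list(ds.outcome) == list(ds2.outcome)
        assert ds.feature_names == ds2.feature_names


def test_split_patients_is_seeded_partition():
    tr1, va1 = split_patients(range(50), train_frac=0.8, seed=3)
    tr2, va2 = split_patients(range(50), train_frac=0.8, seed=3)
    assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)
    assert len(tr1) == 40 and len(va1) == 10
    assert not set(tr1) & set(va1)
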