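"""Bootstrap-ensemble uncertainty estimator and derived agents."""

import numpy as np
import pytest

from sepsisrl.c51 import AgentConfig, C51Net
from sepsisrl.uncertainty import (
    EnsembleMember,
    ensemble_probs,
    ensemble_q,
    model_uncertainty,
    patient_bootstrap,
    train_ensemble,
    voting_vaso_policy,
)
from conftest import make_transition_dataset


def _make_members(n, cfg=None, n_patients=None, seed0=0):
    cfg = cfg or AgentConfig(state_dim=4, n_actions=9, seed=0)
    members = []
    for m in range(n):
        net = C51Net(cfg, seed=seed0 + m)
        members.append(EnsembleMember(
            net=net, member_id=m, seed=seed0 + m,
            n_patients=(n_patients[m] if n_patients else 100)))
    return members


class _FixedNet:
    """Stub net returning a prescribed (A, N) distribution for any state."""

    def __init__(self, probs):
        self._p = np.asarray(probs, dtype=float)
        self.config = AgentConfig(
            state_dim=1, n_actions=self._p.shape[0],
            n_atoms=self._p.shape[1], v_min=-1.0, v_max=1.0)

    def probs(self, states):
        states = np.atleast_2d(states)
        return np.tile(self._p, (states.shape[0], 1, 1))

    def q_values(self, states):
        return self.probs(states) @ self.config.atoms


def _stub_member(probs, m=0, n_patients=100):
    return EnsembleMember(net=_FixedNet(probs), member_id=m, seed=m,
                          n_patients=n_patients)


class TestModelUncertainty:
    def test_identical_members_give_zero(self):
        p = np.tile([[0.5, 0.5, 0.0]], (1, 1))
        members = [_stub_member(p, m) for m in range(4)]
        u = model_uncertainty(members, np.zeros((2, 1)))
        assert np.allclose(u, 0.0, atol=1e-12)

    def test_hand_computed_two_member_kl(self):
        """Members (0.8, 0.2) and (0.2, 0.8) against the mean (0.5, 0.5):
        u = KL((.8,.2)||(.5,.5)) = 0.8 ln 1.6 + 0.2 ln 0.4 ~ 0.19275 nats."""
        a = _stub_member(np.array([[0.8, 0.2]]), 0)
        b = _stub_member(np.array([[0.2, 0.8]]), 1)
        u = model_uncertainty([a, b], np.zeros((1, 1)))
        expected = 0.8 * np.log(0.8 / 0.5) + 0.2 * np.log(0.2 / 0.5)
        assert u[0, 0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.19275, abs=1e-5)

    def test_nonnegative_for_random_members(self):
        members = _make_members(5)
        rng = np.random.default_rng(0)
        u = model_uncertainty(members, rng.normal(size=(10, 4)))
        assert np.all(u >= 0)

    def test_invariant_to_member_ordering(self):
        members = _make_members(5)
        states = np.random.default_rng(1).normal(size=(6, 4))
        u1 = model_uncertainty(members, states)
        u2 = model_uncertainty(members[::-1], states)
        assert np.allclose(u1, u2)

    def test_full_model_reference(self):
        members = _make_members(3)
        full = C51Net(AgentConfig(state_dim=4, n_actions=9, seed=99))
        states = np.zeros((2, 4))
        u = model_uncertainty(members, states, reference="full_model",
                              full_model=full)
        assert u.shape == (2, 9) and np.all(u >= 0)
        with pytest.raises(ValueError):
            model_uncertainty(members, states, reference="full_model")
        with pytest.raises(ValueError):
            model_uncertainty(members, states, reference="nope")

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            model_uncertainty(_make_members(1), np.zeros((1, 4)))


class TestEnsembleQ:
    def test_equal_weights_average_distributions(self):
        a = _stub_member(np.array([[1.0, 0.0]]), 0, n_patients=50)
        b = _stub_member(np.array([[0.0, 1.0]]), 1, n_patients=50)
        mix = ensemble_probs([a, b], np.zeros((1, 1)))
        assert np.allclose(mix, [[[0.5, 0.5]]])

    def test_degenerate_weight_recovers_member(self):
        a = _stub_member(np.array([[1.0, 0.0]]), 0, n_patients=100)
        b = _stub_member(np.array([[0.0, 1.0]]), 1, n_patients=0)
        mix = ensemble_probs([a, b], np.zeros((1, 1)))
        assert np.allclose(mix, [[[1.0, 0.0]]])

    def test_patient_weighted_three_atom_example(self):
        p1 = np.array([[0.5, 0.3, 0.2]])
        p2 = np.array([[0.1, 0.1, 0.8]])
        a = _stub_member(p1, 0, n_patients=600)
        b = _stub_member(p2, 1, n_patients=300)
        mix = ensemble_probs([a, b], np.zeros((1, 1)))
        assert np.allclose(mix[0, 0], (600 * p1[0] + 300 * p2[0]) / 900)
        q = ensemble_q([a, b], np.zeros((1, 1)))
        atoms = a.net.config.atoms
        assert q[0, 0] == pytest.approx(((600 * p1[0] + 300 * p2[0]) / 900)
                                        @ atoms)


class TestVotingPolicy:
    def _members_preferring(self, prefs):
        """Members whose greedy action is fixed by a spiked distribution."""
        members = []
        for m, a in enumerate(prefs):
            p = np.full((9, 3), 1.0 / 3)
            p[a] = [0.0, 0.0, 1.0]  # all mass on the top atom
            members.append(_stub_member(p, m))
        return members

    def test_unanimous_vaso_always_prescribed(self):
        members = self._members_preferring([4, 5, 6, 7])
        for p in (1, 50, 100):
            assert voting_vaso_policy(members, np.zeros(1), p) // 3 > 0

    def test_strict_threshold_single_dissenter_blocks(self):
        members = self._members_preferring([4, 4, 4, 0])
        assert voting_vaso_policy(members, np.zeros(1), 100) // 3 == 0

    def test_majority_13_of_25_passes_at_50(self):
        prefs = [4] * 13 + [0] * 12
        members = self._members_preferring(prefs)
        assert voting_vaso_policy(members, np.zeros(1), 50) // 3 > 0
        assert voting_vaso_policy(members, np.zeros(1), 53) // 3 == 0

    def test_threshold_validation(self):
        members = self._members_preferring([0, 4])
        with pytest.raises(ValueError):
            voting_vaso_policy(members, np.zeros(1), 0)
        with pytest.raises(ValueError):
            voting_vaso_policy(members, np.zeros(1), 101)


class TestTrainEnsemble:
    def test_rejects_single_member_and_bad_fraction(self):
        ds = make_transition_dataset(200, n_death=5, n_survive=20)
        with pytest.raises(ValueError):
            train_ensemble(ds, n_members=1)
        with pytest.raises(ValueError):
            train_ensemble(ds, n_members=3, fraction=1.5)

    def test_patient_bootstrap_draws_with_replacement(self):
        ds = make_transition_dataset(2000, n_death=40, n_survive=200, seed=3)
        rng = np.random.default_rng(0)
        sub, n_distinct = patient_bootstrap(ds, fraction=0.3, rng=rng)
        n_ids = len(np.unique(ds.patient_id))
        assert n_distinct <= int(round(0.3 * n_ids))
        assert n_distinct >= int(round(0.3 * n_ids)) * 0.5
        # all of a patient's transitions travel together
        for pid in np.unique(sub.patient_id):
            assert (sub.patient_id == pid).sum() == \
                (ds.patient_id == pid).sum()

    def test_trained_members_record_metadata(self):
        ds = make_transition_dataset(400, n_death=20, n_survive=40, seed=4)
        cfg = AgentConfig(state_dim=8, n_steps=30, hidden=(16,), seed=0)
        members = train_ensemble(ds, n_members=2, fraction=0.4, config=cfg,
                                 seed=7)
        assert len(members) == 2
        assert members[0].seed != members[1].seed
        assert all(m.n_patients > 0 for m in members)
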