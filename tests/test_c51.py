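"""Categorical distributional RL: projection, backups, replay, Q views."""

import numpy as np
import pytest

from sepsisrl.c51 import (
    AgentConfig,
    C51Net,
    project,
    q_view,
    replay_probabilities,
    td_update,
    train_agent,
    transition_classes,
    value_iteration,
    weighted_sample,
)
from sepsisrl import nn
from conftest import make_transition_dataset


class TestProject:
    def test_hand_example_split_between_neighbors(self):
        atoms = np.array([-1.0, 0.0, 1.0])
        out = project(np.array([[0.5, 1.5, -0.5]]),
                      np.array([[1.0, 0.0, 0.0]]), atoms)
        assert np.allclose(out, [[0.0, 0.5, 0.5]])

    def test_clipping_to_support(self):
        atoms = np.array([-1.0, 0.0, 1.0])
        # gamma=0, r=2: the point mass lands beyond Vmax and is clipped
        out = project(np.array([[2.0]]), np.array([[1.0]]), atoms)
        assert np.allclose(out, [[0.0, 0.0, 1.0]])

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        atoms = np.linspace(-16, 16, 51)
        shifted = rng.uniform(-30, 30, size=(40, 51))
        probs = rng.dirichlet(np.ones(51), size=40)
        out = project(shifted, probs, atoms)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(out >= 0)

    def test_mean_preserved_without_clipping(self):
        rng = np.random.default_rng(1)
        atoms = np.linspace(-16, 16, 51)
        dz = atoms[1] - atoms[0]
        shifted = rng.uniform(-15, 15, size=(20, 51))
        probs = rng.dirichlet(np.ones(51), size=20)
        out = project(shifted, probs, atoms)
        mean_in = (shifted * probs).sum(axis=1)
        mean_out = out @ atoms
        # linear mass splitting preserves each atom's mean contribution
        assert np.allclose(mean_in, mean_out, atol=1e-9)
        assert np.max(np.abs(mean_in - mean_out)) <= dz

    def test_atom_hit_exactly_keeps_point_mass(self):
        atoms = np.linspace(-1, 1, 3)
        out = project(np.array([[0.0]]), np.array([[1.0]]), atoms)
        assert np.allclose(out, [[0.0, 1.0, 0.0]])


def _toy_mdp():
    """5 states: 0 -> 1 -> 2; at 2, action 0 leads to terminal survival
    (+15), action 1 to terminal death (-15)."""
    S, A = 5, 2
    P = np.zeros((S, A, S))
    R = np.zeros((S, A))
    for s in (0, 1):
        P[s, :, s + 1] = 1.0
        R[s, 0], R[s, 1] = 0.1, -0.3
    P[2, 0, 3] = 1.0
    P[2, 1, 4] = 1.0
    R[2, 0], R[2, 1] = 0.1, -0.3
    R[3, :] = 15.0
    R[4, :] = -15.0
    terminal = np.array([False, False, False, True, True])
    return P, R, terminal


def _chain_dataset(n_visits=200):
    P, R, terminal = _toy_mdp()
    eye = np.eye(5)
    states, actions, rewards, nexts, terms = [], [], [], [], []
    for _ in range(n_visits):
        for s in range(5):
            for a in range(2):
                states.append(eye[s])
                actions.append(a)
                if terminal[s]:
                    rewards.append(R[s, a])
                    nexts.append(np.zeros(5))
                    terms.append(1 if R[s, a] > 0 else 2)
                else:
                    rewards.append(R[s, a])
                    nexts.append(eye[P[s, a].argmax()])
                    terms.append(0)
    n = len(states)
    from sepsisrl.cohort import TransitionDataset

    return TransitionDataset(
        states=np.array(states), actions=np.array(actions),
        rewards=np.array(rewards), next_states=np.array(nexts),
        terminal_type=np.array(terms),
        time_to_event=np.zeros(n, dtype=int),
        patient_id=np.zeros(n, dtype=int), hour=np.zeros(n, dtype=int),
        outcome=np.array(["survivor"] * n),
        scaler_mean=np.zeros(5), scaler_std=np.ones(5))


class TestTdUpdate:
    def test_terminal_death_target_is_projected_point_mass(self):
        cfg = AgentConfig(state_dim=3, n_actions=2, seed=0)
        from sepsisrl.c51 import _target_distribution

        batch = {
            "states": np.zeros((1, 3)), "actions": np.array([0]),
            "rewards": np.array([-15.0]), "next_states": np.zeros((1, 3)),
            "terminal_type": np.array([2]),
        }
        net = C51Net(cfg)
        m = _target_distribution(batch, net, net, cfg)
        atoms = cfg.atoms
        # -15 falls between atoms: mass split between the two neighbors
        assert m[0].sum() == pytest.approx(1.0, abs=1e-12)
        assert m[0] @ atoms == pytest.approx(-15.0, abs=1e-9)
        assert (m[0] > 0).sum() <= 2

    def test_repeated_updates_on_fixed_batch_reduce_loss(self):
        cfg = AgentConfig(state_dim=4, n_actions=3, seed=1, lr=1e-3)
        net = C51Net(cfg)
        target = net.clone()
        rng = np.random.default_rng(0)
        batch = {
            "states": rng.normal(size=(16, 4)),
            "actions": rng.integers(0, 3, size=16),
            "rewards": rng.uniform(-1, 1, size=16),
            "next_states": rng.normal(size=(16, 4)),
            "terminal_type": np.zeros(16, dtype=int),
        }
        opt = nn.Adam(net.parameters(), lr=cfg.lr)
        losses = [td_update(batch, net, target, cfg, opt)
                  for _ in range(100)]
        assert losses[-1] < losses[0]

    def test_chain_backup_value(self):
        """Two-state chain: r=1 then terminal +15 at gamma=0.99 converges
        to Q(s0) = 1 + 0.99*15 = 15.85 (within the support)."""
        from sepsisrl.cohort import TransitionDataset

        eye = np.eye(2)
        n = 300
        states = np.tile(eye, (n // 2, 1))
        nexts = np.zeros_like(states)
        nexts[::2] = eye[1]
        ds = TransitionDataset(
            states=states, actions=np.zeros(n, dtype=int),
            rewards=np.where(np.arange(n) % 2 == 0, 1.0, 15.0),
            next_states=nexts,
            terminal_type=np.where(np.arange(n) % 2 == 0, 0, 1),
            time_to_event=np.zeros(n, dtype=int),
            patient_id=np.zeros(n, dtype=int), hour=np.zeros(n, dtype=int),
            outcome=np.array(["survivor"] * n),
            scaler_mean=np.zeros(2), scaler_std=np.ones(2))
        cfg = AgentConfig(state_dim=2, n_actions=1, gamma=0.99,
                          n_steps=3000, target_update=200, lr=2e-3,
                          weighted_replay=False, hidden=(32,), seed=0)
        net, _ = train_agent(ds, cfg)
        q = net.q_values(eye)
        assert q[0, 0] == pytest.approx(15.85, abs=0.1)
        assert q[1, 0] == pytest.approx(15.0, abs=0.1)


class TestToyMdpEquivalence:
    @pytest.mark.parametrize("weighted", [False, True])
    def test_converges_to_value_iteration(self, weighted):
        P, R, terminal = _toy_mdp()
        q_star = value_iteration(P, R, terminal, gamma=0.99)
        ds = _chain_dataset()
        cfg = AgentConfig(state_dim=5, n_actions=2, gamma=0.99,
                          n_steps=4000, target_update=250, lr=1e-3,
                          hidden=(64, 64), weighted_replay=weighted, seed=0)
        net, _ = train_agent(ds, cfg)
        q = net.q_values(np.eye(5))
        assert np.max(np.abs(q - q_star)) < 0.05


class TestWeightedSample:
    def test_batch_size_default_is_100(self):
        assert AgentConfig().batch_size == 100

    def test_equal_weights_reduce_to_uniform(self):
        ds = make_transition_dataset(2000, n_death=20, n_survive=100, seed=0)
        cfg = AgentConfig(state_dim=8, weighted_replay=False)
        n_batches = 1000
        # with weighting disabled, the empirical death-terminal rate matches
        # the population rate within Monte-Carlo error
        rng = np.random.default_rng(1)
        death_counts = [
            (weighted_sample(ds, cfg, rng)["terminal_type"] == 2).sum()
            for _ in range(n_batches)]
        expect = 100 * 20 / 2000
        se = np.sqrt(expect) / np.sqrt(n_batches)
        assert np.mean(death_counts) == pytest.approx(expect, abs=3 * se + 0.05)

    def test_calibrated_death_terminal_rate(self):
        ds = make_transition_dataset(10_000, n_death=40, n_survive=400,
                                     near_death=800, seed=1)
        cfg = AgentConfig(state_dim=8)
        probs = replay_probabilities(ds, cfg)
        # exact expectation: death-class mass is 1/batch_size
        assert probs[ds.terminal_type == 2].sum() == pytest.approx(0.01)
        rng = np.random.default_rng(2)
        counts = [(weighted_sample(ds, cfg, rng, probs=probs)
                   ["terminal_type"] == 2).sum() for _ in range(1000)]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.1)

    def test_near_death_upweighted_relative_to_base(self):
        ds = make_transition_dataset(10_000, n_death=40, n_survive=400,
                                     near_death=800, seed=1)
        cfg = AgentConfig(state_dim=8)
        cls = transition_classes(ds, cfg.near_death_h)
        probs = replay_probabilities(ds, cfg)
        p_near = probs[cls == 1][0]
        p_base = probs[cls == 0][0]
        assert p_near == pytest.approx(cfg.w_neardeath_rel * p_base)

    def test_empty_dataset_rejected(self):
        ds = make_transition_dataset(10, n_death=1, n_survive=1)
        cfg = AgentConfig(state_dim=8)
        with pytest.raises(ValueError):
            weighted_sample(ds.subset(np.zeros(10, dtype=bool)), cfg,
                            np.random.default_rng(0))


class TestQView:
    def test_uniform_distribution_entropy(self):
        cfg = AgentConfig(state_dim=2, n_actions=2)
        net = C51Net(cfg)
        for layer in net.body.layers:
            layer.W.data[:] = 0.0
            layer.b.data[:] = 0.0
        view = q_view(net, np.zeros(2))
        assert np.allclose(view.entropy, np.log(51), atol=1e-9)
        assert view.q == pytest.approx(0.0)  # symmetric support, uniform
        assert view.greedy == 0  # tie -> lowest index

    def test_point_mass_entropy_zero(self):
        p = np.zeros((1, 51))
        p[0, 7] = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.sum(np.where(p > 0, p * np.log(p), 0.0))
        assert ent == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AgentConfig(v_min=5.0, v_max=-5.0)
        with pytest.raises(ValueError):
            AgentConfig(gamma=0.0)
        with pytest.raises(ValueError):
            AgentConfig(batch_size=0)
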