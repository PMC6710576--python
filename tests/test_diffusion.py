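"""Threshold-contagion dynamics: seeding, synchronous updates, AUC, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patrolspread import (
    DiffusionParams,
    Trajectory,
    compute_auc,
    diffusion_step,
    exact_expected_counts,
    generate_network,
    monte_carlo_expected_counts,
    run_diffusion,
    seed_knowledge,
    star_network,
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"T": 0, "L": 0.5, "E": 0.5},
            {"T": 1, "L": 1.5, "E": 0.5},
            {"T": 1, "L": 0.5, "E": -0.1},
            {"T": 1, "L": 0.5, "E": 0.5, "n_steps": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiffusionParams(**kwargs)


class TestSeeding:
    def test_count_proportional_to_effort(self, rng):
        net = generate_network(40, "moderate", 1)
        for E, expect in [(0.25, 10), (0.05, 2), (1.0, 40), (0.0, 0)]:
            assert seed_knowledge(net, E, rng=rng).sum() == expect

    def test_half_rounds_away_from_zero(self, rng, path10):
        # E*n = 2.5 -> 3 seeds
        assert seed_knowledge(path10, 0.25, rng=rng).sum() == 3

    def test_least_connected_chosen_first(self, rng):
        net = generate_network(40, "high", 2)
        informed = seed_knowledge(net, 0.25, "least_connected", rng)
        degs = net.degree_sequence
        assert degs[informed].max() <= degs[~informed].min()

    def test_best_connected_variant(self, rng):
        net = generate_network(40, "high", 2)
        informed = seed_knowledge(net, 0.25, "best_connected", rng)
        degs = net.degree_sequence
        assert degs[informed].min() >= degs[~informed].max()

    def test_ties_broken_uniformly(self, cycle8):
        # all 8 nodes are degree-tied; 1 seed among them, E=1/8
        draws = 4000
        rng = np.random.default_rng(7)
        freq = np.zeros(8)
        for _ in range(draws):
            freq += seed_knowledge(cycle8, 1 / 8, rng=rng)
        p = freq / draws
        se = np.sqrt((1 / 8) * (7 / 8) / draws)
        assert np.all(np.abs(p - 1 / 8) < 3 * se)

    def test_unknown_strategy(self, path3, rng):
        with pytest.raises(ValueError, match="strategy"):
            seed_knowledge(path3, 0.5, "random", rng)


class TestDiffusionStep:
    def test_zero_listening_freezes(self, skewed8, rng):
        state = seed_knowledge(skewed8, 0.5, rng=rng)
        after = diffusion_step(state, skewed8, T=1, L=0.0, rng=rng)
        assert np.array_equal(after, state)

    def test_unmet_threshold_freezes(self, star10, rng):
        # one seeded leaf: the hub has 1 informed contact < T=2
        state = np.zeros(10, dtype=bool)
        state[1] = True
        after = diffusion_step(state, star10, T=2, L=1.0, rng=rng)
        assert np.array_equal(after, state)

    def test_certain_listening_floods_neighbours(self, path3, rng):
        state = np.array([True, False, False])
        after = diffusion_step(state, path3, T=1, L=1.0, rng=rng)
        # B hears from A; C's only neighbour was uninformed at step start
        assert after.tolist() == [True, True, False]

    def test_informed_stay_informed(self, skewed8):
        rng = np.random.default_rng(3)
        state = seed_knowledge(skewed8, 0.25, rng=rng)
        for _ in range(10):
            new = diffusion_step(state, skewed8, T=1, L=0.3, rng=rng)
            assert np.all(new[state])
            state = new


class TestRunDiffusion:
    def test_full_seeding_saturates_auc(self, rng):
        net = generate_network(40, "light", 3)
        traj = run_diffusion(net, DiffusionParams(T=2, L=0.3, E=1.0), rng=rng)
        assert traj.counts == (40,) * 50
        assert traj.auc == 2000

    def test_frozen_dynamics_auc(self, rng):
        net = generate_network(40, "moderate", 4)
        traj = run_diffusion(net, DiffusionParams(T=1, L=0.0, E=0.25), rng=rng)
        assert traj.counts == (10,) * 50
        assert traj.auc == 500

    def test_star_threshold_two_with_certain_listening(self):
        # two seeded leaves inform the hub at step 1; remaining leaves have a
        # single contact and can never reach the threshold
        net = star_network(5)
        params = DiffusionParams(T=2, L=1.0, E=0.4)
        oracle = exact_expected_counts(net, params, seeds=[1, 2])
        assert oracle.tolist() == [3.0] * 50
        traj = run_diffusion(net, params, rng=np.random.default_rng(0))
        assert traj.counts == (3,) * 50
        assert traj.auc == 150

    @given(
        seed=st.integers(0, 10_000),
        T=st.integers(1, 3),
        L=st.floats(0.0, 1.0),
        E=st.floats(0.0, 1.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_counts_monotone_and_auc_bounded(self, seed, T, L, E):
        net = generate_network(15, "moderate", seed % 50)
        params = DiffusionParams(T=T, L=L, E=E, n_steps=20)
        traj = run_diffusion(net, params, rng=np.random.default_rng(seed))
        counts = np.array(traj.counts)
        assert np.all(np.diff(counts) >= 0)
        assert 0 <= traj.auc <= 20 * 15

    def test_auc_maximal_when_all_seeded(self, rng):
        net = generate_network(10, "light", 1)
        full = run_diffusion(net, DiffusionParams(T=1, L=1.0, E=1.0, n_steps=10), rng=rng)
        assert full.auc == 100
        # partial seeding with frozen dynamics stays strictly below the bound
        partial = run_diffusion(net, DiffusionParams(T=1, L=0.0, E=0.9, n_steps=10), rng=rng)
        assert partial.auc == 90 < 100


class TestAuc:
    def test_all_zero(self):
        traj = Trajectory(counts=(0,) * 50, node_count=40)
        assert compute_auc(traj) == 0

    def test_saturated(self):
        traj = Trajectory(counts=(40,) * 50, node_count=40)
        assert compute_auc(traj) == 2000

    def test_direct_summation(self):
        traj = Trajectory(counts=(10, 20) + (40,) * 48, node_count=40)
        assert compute_auc(traj) == 10 + 20 + 48 * 40

    def test_invalid_trajectories_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(counts=(5, 3), node_count=40)
        with pytest.raises(ValueError):
            Trajectory(counts=(41,), node_count=40)


class TestExactOracle:
    def test_three_node_path_hand_enumeration(self, path3):
        # 4 outcome paths: P(B by 2) = 0.75, P(C by 2) = 0.25
        ex = exact_expected_counts(path3, DiffusionParams(T=1, L=0.5, E=0, n_steps=2), [0])
        assert ex == pytest.approx([1.5, 2.0], abs=1e-12)

    def test_zero_listening_constant(self, skewed8):
        ex = exact_expected_counts(skewed8, DiffusionParams(T=1, L=0.0, E=0, n_steps=5), [0, 3])
        assert ex == pytest.approx([2.0] * 5, abs=0)

    def test_certain_listening_flood_fill(self, path10):
        # deterministic flood from one end reaches node k at step k
        ex = exact_expected_counts(path10, DiffusionParams(T=1, L=1.0, E=0, n_steps=12), [0])
        assert ex == pytest.approx([min(10, k + 2) for k in range(12)], abs=1e-12)

    def test_refuses_large_networks(self):
        net = generate_network(13, "light", 0)
        with pytest.raises(ValueError, match="12 nodes"):
            exact_expected_counts(net, DiffusionParams(T=1, L=0.5, E=0), [0])

    def test_monte_carlo_agrees_with_enumeration(self, path10):
        params = DiffusionParams(T=1, L=0.5, E=0, n_steps=15)
        ex = exact_expected_counts(path10, params, [0])
        mc, se = monte_carlo_expected_counts(path10, params, [0], 20_000, rng=5)
        z = np.abs(mc - ex) / np.maximum(se, 1e-12)
        assert z.max() < 3.0


class TestPerContactVariant:
    def test_triangle_uptake_compounds_over_contacts(self):
        import networkx as nx
        from patrolspread import SocialNetwork

        tri = SocialNetwork(graph=nx.complete_graph(3))
        params = DiffusionParams(T=1, L=0.5, E=0, n_steps=1, per_contact=True)
        # node 2 has two informed contacts: P(informed) = 1-(1-0.5)^2 = 0.75
        ex = exact_expected_counts(tri, params, [0, 1])
        assert ex[0] == pytest.approx(2.75, abs=1e-12)

    def test_reduces_to_listener_rule_with_single_contacts(self, path3):
        # on a path the frontier node always has exactly one informed contact
        base = DiffusionParams(T=1, L=0.5, E=0, n_steps=3)
        per = DiffusionParams(T=1, L=0.5, E=0, n_steps=3, per_contact=True)
        a = exact_expected_counts(path3, base, [0])
        b = exact_expected_counts(path3, per, [0])
        assert a == pytest.approx(b, abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self, skewed8):
        params = DiffusionParams(T=1, L=0.3, E=0, n_steps=10, per_contact=True)
        seeds = np.argsort(skewed8.degree_sequence, kind="stable")[:2].tolist()
        ex = exact_expected_counts(skewed8, params, seeds)
        mc, se = monte_carlo_expected_counts(skewed8, params, seeds, 20_000, rng=8)
        z = np.abs(mc - ex) / np.maximum(se, 1e-12)
        assert z.max() < 3.0

    def test_spreads_at_least_as_fast_as_listener_rule(self, skewed8):
        base = DiffusionParams(T=1, L=0.3, E=0, n_steps=10)
        per = DiffusionParams(T=1, L=0.3, E=0, n_steps=10, per_contact=True)
        a = exact_expected_counts(skewed8, base, [0])
        b = exact_expected_counts(skewed8, per, [0])
        assert np.all(b >= a - 1e-12)
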