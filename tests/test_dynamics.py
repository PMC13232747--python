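"""Stochastic update process: initialization, events, splitting, full runs."""

import numpy as np
import pytest

from groupgames import (
    GroupState,
    PayoffMatrix,
    PopulationState,
    SimulationConfig,
    initialize,
    resolve_overflow,
    run,
    split_group,
    step,
)
from groupgames.dynamics import EventLog


class TestInitialize:
    def test_sizes_and_type_range(self, rng):
        cfg = SimulationConfig(d=1000, m=3, n=10)
        state = initialize(cfg, rng)
        assert state.m == 3
        assert all(g.size == 10 for g in state.groups)
        assert state.total_size == 30
        present = set().union(*(g.counts for g in state.groups))
        assert len(present) <= 30
        assert all(0 <= t < 1000 for t in present)

    def test_single_type_pool_gives_homogeneous_groups(self, rng):
        cfg = SimulationConfig(d=1, m=4, n=6)
        state = initialize(cfg, rng)
        assert all(g.counts == {0: 6} for g in state.groups)

    def test_expected_distinct_types_matches_occupancy_formula(self, rng):
        # E[distinct] = d (1 - (1 - 1/d)^(mn)) for mn uniform draws
        d, m, n, reps = 500, 6, 20, 300
        cfg = SimulationConfig(d=d, m=m, n=n)
        expected = d * (1.0 - (1.0 - 1.0 / d) ** (m * n))
        distinct = [
            len(set().union(*(g.counts for g in initialize(cfg, rng).groups)))
            for _ in range(reps)
        ]
        se = np.std(distinct, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(distinct) - expected) < 5 * se + 0.5


class TestSplitGroup:
    def test_size_four_always_splits_two_two(self, rng):
        for _ in range(50):
            a, b = split_group(GroupState({0: 2, 1: 2}), rng)
            assert a.size == 2 and b.size == 2

    def test_size_five_splits_two_three_evenly(self, rng):
        sizes = [split_group(GroupState({0: 3, 1: 2}), rng)[0].size for _ in range(4000)]
        frac_two = np.mean([s == 2 for s in sizes])
        assert set(sizes) == {2, 3}
        assert frac_two == pytest.approx(0.5, abs=0.03)

    def test_composition_conserved_exactly(self, rng):
        for _ in range(100):
            counts = {
                int(t): int(rng.integers(1, 8)) for t in rng.choice(30, 5, replace=False)
            }
            parent = GroupState(counts)
            if parent.size < 4:
                continue
            a, b = split_group(parent, rng)
            merged = dict(a.counts)
            for t, c in b.counts.items():
                merged[t] = merged.get(t, 0) + c
            assert merged == counts
            assert a.size >= 2 and b.size >= 2

    def test_homogeneous_parent_yields_homogeneous_offspring(self, rng):
        a, b = split_group(GroupState({7: 9}), rng)
        assert set(a.counts) == {7} and set(b.counts) == {7}

    def test_too_small_to_split(self, rng):
        with pytest.raises(ValueError, match="unsplittable"):
            split_group(GroupState({0: 3}), rng)


class TestResolveOverflow:
    def _overflowing_state(self, m, n, counts):
        groups = [GroupState(counts)] + [GroupState({9: n}) for _ in range(m - 1)]
        return PopulationState(groups)

    def test_cull_branch_restores_capacity(self, rng):
        cfg = SimulationConfig(d=10, m=3, n=6, q=0.0)
        state = self._overflowing_state(3, 6, {0: 7})
        resolve_overflow(state, 0, cfg, rng)
        assert state.m == 3
        assert state.groups[0].size == 6

    def test_single_group_population_never_splits(self, rng):
        cfg = SimulationConfig(d=10, m=1, n=6, q=1.0)
        state = PopulationState([GroupState({0: 4, 1: 3})])
        log = EventLog()
        resolve_overflow(state, 0, cfg, rng, log)
        assert state.m == 1 and state.groups[0].size == 6
        assert log.split == 0 and log.cull == 1

    def test_split_branch_keeps_m_groups(self, rng):
        cfg = SimulationConfig(d=10, m=4, n=6, q=1.0)
        log = EventLog()
        state = self._overflowing_state(4, 6, {0: 4, 1: 3})
        resolve_overflow(state, 0, cfg, rng, log)
        assert state.m == 4
        assert log.split == 1 and log.group_removal == 1
        # the two offspring of group 0 survive: together they hold all 7 individuals
        assert state.groups[0].size + state.groups[1].size == 7

    def test_cull_removes_uniformly(self, rng):
        # counts {0: n, 1: 1}: the singleton dies with probability 1/(n+1)
        n, trials = 9, 6000
        cfg = SimulationConfig(d=5, m=1, n=n, q=0.0)
        hits = 0
        for _ in range(trials):
            state = PopulationState([GroupState({0: n, 1: 1})])
            resolve_overflow(state, 0, cfg, rng)
            hits += 1 not in state.groups[0].counts
        p = hits / trials
        se = np.sqrt(0.1 * 0.9 / trials)
        assert abs(p - 1.0 / (n + 1)) < 4 * se

    def test_error_without_overflow(self, rng):
        cfg = SimulationConfig(d=5, m=1, n=9)
        state = PopulationState([GroupState({0: 9})])
        with pytest.raises(ValueError, match="no overflow"):
            resolve_overflow(state, 0, cfg, rng)


class TestStep:
    def test_pure_immigration(self, small_matrix, rng):
        cfg = SimulationConfig(d=4, m=2, n=8, lam=1.0, q=0.0)
        state = PopulationState([GroupState({0: 4}), GroupState({1: 4})])
        log = EventLog()
        for _ in range(200):
            step(state, small_matrix, cfg, rng, log)
        assert log.immigration == 200 and log.replication == 0

    def test_no_immigration_means_no_new_types(self, small_matrix, rng):
        cfg = SimulationConfig(d=4, m=2, n=8, lam=0.0, q=0.0)
        state = PopulationState([GroupState({0: 4}), GroupState({2: 4})])
        for _ in range(500):
            step(state, small_matrix, cfg, rng)
        present = set().union(*(g.counts for g in state.groups))
        assert present <= {0, 2}

    def test_neutral_fixation_probability_is_initial_frequency(self, small_matrix):
        """beta = 0, lam = 0, m = 1, q = 0 is a neutral Moran-like process:
        from a 3/3 split on n = 6 each type fixes with probability 1/2
        (martingale argument)."""
        cfg = SimulationConfig(d=4, m=1, n=6, beta=0.0, lam=0.0, q=0.0)
        rng = np.random.default_rng(2024)
        reps, wins = 500, 0
        for _ in range(reps):
            state = PopulationState([GroupState({0: 3, 1: 3})])
            while len(state.groups[0].counts) > 1:
                step(state, small_matrix, cfg, rng)
            wins += 0 in state.groups[0].counts
        se = np.sqrt(0.25 / reps)
        assert abs(wins / reps - 0.5) < 4 * se


class TestRun:
    def test_dimension_mismatch(self, small_matrix):
        cfg = SimulationConfig(d=7, m=2, n=5)
        with pytest.raises(ValueError, match="dimension"):
            run(cfg, small_matrix)

    def test_invariants_hold_throughout(self, gauss200):
        cfg = SimulationConfig(
            d=200, m=4, n=8, q=0.05, seed=3, n_events=4000, sample_every=200
        )
        traj, log = run(cfg, gauss200, validate=True)
        assert log.immigration + log.replication == cfg.n_events
        assert log.split + log.cull >= 1
        assert log.group_removal == log.split
        clocks = [c for c, _ in traj.snapshots]
        assert clocks == sorted(set(clocks))

    def test_same_seed_reproduces_bit_identical_trajectories(self, gauss200, quick_config):
        cfg = SimulationConfig(
            d=200, m=3, n=10, seed=99, n_events=3000, sample_every=100
        )
        t1, l1 = run(cfg, gauss200)
        t2, l2 = run(cfg, gauss200)
        assert t1.snapshots == t2.snapshots
        assert l1 == l2

    def test_neutral_runs_do_not_depend_on_the_matrix(self):
        cfg = SimulationConfig(
            d=40, m=3, n=10, beta=0.0, seed=5, n_events=3000, sample_every=150
        )
        A1 = PayoffMatrix(np.random.default_rng(1).normal(size=(40, 40)))
        A2 = PayoffMatrix(np.random.default_rng(2).normal(size=(40, 40)))
        t1, _ = run(cfg, A1)
        t2, _ = run(cfg, A2)
        assert t1.snapshots == t2.snapshots

    def test_immigration_fraction_concentrates_at_lambda(self, gauss200):
        cfg = SimulationConfig(d=200, m=3, n=10, lam=0.3, seed=8, n_events=20000)
        _, log = run(cfg, gauss200)
        se = np.sqrt(0.3 * 0.7 / cfg.n_events)
        assert abs(log.immigration / cfg.n_events - 0.3) < 4 * se

    def test_frequent_splitting_keeps_groups_below_capacity(self, gauss200):
        """With q << 1 groups sit at carrying capacity most of the time;
        with q = 1 they are mostly below it."""
        means = {}
        for q in (0.001, 1.0):
            cfg = SimulationConfig(
                d=200, m=6, n=20, q=q, seed=17, n_events=20000, sample_every=200
            )
            traj, _ = run(cfg, gauss200)
            sizes = [
                sum(grp.values()) for _, snap in traj.snapshots[10:] for grp in snap
            ]
            means[q] = np.mean(sizes)
        assert means[1.0] < means[0.001]
        assert means[0.001] > 0.9 * 20

    def test_per_group_parent_selection_variant_runs(self, gauss200):
        cfg = SimulationConfig(
            d=200, m=3, n=10, seed=4, n_events=2000, sample_every=100,
            parent_selection="per_group",
        )
        traj, _ = run(cfg, gauss200, validate=True)
        assert len(traj) >= 2

    def test_split_removal_may_include_offspring_when_configured(self, gauss200):
        cfg = SimulationConfig(
            d=200, m=2, n=8, q=1.0, seed=21, n_events=5000, sample_every=500,
            split_removal="any",
        )
        traj, log = run(cfg, gauss200, validate=True)
        assert log.split > 0
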