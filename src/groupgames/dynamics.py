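"""Stochastic update process: immigration, replication, splitting, culling.

One update event does the following. With probability ``lam`` an immigrant
of a uniformly random type joins a uniformly random group; otherwise a
parent is drawn fitness-proportionally and its offspring is added to the
parent's group. If the affected group then exceeds the carrying capacity
``n``, the overflow is resolved immediately: with probability ``q`` the
group splits into two (each individual assigned to either offspring by a
fair coin, rejected and redrawn until both offspring hold at least two
individuals) and one *other* group is removed to keep the group count at
``m``; with probability ``1 - q`` one uniformly random individual is
removed from the group.

All randomness flows through a single ``numpy.random.Generator`` in a fixed
consumption order (event kind, actor, placement, overflow resolution), so a
run is bit-reproducible from its seed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np

from .core_model import (
    GroupState,
    PayoffMatrix,
    PopulationState,
    SimulationConfig,
    Trajectory,
    group_weights,
)

__all__ = [
    "EventLog",
    "initialize",
    "step",
    "resolve_overflow",
    "split_group",
    "run",
]


@dataclass
class EventLog:
    """Counters of executed events, for diagnostics and reproducibility audits."""

    immigration: int = 0
    replication: int = 0
    split: int = 0
    cull: int = 0
    group_removal: int = 0
    rng_seed: int | None = None

    def as_dict(self) -> dict[str, int | None]:
        return {
            "immigration": self.immigration,
            "replication": self.replication,
            "split": self.split,
            "cull": self.cull,
            "group_removal": self.group_removal,
            "rng_seed": self.rng_seed,
        }


class _WeightCache:
    """Per-group replication-weight cache keyed by group identity + version.

    Only the group touched by an event is recomputed, which keeps the cost
    of one event at O(k^2) for k types present in that group instead of
    recomputing every group.
    """

    def __init__(self, A: PayoffMatrix, beta: float):
        self.A = A
        self.beta = beta
        self._store: dict[int, tuple[int, np.ndarray, np.ndarray, float]] = {}

    def get(self, group: GroupState) -> tuple[np.ndarray, np.ndarray, float]:
        key = id(group)
        hit = self._store.get(key)
        if hit is not None and hit[0] == group.version:
            return hit[1], hit[2], hit[3]
        idx, w = group_weights(group, self.A, self.beta)
        cw = np.cumsum(w)
        total = float(cw[-1])
        self._store[key] = (group.version, idx, cw, total)
        return idx, cw, total

    def prune(self, groups: list[GroupState]) -> None:
        live = {id(g) for g in groups}
        for key in [k for k in self._store if k not in live]:
            del self._store[key]


def initialize(config: SimulationConfig, rng: np.random.Generator) -> PopulationState:
    """Populate each of the m groups with n individuals of uniformly random type."""
    groups = [
        GroupState.from_types(rng.integers(0, config.d, size=config.n))
        for _ in range(config.m)
    ]
    return PopulationState(groups=groups, event_clock=0)


def _pick_individual(group: GroupState, r: int) -> int:
    """Type of the r-th individual (0-based) under the canonical type order."""
    acc = 0
    for t, c in group.sorted_items():
        acc += c
        if r < acc:
            return t
    raise IndexError("individual index out of range")


def split_group(
    group: GroupState, rng: np.random.Generator
) -> tuple[GroupState, GroupState]:
    """Split a group in two by assigning each individual a fair coin flip.

    The allocation is redrawn from scratch until both offspring hold at
    least two individuals, so the accepted allocation is distributed as an
    independent fair assignment conditioned on both sizes >= 2. Requires a
    parent of size >= 4 (the conditioning event is empty otherwise).
    """
    if group.size < 4:
        raise ValueError("unsplittable group: size must be at least 4")
    items = group.sorted_items()
    while True:
        left = {t: int(rng.binomial(c, 0.5)) for t, c in items}
        size_left = sum(left.values())
        if 2 <= size_left <= group.size - 2:
            break
    a = GroupState({t: c for t, c in left.items() if c > 0})
    b = GroupState({t: c - left[t] for t, c in items if c - left[t] > 0})
    return a, b


def resolve_overflow(
    state: PopulationState,
    g: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    log: EventLog | None = None,
) -> PopulationState:
    """Resolve a group that has just exceeded the carrying capacity.

    With probability q the group splits and one other group is removed so
    the number of groups stays m; otherwise one uniformly random individual
    is culled from the group. Single-group populations never split (there is
    no other group to remove), nor do groups too small to yield two
    offspring of size >= 2.
    """
    group = state.groups[g]
    if group.size <= config.n:
        raise ValueError("no overflow: group is not above carrying capacity")
    can_split = config.m > 1 and group.size >= 4
    do_split = can_split and config.q > 0 and rng.random() < config.q
    if do_split:
        off_a, off_b = split_group(group, rng)
        expanded = state.groups[:g] + [off_a, off_b] + state.groups[g + 1 :]
        if config.split_removal == "exclude_offspring":
            candidates = [i for i in range(len(expanded)) if i not in (g, g + 1)]
        else:
            candidates = list(range(len(expanded)))
        victim = candidates[int(rng.integers(len(candidates)))]
        del expanded[victim]
        state.groups = expanded
        if log is not None:
            log.split += 1
            log.group_removal += 1
    else:
        r = int(rng.integers(group.size))
        group.remove_one(_pick_individual(group, r))
        if log is not None:
            log.cull += 1
    return state


def step(
    state: PopulationState,
    A: PayoffMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
    log: EventLog | None = None,
    _cache: _WeightCache | None = None,
) -> PopulationState:
    """Execute exactly one update event, mutating ``state`` in place.

    Randomness consumption order: event kind, then actor (immigrant type /
    parent), then placement (target group / implicit parent group), then any
    overflow-resolution draws.
    """
    if config.lam > 0 and rng.random() < config.lam:
        t = int(rng.integers(config.d))
        g = int(rng.integers(config.m))
        if log is not None:
            log.immigration += 1
    else:
        cache = _cache if _cache is not None else _WeightCache(A, config.beta)
        if config.parent_selection == "per_group":
            g = int(rng.integers(config.m))
            idx, cw, total = cache.get(state.groups[g])
        else:
            totals = np.empty(config.m)
            per_group = []
            for gi, grp in enumerate(state.groups):
                idx_g, cw_g, tot_g = cache.get(grp)
                per_group.append((idx_g, cw_g))
                totals[gi] = tot_g
            cum = np.cumsum(totals)
            g = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            g = min(g, config.m - 1)
            idx, cw = per_group[g]
            total = totals[g]
        j = int(np.searchsorted(cw, rng.random() * total, side="right"))
        t = int(idx[min(j, len(idx) - 1)])
        if log is not None:
            log.replication += 1
    state.groups[g].add(t)
    if state.groups[g].size > config.n:
        resolve_overflow(state, g, config, rng, log)
        if _cache is not None:
            _cache.prune(state.groups)
    state.event_clock += 1
    return state


def run(
    config: SimulationConfig,
    A: PayoffMatrix,
    validate: bool = False,
    progress: bool = False,
) -> tuple[Trajectory, EventLog]:
    """Run a full simulation: initialize, execute n_events steps, sample.

    Snapshots are recorded at event 0, every ``sample_every`` events, and at
    the final event. Identical (config, A) — including the seed — produce a
    bit-identical trajectory. ``validate`` re-checks all population
    invariants after every event (slow; intended for tests).
    """
    if A.d != config.d:
        raise ValueError(f"matrix dimension {A.d} != config.d = {config.d}")
    rng = np.random.default_rng(config.seed)
    log = EventLog(rng_seed=config.seed)
    state = initialize(config, rng)
    if validate:
        state.validate(config)
    traj = Trajectory(config=config)
    traj.append(state)
    cache = _WeightCache(A, config.beta)
    for ev in range(1, config.n_events + 1):
        step(state, A, config, rng, log=log, _cache=cache)
        if validate:
            state.validate(config)
        if ev % config.sample_every == 0 or ev == config.n_events:
            traj.append(state)
        if progress and ev % max(1, config.n_events // 10) == 0:
            print(
                f"[groupgames] event {ev}/{config.n_events} "
                f"(immigration={log.immigration}, replication={log.replication}, "
                f"splits={log.split}, culls={log.cull})",
                file=sys.stderr,
            )
    return traj, log
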