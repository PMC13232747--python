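"""Domain types and per-state game computations.

A population of ``d`` microbial types is structured into ``m`` groups
(hosts), each with carrying capacity ``n``. Individuals interact with all
other members of their group through a matrix game: a type-``j`` individual
in group ``g`` receives the mean payoff

    pi_j = (n_jg - 1)/(N_g - 1) * a_jj + sum_{k != j} n_kg/(N_g - 1) * a_jk,

where ``n_jg`` is the number of type-``j`` individuals in the group and
``N_g`` its size; self-interaction is excluded. Payoff maps to fitness
exponentially, ``f_j = exp(beta * pi_j)``, so fitness stays positive for
arbitrarily negative payoffs and ``beta`` tunes the strength of selection
(``beta = 0`` is neutral).

Type and group indices are 0-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PayoffMatrix",
    "SimulationConfig",
    "GroupState",
    "PopulationState",
    "Trajectory",
    "payoff",
    "group_payoffs",
    "fitness",
    "replication_weights",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """A d x d game matrix A = (a_ij).

    ``entries[i, j]`` is the payoff a type-``i`` individual receives from
    interacting with a type-``j`` individual. ``gen_meta`` optionally records
    how the matrix was generated (mean, variance, seed).
    """

    entries: np.ndarray
    gen_meta: dict | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"payoff matrix must be square, got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("payoff matrix needs at least d = 2 types")
        if not np.all(np.isfinite(arr)):
            raise ValueError("payoff matrix entries must be finite")
        object.__setattr__(self, "entries", arr)

    @property
    def d(self) -> int:
        return self.entries.shape[0]

    @property
    def self_payoffs(self) -> np.ndarray:
        """Diagonal a_ii: payoff of each type against its own kind."""
        return np.diagonal(self.entries)


@dataclass(frozen=True)
class SimulationConfig:
    """All model and runtime parameters for one simulation run.

    Parameters
    ----------
    d : number of types in the environmental pool.
    m : number of groups (held constant throughout the run).
    n : group carrying capacity; exceeding it triggers overflow resolution.
    beta : selection intensity; 0 means neutral drift.
    lam : per-event immigration probability (an immigrant of a uniformly
        random type joins a uniformly random group).
    q : probability that an overflowing group splits rather than losing one
        random individual. Single-group populations never split.
    seed : integer seed for the single RNG stream driving the run.
    n_events : total number of update events to execute.
    sample_every : snapshot recording interval, in events.
    burn_in : events ignored by long-run statistics downstream.
    last_k_snapshots : window (in snapshots) for time-averaged abundances.
    parent_selection : "global" draws the replicating parent
        fitness-proportionally over all individuals in the population;
        "per_group" first picks a group uniformly, then an individual
        within it fitness-proportionally.
    split_removal : which groups are eligible for removal after a split:
        "exclude_offspring" (default) draws uniformly from the m - 1 groups
        other than the two offspring; "any" includes the offspring.
    """

    d: int
    m: int
    n: int
    beta: float = 1.0
    lam: float = 0.1
    q: float = 0.001
    seed: int = 0
    n_events: int = 10_000
    sample_every: int = 100
    burn_in: int = 0
    last_k_snapshots: int = 15
    parent_selection: str = "global"
    split_removal: str = "exclude_offspring"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be a positive integer")
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if self.n < 2:
            raise ValueError("carrying capacity n must be at least 2")
        if self.beta < 0:
            raise ValueError("selection intensity beta must be nonnegative")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("immigration probability lam must lie in [0, 1]")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("splitting probability q must lie in [0, 1]")
        if self.n_events < 1:
            raise ValueError("n_events must be positive")
        if self.sample_every < 1:
            raise ValueError("sample_every must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if self.last_k_snapshots < 1:
            raise ValueError("last_k_snapshots must be positive")
        if self.parent_selection not in ("global", "per_group"):
            raise ValueError("parent_selection must be 'global' or 'per_group'")
        if self.split_removal not in ("exclude_offspring", "any"):
            raise ValueError("split_removal must be 'exclude_offspring' or 'any'")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


class GroupState:
    """Type composition of one group.

    Counts are stored sparsely: only types with at least one individual
    appear in the mapping. The group size is maintained incrementally, and a
    version counter lets callers cache derived quantities (payoffs, fitness
    weights) between mutations.
    """

    __slots__ = ("counts", "size", "_version")

    def __init__(self, counts: Mapping[int, int] | None = None) -> None:
        self.counts: dict[int, int] = {}
        self.size = 0
        self._version = 0
        if counts:
            for t, c in counts.items():
                if c < 1:
                    raise ValueError("stored counts must be >= 1")
                self.counts[int(t)] = int(c)
                self.size += int(c)

    @classmethod
    def from_types(cls, types: Iterable[int]) -> "GroupState":
        g = cls()
        for t in types:
            g.add(int(t))
        return g

    @property
    def version(self) -> int:
        return self._version

    def add(self, t: int) -> None:
        """Add one individual of type ``t``."""
        self.counts[t] = self.counts.get(t, 0) + 1
        self.size += 1
        self._version += 1

    def remove_one(self, t: int) -> None:
        """Remove one individual of type ``t``."""
        c = self.counts.get(t, 0)
        if c == 0:
            raise ValueError(f"type {t} not present in group")
        if c == 1:
            del self.counts[t]
        else:
            self.counts[t] = c - 1
        self.size -= 1
        self._version += 1

    def richness(self) -> int:
        return len(self.counts)

    def type_set(self) -> frozenset[int]:
        return frozenset(self.counts)

    def sorted_items(self) -> list[tuple[int, int]]:
        """(type, count) pairs in ascending type order — the canonical
        iteration order for all randomness consumption."""
        return sorted(self.counts.items())

    def copy(self) -> "GroupState":
        return GroupState(self.counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GroupState({self.counts!r})"


@dataclass
class PopulationState:
    """The m groups' composition at one instant plus the event clock."""

    groups: list[GroupState]
    event_clock: int = 0

    @property
    def m(self) -> int:
        return len(self.groups)

    @property
    def total_size(self) -> int:
        return sum(g.size for g in self.groups)

    def snapshot_counts(self) -> list[dict[int, int]]:
        """Deep-copied per-group counts, suitable for storing in a Trajectory."""
        return [dict(g.counts) for g in self.groups]

    def validate(self, config: SimulationConfig) -> None:
        """Check the inter-event invariants; raise on violation."""
        if len(self.groups) != config.m:
            raise AssertionError(
                f"group count {len(self.groups)} != m = {config.m}"
            )
        for gi, g in enumerate(self.groups):
            if not 2 <= g.size <= config.n:
                raise AssertionError(
                    f"group {gi} size {g.size} outside [2, {config.n}]"
                )
            if any(c < 1 for c in g.counts.values()):
                raise AssertionError(f"group {gi} holds a nonpositive count")
        total = self.total_size
        if not 2 * config.m <= total <= config.m * config.n:
            raise AssertionError(
                f"total size {total} outside [{2 * config.m}, {config.m * config.n}]"
            )


@dataclass
class Trajectory:
    """Time-ordered sequence of sampled population snapshots.

    Each snapshot is ``(event_clock, per_group_counts)`` where
    ``per_group_counts`` is a list of ``{type: count}`` mappings.
    """

    config: SimulationConfig
    snapshots: list[tuple[int, list[dict[int, int]]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snapshots)

    def append(self, state: PopulationState) -> None:
        if self.snapshots and state.event_clock <= self.snapshots[-1][0]:
            raise ValueError("snapshot event clocks must be strictly increasing")
        self.snapshots.append((state.event_clock, state.snapshot_counts()))


def payoff(group: GroupState, j: int, A: PayoffMatrix) -> float:
    """Mean game payoff of a type-``j`` individual in ``group``.

    Every individual interacts with the other ``N_g - 1`` group members;
    self-interaction is excluded. A single-individual group has no
    interaction partners, so its payoff is 0 by convention.
    """
    nj = group.counts.get(j, 0)
    if nj == 0:
        raise ValueError(f"type {j} not present in group")
    if group.size == 1:
        return 0.0
    a = A.entries
    total = -a[j, j]  # remove the self-pairing from the n_jg * a_jj term
    for k, ck in group.counts.items():
        total += ck * a[j, k]
    return total / (group.size - 1)


def group_payoffs(group: GroupState, A: PayoffMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Payoffs of every type present in ``group``.

    Returns ``(types, payoffs)`` with types ascending. Vectorized over the
    present types only, so the cost is O(k^2) for k <= n present types
    rather than O(d^2).
    """
    items = group.sorted_items()
    idx = np.fromiter((t for t, _ in items), dtype=np.int64, count=len(items))
    cnt = np.fromiter((c for _, c in items), dtype=np.float64, count=len(items))
    if group.size == 1:
        return idx, np.zeros(1)
    sub = A.entries[np.ix_(idx, idx)]
    pi = (sub @ cnt - np.diagonal(sub)) / (group.size - 1)
    return idx, pi


def fitness(pi: float | np.ndarray, beta: float) -> float | np.ndarray:
    """Exponential payoff-to-fitness map f = exp(beta * pi)."""
    if not np.all(np.isfinite(pi)):
        raise ValueError("payoff must be finite")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    return np.exp(beta * np.asarray(pi, dtype=float)) if np.ndim(pi) else math.exp(beta * pi)


def group_weights(group: GroupState, A: PayoffMatrix, beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Replication weights n_jg * f_j for every type present in ``group``.

    Normalizing within the group gives each type's within-group replication
    probability; summing across groups gives the group's total fitness mass
    used for global parent selection.
    """
    if group.size == 0:
        raise ValueError("empty group has no replication weights")
    idx, pi = group_payoffs(group, A)
    cnt = np.fromiter((group.counts[int(t)] for t in idx), dtype=np.float64, count=len(idx))
    return idx, cnt * np.exp(beta * pi)


def replication_weights(
    state: PopulationState, A: PayoffMatrix, beta: float
) -> dict[tuple[int, int], float]:
    """Replication weight w_{g,j} = n_jg * f_j for every present (group, type).

    Sampling the parent proportionally to these weights over all groups
    jointly realizes fitness-proportional selection across the whole
    population; restricting to one group and renormalizing recovers the
    within-group replication probabilities exactly.
    """
    out: dict[tuple[int, int], float] = {}
    for gi, g in enumerate(state.groups):
        idx, w = group_weights(g, A, beta)
        for t, wt in zip(idx, w):
            out[(gi, int(t))] = float(wt)
    return out
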