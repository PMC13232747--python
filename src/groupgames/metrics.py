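"""Summary statistics on simulated trajectories.

Diversity is measured at the population level (total richness, Shannon
index), at the group level (per-group richness, homogeneous-group
fraction), and between groups (mean pairwise Jaccard similarity of the
type-presence sets). Realized interaction frequencies reweight the
matrix-level stability classes by who actually shares a group: a
heterotypic pair {i, j} co-resident in a group with counts n_ig, n_jg
contributes n_ig * n_jg interacting individual pairs to its class.

A "snapshot" throughout is a list of per-group ``{type: count}`` mappings,
as stored in :class:`~groupgames.core_model.Trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import PayoffMatrix, Trajectory
from .interactions import InteractionClass, InteractionTable

Snapshot = Sequence[dict[int, int]]

__all__ = [
    "realized_interaction_frequencies",
    "total_richness",
    "group_richness",
    "shannon_index",
    "group_similarity",
    "homogeneous_fraction",
    "abundance_ranking",
    "AbundanceRanking",
    "turnover_stats",
    "snapshot_metrics",
    "long_run_summary",
]


def _pooled_counts(snapshot: Snapshot) -> dict[int, int]:
    pooled: dict[int, int] = {}
    for grp in snapshot:
        for t, c in grp.items():
            pooled[t] = pooled.get(t, 0) + c
    return pooled


def realized_interaction_frequencies(
    snapshots: Sequence[Snapshot],
    table: InteractionTable,
    weighting: str = "pairs",
) -> dict[str, float]:
    """Class fractions among effectively interacting individuals.

    Only types sharing a group at the same time interact. With
    ``weighting="pairs"`` (default) each co-resident heterotypic pair {i, j}
    contributes weight n_ig * n_jg — the number of interacting individual
    pairs; ``weighting="presence"`` counts each co-occurring pair once.
    Weights are summed over groups and snapshots and normalized over the
    non-degenerate classes, with dominance pooling both orientations.
    """
    if weighting not in ("pairs", "presence"):
        raise ValueError("weighting must be 'pairs' or 'presence'")
    if not snapshots:
        raise ValueError("no snapshots given")
    mass = {
        InteractionClass.FIRST_DOMINATES: 0.0,
        InteractionClass.SECOND_DOMINATES: 0.0,
        InteractionClass.BISTABLE: 0.0,
        InteractionClass.COEXISTENCE: 0.0,
        InteractionClass.DEGENERATE: 0.0,
    }
    acc = np.zeros(len(InteractionClass))
    for snap in snapshots:
        for grp in snap:
            if len(grp) < 2:
                continue
            items = sorted(grp.items())
            idx = np.array([t for t, _ in items])
            cnt = np.array([c for _, c in items], dtype=float)
            codes = table.codes[np.ix_(idx, idx)]
            iu, ju = np.triu_indices(len(idx), k=1)
            w = cnt[iu] * cnt[ju] if weighting == "pairs" else np.ones(len(iu))
            np.add.at(acc, codes[iu, ju], w)
    for cls in mass:
        mass[cls] = acc[int(cls)]
    dom = mass[InteractionClass.FIRST_DOMINATES] + mass[InteractionClass.SECOND_DOMINATES]
    bis = mass[InteractionClass.BISTABLE]
    coex = mass[InteractionClass.COEXISTENCE]
    total = dom + bis + coex
    if total == 0:
        raise ValueError("no interactions observed: no heterotypic pair co-occurs")
    return {
        "dominance": dom / total,
        "bistability": bis / total,
        "coexistence": coex / total,
    }


def total_richness(snapshot: Snapshot) -> int:
    """Number of distinct types present anywhere in the population."""
    present: set[int] = set()
    for grp in snapshot:
        present.update(grp)
    return len(present)


def group_richness(snapshot: Snapshot) -> tuple[list[int], float]:
    """Distinct-type count of each group and the mean over groups."""
    per_group = [len(grp) for grp in snapshot]
    return per_group, float(np.mean(per_group))


def shannon_index(snapshot: Snapshot) -> float:
    """Shannon diversity H = -sum p_i ln p_i over population-wide abundances.

    Natural logarithm; 0 <= H <= ln(richness), with equality at uniform
    abundances.
    """
    pooled = _pooled_counts(snapshot)
    counts = np.array(list(pooled.values()), dtype=float)
    if counts.sum() < 1:
        raise ValueError("empty population")
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def group_similarity(snapshot: Snapshot, method: str = "jaccard") -> float:
    """Mean pairwise between-group similarity of type composition.

    ``"jaccard"`` (default) compares presence sets: |S_g & S_h| / |S_g | S_h|
    averaged over all unordered group pairs. ``"bray-curtis"`` is the
    abundance-weighted alternative (1 - Bray-Curtis dissimilarity).
    """
    if len(snapshot) < 2:
        raise ValueError("similarity undefined for one group")
    sims = []
    if method == "jaccard":
        sets = [set(grp) for grp in snapshot]
        for sg, sh in combinations(sets, 2):
            union = sg | sh
            sims.append(len(sg & sh) / len(union) if union else 1.0)
    elif method == "bray-curtis":
        for g, h in combinations(snapshot, 2):
            shared = sum(min(g.get(t, 0), h.get(t, 0)) for t in set(g) | set(h))
            tot = sum(g.values()) + sum(h.values())
            sims.append(2.0 * shared / tot if tot else 1.0)
    else:
        raise ValueError("method must be 'jaccard' or 'bray-curtis'")
    return float(np.mean(sims))


def homogeneous_fraction(snapshot: Snapshot) -> float:
    """Fraction of groups whose members are all of a single type."""
    return sum(1 for grp in snapshot if len(grp) == 1) / len(snapshot)


@dataclass
class AbundanceRanking:
    """Long-run abundance report.

    ``table`` has one row per type with its window-averaged relative
    abundance and self-payoff; ``by_abundance`` and ``by_self_payoff`` are
    the same rows sorted by each criterion (descending).
    ``spearman`` is the rank correlation between abundance and self-payoff
    across the types present in the window.
    """

    table: pd.DataFrame
    spearman: float

    @property
    def by_abundance(self) -> pd.DataFrame:
        return self.table.sort_values("mean_abundance", ascending=False, ignore_index=True)

    @property
    def by_self_payoff(self) -> pd.DataFrame:
        return self.table.sort_values("self_payoff", ascending=False, ignore_index=True)


def abundance_ranking(
    trajectory: Trajectory, A: PayoffMatrix, last_k: int | None = None
) -> AbundanceRanking:
    """Time-averaged relative abundances over the last ``last_k`` snapshots.

    Each type's relative abundance (population-wide count over total size)
    is averaged across the window; the Spearman correlation against the
    self-payoffs a_ii is computed over types present in the window.
    """
    if last_k is None:
        last_k = trajectory.config.last_k_snapshots
    if len(trajectory) < last_k:
        raise ValueError(
            f"trajectory has {len(trajectory)} snapshots, fewer than last_k = {last_k}"
        )
    window = trajectory.snapshots[-last_k:]
    mean_ab = np.zeros(A.d)
    for _, snap in window:
        pooled = _pooled_counts(snap)
        total = sum(pooled.values())
        for t, c in pooled.items():
            mean_ab[t] += c / total
    mean_ab /= last_k
    table = pd.DataFrame(
        {
            "type": np.arange(A.d),
            "mean_abundance": mean_ab,
            "self_payoff": A.self_payoffs,
        }
    )
    present = table[table.mean_abundance > 0]
    if len(present) >= 2:
        rho = float(stats.spearmanr(present.mean_abundance, present.self_payoff).statistic)
    else:
        rho = float("nan")
    return AbundanceRanking(table=table, spearman=rho)


def turnover_stats(trajectory: Trajectory) -> float:
    """Mean duration (in snapshots) of runs of an unchanged most abundant type.

    The population-wide most abundant type is identified at each snapshot,
    ties broken by the lowest type index; maximal constant runs are
    run-length encoded and their mean length returned.
    """
    if len(trajectory) < 2:
        raise ValueError("turnover needs at least 2 snapshots")
    leaders = []
    for _, snap in trajectory.snapshots:
        pooled = _pooled_counts(snap)
        leaders.append(min(pooled, key=lambda t: (-pooled[t], t)))
    runs = []
    length = 1
    for prev, cur in zip(leaders, leaders[1:]):
        if cur == prev:
            length += 1
        else:
            runs.append(length)
            length = 1
    runs.append(length)
    return float(np.mean(runs))


def snapshot_metrics(trajectory: Trajectory) -> pd.DataFrame:
    """Per-snapshot diversity table.

    Columns: event_clock, total_richness, mean_group_richness,
    shannon_index, group_similarity (NaN for single-group populations),
    homogeneous_fraction.
    """
    rows = []
    for clock, snap in trajectory.snapshots:
        per_group, mean_rich = group_richness(snap)
        rows.append(
            {
                "event_clock": clock,
                "total_richness": total_richness(snap),
                "mean_group_richness": mean_rich,
                "shannon_index": shannon_index(snap),
                "group_similarity": group_similarity(snap) if len(snap) > 1 else np.nan,
                "homogeneous_fraction": homogeneous_fraction(snap),
            }
        )
    return pd.DataFrame(rows)


def long_run_summary(
    trajectory: Trajectory,
    A: PayoffMatrix,
    table: InteractionTable,
    last_k: int | None = None,
) -> dict[str, float]:
    """Long-run averages over the last ``last_k`` snapshots plus realized
    interaction fractions, abundance/self-payoff correlation, and turnover."""
    if last_k is None:
        last_k = trajectory.config.last_k_snapshots
    if len(trajectory) < last_k:
        raise ValueError("trajectory shorter than the averaging window")
    per_snap = snapshot_metrics(trajectory).tail(last_k)
    window = [snap for _, snap in trajectory.snapshots[-last_k:]]
    out = {
        "total_richness": float(per_snap.total_richness.mean()),
        "mean_group_richness": float(per_snap.mean_group_richness.mean()),
        "shannon_index": float(per_snap.shannon_index.mean()),
        "group_similarity": float(per_snap.group_similarity.mean()),
        "homogeneous_fraction": float(per_snap.homogeneous_fraction.mean()),
        "turnover_mean_duration": turnover_stats(trajectory),
        "spearman_selfpayoff_abundance": abundance_ranking(trajectory, A, last_k).spearman,
    }
    try:
        fracs = realized_interaction_frequencies(window, table)
    except ValueError:
        fracs = {"dominance": np.nan, "bistability": np.nan, "coexistence": np.nan}
    out.update({f"realized_{k}": float(v) for k, v in fracs.items()})
    return out
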