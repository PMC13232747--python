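"""Stability classification of pairwise interactions.

Every unordered pair of types {i, j} defines a 2x2 subgame

        (a_ii  a_ij)
        (a_ji  a_jj)

whose two-type replicator dynamics has one of three generic outcomes,
determined by the invasion conditions. Type i invades a resident-j
population iff a_ij > a_jj; type j invades resident i iff a_ji > a_ii.

* dominance      — exactly one type invades the other: the invader excludes
                   the other from any interior frequency (i <- j).
* bistability    — neither invades: each type is stable when common, the
                   winner depends on initial frequencies (i <-> j).
* coexistence    — both invade: a stable interior equilibrium exists at
                   x* = (a_ij - a_jj) / (a_ij - a_jj + a_ji - a_ii) (i -> <- j).

Exact equality in either comparison is non-generic and classified
DEGENERATE; degenerate pairs are excluded from frequency denominators and
reported separately. For a matrix with i.i.d. continuous entries each
invasion condition is an independent fair coin, so the expected class
fractions are dominance 1/2, bistability 1/4, coexistence 1/4.

The classification is a property of the payoff matrix alone; it never looks
at simulated frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import PayoffMatrix

__all__ = [
    "InteractionClass",
    "InteractionTable",
    "classify_pair",
    "classify_all",
    "baseline_frequencies",
    "ranked_profile",
]


class InteractionClass(IntEnum):
    DEGENERATE = 0
    FIRST_DOMINATES = 1
    SECOND_DOMINATES = 2
    BISTABLE = 3
    COEXISTENCE = 4

    def swapped(self) -> "InteractionClass":
        """The class seen when the pair is presented in the opposite order."""
        if self is InteractionClass.FIRST_DOMINATES:
            return InteractionClass.SECOND_DOMINATES
        if self is InteractionClass.SECOND_DOMINATES:
            return InteractionClass.FIRST_DOMINATES
        return self


_CLASS_LABEL = {
    InteractionClass.DEGENERATE: "degenerate",
    InteractionClass.FIRST_DOMINATES: "dominance",
    InteractionClass.SECOND_DOMINATES: "dominance",
    InteractionClass.BISTABLE: "bistability",
    InteractionClass.COEXISTENCE: "coexistence",
}


def _classify_signs(s_ij: int, s_ji: int) -> InteractionClass:
    """Map the signs of (a_ij - a_jj, a_ji - a_ii) to the ordered class."""
    if s_ij == 0 or s_ji == 0:
        return InteractionClass.DEGENERATE
    if s_ij > 0 and s_ji < 0:
        return InteractionClass.FIRST_DOMINATES
    if s_ij < 0 and s_ji > 0:
        return InteractionClass.SECOND_DOMINATES
    if s_ij < 0 and s_ji < 0:
        return InteractionClass.BISTABLE
    return InteractionClass.COEXISTENCE


def classify_pair(A: PayoffMatrix, i: int, j: int) -> InteractionClass:
    """Classify the ordered pair (i, j) by its 2x2 subgame outcome."""
    if i == j:
        raise ValueError("self-pair: i and j must differ")
    a = A.entries
    s_ij = int(np.sign(a[i, j] - a[j, j]))  # i invades resident j?
    s_ji = int(np.sign(a[j, i] - a[i, i]))  # j invades resident i?
    return _classify_signs(s_ij, s_ji)


@dataclass(frozen=True)
class InteractionTable:
    """Classified stability outcome for every unordered type pair.

    ``codes[i, j]`` holds the :class:`InteractionClass` of the ordered
    presentation (i, j); the matrix is consistent under transposition
    (``codes[j, i]`` is the orientation-swapped class). The diagonal is
    unused.
    """

    d: int
    codes: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.d * (self.d - 1) // 2

    def pair_class(self, i: int, j: int) -> InteractionClass:
        if i == j:
            raise ValueError("self-pair: i and j must differ")
        return InteractionClass(int(self.codes[i, j]))

    def class_counts(self) -> dict[InteractionClass, int]:
        """Counts over unordered pairs; dominance split by orientation of (i<j)."""
        iu, ju = np.triu_indices(self.d, k=1)
        vals, counts = np.unique(self.codes[iu, ju], return_counts=True)
        out = {c: 0 for c in InteractionClass}
        for v, c in zip(vals, counts):
            out[InteractionClass(int(v))] = int(c)
        return out

    def to_edgelist(self) -> pd.DataFrame:
        """Tidy edge list: type_i < type_j, pooled class label, orientation.

        Orientation is "i->j" when type_i dominates, "j->i" when type_j
        dominates, empty otherwise.
        """
        iu, ju = np.triu_indices(self.d, k=1)
        codes = self.codes[iu, ju]
        labels = np.array(
            [_CLASS_LABEL[InteractionClass(int(c))] for c in codes], dtype=object
        )
        orient = np.where(
            codes == InteractionClass.FIRST_DOMINATES,
            "i->j",
            np.where(codes == InteractionClass.SECOND_DOMINATES, "j->i", ""),
        )
        return pd.DataFrame(
            {"type_i": iu, "type_j": ju, "class": labels, "orientation": orient}
        )

    def to_graph(self) -> nx.Graph:
        """Undirected interaction graph with class/orientation edge attributes."""
        g = nx.Graph()
        g.add_nodes_from(range(self.d))
        for row in self.to_edgelist().itertuples(index=False):
            g.add_edge(
                int(row.type_i),
                int(row.type_j),
                **{"class": row._2, "orientation": row.orientation},
            )
        return g


def classify_all(A: PayoffMatrix) -> InteractionTable:
    """Classify all d(d-1)/2 unordered pairs of a payoff matrix (vectorized)."""
    a = A.entries
    d = A.d
    # invade[i, j] > 0 iff a rare type i invades a resident-j population
    invade = np.sign(a - np.diagonal(a)[np.newaxis, :]).astype(np.int8)
    s_ij = invade
    s_ji = invade.T
    codes = np.zeros((d, d), dtype=np.int8)
    codes[(s_ij > 0) & (s_ji < 0)] = InteractionClass.FIRST_DOMINATES
    codes[(s_ij < 0) & (s_ji > 0)] = InteractionClass.SECOND_DOMINATES
    codes[(s_ij < 0) & (s_ji < 0)] = InteractionClass.BISTABLE
    codes[(s_ij > 0) & (s_ji > 0)] = InteractionClass.COEXISTENCE
    np.fill_diagonal(codes, InteractionClass.DEGENERATE)
    return InteractionTable(d=d, codes=codes)


def baseline_frequencies(table: InteractionTable) -> dict[str, float]:
    """Class fractions over all unordered pairs of the matrix.

    Dominance pools both orientations. Degenerate pairs (exact payoff ties)
    are excluded from the denominator and reported under ``degenerate`` as a
    fraction of all pairs.
    """
    counts = table.class_counts()
    dom = (
        counts[InteractionClass.FIRST_DOMINATES]
        + counts[InteractionClass.SECOND_DOMINATES]
    )
    bis = counts[InteractionClass.BISTABLE]
    coex = counts[InteractionClass.COEXISTENCE]
    deg = counts[InteractionClass.DEGENERATE]
    valid = dom + bis + coex
    if valid == 0:
        raise ValueError("all pairs are degenerate; class fractions undefined")
    return {
        "dominance": dom / valid,
        "bistability": bis / valid,
        "coexistence": coex / valid,
        "degenerate": deg / table.n_pairs,
    }


def ranked_profile(A: PayoffMatrix, table: InteractionTable) -> pd.DataFrame:
    """Per-type interaction profile ordered by descending self-payoff a_ii.

    For each type, counts over its d - 1 pairs of how often it dominates, is
    dominated, is in a bistable pair, or coexists. Types with higher
    self-payoff tend to dominate more and appear in more bistable pairs,
    since both require a_ii to exceed the opponent's invasion payoff.
    """
    codes = table.codes.copy()
    np.fill_diagonal(codes, -1)
    df = pd.DataFrame(
        {
            "type": np.arange(table.d),
            "self_payoff": A.self_payoffs,
            "dominates": (codes == InteractionClass.FIRST_DOMINATES).sum(axis=1),
            "dominated": (codes == InteractionClass.SECOND_DOMINATES).sum(axis=1),
            "bistable": (codes == InteractionClass.BISTABLE).sum(axis=1),
            "coexists": (codes == InteractionClass.COEXISTENCE).sum(axis=1),
            "degenerate": (codes == InteractionClass.DEGENERATE).sum(axis=1),
        }
    )
    return df.sort_values("self_payoff", ascending=False, ignore_index=True)
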