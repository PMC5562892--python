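"""Pareto machinery: dominance, non-dominated sorting, crowding, selection.

Objective vectors are compared coordinate-wise after orientation (similarity
and non-gap percentage maximized, gap penalty minimized).  Sorting follows
the fast non-dominated sorting scheme: front 0 holds all non-dominated
individuals, front 1 those dominated only by front 0, and so on.  Diversity
within a front is measured by crowding distance — the normalized objective
gap between each individual's neighbors, with boundary individuals given
infinite distance — and selection is the crowded tournament: lowest rank
wins, ties broken by largest crowding distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_core import ParameterError
from .objectives import ObjectiveVector


@dataclass
class RankedIndividual:
    """Population member annotated with Pareto rank and crowding distance."""

    index: int
    objectives: ObjectiveVector
    rank: int = 0
    crowding: float = 0.0


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff ``a`` is at least as good as ``b`` on every objective and
    strictly better on at least one."""
    ao, bo = a.oriented(), b.oriented()
    ge = all(x >= y for x, y in zip(ao, bo))
    gt = any(x > y for x, y in zip(ao, bo))
    return ge and gt


def non_dominated_sort(pop: list[ObjectiveVector]) -> list[list[int]]:
    """Partition population indices into Pareto fronts F0, F1, ...

    Each index appears exactly once; members of a front do not dominate each
    other, and every member of front k > 0 is dominated by someone in an
    earlier front.
    """
    if not pop:
        raise ParameterError("empty population")
    n = len(pop)
    oriented = np.array([v.oriented() for v in pop])
    # pairwise domination matrix: dom[i, j] = i dominates j
    ge = (oriented[:, None, :] >= oriented[None, :, :]).all(axis=2)
    gt = (oriented[:, None, :] > oriented[None, :, :]).any(axis=2)
    dom = ge & gt
    n_dominators = dom.sum(axis=0)
    dominated_by: list[np.ndarray] = [np.flatnonzero(dom[i]) for i in range(n)]

    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominators[i] == 0]
    remaining = n_dominators.copy()
    while current:
        fronts.append(sorted(current))
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    nxt.append(int(j))
        current = nxt
    return fronts


def crowding_distance(front: list[ObjectiveVector]) -> list[float]:
    """Crowding distance of each member of one front.

    Per objective, individuals are sorted and each interior one accrues the
    gap between its neighbors normalized by the front's range on that
    objective (a zero range contributes nothing); the two extremes get
    infinity.  A front of size <= 2 is all-infinite.
    """
    m = len(front)
    if m == 0:
        return []
    vals = np.array([v.oriented() for v in front])
    dist = np.zeros(m)
    for k in range(vals.shape[1]):
        order = np.argsort(vals[:, k], kind="stable")
        lo, hi = vals[order[0], k], vals[order[-1], k]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        rng = hi - lo
        if rng == 0 or m <= 2:
            continue
        for pos in range(1, m - 1):
            i = order[pos]
            if np.isinf(dist[i]):
                continue
            dist[i] += (vals[order[pos + 1], k] - vals[order[pos - 1], k]) / rng
    return [float(d) for d in dist]


def rank_population(pop: list[ObjectiveVector]) -> list[RankedIndividual]:
    """Convenience: full non-dominated sort plus per-front crowding."""
    fronts = non_dominated_sort(pop)
    out = [RankedIndividual(i, v) for i, v in enumerate(pop)]
    for r, front in enumerate(fronts):
        dists = crowding_distance([pop[i] for i in front])
        for i, d in zip(front, dists):
            out[i].rank = r
            out[i].crowding = d
    return out


def crowded_tournament(
    pop: list[RankedIndividual], k: int, rng: np.random.Generator
) -> int:
    """Index of the winner among k uniformly drawn candidates: lowest rank,
    ties broken by highest crowding, remaining ties by the rng."""
    if not (1 <= k <= len(pop)):
        raise ParameterError(f"tournament size {k} out of range [1, {len(pop)}]")
    picks = rng.integers(0, len(pop), size=k)
    best = None
    for p in picks:
        cand = pop[int(p)]
        if best is None:
            best = cand
            continue
        if cand.rank < best.rank or (
            cand.rank == best.rank and cand.crowding > best.crowding
        ):
            best = cand
        elif (
            cand.rank == best.rank
            and cand.crowding == best.crowding
            and rng.random() < 0.5
        ):
            best = cand
    assert best is not None
    return best.index
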