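"""The three alignment objectives: similarity, gap penalty, non-gap percentage.

An alignment is scored by a triple of objectives that the optimizer treats
under Pareto dominance rather than collapsing into a single scalar:

* **similarity (SM)** — the mean, over columns, of the relative frequency of
  each column's dominant residue (gaps never dominate but do dilute the
  denominator).  SM is 1 exactly when every column is perfectly conserved
  and gap-free, and is maximized.
* **gap penalty** — either the classical affine scheme (a fixed opening cost
  plus a per-column extension cost for every maximal gap run in every
  pairwise projection), or a position-specific *variable* scheme in which the
  opening/extension costs are rescaled per sequence pair and per column by
  length, percent identity, proximity to existing gaps, hydrophilic
  stretches, and residue-specific gap propensities.  Minimized.
* **non-gap percentage (NGP)** — the percentage of alignment cells that hold
  residues rather than gaps; maximized, to discourage inflating alignments
  with gaps.  (A "literal" variant reporting gaps/residues x 100 is
  available for reference.)

Columns in which *both* rows of a pairwise projection are gapped carry no
signal and are skipped before gap runs are measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np

from .msa_core import (
    GAP,
    Alignment,
    ParameterError,
    SubstitutionMatrix,
    load_substitution_matrix,
)

_GAP = ord(GAP)

# Hydrophilic residues (ClustalW convention); a run of >=5 of these marks a
# probable loop/coil region where gaps are biologically cheaper.
HYDROPHILIC_SET = frozenset("GPSNDQEKR")
HYDROPHILIC_RUN = 5

# Residue-specific gap-propensity multipliers in the style of the
# Pascarella-Argos counts used by ClustalW: >1 means gaps next to this
# residue are penalized more, <1 less.  Normalized below to mean 1 so the
# table rescales without shifting the overall penalty level.
_RAW_RESIDUE_GAP_TABLE: dict[str, float] = {
    "A": 1.13, "R": 0.72, "N": 0.63, "D": 0.90, "C": 1.13,
    "Q": 1.07, "E": 1.31, "G": 0.61, "H": 1.00, "I": 1.32,
    "L": 1.21, "K": 0.96, "M": 1.29, "F": 1.20, "P": 0.74,
    "S": 0.76, "T": 0.89, "W": 1.23, "Y": 1.00, "V": 1.25,
}
_mean = sum(_RAW_RESIDUE_GAP_TABLE.values()) / len(_RAW_RESIDUE_GAP_TABLE)
RESIDUE_GAP_TABLE: dict[str, float] = {
    k: v / _mean for k, v in _RAW_RESIDUE_GAP_TABLE.items()
}


@dataclass(frozen=True)
class ObjectiveVector:
    """(similarity, gap penalty, non-gap percentage) fitness triple.

    ``sm`` and ``ngp`` are maximized, ``gap_penalty`` is minimized; the
    :meth:`oriented` tuple re-signs the penalty so that "larger is better"
    holds coordinate-wise, which is what the Pareto layer compares.
    """

    sm: float
    gap_penalty: float
    ngp: float

    MAXIMIZE = (True, False, True)  # orientation metadata per coordinate

    def oriented(self) -> tuple[float, float, float]:
        return (self.sm, -self.gap_penalty, self.ngp)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sm, self.gap_penalty, self.ngp)


@dataclass(frozen=True)
class AffineGapParams:
    """Classical affine gap costs: a run of length g costs
    ``gap_open + gap_extend * (g - 1)``."""

    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ParameterError(
                "require gap_open >= gap_extend > 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )


# ---------------------------------------------------------------------------
# Position weight matrix, dominance, similarity
# ---------------------------------------------------------------------------


class PositionWeightMatrix:
    """Per-column relative residue frequencies of an alignment.

    ``f(x, y)`` is the count of residue ``x`` in column ``y`` divided by the
    number of sequences *n* — gaps are excluded from the numerator but still
    count in the denominator, so heavily gapped columns have low dominance.
    """

    def __init__(self, al: Alignment):
        n, h = al.n, al.h
        counts = np.zeros((256, h), dtype=np.int64)
        cols = np.broadcast_to(np.arange(h), (n, h))
        np.add.at(counts, (al.chars.ravel(), cols.ravel()), 1)
        counts[_GAP] = 0
        self._freqs = counts / n
        self.h = h
        self.n = n

    def f(self, x: str, y: int) -> float:
        if not (0 <= y < self.h):
            raise IndexError(f"column {y} out of range [0, {self.h})")
        return float(self._freqs[ord(x.upper()), y])

    def column_max(self) -> np.ndarray:
        """Dominance value of every column as a length-h vector."""
        return self._freqs.max(axis=0)


def position_weight_matrix(al: Alignment) -> PositionWeightMatrix:
    return PositionWeightMatrix(al)


def dominance(pwm: PositionWeightMatrix, y: int) -> float:
    """Relative frequency of the dominant (most frequent) residue in column
    ``y``; the gap symbol is never a candidate."""
    if not (0 <= y < pwm.h):
        raise IndexError(f"column {y} out of range [0, {pwm.h})")
    return float(pwm.column_max()[y])


def similarity(al: Alignment) -> float:
    """Mean column dominance: 1.0 for identical gap-free sequences, tending
    to 1/n for unrelated ones."""
    return float(PositionWeightMatrix(al).column_max().mean())


# ---------------------------------------------------------------------------
# Affine gap penalty
# ---------------------------------------------------------------------------


def _pair_run_stats(gi: np.ndarray, gj: np.ndarray) -> tuple[int, int, int, int]:
    """Run counts and total gap columns for one row pair, after dropping
    columns gapped in both rows.  Returns (runs_i, gaps_i, runs_j, gaps_j)."""
    keep = ~(gi & gj)
    a = gi[keep]
    b = gj[keep]
    out = []
    for g in (a, b):
        if g.size == 0:
            out.extend((0, 0))
            continue
        starts = int(g[0]) + int((g[1:] & ~g[:-1]).sum())
        out.extend((starts, int(g.sum())))
    return tuple(out)  # type: ignore[return-value]


def affine_gap_penalty(al: Alignment, params: AffineGapParams | None = None) -> float:
    """Sum of affine gap costs over all unordered row pairs.

    For each pair, columns gapped in both rows are skipped; every maximal
    remaining gap run of length g in either row costs
    ``gap_open + gap_extend * (g - 1)``.
    """
    params = params or AffineGapParams()
    gm = al.gap_mask()
    total = 0.0
    for i in range(al.n):
        for j in range(i + 1, al.n):
            ri, gi_, rj, gj_ = _pair_run_stats(gm[i], gm[j])
            total += params.gap_open * (ri + rj)
            total += params.gap_extend * ((gi_ - ri) + (gj_ - rj))
    return total


# ---------------------------------------------------------------------------
# Variable (position-specific) gap penalty
# ---------------------------------------------------------------------------


class StaleTablesError(ValueError):
    """Gap-penalty tables no longer match the alignment they score."""


class GapPenaltyTables:
    """Position-specific gap opening (GOT) and extension (GET) tables.

    For every sequence pair a scalar opening cost is derived from the pair's
    lengths, percent identity and the substitution matrix's mean mismatch
    score, and a scalar extension cost from the pair's length ratio.  The
    opening cost is then modulated per column and per sequence by, in order
    of precedence:

    1. *inside an existing gap column*: multiplied by ``0.3 x (fraction of
       sequences without a gap there)`` — gaps are encouraged to stack;
    2. *within 8 columns of a gap column*: multiplied by
       ``2 + 2 x (8 - d) / 8`` where d is the distance in columns (d = 0
       immediately adjacent) — discourages scattering gaps around existing
       ones;
    3. *inside a hydrophilic stretch* (a run of >= ``hydrophilic_run``
       hydrophilic residues in that sequence): halved;
    4. otherwise: multiplied by that residue's gap-propensity factor.

    ``GOP(i, j)[col] = GOT_i[col] + GOT_j[col]`` and ``GEP(i, j)[col]`` is
    the pair's (flat) extension cost.  Under all-ones modulation and unit
    pair scalars these tables reduce the variable penalty exactly to the
    affine one.
    """

    def __init__(
        self,
        h: int,
        pair_open: Mapping[tuple[int, int], float],
        pair_extend: Mapping[tuple[int, int], float],
        factors: np.ndarray,
        residue_table: Mapping[str, float],
        hydrophilic_set: frozenset[str],
    ):
        self.h = h
        self.pair_open = dict(pair_open)
        self.pair_extend = dict(pair_extend)
        self.factors = factors  # (n, h) per-sequence modulation
        self.residue_table = dict(residue_table)
        self.hydrophilic_set = hydrophilic_set
        if (factors < 0).any():
            raise ParameterError("gap table factors must be nonnegative")

    def got(self, i: int) -> np.ndarray:
        """Per-column opening table of sequence i, before pair scaling."""
        return self.factors[i]

    def gop(self, i: int, j: int) -> np.ndarray:
        key = (min(i, j), max(i, j))
        half = self.pair_open[key] / 2.0
        return half * (self.factors[i] + self.factors[j])

    def gep(self, i: int, j: int) -> np.ndarray:
        key = (min(i, j), max(i, j))
        return np.full(self.h, self.pair_extend[key])

    @classmethod
    def constant(
        cls, al: Alignment, gap_open: float, gap_extend: float
    ) -> "GapPenaltyTables":
        """Flat tables under which the variable penalty equals the affine
        penalty with the same parameters (reduction oracle)."""
        pairs = {
            (i, j): gap_open for i in range(al.n) for j in range(i + 1, al.n)
        }
        ext = {k: gap_extend for k in pairs}
        return cls(
            al.h,
            pairs,
            ext,
            np.ones((al.n, al.h)),
            RESIDUE_GAP_TABLE,
            HYDROPHILIC_SET,
        )


def _distance_to_gap_column(has_gap: np.ndarray) -> np.ndarray:
    """Per column, number of columns between it and the nearest gap-bearing
    column (0 = adjacent); gap columns themselves get -1, columns with no
    gap column anywhere get a large sentinel."""
    h = has_gap.size
    big = h + 100
    dist = np.full(h, big)
    # forward sweep
    last = -big
    for c in range(h):
        if has_gap[c]:
            last = c
            continue
        dist[c] = min(dist[c], c - last - 1)
    # backward sweep
    nxt = big * 2
    for c in range(h - 1, -1, -1):
        if has_gap[c]:
            nxt = c
            continue
        dist[c] = min(dist[c], nxt - c - 1)
    dist[has_gap] = -1
    return dist


def _hydrophilic_mask(
    al: Alignment, hydro: frozenset[str], run: int
) -> np.ndarray:
    """(n, h) mask of columns lying inside a hydrophilic stretch of the row:
    >= ``run`` consecutive hydrophilic residues (gap cells never qualify)."""
    mask = np.zeros((al.n, al.h), dtype=bool)
    hydro_bytes = {ord(c) for c in hydro}
    for i in range(al.n):
        row = al.chars[i]
        is_h = np.fromiter((int(b) in hydro_bytes for b in row), bool, al.h)
        # consecutive-run detection over residue positions, gaps break runs
        start = 0
        c = 0
        while c <= al.h:
            if c == al.h or not is_h[c]:
                if c - start >= run:
                    mask[i, start:c] = True
                start = c + 1
            c += 1
    return mask


def _pair_identity(al: Alignment, i: int, j: int) -> float:
    """Percent identity of rows i and j on their residue-residue columns, as
    a fraction clamped into (0, 1]."""
    a, b = al.chars[i], al.chars[j]
    both = (a != _GAP) & (b != _GAP)
    n_comp = int(both.sum())
    if n_comp == 0:
        return 1.0
    pid = float((a[both] == b[both]).sum()) / n_comp
    floor = 1.0 / max(
        1, min(len(al.ungapped(i)), len(al.ungapped(j)))
    )
    return max(pid, floor)


def build_gap_tables(
    al: Alignment,
    base_open: float,
    base_extend: float,
    matrix: SubstitutionMatrix,
    *,
    hydrophilic_set: frozenset[str] = HYDROPHILIC_SET,
    hydrophilic_run: int = HYDROPHILIC_RUN,
    residue_table: Mapping[str, float] | None = None,
    near_gap_window: int = 8,
) -> GapPenaltyTables:
    """Build position-specific gap penalty tables for ``al``.

    Pair-level scalars (natural logs):

    * opening: ``(base_open + log(min(R, T))) * nbar * m`` where R, T are the
      two ungapped lengths, ``nbar`` the positive mean residue mismatch score
      of the matrix and ``m`` the pair's percent identity (fraction);
    * extension: ``base_extend * (1 + |log(R / T)|)``.
    """
    if base_open <= 0 or base_extend <= 0:
        raise ParameterError("base gap penalties must be positive")
    residue_table = dict(residue_table or RESIDUE_GAP_TABLE)
    n, h = al.n, al.h
    lengths = [len(s) for s in al.ungapped_all()]
    if min(lengths) == 0:
        raise ParameterError("zero-length sequence in alignment")
    nbar = matrix.mean_mismatch()

    gm = al.gap_mask()
    has_gap = gm.any(axis=0)
    n_ungapped = (~gm).sum(axis=0)
    dist = _distance_to_gap_column(has_gap)
    hydro = _hydrophilic_mask(al, hydrophilic_set, hydrophilic_run)

    factors = np.ones((n, h))
    inside = has_gap
    near = (~has_gap) & (dist >= 0) & (dist <= near_gap_window)
    near_mult = 2.0 + (near_gap_window - dist) * 2.0 / near_gap_window
    for i in range(n):
        f = factors[i]
        f[inside] = 0.3 * (n_ungapped[inside] / n)
        f[near] = near_mult[near]
        rest = ~(inside | near)
        hcols = rest & hydro[i]
        f[hcols] = 0.5
        other = rest & ~hydro[i]
        for c in np.flatnonzero(other):
            f[c] = residue_table.get(chr(al.chars[i, c]), 1.0)

    pair_open: dict[tuple[int, int], float] = {}
    pair_ext: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            r, t = lengths[i], lengths[j]
            m = _pair_identity(al, i, j)
            pair_open[(i, j)] = (base_open + math.log(min(r, t))) * nbar * m
            pair_ext[(i, j)] = base_extend * (1.0 + abs(math.log(r / t)))
    return GapPenaltyTables(
        h, pair_open, pair_ext, factors, residue_table, hydrophilic_set
    )


def variable_gap_penalty(al: Alignment, tables: GapPenaltyTables) -> float:
    """Position-specific gap penalty: same pairwise run accounting as the
    affine scheme, but each run charges the GOP table at its opening column
    and the GEP table at every additional column."""
    if tables.h != al.h:
        raise StaleTablesError(
            f"tables were built for width {tables.h}, alignment has {al.h}"
        )
    gm = al.gap_mask()
    total = 0.0
    for i in range(al.n):
        for j in range(i + 1, al.n):
            keep = np.flatnonzero(~(gm[i] & gm[j]))
            if keep.size == 0:
                continue
            gop = tables.gop(i, j)
            gep = tables.gep(i, j)
            for g in (gm[i][keep], gm[j][keep]):
                if not g.any():
                    continue
                # maximal runs of True in g, mapped back to original columns
                padded = np.concatenate(([False], g, [False]))
                d = np.diff(padded.astype(np.int8))
                starts = np.flatnonzero(d == 1)
                ends = np.flatnonzero(d == -1)
                for s, e in zip(starts, ends):
                    cols = keep[s:e]
                    total += float(gop[cols[0]]) + float(gep[cols[1:]].sum())
    return total


# ---------------------------------------------------------------------------
# Non-gap percentage
# ---------------------------------------------------------------------------


def non_gap_percentage(al: Alignment, literal: bool = False) -> float:
    """Percentage of alignment cells holding residues (default), in (0, 100].

    With ``literal=True`` returns gaps / residues x 100 instead — the
    reciprocal bookkeeping sometimes quoted for this quantity; the default
    orientation is the one consistent with *maximizing* the objective.
    """
    n_gaps = int(al.gap_mask().sum())
    n_cells = al.n * al.h
    n_res = n_cells - n_gaps
    if literal:
        return 100.0 * n_gaps / n_res
    return 100.0 * n_res / n_cells


# ---------------------------------------------------------------------------
# Combined evaluation
# ---------------------------------------------------------------------------


@dataclass
class ObjectiveConfig:
    """Parameters of the three-objective evaluation.

    ``gap_mode`` selects affine or variable (position-specific) penalties;
    the matrix feeds the variable scheme's pair-level opening scalar.
    """

    gap_mode: str = "affine"  # "affine" | "variable"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    matrix: str = "BLOSUM62"
    ngp_literal: bool = False
    hydrophilic_set: str = "".join(sorted(HYDROPHILIC_SET))
    hydrophilic_run: int = HYDROPHILIC_RUN
    residue_gap_table: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.gap_mode not in ("affine", "variable"):
            raise ParameterError(f"unknown gap_mode {self.gap_mode!r}")
        AffineGapParams(self.gap_open, self.gap_extend)  # validates

    @cached_property
    def matrix_obj(self) -> SubstitutionMatrix:
        return load_substitution_matrix(self.matrix)


def evaluate(al: Alignment, config: ObjectiveConfig | None = None) -> ObjectiveVector:
    """Score an alignment under the configured objective triple.

    Pure function of the alignment and configuration: similarity, gap
    penalty in the selected mode, and non-gap percentage.
    """
    config = config or ObjectiveConfig()
    sm = similarity(al)
    if config.gap_mode == "affine":
        gp = affine_gap_penalty(
            al, AffineGapParams(config.gap_open, config.gap_extend)
        )
    else:
        tables = build_gap_tables(
            al,
            config.gap_open,
            config.gap_extend,
            config.matrix_obj,
            hydrophilic_set=frozenset(config.hydrophilic_set),
            hydrophilic_run=config.hydrophilic_run,
            residue_table=config.residue_gap_table,
        )
        gp = variable_gap_penalty(al, tables)
    ngp = non_gap_percentage(al, literal=config.ngp_literal)
    return ObjectiveVector(sm, gp, ngp)
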