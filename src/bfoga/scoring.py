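"""Benchmark scoring of a test alignment against a reference alignment.

Sum-of-Pairs (SP) is the fraction of residue pairs aligned in the reference
that the test alignment recovers; Total Column Score (TCS) is the fraction
of test columns whose entire residue-ordinal tuple occurs as a column of the
reference.  Both identify residues by their gap-free ordinal within each
sequence, so the scores are independent of alignment coordinates.  A
Wilcoxon matched-pair signed-rank comparison is provided for paired
per-dataset score lists, judged at the conventional 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .msa_core import Alignment, ParameterError

Pair = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class ScoreReport:
    """SP and TCS of a test alignment against a reference."""

    sp: float
    tcs: float
    columns_test: int
    columns_ref: int
    n_sequences: int

    def as_dict(self) -> dict:
        return {
            "SP": self.sp,
            "TCS": self.tcs,
            "columns_test": self.columns_test,
            "columns_ref": self.columns_ref,
            "n_sequences": self.n_sequences,
        }


def _ordinals(al: Alignment) -> np.ndarray:
    """(n, h) array of residue ordinals (gap-free position within the row),
    with -1 at gap cells."""
    gm = al.gap_mask()
    ords = np.cumsum(~gm, axis=1) - 1
    ords[gm] = -1
    return ords


def residue_pair_map(al: Alignment) -> set[Pair]:
    """All aligned residue pairs: ((row a, ordinal), (row b, ordinal)) for
    every column and unordered row pair where both rows hold residues."""
    ords = _ordinals(al)
    pairs: set[Pair] = set()
    n = al.n
    for c in range(al.h):
        col = ords[:, c]
        rows = np.flatnonzero(col >= 0)
        for x in range(len(rows)):
            for y in range(x + 1, len(rows)):
                a, b = int(rows[x]), int(rows[y])
                pairs.add(((a, int(col[a])), (b, int(col[b]))))
    return pairs


def _check_same_sequences(test: Alignment, ref: Alignment) -> None:
    if test.ids != ref.ids or test.ungapped_all() != ref.ungapped_all():
        raise ParameterError(
            "test and reference alignments must contain the same sequences "
            "in the same order"
        )


def sum_of_pairs(test: Alignment, ref: Alignment) -> float:
    """Fraction of the reference's aligned residue pairs recovered by the
    test alignment; 1.0 iff the pair sets coincide on the reference."""
    _check_same_sequences(test, ref)
    ref_pairs = residue_pair_map(ref)
    if not ref_pairs:
        raise ParameterError("reference alignment has no aligned residue pairs")
    test_pairs = residue_pair_map(test)
    return len(test_pairs & ref_pairs) / len(ref_pairs)


def total_column_score(test: Alignment, ref: Alignment) -> float:
    """Fraction of test columns whose full residue-ordinal tuple (including
    the gap pattern) appears as a column of the reference."""
    _check_same_sequences(test, ref)
    to, ro = _ordinals(test), _ordinals(ref)
    ref_cols = {tuple(ro[:, c]) for c in range(ref.h)}
    hits = sum(1 for c in range(test.h) if tuple(to[:, c]) in ref_cols)
    return hits / test.h


def score_report(test: Alignment, ref: Alignment) -> ScoreReport:
    return ScoreReport(
        sp=sum_of_pairs(test, ref),
        tcs=total_column_score(test, ref),
        columns_test=test.h,
        columns_ref=ref.h,
        n_sequences=test.n,
    )


def wilcoxon_compare(
    scores_a: list[float], scores_b: list[float], alpha: float = 0.05
) -> tuple[float, bool]:
    """Two-sided Wilcoxon matched-pair signed-rank test on paired scores.

    Zero differences are dropped (the classical procedure); if every pair is
    tied the result is (1.0, False).  Returns (p_value, p_value < alpha).
    """
    if len(scores_a) != len(scores_b):
        raise ParameterError("paired score lists must have equal length")
    if not scores_a:
        raise ParameterError("empty score lists")
    diffs = np.asarray(scores_a, dtype=float) - np.asarray(scores_b, dtype=float)
    if np.all(diffs == 0):
        return 1.0, False
    res = stats.wilcoxon(
        scores_a, scores_b, zero_method="wilcox", alternative="two-sided"
    )
    p = float(res.pvalue)
    return p, p < alpha
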