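"""Sequence and alignment data model, substitution matrices, and format I/O.

The optimizer moves through a space of *alignments*: rectangular arrays of
residues and gap characters in which stripping the gaps from any row
reproduces the corresponding input sequence exactly.  This module owns that
data model, the FASTA/Clustal readers and writers, the substitution-matrix
loader, and the random gap-padded initialization used to seed the optimizer
population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Align import substitution_matrices as _bp_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("bfoga")

GAP = "-"
_GAP_BYTE = b"-"

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"
# Ambiguity codes accepted on input; scored via the matrix when present,
# otherwise 0, and flagged in the log.
PROTEIN_AMBIGUOUS = "BZXUO*"
DNA_AMBIGUOUS = "N"


class ParseError(ValueError):
    """Raised on malformed input files (FASTA, Clustal, matrix text)."""


class ParameterError(ValueError):
    """Raised on out-of-range user parameters."""


def _alphabet_for(moltype: str) -> str:
    if moltype == "protein":
        return PROTEIN_ALPHABET + PROTEIN_AMBIGUOUS
    if moltype == "dna":
        return DNA_ALPHABET + DNA_AMBIGUOUS
    raise ParameterError(f"unknown moltype {moltype!r}; expected 'protein' or 'dna'")


@dataclass(frozen=True)
class SequenceRecord:
    """An unaligned sequence: identifier, residues, and molecule type.

    Residues are upper-case, gap-free, and restricted to the declared
    alphabet (20 amino acids or 4 nucleotides, plus standard ambiguity
    codes).
    """

    id: str
    residues: str
    moltype: str = "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParseError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if GAP in self.residues or "." in self.residues:
            raise ParseError(f"gap character in unaligned input: sequence {self.id!r}")
        allowed = set(_alphabet_for(self.moltype))
        bad = set(self.residues) - allowed
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.moltype} alphabet: {sorted(bad)}"
            )
        ambiguous = set(self.residues) & set(
            PROTEIN_AMBIGUOUS if self.moltype == "protein" else DNA_AMBIGUOUS
        )
        if ambiguous:
            log.warning(
                "sequence %s contains ambiguity codes %s; they score 0 unless "
                "the substitution matrix defines them",
                self.id,
                sorted(ambiguous),
            )

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """A rectangular multiple alignment over residues and ``'-'`` gaps.

    Invariants enforced on construction:

    * every row has the same length ``h``;
    * no column is entirely gaps (such columns are deleted, with a log
      message, because a gap shared by all sequences carries no signal);
    * stripping gaps from row *i* reproduces the *i*-th input sequence.
    """

    __slots__ = ("ids", "chars")

    def __init__(self, rows: Iterable[tuple[str, str]]):
        rows = [(str(i), str(s).upper().replace(".", GAP)) for i, s in rows]
        if not rows:
            raise ParseError("alignment has no rows")
        lengths = {len(s) for _, s in rows}
        if len(lengths) != 1:
            ragged = [i for i, s in rows if len(s) != len(rows[0][1])]
            raise ParseError(
                "ragged alignment rows (unequal lengths): "
                + ", ".join([rows[0][0]] + ragged)
            )
        self.ids: tuple[str, ...] = tuple(i for i, _ in rows)
        mat = np.array([list(s.encode()) for _, s in rows], dtype=np.uint8)
        if mat.shape[1] == 0:
            raise ParseError("alignment has zero columns")
        all_gap = (mat == _GAP_BYTE[0]).all(axis=0)
        if all_gap.any():
            log.debug("removing %d all-gap column(s)", int(all_gap.sum()))
            mat = mat[:, ~all_gap]
        if mat.shape[1] == 0:
            raise ParseError("alignment is entirely gaps")
        self.chars: np.ndarray = mat
        self.chars.flags.writeable = False

    # -- construction helpers ------------------------------------------------

    @classmethod
    def _from_matrix(cls, ids: tuple[str, ...], mat: np.ndarray) -> "Alignment":
        """Internal fast path: wrap an (n, h) uint8 matrix, purging all-gap
        columns, without re-encoding strings."""
        self = object.__new__(cls)
        all_gap = (mat == _GAP_BYTE[0]).all(axis=0)
        if all_gap.any():
            mat = mat[:, ~all_gap]
        if mat.shape[1] == 0:
            raise ParseError("alignment is entirely gaps")
        self.ids = ids
        self.chars = np.ascontiguousarray(mat)
        self.chars.flags.writeable = False
        return self

    # -- basic properties ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.chars.shape[0]

    @property
    def h(self) -> int:
        """Number of columns (the alignment length)."""
        return self.chars.shape[1]

    def row(self, i: int) -> str:
        return self.chars[i].tobytes().decode()

    @property
    def rows(self) -> list[tuple[str, str]]:
        return [(self.ids[i], self.row(i)) for i in range(self.n)]

    def gap_mask(self) -> np.ndarray:
        """Boolean (n, h) array, True where a cell is a gap."""
        return self.chars == _GAP_BYTE[0]

    def ungapped(self, i: int) -> str:
        return self.row(i).replace(GAP, "")

    def ungapped_all(self) -> list[str]:
        return [self.ungapped(i) for i in range(self.n)]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and self.chars.shape == other.chars.shape
            and bool((self.chars == other.chars).all())
        )

    def __hash__(self) -> int:
        return hash((self.ids, self.chars.tobytes()))

    def __repr__(self) -> str:
        return f"<Alignment n={self.n} h={self.h}>"


def check_round_trip(al: Alignment, records: Sequence[SequenceRecord]) -> None:
    """Assert that stripping gaps from ``al`` reproduces ``records`` exactly.

    This is the central safety invariant of the optimizer: no move, crossover
    or mutation may ever create, destroy or reorder residues.
    """
    if len(records) != al.n:
        raise AssertionError("row count differs from record count")
    for i, rec in enumerate(records):
        got = al.ungapped(i)
        if got != rec.residues:
            raise AssertionError(
                f"gap-strip round trip failed for sequence {rec.id!r}"
            )


# ---------------------------------------------------------------------------
# FASTA / Clustal I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, moltype: str = "protein") -> list[SequenceRecord]:
    """Read unaligned sequences from a FASTA file.

    Raises :class:`ParseError` (naming the offending line where possible) on
    malformed headers, empty sequences, gap characters, or characters outside
    the declared alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    _prevalidate_fasta(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq), moltype))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _prevalidate_fasta(path: Path) -> None:
    """Line-level scan so that errors can name a line number."""
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                if len(s) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            elif not seen_header:
                raise ParseError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an alignment from FASTA or Clustal format.

    All-gap columns are removed (with a warning); ragged rows raise
    :class:`ParseError` listing the offending identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if fmt not in ("fasta", "clustal"):
        raise ParameterError(f"unknown alignment format {fmt!r}")
    if fmt == "fasta":
        # Bio.AlignIO rejects ragged FASTA with an opaque message; read the
        # entries ourselves so the error can name the rows.
        entries: list[tuple[str, str]] = []
        for rec in SeqIO.parse(str(path), "fasta"):
            entries.append((rec.id, str(rec.seq)))
        if not entries:
            raise ParseError(f"{path}: no alignment entries found")
        return Alignment(entries)
    try:
        msa = AlignIO.read(str(path), "clustal")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return Alignment([(rec.id, str(rec.seq)) for rec in msa])


def write_alignment(al: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    if fmt not in ("fasta", "clustal"):
        raise ParameterError(f"unknown alignment format {fmt!r}")
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=i, description="") for i, s in al.rows]
    )
    AlignIO.write(msa, str(path), fmt)


# ---------------------------------------------------------------------------
# Random gap-padded initialization
# ---------------------------------------------------------------------------


def initialize_alignment(
    records: Sequence[SequenceRecord],
    gap_fraction: float = 0.19,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Pad sequences with randomly placed gaps into a rectangular alignment.

    The target width is ``h = ceil(L_max * (1 + gap_fraction))`` where
    ``L_max`` is the longest input length: the number of gaps added to the
    longest sequence stays below 20% of its length, and all shorter
    sequences are padded up to the same width.  Gap positions are drawn from
    ``rng``, so the result is reproducible from a seed.  The default
    ``gap_fraction`` of 0.19 is the setting that performs best in practice.
    """
    if len(records) < 2:
        raise ParameterError("need at least 2 sequences to build an alignment")
    if not (0.0 < gap_fraction <= 0.20):
        raise ParameterError(
            f"gap_fraction must lie in (0, 0.20], got {gap_fraction}"
        )
    rng = np.random.default_rng() if rng is None else rng
    l_max = max(len(r) for r in records)
    h = math.ceil(l_max * (1.0 + gap_fraction))
    gap_sets = [
        set(map(int, rng.choice(h, size=h - len(rec), replace=False)))
        for rec in records
    ]
    # repair columns that happen to be gapped in every row: such columns
    # would be purged on construction and the target width lost
    while True:
        all_gap = set.intersection(*gap_sets) if gap_sets else set()
        if not all_gap:
            break
        c = min(all_gap)
        i = int(rng.integers(0, len(records)))
        candidates = [
            col
            for col in range(h)
            if col not in gap_sets[i]
            and any(col not in gap_sets[j] for j in range(len(records)) if j != i)
        ]
        new_c = int(candidates[int(rng.integers(0, len(candidates)))])
        gap_sets[i].remove(c)
        gap_sets[i].add(new_c)
    rows = []
    for rec, gaps in zip(records, gap_sets):
        row = np.full(h, ord(GAP), dtype=np.uint8)
        residue_pos = np.setdiff1d(np.arange(h), sorted(gaps))
        row[residue_pos] = np.frombuffer(rec.residues.encode(), dtype=np.uint8)
        rows.append(row)
    al = Alignment._from_matrix(tuple(r.id for r in records), np.array(rows))
    check_round_trip(al, records)
    return al


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

BUNDLED_MATRICES = ("BLOSUM30", "BLOSUM45", "BLOSUM62", "BLOSUM80", "PAM100", "PAM200")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair scoring matrix (e.g. BLOSUM62).

    ``scores`` maps ordered residue pairs to integers and is defined for all
    pairs over ``alphabet``; symmetry is validated on construction.
    """

    name: str
    alphabet: tuple[str, ...]
    scores: dict[tuple[str, str], float] = field(repr=False)

    def __post_init__(self) -> None:
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise ParseError(
                        f"matrix {self.name!r} missing pair ({a}, {b})"
                    )
                if self.scores[(a, b)] != self.scores[(b, a)]:
                    raise ParseError(
                        f"matrix {self.name!r} is asymmetric at pair ({a}, {b})"
                    )

    def score(self, a: str, b: str) -> float:
        """Score a residue pair; unknown residues (ambiguity codes absent
        from the matrix) score 0."""
        try:
            return self.scores[(a, b)]
        except KeyError:
            return 0.0

    def mean_mismatch(self) -> float:
        """Mean off-diagonal score, sign-flipped so the result is positive
        (off-diagonal entries of log-odds matrices are negative on average)."""
        vals = [
            self.scores[(a, b)]
            for a in self.alphabet
            for b in self.alphabet
            if a != b
        ]
        return -float(np.mean(vals))

    def as_lookup(self) -> np.ndarray:
        """256x256 float array indexed by character byte values; unknown
        pairs are 0.  Used for vectorized scoring."""
        table = np.zeros((256, 256), dtype=np.float64)
        for (a, b), v in self.scores.items():
            table[ord(a), ord(b)] = v
        return table


def _validate_matrix_file(path: Path) -> None:
    """Reject NCBI matrix files with missing entries, naming the first
    absent pair (lenient parsers silently zero-fill them)."""
    lines = [
        l for l in path.read_text().splitlines()
        if l.strip() and not l.lstrip().startswith("#")
    ]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    header = lines[0].split()
    for line in lines[1:]:
        parts = line.split()
        row, entries = parts[0], parts[1:]
        if len(entries) < len(header):
            raise ParseError(
                f"{path}: matrix missing pair ({row}, {header[len(entries)]})"
            )


def _from_biotite(name: str) -> SubstitutionMatrix:
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    alph = bseq.ProteinSequence.alphabet
    m = balign.SubstitutionMatrix(alph, alph, name)
    letters = [l for l in alph.get_symbols() if l in PROTEIN_ALPHABET]
    scores = {
        (a, b): float(m.get_score(a, b)) for a in letters for b in letters
    }
    return SubstitutionMatrix(name, tuple(letters), scores)


def load_substitution_matrix(name_or_path: str | Path) -> SubstitutionMatrix:
    """Load a substitution matrix by bundled name or from an NCBI-format file.

    Bundled names: BLOSUM30/45/62/80 and PAM100/200 (plus anything else in
    the biotite matrix database).  Files are parsed with Biopython's NCBI
    matrix reader and reduced to the 20-letter protein (or 4-letter DNA)
    alphabet present in the file.
    """
    name = str(name_or_path)
    path = Path(name)
    if path.exists():
        _validate_matrix_file(path)
        try:
            arr = _bp_matrices.read(str(path))
        except Exception as exc:
            raise ParseError(f"{path}: not a valid NCBI matrix file ({exc})") from exc
        letters = [
            l for l in arr.alphabet if l in PROTEIN_ALPHABET or l in DNA_ALPHABET
        ]
        scores = {
            (a, b): float(arr[a, b]) for a in letters for b in letters
        }
        return SubstitutionMatrix(path.stem, tuple(letters), scores)
    try:
        return _from_biotite(name.upper())
    except Exception as exc:
        raise ParameterError(
            f"unknown substitution matrix {name!r}: not a file and not a "
            f"bundled name (bundled: {', '.join(BUNDLED_MATRICES)})"
        ) from exc
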