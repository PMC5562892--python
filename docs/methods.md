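# Methods

## Problem and representation

Given `n >= 3` unaligned sequences over the 20-letter amino-acid alphabet
(or 4-letter nucleotide alphabet), the optimizer searches the space of
rectangular alignments: each row is the corresponding input sequence with
gap characters (`-`) interleaved.  Two invariants are enforced everywhere:

* **Round trip** — stripping gaps from row *i* reproduces input sequence
  *i* exactly.  Search operators only relocate gaps; they can never create,
  destroy or reorder residues.
* **No all-gap columns** — a column gapped in every row carries no signal
  and is deleted immediately on construction, so the alignment width may
  shrink during optimization.

Initial candidates pad every sequence to width
`h = ceil(L_max · (1 + gap_fraction))` with uniformly placed random gaps.
`gap_fraction` defaults to 0.19 and is capped at 0.20 — the number of gaps
added to the longest sequence stays below 20% of its length, and 19% is the
setting that performed best across gap-value sweeps.  Initial draws that
would produce an all-gap column are repaired by relocating one of the
offending gaps, so the target width is exact and deterministic per seed.

## Objectives

Three objectives, compared only by Pareto dominance (the method never
scalarizes):

1. **Similarity (maximize).**  `f(x, y)` is the count of residue `x` in
   column `y` divided by `n`; gaps are counted in the denominator but are
   never candidates for the column's dominant residue.  The column
   dominance is `ce(y) = max_x f(x, y)` and `SM` is its mean over columns.
   This choice makes heavily gapped columns low-dominance, so maximizing
   `SM` implicitly penalizes gap-diluted columns.
2. **Gap penalty (minimize).**  Both modes share pairwise-projection
   semantics: for each unordered row pair, columns gapped in both rows are
   dropped before maximal gap runs are measured.  *Affine* mode charges
   `gap_open + gap_extend·(g−1)` per run of length `g` (defaults 10 and 1,
   in substitution-matrix score units; `gap_open >= gap_extend > 0`
   enforced).  *Variable* mode builds position-specific tables first (next
   section) and charges the per-column opening table at the run's first
   column and the extension table at each additional column.
3. **Non-gap percentage (maximize).**  `NGP = 100 · residue cells / total
   cells`, in (0, 100].  The literal reciprocal convention
   (`100 · gaps / residues`) is available behind `ngp_literal` /
   `--ngp-literal` for reference; the default is the orientation consistent
   with maximization (the two disagree only in bookkeeping, not in which
   alignments are preferred, since one is monotone-decreasing in the other
   at fixed residue content).

### Variable gap penalty tables

For each sequence pair with ungapped lengths `R`, `T`:

* pair opening scalar `(gap_open + ln min(R,T)) · n̄ · m`, where `n̄` is the
  sign-flipped mean off-diagonal score of the substitution matrix (positive
  for the usual log-odds matrices) and `m` the pair's percent identity on
  its residue–residue columns, as a fraction clamped below at
  `1/min(R,T)` so unrelated pairs do not zero the penalty;
* pair extension scalar `gap_extend · (1 + |ln(R/T)|)` (equal-length pairs
  keep the base value).

Each sequence then gets a per-column opening multiplier, rules applied in
strict precedence order:

1. columns where any sequence is gapped: `0.3 · (fraction of ungapped
   sequences)` — existing gaps attract further gaps;
2. columns within 8 of a gap-bearing column (distance 0 = adjacent, ties to
   the nearer side): `2 + 2(8 − d)/8`, i.e. 4 next to a gap falling to 2 at
   distance 8 — discourages scattering new gaps near existing ones;
3. columns inside a hydrophilic stretch (≥ 5 consecutive residues from
   `{G,P,S,N,D,Q,E,K,R}` in that row; both the run length and the set are
   configurable): × 0.5;
4. otherwise: a residue-specific gap-propensity multiplier
   (Pascarella–Argos-style counts as used by ClustalW, normalized to mean
   1; fully overridable).

The pairwise opening cost at a column is the sum of the two sequences'
table values (`GOP = GOT_i + GOT_j`, each carrying half the pair scalar);
the extension cost is the pair's flat extension scalar.  With all
multipliers 1 and unit scalars the variable penalty reduces *exactly* to
the affine penalty — this reduction is the oracle test for the
implementation.  Natural logarithms are used throughout (the convention of
the ClustalW-family heuristics this scheme mirrors).

## Pareto layer

Dominance is the standard strict partial order on the oriented objective
triple.  Fast non-dominated sorting partitions the population into fronts;
crowding distance is the per-front, per-objective normalized neighbor gap
with infinite distance at the boundary individuals; selection is the
binary crowded tournament (size 2 by default, configurable): lower rank
wins, ties by larger crowding, residual ties by coin flip from the run's
generator.  Objectives are compared on native scales for dominance;
normalization happens only inside crowding distance, where it matters.

## Optimizer

Each of `generations` cycles runs, for every dispersal step
(`M_eld`) and reproduction step (`M_rep`):

* `M_ch` chemotaxis sweeps — every bacterium tumbles (samples a random
  move: single-gap shift, block shift, block merge, or block split of a
  gap run in one row, magnitude 1–3 columns), accepts the move if the old
  objectives do not dominate the new ones, and if the new objectives
  strictly dominate the old, *swims*: the same block is shifted again in
  the same direction while each reapplication keeps strictly dominating,
  at most `swim_length` (default 5) extra times;
* then reproduction: bacteria are sorted by health — lexicographically
  (Pareto rank, −crowding, swarming penalty), lower better, ties by index
  — and the healthier half is duplicated over the weaker half.  The
  swarming penalty is the size of the symmetric difference between a
  bacterium's gap-coordinate set and the current fittest bacterium's,
  normalized by their total gap count: bacteria far from the incumbent
  best are demoted, pulling the swarm together.

After the reproduction loop, the GA phase draws
`ceil(chi · J_e / 2)` parent pairs by crowded tournament (`chi = 0.3`),
applies residue-anchored single-point crossover, and mutates each child
with probability `mu = 0.8` (one random move, optionally followed by a
second single-gap relocation, leaving per-row gap counts unchanged).
Elimination–dispersal then swaps in offspring that are jointly ranked
better than the worst population members, and independently re-randomizes
each bacterium with probability `B_eld = 0.25`.  Population size `J_e`
(default 20, must be even) is constant through every phase.

The crossover cut is anchored on a *residue ordinal* of a random row: each
offspring row takes its columns left of the cut from one parent and its
suffix after the same residue count from the other, left-padded with gaps
to a common width.  This guarantees offspring validity without any repair
pass; all-gap junction columns are purged, which makes self-crossover an
exact identity.

An unbounded external elitist archive collects every non-dominated
alignment seen (population or offspring), pruned on insertion.  The
per-generation trace — best similarity, best gap penalty, best NGP on the
archive, plus population front size — is therefore monotone by
construction.  All randomness flows through one `numpy` generator seeded
from the configuration, so runs are bit-for-bit reproducible.

### Moves and invertibility

A move removes gap characters at given columns of one row and reinserts
them at given positions of the resulting row; its inverse simply swaps the
two position sets.  A move whose destination would complete an all-gap
column would not be invertible after the mandatory purge, so the samplers
reject such candidates (cheaply, by trial application).  Chemotaxis
rejection/acceptance never needs the inverse — the pre-move bacterium is
simply retained — but the inverse property is kept exact for all sampled
moves and is property-tested.

## Benchmark scoring

Residues are identified by (row, gap-free ordinal), so scores are
independent of alignment coordinates.  Sum-of-pairs is
`|pairs(test) ∩ pairs(ref)| / |pairs(ref)|` over all column-wise
residue–residue pairs; the total-column score is the fraction of *test*
columns whose full ordinal tuple (including the gap pattern) occurs as a
reference column.  Both are 1.0 exactly when the alignments agree up to
all-gap columns.  Reference core-block masks (as used by curated benchmark
databases) are not modeled; scoring is whole-column.  The Wilcoxon
matched-pair signed-rank comparison drops zero differences, is two-sided,
and uses the exact small-sample null through `scipy.stats.wilcoxon`;
all-tied inputs short-circuit to p = 1.

## Synthetic families

The generator evolves each descendant independently from one random
ancestor (star tree): per-site substitutions at `substitution_rate`
(uniform over the 19 alternatives), and indels opened at `indel_rate` per
site with geometric lengths capped at `max_indel_length` (insertion or
deletion with equal probability).  Because edits are recorded in ancestor
coordinates, the true alignment is assembled exactly: insertions open gap
columns in non-carriers (co-located insertions share left-aligned
columns), deletions leave gaps in the carrier.  A twilight-zone preset
(substitution rate 0.55, expected pairwise identity ≈ 22% for proteins)
stresses the low-identity regime.  The generator deliberately omits
position-dependent rates, matrix-biased substitutions and realistic
phylogenies: passing tests demonstrate the optimizer's mechanics and
scoring on families with a known truth, not performance on real protein
families.

## Study conditions and problem sizes

Defaults mirror the method's stated operating point: swim length 5,
crossover fraction 0.3, mutation rate 0.8, 19% initialization gaps,
500 generations, BLOSUM62.  The nesting counts (`M_eld = 2`, `M_rep = 4`,
`M_ch = 10`) are exposed placeholders rather than canonical values.  The
packaged end-to-end runs (test suite and acceptance script) use a compact
operating point chosen once as this package's study condition: the
standard synthetic family (6 sequences, 120-residue ancestor, 15%
substitutions, 2% indel rate), population 20, 50 generations with nesting
`M_eld = 1`, `M_rep = 2`, `M_ch = 5`, affine objectives, and a reduced
repeat-run protocol (8 short seeded runs) for the paired significance
check.

## Known limitations

* The variable-penalty pair scalars are recomputed from the *current*
  alignment's pairwise identity, so the variable objective is
  state-dependent in a way the affine objective is not (and roughly an
  order of magnitude slower to evaluate).
* `GEP(i, j)` depends only on the pair's length ratio, not on position —
  the extension table is flat by design.
* The swarming penalty compares gap layouts by coordinates, which is crude
  when alignments have drifted to different widths.
* No progressive-alignment seeding: initial populations are random
  paddings, so absolute SP/TCS on hard families is modest at the packaged
  problem sizes; the guarantees tested are improvement, monotonicity and
  reproducibility, not parity with mature progressive aligners.
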