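"""Hybrid bacterial-foraging / genetic optimizer over alignment space.

Each *bacterium* carries one candidate alignment.  A generation interleaves:

* **chemotaxis** — every bacterium tumbles (samples a random discrete gap
  move), keeps the move if it is non-worsening under Pareto dominance, and
  *swims* (reapplies the same move in the same direction) while it keeps
  strictly improving, up to the swim length;
* **swarming** — a penalty proportional to each bacterium's gap-layout
  distance from the current fittest bacterium is added to its health, pulling
  the population toward the incumbent best;
* **reproduction** — the healthier half of the population is duplicated over
  the weaker half (population size constant);
* **a GA phase** — crowded-tournament parent selection, residue-anchored
  single-point crossover, and move-based mutation produce an offspring pool;
* **elimination–dispersal** — offspring that beat the worst bacteria replace
  them, then each bacterium is independently re-randomized with a small
  probability to escape stagnation.

Because alignments are discrete objects, the continuous chemotactic step is
realized as a random *Move*: a relocation of gap characters within one row
(single-gap shift, whole-block shift, block merge, or block split).  Moves
never create, destroy or reorder residues, so the gap-strip round trip is an
invariant of the whole search.  An external elitist archive keeps every
non-dominated alignment found, making the reported front monotone over
generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .msa_core import (
    Alignment,
    ParameterError,
    SequenceRecord,
    check_round_trip,
    initialize_alignment,
)
from .objectives import ObjectiveConfig, ObjectiveVector, evaluate
from .pareto import RankedIndividual, crowded_tournament, dominates, rank_population

_GAP = ord("-")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class BFOGAConfig:
    """All optimizer knobs.

    ``pop_size`` (J_e) must be even so reproduction can split the population
    into halves.  ``chemotaxis_steps`` / ``reproduction_steps`` /
    ``dispersal_steps`` set the classical nesting of sweeps inside each
    generation; ``swim_length`` bounds how often an improving move is
    reapplied; ``crossover_fraction`` (chi) and ``mutation_rate`` (mu) drive
    the GA phase; ``dispersal_prob`` (B_eld) is the per-bacterium
    re-randomization probability.
    """

    pop_size: int = 20                 # J_e
    chemotaxis_steps: int = 10         # M_ch
    swim_length: int = 5               # M_se
    reproduction_steps: int = 4        # M_rep
    dispersal_steps: int = 2           # M_eld
    dispersal_prob: float = 0.25       # B_eld
    crossover_fraction: float = 0.3    # chi
    mutation_rate: float = 0.8         # mu
    generations: int = 500
    tournament_k: int = 2
    gap_fraction: float = 0.19
    seed: int = 0
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    validate: bool = False  # assert invariants after every phase

    def __post_init__(self) -> None:
        if self.pop_size < 2 or self.pop_size % 2:
            raise ParameterError("pop_size must be an even integer >= 2")
        for name in ("chemotaxis_steps", "reproduction_steps", "dispersal_steps"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.swim_length < 0:
            raise ParameterError("swim_length must be >= 0")
        if self.generations < 0:
            raise ParameterError("generations must be >= 0")
        for name in ("dispersal_prob", "crossover_fraction", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.gap_fraction <= 0.20):
            raise ParameterError("gap_fraction must lie in (0, 0.20]")
        if self.tournament_k < 1:
            raise ParameterError("tournament_k must be >= 1")


# ---------------------------------------------------------------------------
# Moves: discrete chemotactic steps
# ---------------------------------------------------------------------------

MOVE_KINDS = ("gap_shift", "gap_block_shift", "gap_merge", "gap_split")


@dataclass(frozen=True)
class Move:
    """Relocation of gap characters within one row.

    ``remove_cols`` are gap positions in the *current* alignment's
    coordinates; ``insert_cols`` are the positions the relocated gaps occupy
    in the *resulting* row.  The inverse move swaps the two, so applying a
    move and then its inverse restores the original alignment (provided the
    move did not trigger the all-gap-column purge, which samplers avoid).
    """

    kind: str
    row: int
    remove_cols: tuple[int, ...]
    insert_cols: tuple[int, ...]
    direction: str  # "left" | "right"
    magnitude: int

    def apply(self, al: Alignment) -> Alignment:
        row = al.chars[self.row]
        if any(row[c] != _GAP for c in self.remove_cols):
            raise ParameterError("move removes a non-gap cell")
        keep_mask = np.ones(al.h, dtype=bool)
        keep_mask[list(self.remove_cols)] = False
        kept = row[keep_mask]
        new_row = np.empty(al.h, dtype=np.uint8)
        ins_mask = np.zeros(al.h, dtype=bool)
        ins_mask[list(self.insert_cols)] = True
        new_row[ins_mask] = _GAP
        new_row[~ins_mask] = kept
        mat = al.chars.copy()
        mat[self.row] = new_row
        return Alignment._from_matrix(al.ids, mat)

    def inverse(self) -> "Move":
        return Move(
            self.kind,
            self.row,
            self.insert_cols,
            self.remove_cols,
            "left" if self.direction == "right" else "right",
            self.magnitude,
        )


def _gap_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal gap runs of a row as half-open (start, end) pairs."""
    g = row == _GAP
    if not g.any():
        return []
    padded = np.concatenate(([False], g, [False]))
    d = np.diff(padded.astype(np.int8))
    return list(
        zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist())
    )


def _would_purge(al: Alignment, move: Move) -> bool:
    """True if applying ``move`` creates an all-gap column (which the
    alignment constructor would immediately delete, shrinking the width)."""
    return move.apply(al).h != al.h


def _block_shift_move(
    al: Alignment,
    row: int,
    block: tuple[int, int],
    direction: str,
    magnitude: int,
    kind: str = "gap_block_shift",
) -> Move | None:
    s, e = block
    length = e - s
    step = -magnitude if direction == "left" else magnitude
    t = s + step
    t = max(0, min(al.h - length, t))
    if t == s:
        return None
    mv = Move(
        kind,
        row,
        tuple(range(s, e)),
        tuple(range(t, t + length)),
        direction,
        magnitude,
    )
    if _would_purge(al, mv):
        return None
    return mv


def sample_move(
    al: Alignment, rng: np.random.Generator, max_tries: int = 20
) -> Move | None:
    """Uniformly sample a valid gap move (the 'tumble' direction).

    Kind, row, direction and magnitude are drawn independently of any
    previous move; candidates that would trigger the all-gap purge or are
    no-ops are rejected and resampled, up to ``max_tries``.
    """
    for _ in range(max_tries):
        row = int(rng.integers(0, al.n))
        runs = _gap_runs(al.chars[row])
        if not runs:
            continue
        kind = MOVE_KINDS[int(rng.integers(0, len(MOVE_KINDS)))]
        direction = "left" if rng.random() < 0.5 else "right"
        magnitude = int(rng.integers(1, 4))
        mv: Move | None = None
        if kind == "gap_shift":
            s, e = runs[int(rng.integers(0, len(runs)))]
            c = int(rng.integers(s, e))
            mv = _block_shift_move(
                al, row, (c, c + 1), direction, magnitude, "gap_shift"
            )
        elif kind == "gap_block_shift":
            blk = runs[int(rng.integers(0, len(runs)))]
            mv = _block_shift_move(al, row, blk, direction, magnitude)
        elif kind == "gap_merge":
            if len(runs) < 2:
                continue
            ia, ib = rng.choice(len(runs), size=2, replace=False)
            a, b = runs[int(ia)], runs[int(ib)]
            la = a[1] - a[0]
            # destination: pack run a against run b (after removal of a)
            shift = la if a[0] < b[0] else 0
            t = b[1] - shift if a[0] < b[0] else b[0]
            t = max(0, min(al.h - la, t))
            mv = Move(
                "gap_merge",
                row,
                tuple(range(a[0], a[1])),
                tuple(range(t, t + la)),
                "left" if a[0] > b[0] else "right",
                abs(a[0] - b[0]),
            )
            if _would_purge(al, mv):
                mv = None
        elif kind == "gap_split":
            wide = [r for r in runs if r[1] - r[0] >= 2]
            if not wide:
                continue
            s, e = wide[int(rng.integers(0, len(wide)))]
            k = (e - s) // 2
            dist = int(rng.integers(2, 7))
            if direction == "right":
                mv = _block_shift_move(
                    al, row, (e - k, e), "right", dist, "gap_split"
                )
            else:
                mv = _block_shift_move(
                    al, row, (s, s + k), "left", dist, "gap_split"
                )
        if mv is not None:
            return mv
    return None


def _successor_move(al: Alignment, mv: Move) -> Move | None:
    """The same move one step further: shift the relocated block again by the
    same magnitude in the same direction.  Merges do not continue."""
    if mv.kind == "gap_merge":
        return None
    cols = sorted(mv.insert_cols)
    block = (cols[0], cols[-1] + 1)
    return _block_shift_move(al, mv.row, block, mv.direction, mv.magnitude, mv.kind)


# ---------------------------------------------------------------------------
# Bacteria
# ---------------------------------------------------------------------------


@dataclass
class Bacterium:
    """One candidate alignment plus optimizer bookkeeping."""

    alignment: Alignment
    objectives: ObjectiveVector
    rank: int = 0
    crowding: float = 0.0
    swarm_penalty: float = 0.0
    last_move: Move | None = None

    def health_key(self) -> tuple[float, float, float]:
        """Lexicographic health, lower is better: Pareto rank, then
        negative crowding, then the swarming penalty."""
        return (float(self.rank), -self.crowding, self.swarm_penalty)


def _new_bacterium(
    records: Sequence[SequenceRecord],
    cfg: BFOGAConfig,
    rng: np.random.Generator,
) -> Bacterium:
    al = initialize_alignment(records, cfg.gap_fraction, rng)
    return Bacterium(al, evaluate(al, cfg.objective))


def _rank_in_place(pop: list[Bacterium]) -> list[RankedIndividual]:
    ranked = rank_population([b.objectives for b in pop])
    for b, r in zip(pop, ranked):
        b.rank, b.crowding = r.rank, r.crowding
    return ranked


# ---------------------------------------------------------------------------
# Phases
# ---------------------------------------------------------------------------


def tumble(b: Bacterium, rng: np.random.Generator) -> Move | None:
    """Sample a random move for this bacterium (direction of the tumble)."""
    return sample_move(b.alignment, rng)


def chemotaxis_step(
    b: Bacterium, cfg: BFOGAConfig, rng: np.random.Generator
) -> Bacterium:
    """One tumble-and-swim: accept the move if non-worsening, and while it
    strictly improves (dominates the previous objectives) reapply it in the
    same direction up to ``swim_length`` more times."""
    mv = tumble(b, rng)
    if mv is None:
        return b
    new_al = mv.apply(b.alignment)
    new_obj = evaluate(new_al, cfg.objective)
    if dominates(new_obj, b.objectives):
        cur_al, cur_obj = new_al, new_obj
        cur_mv = mv
        for _ in range(cfg.swim_length):
            nxt = _successor_move(cur_al, cur_mv)
            if nxt is None:
                break
            cand_al = nxt.apply(cur_al)
            cand_obj = evaluate(cand_al, cfg.objective)
            if not dominates(cand_obj, cur_obj):
                break
            cur_al, cur_obj, cur_mv = cand_al, cand_obj, nxt
        return replace(b, alignment=cur_al, objectives=cur_obj, last_move=cur_mv)
    if not dominates(b.objectives, new_obj):
        # sideways step: keep the tumble result
        return replace(b, alignment=new_al, objectives=new_obj, last_move=mv)
    return b  # worsening move: revert


def gap_coordinates(al: Alignment) -> set[tuple[int, int]]:
    """Set of (row, column) gap cells of an alignment."""
    gm = al.gap_mask()
    rows, cols = np.nonzero(gm)
    return set(zip(rows.tolist(), cols.tolist()))


def gap_displacement(a: Alignment, b: Alignment) -> int:
    """Size of the symmetric difference of the two gap-coordinate sets."""
    return len(gap_coordinates(a) ^ gap_coordinates(b))


def swarming_penalty(pop: list[Bacterium]) -> list[float]:
    """Distance of each bacterium's gap layout from the fittest bacterium
    (rank 0, largest crowding), normalized by the total gap count of the two
    alignments.  The fittest bacterium itself gets 0."""
    if not pop:
        return []
    best = min(
        range(len(pop)),
        key=lambda i: (pop[i].rank, -pop[i].crowding, i),
    )
    ref = gap_coordinates(pop[best].alignment)
    out = []
    for i, b in enumerate(pop):
        if i == best:
            out.append(0.0)
            continue
        mine = gap_coordinates(b.alignment)
        denom = max(1, len(ref) + len(mine))
        out.append(len(ref ^ mine) / denom)
    return out


def reproduction(pop: list[Bacterium]) -> list[Bacterium]:
    """Duplicate the healthier half of the population over the weaker half.

    Health ties are broken by crowding (via the health key) and then by
    population index, so the outcome is deterministic.  Population size is
    unchanged and must be even.
    """
    if len(pop) % 2:
        raise ParameterError("reproduction requires an even population size")
    order = sorted(range(len(pop)), key=lambda i: (pop[i].health_key(), i))
    top = order[: len(pop) // 2]
    out = []
    for i in top:
        out.append(pop[i])
    for i in top:
        out.append(replace(pop[i]))
    return out


def select_parents(
    pop: list[Bacterium], cfg: BFOGAConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """ceil(chi * J_e / 2) parent pairs via crowded tournament selection."""
    n_pairs = math.ceil(cfg.crossover_fraction * cfg.pop_size / 2.0)
    ranked = [
        RankedIndividual(i, b.objectives, b.rank, b.crowding)
        for i, b in enumerate(pop)
    ]
    pairs = []
    for _ in range(n_pairs):
        p1 = crowded_tournament(ranked, cfg.tournament_k, rng)
        p2 = crowded_tournament(ranked, cfg.tournament_k, rng)
        pairs.append((p1, p2))
    return pairs


def _residue_prefix_counts(al: Alignment) -> np.ndarray:
    """(n, h+1) cumulative residue counts: entry [i, c] = residues of row i
    strictly left of column c."""
    res = (al.chars != _GAP).astype(np.int64)
    return np.concatenate(
        [np.zeros((al.n, 1), dtype=np.int64), np.cumsum(res, axis=1)], axis=1
    )


def _column_after_residue(al: Alignment, row: int, ordinal: int) -> int:
    """Column index just after the ``ordinal``-th residue (1-based count) of
    ``row``; 0 when ordinal is 0."""
    if ordinal == 0:
        return 0
    res_cols = np.flatnonzero(al.chars[row] != _GAP)
    return int(res_cols[ordinal - 1]) + 1


def crossover(
    a: Alignment, b: Alignment, rng: np.random.Generator
) -> tuple[Alignment, Alignment]:
    """Residue-anchored single-point crossover.

    A random row and residue ordinal define the cut.  Each offspring takes
    the column block left of the cut from one parent and, per row, the
    suffix after that row's own residue-count boundary from the other
    parent; suffixes are left-padded with gaps to a common width so no
    residue is moved relative to its donor parent.  All-gap columns arising
    at the junction are purged, so crossing an alignment with itself yields
    the alignment back.
    """
    if a.ids != b.ids or a.ungapped_all() != b.ungapped_all():
        raise ParameterError("crossover parents must carry the same sequences")
    row = int(rng.integers(0, a.n))
    n_res = len(a.ungapped(row))
    p = int(rng.integers(0, n_res + 1))

    def splice(left: Alignment, right: Alignment) -> Alignment:
        cut = _column_after_residue(left, row, p)
        prefix_counts = _residue_prefix_counts(left)[:, cut]
        d = [
            _column_after_residue(right, i, int(prefix_counts[i]))
            for i in range(left.n)
        ]
        tail_len = right.h - min(d)
        rows = []
        for i in range(left.n):
            head = left.chars[i, :cut].tobytes().decode()
            tail = right.chars[i, d[i]:].tobytes().decode()
            pad = "-" * (tail_len - len(tail))
            rows.append((left.ids[i], head + pad + tail))
        return Alignment(rows)

    return splice(a, b), splice(b, a)


def mutate(al: Alignment, mu: float, rng: np.random.Generator) -> Alignment:
    """With probability ``mu`` apply one random move, optionally followed by
    a second single-gap relocation in one row (a delete-and-insert pair that
    leaves the per-row gap count unchanged); otherwise return the input."""
    if not (0.0 <= mu <= 1.0):
        raise ParameterError("mutation rate must lie in [0, 1]")
    if rng.random() >= mu:
        return al
    mv = sample_move(al, rng)
    out = mv.apply(al) if mv is not None else al
    if rng.random() < 0.5:
        mv2 = sample_move(out, rng)
        if mv2 is not None:
            out = mv2.apply(out)
    return out


def eliminate_disperse(
    pop: list[Bacterium],
    cfg: BFOGAConfig,
    rng: np.random.Generator,
    offspring_pool: list[Bacterium],
    records: Sequence[SequenceRecord],
) -> list[Bacterium]:
    """Replace worst bacteria by better offspring, then re-randomize each
    surviving bacterium with probability ``dispersal_prob``."""
    pop = list(pop)
    if offspring_pool:
        merged = [b.objectives for b in pop + offspring_pool]
        ranked = rank_population(merged)
        keys = [(r.rank, -r.crowding) for r in ranked]
        pop_keys = keys[: len(pop)]
        off_keys = keys[len(pop):]
        off_order = sorted(range(len(offspring_pool)), key=lambda i: (off_keys[i], i))
        for oi in off_order:
            worst = max(range(len(pop)), key=lambda i: (pop_keys[i], i))
            better = off_keys[oi] < pop_keys[worst] or dominates(
                offspring_pool[oi].objectives, pop[worst].objectives
            )
            if not better:
                break
            pop[worst] = offspring_pool[oi]
            pop_keys[worst] = off_keys[oi]
    for i in range(len(pop)):
        if rng.random() < cfg.dispersal_prob:
            pop[i] = _new_bacterium(records, cfg, rng)
    return pop


# ---------------------------------------------------------------------------
# Elitist archive and full run
# ---------------------------------------------------------------------------


class ParetoArchive:
    """Unbounded external archive of non-dominated (alignment, objectives)
    pairs, pruned on every insertion."""

    def __init__(self) -> None:
        self.entries: list[tuple[Alignment, ObjectiveVector]] = []

    def add(self, al: Alignment, obj: ObjectiveVector) -> None:
        for _, o in self.entries:
            if dominates(o, obj) or o == obj:
                return
        self.entries = [
            (a, o) for a, o in self.entries if not dominates(obj, o)
        ]
        self.entries.append((al, obj))

    def update(self, pop: Sequence[Bacterium]) -> None:
        for b in pop:
            self.add(b.alignment, b.objectives)

    def best(self) -> dict[str, float]:
        sms = [o.sm for _, o in self.entries]
        gps = [o.gap_penalty for _, o in self.entries]
        ngps = [o.ngp for _, o in self.entries]
        return {
            "best_sm": max(sms),
            "best_gap_penalty": min(gps),
            "best_ngp": max(ngps),
        }

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class OptimizationResult:
    """Final archive, per-generation trace, and run bookkeeping."""

    archive: list[tuple[Alignment, ObjectiveVector]]
    trace: list[dict]
    initial_population: list[tuple[Alignment, ObjectiveVector]]
    config: BFOGAConfig

    def best_alignment(self) -> Alignment:
        """Best-compromise member of the final front: the entry with the
        largest crowding distance (ties to the first)."""
        from .pareto import crowding_distance

        objs = [o for _, o in self.archive]
        dists = crowding_distance(objs)
        finite = [d if not np.isinf(d) else np.inf for d in dists]
        idx = int(np.argmax(finite))
        return self.archive[idx][0]


def run(
    records: Sequence[SequenceRecord],
    cfg: BFOGAConfig,
    progress: Callable[[int, dict], None] | None = None,
) -> OptimizationResult:
    """Run the full optimizer for ``cfg.generations`` cycles.

    Fully reproducible from ``cfg.seed``.  With ``cfg.validate`` set, the
    gap-strip round trip and the constant population size are asserted after
    every phase of every generation.
    """
    if len(records) < 3:
        raise ParameterError("multiple sequence alignment needs >= 3 sequences")
    rng = np.random.default_rng(cfg.seed)
    pop = [_new_bacterium(records, cfg, rng) for _ in range(cfg.pop_size)]
    archive = ParetoArchive()
    _rank_in_place(pop)
    archive.update(pop)
    initial = [(b.alignment, b.objectives) for b in pop]

    def check(phase: str) -> None:
        if not cfg.validate:
            return
        assert len(pop) == cfg.pop_size, f"population size broke in {phase}"
        for b in pop:
            check_round_trip(b.alignment, records)

    trace: list[dict] = []
    for gen in range(cfg.generations):
        for _ in range(cfg.dispersal_steps):
            for _ in range(cfg.reproduction_steps):
                for _ in range(cfg.chemotaxis_steps):
                    _rank_in_place(pop)
                    for i, pen in enumerate(swarming_penalty(pop)):
                        pop[i].swarm_penalty = pen
                    pop = [chemotaxis_step(b, cfg, rng) for b in pop]
                    check("chemotaxis")
                archive.update(pop)
                _rank_in_place(pop)
                for i, pen in enumerate(swarming_penalty(pop)):
                    pop[i].swarm_penalty = pen
                pop = reproduction(pop)
                check("reproduction")
            _rank_in_place(pop)
            offspring: list[Bacterium] = []
            for i, j in select_parents(pop, cfg, rng):
                c1, c2 = crossover(pop[i].alignment, pop[j].alignment, rng)
                for child in (c1, c2):
                    child = mutate(child, cfg.mutation_rate, rng)
                    if cfg.validate:
                        check_round_trip(child, records)
                    offspring.append(
                        Bacterium(child, evaluate(child, cfg.objective))
                    )
            archive.update(offspring)
            pop = eliminate_disperse(pop, cfg, rng, offspring, records)
            check("elimination-dispersal")
            archive.update(pop)
        _rank_in_place(pop)
        front_size = sum(1 for b in pop if b.rank == 0)
        row = {
            "generation": gen,
            **archive.best(),
            "front_size": front_size,
            "archive_size": len(archive),
        }
        trace.append(row)
        if progress is not None:
            progress(gen, row)
    return OptimizationResult(list(archive.entries), trace, initial, cfg)
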