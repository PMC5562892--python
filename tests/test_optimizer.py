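"""Optimizer mechanics: moves, phases, and whole-run invariants."""

import math

import numpy as np
import pytest

from bfoga import (
    Alignment,
    BFOGAConfig,
    Bacterium,
    ObjectiveConfig,
    ParameterError,
    SequenceRecord,
    check_round_trip,
    chemotaxis_step,
    crossover,
    dominates,
    eliminate_disperse,
    evaluate,
    initialize_alignment,
    mutate,
    reproduction,
    run,
    select_parents,
    swarming_penalty,
    tumble,
)
from bfoga.optimizer import (
    ParetoArchive,
    _successor_move,
    gap_displacement,
    sample_move,
)


def small_cfg(**kw):
    kw.setdefault("pop_size", 8)
    kw.setdefault("generations", 2)
    kw.setdefault("chemotaxis_steps", 2)
    kw.setdefault("reproduction_steps", 1)
    kw.setdefault("dispersal_steps", 1)
    kw.setdefault("seed", 3)
    kw.setdefault("validate", True)
    return BFOGAConfig(**kw)


@pytest.fixture()
def padded(toy_records, rng):
    return initialize_alignment(toy_records, 0.19, rng)


class TestMoves:
    def test_sampled_move_applies_and_inverts(self, padded, toy_records):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mv = sample_move(padded, rng)
            assert mv is not None
            moved = mv.apply(padded)
            check_round_trip(moved, toy_records)
            assert moved.h == padded.h
            assert mv.inverse().apply(moved) == padded

    def test_fixed_seed_fixed_move(self, padded):
        m1 = sample_move(padded, np.random.default_rng(9))
        m2 = sample_move(padded, np.random.default_rng(9))
        assert m1 == m2

    def test_direction_symmetry(self, toy_records):
        # central gaps so that left/right are equally available
        al = Alignment([("a", "ACD--EFG"), ("b", "AC--DEFG"), ("c", "A--CDEFG")])
        rng = np.random.default_rng(1)
        dirs = [sample_move(al, rng).direction for _ in range(10_000)]
        frac_left = dirs.count("left") / len(dirs)
        assert abs(frac_left - 0.5) < 0.02

    def test_successor_continues_in_same_direction(self, padded):
        rng = np.random.default_rng(4)
        mv = sample_move(padded, rng)
        moved = mv.apply(padded)
        nxt = _successor_move(moved, mv)
        if nxt is not None:
            assert nxt.direction == mv.direction
            assert nxt.magnitude == mv.magnitude
            assert nxt.kind == mv.kind


class TestChemotaxis:
    def test_swim_follows_an_improving_gradient(self):
        # row c's gap block is misaligned; shifting it left one column at a
        # time strictly improves similarity until it matches the others
        rows = [
            ("a", "WWWW----CCCC"),
            ("b", "WWWW----CCCC"),
            ("c", "WWWWCCCC----"),
        ]
        al = Alignment(rows)
        from bfoga.optimizer import Move

        mv = Move("gap_block_shift", 2, (8, 9, 10, 11), (4, 5, 6, 7), "left", 4)
        out = mv.apply(al)
        assert evaluate(out).sm == 1.0
        assert dominates(evaluate(out), evaluate(al))

    def test_step_never_worsens(self, toy_records):
        cfg = small_cfg()
        rng = np.random.default_rng(5)
        al = initialize_alignment(toy_records, 0.19, rng)
        b = Bacterium(al, evaluate(al, cfg.objective))
        for _ in range(30):
            b2 = chemotaxis_step(b, cfg, rng)
            assert not dominates(b.objectives, b2.objectives)
            check_round_trip(b2.alignment, toy_records)
            b = b2

    def test_zero_swim_length_single_move(self, toy_records):
        cfg = small_cfg(swim_length=0)
        rng = np.random.default_rng(6)
        al = initialize_alignment(toy_records, 0.19, rng)
        b = Bacterium(al, evaluate(al, cfg.objective))
        b2 = chemotaxis_step(b, cfg, rng)
        # with no swimming the result differs from the input by at most one
        # applied move: the gap layouts differ in at most 2 * magnitude cells
        assert gap_displacement(b.alignment, b2.alignment) <= 2 * 4

    def test_tumble_is_seed_deterministic(self, toy_records, rng):
        al = initialize_alignment(toy_records, 0.19, rng)
        b = Bacterium(al, evaluate(al))
        assert tumble(b, np.random.default_rng(2)) == tumble(
            b, np.random.default_rng(2)
        )


class TestSwarming:
    def test_identical_to_fittest_is_zero(self, padded):
        obj = evaluate(padded)
        pop = [Bacterium(padded, obj), Bacterium(padded, obj)]
        pop[0].rank, pop[1].rank = 0, 0
        pens = swarming_penalty(pop)
        assert pens == [0.0, 0.0]

    def test_symmetric_distance(self, toy_records):
        a = initialize_alignment(toy_records, 0.19, np.random.default_rng(1))
        b = initialize_alignment(toy_records, 0.19, np.random.default_rng(2))
        assert gap_displacement(a, b) == gap_displacement(b, a)

    def test_disjoint_displacement_adds(self):
        base = Alignment([("a", "-WWCC"), ("b", "WWCC-")])
        one = Alignment([("a", "W-WCC"), ("b", "WWCC-")])
        two = Alignment([("a", "W-WCC"), ("b", "WWC-C")])
        d1 = gap_displacement(base, one)
        d2 = gap_displacement(base, two)
        assert d2 == 2 * d1


class TestReproduction:
    def test_healthier_half_duplicated(self, padded):
        obj = evaluate(padded)
        pop = [Bacterium(padded, obj) for _ in range(4)]
        for i, b in enumerate(pop):
            b.rank = i  # distinct health, 0 best
        out = reproduction(pop)
        assert len(out) == 4
        assert [b.rank for b in out] == [0, 1, 0, 1]

    def test_odd_population_rejected(self, padded):
        obj = evaluate(padded)
        with pytest.raises(ParameterError):
            reproduction([Bacterium(padded, obj)] * 3)


class TestSelection:
    def _pop(self, al, n):
        obj = evaluate(al)
        pop = [Bacterium(al, obj) for _ in range(n)]
        for b in pop:
            b.rank = 0
        return pop

    def test_pair_count_from_crossover_fraction(self, padded):
        cfg = BFOGAConfig(pop_size=20, crossover_fraction=0.3)
        pairs = select_parents(self._pop(padded, 20), cfg, np.random.default_rng(0))
        assert len(pairs) == 3 == math.ceil(0.3 * 20 / 2)

    def test_zero_fraction_no_pairs(self, padded):
        cfg = BFOGAConfig(pop_size=20, crossover_fraction=0.0)
        assert select_parents(self._pop(padded, 20), cfg, np.random.default_rng(0)) == []

    def test_seeded_reproducibility(self, padded):
        cfg = BFOGAConfig(pop_size=20, crossover_fraction=0.5)
        pop = self._pop(padded, 20)
        a = select_parents(pop, cfg, np.random.default_rng(8))
        b = select_parents(pop, cfg, np.random.default_rng(8))
        assert a == b


class _FakeRng:
    """Minimal stand-in driving crossover to a chosen row / cut point."""

    def __init__(self, values):
        self.values = list(values)

    def integers(self, lo, hi):
        return self.values.pop(0)


class TestCrossover:
    def test_self_cross_is_identity(self, padded):
        for seed in range(5):
            c1, c2 = crossover(padded, padded, np.random.default_rng(seed))
            assert c1 == padded and c2 == padded

    def test_round_trip_preserved(self, toy_records):
        a = initialize_alignment(toy_records, 0.19, np.random.default_rng(1))
        b = initialize_alignment(toy_records, 0.19, np.random.default_rng(2))
        for seed in range(10):
            c1, c2 = crossover(a, b, np.random.default_rng(seed))
            check_round_trip(c1, toy_records)
            check_round_trip(c2, toy_records)

    def test_cut_at_zero_swaps_parents(self, toy_records):
        a = initialize_alignment(toy_records, 0.19, np.random.default_rng(1))
        b = initialize_alignment(toy_records, 0.19, np.random.default_rng(2))
        c1, c2 = crossover(a, b, _FakeRng([0, 0]))
        assert c1 == b and c2 == a

    def test_mismatched_parents_rejected(self, padded):
        other = Alignment([("x", "WW"), ("y", "WW"), ("z", "WW")])
        with pytest.raises(ParameterError):
            crossover(padded, other, np.random.default_rng(0))


class TestMutation:
    def test_zero_rate_is_identity(self, padded):
        assert mutate(padded, 0.0, np.random.default_rng(0)) == padded

    def test_full_rate_deterministic(self, padded, toy_records):
        a = mutate(padded, 1.0, np.random.default_rng(3))
        b = mutate(padded, 1.0, np.random.default_rng(3))
        assert a == b
        check_round_trip(a, toy_records)

    def test_gap_count_per_row_conserved(self, padded):
        out = mutate(padded, 1.0, np.random.default_rng(4))
        if out.h == padded.h:  # no purge: relocations conserve gap counts
            for i in range(padded.n):
                assert out.row(i).count("-") == padded.row(i).count("-")


class TestEliminationDispersal:
    def test_no_dispersal_empty_pool_is_identity(self, toy_records, padded):
        cfg = small_cfg(dispersal_prob=0.0)
        obj = evaluate(padded, cfg.objective)
        pop = [Bacterium(padded, obj) for _ in range(4)]
        out = eliminate_disperse(pop, cfg, np.random.default_rng(0), [], toy_records)
        assert [b.alignment for b in out] == [b.alignment for b in pop]

    def test_full_dispersal_rerandomizes(self, toy_records, padded):
        cfg = small_cfg(dispersal_prob=1.0)
        obj = evaluate(padded, cfg.objective)
        pop = [Bacterium(padded, obj) for _ in range(4)]
        out = eliminate_disperse(pop, cfg, np.random.default_rng(0), [], toy_records)
        assert len(out) == 4
        for b in out:
            check_round_trip(b.alignment, toy_records)
        assert any(b.alignment != padded for b in out)

    def test_dominating_offspring_enters(self, toy_records, padded):
        cfg = small_cfg(dispersal_prob=0.0)
        obj = evaluate(padded, cfg.objective)
        pop = [Bacterium(padded, obj) for _ in range(4)]
        # an offspring strictly better on all objectives must replace someone
        from bfoga import ObjectiveVector

        better = Bacterium(
            padded, ObjectiveVector(obj.sm + 0.1, obj.gap_penalty - 1, obj.ngp + 1)
        )
        out = eliminate_disperse(
            pop, cfg, np.random.default_rng(0), [better], toy_records
        )
        assert any(b.objectives == better.objectives for b in out)


class TestRun:
    def test_zero_generations_archive_is_initial_front(self, toy_records):
        cfg = small_cfg(generations=0)
        res = run(toy_records, cfg)
        archive_objs = {o.as_tuple() for _, o in res.archive}
        init_objs = [o for _, o in res.initial_population]
        from bfoga import non_dominated_sort

        front0 = non_dominated_sort(init_objs)[0]
        assert archive_objs == {init_objs[i].as_tuple() for i in front0}

    def test_seed_determinism(self, toy_records):
        r1 = run(toy_records, small_cfg(seed=12))
        r2 = run(toy_records, small_cfg(seed=12))
        assert [(a, o) for a, o in r1.archive] == [(a, o) for a, o in r2.archive]
        assert r1.trace == r2.trace

    def test_archive_best_values_monotone(self, family):
        records, _ = family
        res = run(records, small_cfg(generations=4, pop_size=10))
        sm = [t["best_sm"] for t in res.trace]
        gp = [t["best_gap_penalty"] for t in res.trace]
        ngp = [t["best_ngp"] for t in res.trace]
        assert all(a <= b for a, b in zip(sm, sm[1:]))
        assert all(a >= b for a, b in zip(gp, gp[1:]))
        assert all(a <= b for a, b in zip(ngp, ngp[1:]))

    def test_degenerate_config_is_pure_local_search(self, toy_records):
        cfg = small_cfg(
            swim_length=0,
            crossover_fraction=0.0,
            mutation_rate=0.0,
            dispersal_prob=0.0,
            generations=3,
        )
        res = run(toy_records, cfg)
        sm = [t["best_sm"] for t in res.trace]
        assert all(a <= b for a, b in zip(sm, sm[1:]))

    def test_too_few_sequences(self):
        recs = [SequenceRecord("a", "ACDE"), SequenceRecord("b", "ACDE")]
        with pytest.raises(ParameterError):
            run(recs, small_cfg())

    def test_improvement_over_25_style_repeat(self, family):
        """Median final best similarity over repeated short seeded runs
        exceeds the median initial best similarity."""
        records, _ = family
        finals, initials = [], []
        for seed in range(5):
            res = run(
                records,
                small_cfg(generations=3, pop_size=10, seed=seed, validate=False),
            )
            finals.append(res.trace[-1]["best_sm"])
            initials.append(max(o.sm for _, o in res.initial_population))
        assert np.median(finals) > np.median(initials)


class TestArchive:
    def test_archive_keeps_only_non_dominated(self, padded):
        from bfoga import ObjectiveVector

        arch = ParetoArchive()
        arch.add(padded, ObjectiveVector(0.5, 10, 50))
        arch.add(padded, ObjectiveVector(0.6, 9, 60))  # dominates the first
        assert len(arch) == 1
        arch.add(padded, ObjectiveVector(0.4, 1, 40))  # trade-off: kept
        assert len(arch) == 2


def test_config_validation():
    with pytest.raises(ParameterError):
        BFOGAConfig(pop_size=7)  # odd
    with pytest.raises(ParameterError):
        BFOGAConfig(mutation_rate=1.5)
    with pytest.raises(ParameterError):
        BFOGAConfig(gap_fraction=0.5)
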