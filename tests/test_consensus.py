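import numpy as np
import pytest

from tadlink.consensus import (
    ConsensusConfig,
    build_intersection_tad,
    build_union_tad,
    call_consensus_tads,
    conservation_score,
    fdr_adjust,
    permutation_null,
)
from tadlink.intervals import GenomicInterval, IntervalSet

from helpers import oracle_conservation_score, random_interval_set


def _sets(*coord_lists):
    return [
        IntervalSet([GenomicInterval(*c) for c in coords], label=f"ct{i}")
        for i, coords in enumerate(coord_lists)
    ]


def test_conservation_score_mixed_example():
    tad = GenomicInterval("chr1", 0, 100_000)
    others = _sets(
        [("chr1", 0, 100_000)],      # identical -> 1.0
        [("chr1", 0, 50_000)],       # half -> 0.5
        [("chr2", 0, 100_000)],      # wrong chromosome -> 0.0
    )
    sc = conservation_score(tad, others)
    assert sc.per_celltype_best == (1.0, 0.5, 0.0)
    assert sc.score == 0.5


def test_conservation_score_boundary_values():
    tad = GenomicInterval("chr1", 0, 100_000)
    identical = _sets(*[[("chr1", 0, 100_000)]] * 3)
    assert conservation_score(tad, identical).score == 1.0
    nothing = _sets(*[[("chr1", 500_000, 600_000)]] * 3)
    assert conservation_score(tad, nothing).score == 0.0


def test_conservation_score_requires_three_sets():
    tad = GenomicInterval("chr1", 0, 100_000)
    with pytest.raises(ValueError):
        conservation_score(tad, _sets([("chr1", 0, 1_000)]))


def test_conservation_score_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(25):
        others = [random_interval_set(rng, int(rng.integers(0, 20))) for _ in range(3)]
        tad_set = random_interval_set(rng, 1)
        sc = conservation_score(tad_set.intervals[0], others)
        assert sc.score == oracle_conservation_score(tad_set.intervals[0], others)


def test_permutation_counting_formula():
    chrom_sizes = {"chr1": 10_000_000}
    tad = GenomicInterval("chr1", 4_000_000, 4_100_000)
    exact = _sets(*[[("chr1", 4_000_000, 4_100_000)]] * 3)
    # observed score 1.0; a random interval essentially never reproduces it
    p = permutation_null(tad, exact, chrom_sizes, n=999, rng_seed=0)
    assert p == pytest.approx(1 / 1000)
    # observed score 0.0: every null score is >= 0, so p = 1
    empty = _sets([], [], [])
    p0 = permutation_null(tad, empty, chrom_sizes, n=499, rng_seed=0)
    assert p0 == 1.0


def test_permutation_errors():
    tad = GenomicInterval("chr1", 0, 100_000)
    with pytest.raises(KeyError):
        permutation_null(tad, _sets([], [], []), {"chr2": 1_000_000}, n=100)


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.5], [0.5]),
        ([0.2, 0.2, 0.2, 0.2], [0.2, 0.2, 0.2, 0.2]),
    ],
)
def test_fdr_adjust_examples(p, expected):
    assert fdr_adjust(p) == pytest.approx(expected)


def test_fdr_adjust_empty_rejected():
    with pytest.raises(ValueError):
        fdr_adjust([])


def test_build_intersection_and_union():
    tad = GenomicInterval("chr1", 0, 100_000)
    matches = [
        GenomicInterval("chr1", 10_000, 100_000),
        GenomicInterval("chr1", 0, 90_000),
        GenomicInterval("chr1", 5_000, 95_000),
    ]
    inter = build_intersection_tad(tad, matches)
    assert (inter.start, inter.end) == (10_000, 90_000)
    uni = build_union_tad(
        tad,
        [
            GenomicInterval("chr1", 10_000, 110_000),
            GenomicInterval("chr1", 0, 90_000),
            GenomicInterval("chr1", 5_000, 95_000),
        ],
    )
    assert (uni.start, uni.end) == (0, 110_000)
    assert uni.start <= inter.start and inter.end <= uni.end
    # identity
    same = build_intersection_tad(tad, [tad, tad, tad])
    assert (same.start, same.end) == (0, 100_000)
    # disjoint best matches -> empty intersection
    assert (
        build_intersection_tad(
            tad,
            [
                GenomicInterval("chr1", 0, 10_000),
                GenomicInterval("chr1", 90_000, 100_000),
                tad,
            ],
        )
        is None
    )


def _planted_scene(score_middle: float):
    """Basis with one 200 kb TAD whose middle per-celltype overlap is tunable."""
    tad = GenomicInterval("chr1", 1_000_000, 1_200_000)
    basis = IntervalSet([tad], label="A", ids=["t0"])
    # B identical, D nothing; C nested in the TAD sets the median exactly
    c_end = 1_000_000 + int(200_000 * score_middle)
    others = [
        IntervalSet([tad], label="B"),
        IntervalSet([GenomicInterval("chr1", 1_000_000, c_end)], label="C"),
        IntervalSet([GenomicInterval("chr1", 5_000_000, 5_200_000)], label="D"),
    ]
    return basis, others


def test_score_exactly_at_threshold_is_excluded():
    basis, others = _planted_scene(0.5)
    sc = conservation_score(basis.intervals[0], others)
    assert sc.score == pytest.approx(0.5)
    called = call_consensus_tads(
        basis, others, {"chr1": 10_000_000}, ConsensusConfig(n_permutations=200)
    )
    assert called == []


def test_short_tad_excluded_despite_perfect_score():
    tad = GenomicInterval("chr1", 0, 90_000)
    basis = IntervalSet([tad], label="A")
    others = [IntervalSet([tad], label=x) for x in "BCD"]
    called = call_consensus_tads(
        basis, others, {"chr1": 10_000_000}, ConsensusConfig(n_permutations=200)
    )
    assert called == []


def test_planted_tads_called_and_deterministic():
    rng = np.random.default_rng(3)
    planted = [
        GenomicInterval("chr1", 500_000, 800_000),
        GenomicInterval("chr1", 2_000_000, 2_400_000),
        GenomicInterval("chr2", 1_000_000, 1_150_000),
    ]
    decoy_sets = [random_interval_set(rng, 20, label=x) for x in "ABCD"]
    basis = IntervalSet(planted + decoy_sets[0].intervals, label="A")
    others = [
        IntervalSet(planted + s.intervals, label=s.label) for s in decoy_sets[1:]
    ]
    sizes = {"chr1": 5_000_000, "chr2": 5_000_000}
    cfg = ConsensusConfig(n_permutations=500, seed=9)
    called = call_consensus_tads(basis, others, sizes, cfg)
    called_src = {(c.source_tad.chrom, c.source_tad.start, c.source_tad.end) for c in called}
    for t in planted:
        assert (t.chrom, t.start, t.end) in called_src
        # jitter-free planted TADs keep their exact coordinates in both variants
        c = next(c for c in called if c.source_tad == t)
        assert c.score == 1.0 and c.intersection_iv == t and c.union_iv == t
    again = call_consensus_tads(basis, others, sizes, cfg)
    assert [(c.id, c.score, c.p_value, c.q_value) for c in called] == [
        (c.id, c.score, c.p_value, c.q_value) for c in again
    ]


def test_empty_basis_rejected():
    with pytest.raises(ValueError):
        call_consensus_tads(
            IntervalSet([], label="A"),
            [IntervalSet([], label=x) for x in "BCD"],
            {"chr1": 1_000_000},
        )
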