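import numpy as np
import pytest
from scipy import stats as sps

from tadlink.genome import Genome
from tadlink.intervals import GenomicInterval, IntervalSet
from tadlink.placement import (
    DMRRecord,
    MatchTolerance,
    boundary_distance,
    boundary_proximity_test,
    compute_gc_cpg,
    inside_tad_fraction,
    inside_tad_test,
    matched_random_interval,
    matched_random_starts,
)


def _dmr(chrom, start, end, id="d", gc=0.41, cpg=0.01, genic=False):
    return DMRRecord(GenomicInterval(chrom, start, end), id, gc, cpg, genic)


@pytest.mark.parametrize(
    "seq,gc,cpg",
    [
        ("GCGC", 1.0, 1 / 4),
        ("ATAT", 0.0, 0.0),
        ("CGCG", 1.0, 2 / 4),
        ("ANCGN", 2 / 5, 1 / 5),  # N counts in length only
        ("acgt", 0.5, 1 / 4),  # case-insensitive
    ],
)
def test_compute_gc_cpg(seq, gc, cpg):
    genome = Genome({"c": seq})
    got = compute_gc_cpg(GenomicInterval("c", 0, len(seq)), genome)
    assert got == (pytest.approx(gc), pytest.approx(cpg))


def test_gc_cpg_subinterval_excludes_straddling_dinucleotide():
    genome = Genome({"c": "ACGT"})
    # [0,2) = "AC": the CG starting at position 1 straddles the boundary
    assert genome.gc_cpg("c", 0, 2) == (0.5, 0.0)
    assert genome.gc_cpg("c", 1, 3) == (1.0, 0.5)


def test_gc_cpg_errors():
    genome = Genome({"c": "ACGT"})
    with pytest.raises(KeyError):
        genome.gc_cpg("missing", 0, 2)
    with pytest.raises(ValueError):
        genome.gc_cpg("c", 0, 10)


def test_matched_interval_preserves_length_and_composition(uniform_genome):
    rng = np.random.default_rng(1)
    tol = MatchTolerance()
    dmr = _dmr("chr1", 1000, 2500)
    dmr.gc_fraction, dmr.cpg_density = compute_gc_cpg(dmr.interval, uniform_genome)
    for _ in range(20):
        iv = matched_random_interval(dmr, uniform_genome, tol, rng)
        assert iv.length == dmr.interval.length
        gc, cpg = compute_gc_cpg(iv, uniform_genome)
        assert abs(gc - dmr.gc_fraction) <= tol.gc_abs_tol
        assert abs(cpg - dmr.cpg_density) <= tol.cpg_abs_tol


def test_matched_positions_approximately_uniform(uniform_genome):
    """On a homogeneous genome the accepted positions show no spatial bias."""
    rng = np.random.default_rng(2)
    chroms, starts, _ = matched_random_starts(
        1500, 0.41, 0.01, uniform_genome, 10_000, MatchTolerance(), rng, chrom="chr1"
    )
    counts, _ = np.histogram(starts, bins=20, range=(0, 1_000_000))
    p = sps.chisquare(counts).pvalue
    assert p > 1e-3


def test_matched_interval_impossible_length(uniform_genome):
    with pytest.raises(ValueError):
        matched_random_starts(
            5_000_000, 0.4, 0.01, uniform_genome, 1, MatchTolerance(), np.random.default_rng(0)
        )


def test_inside_tad_fraction_examples():
    tads = IntervalSet([GenomicInterval("chr1", 1000, 5000)])
    inside = [_dmr("chr1", 2000, 2100), _dmr("chr1", 4000, 4500)]
    assert inside_tad_fraction(inside, tads) == 1.0
    off_chrom = [_dmr("chr9", 2000, 2100)]
    assert inside_tad_fraction(off_chrom, tads) == 0.0
    # one DMR overlapping by a single base counts as inside
    mixed = [
        _dmr("chr1", 2000, 2100),
        _dmr("chr1", 4999, 5100),
        _dmr("chr1", 999, 1000),  # ends where the TAD starts: no overlap
        _dmr("chr1", 3000, 3100),
    ]
    assert inside_tad_fraction(mixed, tads) == 0.75
    with pytest.raises(ValueError):
        inside_tad_fraction([], tads)


@pytest.mark.parametrize(
    "dmr_iv,tad_iv,expected",
    [
        ((10_000, 12_000), (0, 1_000_000), 10_000),
        ((499_000, 501_000), (0, 1_000_000), 499_000),  # dead center
        ((0, 5_000), (1_000, 1_001_000), 0),  # straddles the start (clamped)
    ],
)
def test_boundary_distance(dmr_iv, tad_iv, expected):
    assert boundary_distance(_dmr("chr1", *dmr_iv), GenomicInterval("chr1", *tad_iv)) == expected


def test_boundary_distance_requires_overlap():
    with pytest.raises(ValueError):
        boundary_distance(_dmr("chr1", 0, 100), GenomicInterval("chr1", 1_000, 2_000))


def test_inside_tad_test_planted_enrichment(uniform_genome):
    """DMRs planted inside TADs covering ~30% of the genome: minimal mc_p."""
    tads = IntervalSet(
        [GenomicInterval("chr1", 100_000, 400_000), GenomicInterval("chr2", 500_000, 800_000)]
    )
    rng = np.random.default_rng(3)
    dmrs = []
    for k in range(40):
        chrom = "chr1" if k % 2 else "chr2"
        lo = 100_000 if k % 2 else 500_000
        start = int(rng.integers(lo, lo + 298_000))
        iv = GenomicInterval(chrom, start, start + 1_000)
        gc, cpg = uniform_genome.gc_cpg(chrom, iv.start, iv.end)
        dmrs.append(DMRRecord(iv, f"d{k}", gc, cpg))
    res = inside_tad_test(dmrs, tads, uniform_genome, n_sims=200, seed=7)
    assert res.observed_stat == 1.0
    assert res.mc_p == pytest.approx(1 / 201)
    assert res.chi2_p < 1e-6
    assert len(res.per_sim_stats) == 200
    assert res.expected_stat == pytest.approx(float(np.mean(res.per_sim_stats)))


def test_inside_tad_test_degenerate_all_equal(uniform_genome):
    """TADs covering everything: every simulation ties the observation."""
    tads = IntervalSet(
        [GenomicInterval("chr1", 0, 1_000_000), GenomicInterval("chr2", 0, 1_000_000)]
    )
    dmrs = [_dmr("chr1", 5_000, 6_000)]
    dmrs[0].gc_fraction, dmrs[0].cpg_density = uniform_genome.gc_cpg("chr1", 5_000, 6_000)
    res = inside_tad_test(dmrs, tads, uniform_genome, n_sims=100, seed=1)
    assert res.observed_stat == 1.0 and res.mc_p == 1.0


def test_inside_tad_test_deterministic(uniform_genome):
    tads = IntervalSet([GenomicInterval("chr1", 100_000, 400_000)])
    dmrs = [_dmr("chr1", 150_000 + 5_000 * k, 151_000 + 5_000 * k, id=f"d{k}") for k in range(10)]
    for d in dmrs:
        d.gc_fraction, d.cpg_density = uniform_genome.gc_cpg("chr1", d.interval.start, d.interval.end)
    r1 = inside_tad_test(dmrs, tads, uniform_genome, n_sims=100, seed=42)
    r2 = inside_tad_test(dmrs, tads, uniform_genome, n_sims=100, seed=42)
    assert np.array_equal(r1.per_sim_stats, r2.per_sim_stats)
    assert r1.mc_p == r2.mc_p


def test_boundary_test_planted_proximal():
    tads = IntervalSet(
        [GenomicInterval("chr1", 0, 1_000_000), GenomicInterval("chr1", 2_000_000, 3_000_000)]
    )
    dmrs = [
        _dmr("chr1", 10_000 + 2_000 * k, 11_000 + 2_000 * k, id=f"a{k}") for k in range(10)
    ] + [
        _dmr("chr1", 2_960_000 + 3_000 * k, 2_961_000 + 3_000 * k, id=f"b{k}") for k in range(10)
    ]
    res = boundary_proximity_test(dmrs, tads, n_sims=2_000, seed=5)
    assert res.observed_stat == 20
    assert res.mc_p == pytest.approx(1 / 2_001)
    assert res.chi2_p < 1e-8


def test_boundary_test_saturated_tad_contributes_equally():
    """In a TAD where every position is proximal the DMR never discriminates."""
    tads = IntervalSet([GenomicInterval("chr1", 0, 60_000)])
    dmrs = [_dmr("chr1", 30_000, 31_000)]
    res = boundary_proximity_test(dmrs, tads, n_sims=500, proximal_cutoff=50_000, seed=1)
    assert res.observed_stat == 1
    assert np.all(res.per_sim_stats == 1.0)
    assert res.mc_p == 1.0


def test_boundary_test_excludes_oversized_dmr():
    tads = IntervalSet([GenomicInterval("chr1", 0, 10_000), GenomicInterval("chr1", 50_000, 1_050_000)])
    dmrs = [_dmr("chr1", 0, 20_000, id="big"), _dmr("chr1", 60_000, 61_000, id="ok")]
    res = boundary_proximity_test(dmrs, tads, n_sims=200, seed=1)
    assert res.n_excluded == 1


def test_boundary_calibration_under_uniform_null():
    """DMRs repositioned uniformly within their TADs: type-I error near alpha."""
    tads = IntervalSet(
        [GenomicInterval("chr1", 0, 1_500_000), GenomicInterval("chr2", 0, 2_000_000)]
    )
    rng = np.random.default_rng(11)
    rejections = 0
    n_reps = 200
    for _ in range(n_reps):
        dmrs = []
        for k in range(25):
            tad = tads.intervals[int(rng.integers(0, 2))]
            start = int(rng.integers(tad.start, tad.end - 1_000))
            dmrs.append(_dmr(tad.chrom, start, start + 1_000, id=f"d{k}"))
        res = boundary_proximity_test(dmrs, tads, n_sims=500, seed=rng)
        rejections += res.mc_p <= 0.05
    # binomial 95% band around alpha = 0.05 at 200 replicates
    assert 0.02 <= rejections / n_reps <= 0.08
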