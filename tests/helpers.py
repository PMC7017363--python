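"""Independent brute-force oracles and small builders used across tests.

The oracles deliberately avoid the package's vectorized code paths: they
enumerate pairs and triples directly so the implementation can be checked
against them on random instances.
"""

from __future__ import annotations

import numpy as np

from tadlink.intervals import GenomicInterval, IntervalSet
from tadlink.linking import GeneModel
from tadlink.consensus import ConsensusTAD
from tadlink.placement import DMRRecord


def oracle_jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    if inter == 0:
        return 0.0
    return inter / ((a.end - a.start) + (b.end - b.start) - inter)


def oracle_conservation_score(tad: GenomicInterval, others) -> float:
    """Exhaustive all-pairs max Jaccard per cell type, sort-based median."""
    bests = []
    for ivset in others:
        vals = [oracle_jaccard(tad, t) for t in ivset]
        bests.append(max(vals) if vals else 0.0)
    return sorted(bests)[1]


def oracle_links(ngdmrs, genes, tads, max_distance: int, variant: str):
    """Triple-loop DMR x gene x TAD linker, mirroring the stated tie-breaks.

    Returns {dmr_id: (distance, gene_id, kind)}.
    """
    best: dict[str, tuple] = {}
    for d in ngdmrs:
        for g in genes:
            for t in tads:
                tad = t.intersection_iv if variant == "intersection" else t.union_iv
                di, gi = d.interval, g.interval
                if di.chrom != tad.chrom or gi.chrom != tad.chrom:
                    continue
                if min(di.end, tad.end) <= max(di.start, tad.start):
                    continue
                if min(gi.end, tad.end) <= max(gi.start, tad.start):
                    continue
                linear = max(0, max(di.start, gi.start) - min(di.end, gi.end))
                spatial = min(
                    max(0, di.start - tad.start) + max(0, tad.end - gi.end),
                    max(0, tad.end - di.end) + max(0, gi.start - tad.start),
                )
                for dist, kind_rank in ((linear, 0), (spatial, 1)):
                    if dist >= max_distance:
                        continue
                    cand = (dist, g.gene_id, kind_rank, t.id)
                    if d.id not in best or cand < best[d.id]:
                        best[d.id] = cand
    return {
        k: (v[0], v[1], "linear" if v[2] == 0 else "spatial") for k, v in best.items()
    }


def random_linking_instance(rng: np.random.Generator, n_dmrs=30, n_genes=30, n_tads=8):
    """One random instance of DMRs, genes and consensus TADs on two chromosomes."""
    chroms = ["chr1", "chr2"]
    size = 5_000_000
    tads = []
    for k in range(n_tads):
        chrom = chroms[int(rng.integers(0, 2))]
        start = int(rng.integers(0, size - 600_000))
        length = int(rng.integers(100_000, 600_000))
        src = GenomicInterval(chrom, start, start + length)
        # shrink/grow a little for the two boundary variants
        d1, d2 = int(rng.integers(0, 20_000)), int(rng.integers(0, 20_000))
        inter = GenomicInterval(chrom, start + d1, start + length - d2) if length - d1 - d2 > 0 else src
        union = GenomicInterval(chrom, max(0, start - d1), start + length + d2)
        tads.append(
            ConsensusTAD(
                id=f"t{k}", source_tad=src, intersection_iv=inter, union_iv=union,
                score=0.9, p_value=0.001, q_value=0.01,
            )
        )
    dmrs = []
    for k in range(n_dmrs):
        chrom = chroms[int(rng.integers(0, 2))]
        start = int(rng.integers(0, size - 3_000))
        length = int(rng.integers(500, 3_000))
        dmrs.append(
            DMRRecord(GenomicInterval(chrom, start, start + length), id=f"d{k:03d}",
                      gc_fraction=0.4, cpg_density=0.01)
        )
    genes = []
    for k in range(n_genes):
        chrom = chroms[int(rng.integers(0, 2))]
        start = int(rng.integers(0, size - 60_000))
        length = int(rng.integers(5_000, 60_000))
        genes.append(GeneModel(GenomicInterval(chrom, start, start + length), gene_id=f"g{k:03d}"))
    return dmrs, genes, tads


def random_interval_set(
    rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), size=5_000_000,
    min_len=50_000, max_len=500_000, label="x",
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, size - length))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs, label=label)
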