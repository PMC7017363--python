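"""Synthetic genomes, TAD calls, genes, DMRs and organ annotations.

Every pipeline stage is testable against planted ground truth generated
here: a small genome with controllable GC and CpG composition, four
cell-type TAD tracks sharing a configurable conserved fraction with
jittered boundaries, genes, DMRs planted genic / boundary-proximal /
uniform, anchor-opposite DMR–gene pairs that can only be linked through
spatial distance, and a gene→organ table with planted enrichment.

One seed fixes every emitted byte.  Default scale — 2 chromosomes of
20 Mb, 60 TADs per cell type, 200 genes, 150 DMRs — keeps Monte Carlo
statistics stable while whole-pipeline runs stay in the seconds-to-
minutes range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import GenomicInterval, IntervalSet
from .linking import GeneModel
from .placement import DMRRecord

logger = logging.getLogger("tadlink.simulate")

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_genome",
    "generate_tad_calls",
    "generate_genes_and_dmrs",
    "generate_organ_annotations",
    "generate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CELL_LABELS = ("cellA", "cellB", "cellC", "cellD")  # cellA is the basis


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    gc_target: float = 0.41
    cpg_rate: float = 0.01  # CpG dinucleotide starts per bp, genome-wide
    n_tads_per_celltype: int = 60
    conserved_fraction: float = 0.5
    boundary_jitter_sd: int = 5_000
    tad_length_range: tuple[int, int] = (120_000, 500_000)
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    n_dmrs: int = 150
    dmr_length_range: tuple[int, int] = (500, 2_500)
    frac_dmrs_boundary_proximal: float = 0.5
    frac_dmrs_genic: float = 0.67
    n_spatial_link_pairs: int = 5
    organ_count: int = 15
    organ_base_rate: float = 0.2
    planted_enriched_organs: tuple[tuple[str, float], ...] = (("organ_01", 2.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conserved_fraction", "frac_dmrs_boundary_proximal", "frac_dmrs_genic"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")


@dataclass
class GroundTruth:
    """Planted structure to validate pipeline output against."""

    conserved_tad_ids: list[str] = field(default_factory=list)
    conserved_tads: dict[str, GenomicInterval] = field(default_factory=dict)
    boundary_proximal_dmr_ids: list[str] = field(default_factory=list)
    planted_link_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    enriched_organs: list[str] = field(default_factory=list)
    true_dmg_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "conserved_tad_ids": self.conserved_tad_ids,
            "boundary_proximal_dmr_ids": self.boundary_proximal_dmr_ids,
            "planted_link_pairs": [list(t) for t in self.planted_link_pairs],
            "enriched_organs": self.enriched_organs,
            "true_dmg_ids": self.true_dmg_ids,
        }


@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    genome: Genome
    tad_sets: dict[str, IntervalSet]
    basis_label: str
    genes: list[GeneModel]
    dmrs: list[DMRRecord]
    annotations: pd.DataFrame
    truth: GroundTruth


# ----------------------------------------------------------------------
# genome


def _adjust_cpg(arr: np.ndarray, target: int, rng: np.random.Generator) -> None:
    """Drive the CG-dinucleotide count of ``arr`` to ``target`` in place.

    Excess CGs are destroyed by swapping to GC (composition-preserving);
    deficits are filled by planting CG at random positions.  Both edits
    can create or destroy neighbouring CGs, so the loop re-counts.
    """
    for _ in range(50):
        starts = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        current = starts.size
        tol = 0 if target == 0 else max(1, int(0.02 * target))
        if abs(current - target) <= tol:
            return
        if current > target:
            k = current - target
            chosen = rng.choice(starts, size=min(k, starts.size), replace=False)
            arr[chosen], arr[chosen + 1] = ord("G"), ord("C")
        else:
            k = target - current
            cand = np.sort(rng.integers(0, arr.size - 1, size=2 * k))
            keep = np.ones(cand.size, dtype=bool)
            keep[1:] = np.diff(cand) > 1  # avoid overlapping plants
            cand = cand[keep][:k]
            arr[cand], arr[cand + 1] = ord("C"), ord("G")
    logger.warning("CpG adjustment did not fully converge (target %d)", target)


def generate_genome(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Genome:
    """Random genome hitting ``gc_target`` (±0.02) and ``cpg_rate`` (±20%).

    Bases are drawn i.i.d. at the target GC fraction, then the CpG
    dinucleotide count is edited to the target rate with composition-
    preserving swaps; the residual GC drift from planting is well inside
    the stated tolerance at the default scale.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    gc = cfg.gc_target
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, np.ndarray] = {}
    for chrom, size in cfg.chrom_sizes.items():
        arr = _BASES[rng.choice(4, size=size, p=probs)]
        _adjust_cpg(arr, int(round(cfg.cpg_rate * size)), rng)
        seqs[chrom] = arr
    return Genome(seqs)


# ----------------------------------------------------------------------
# interval placement helpers


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    lengths: Sequence[int],
    occupied: dict[str, list[tuple[int, int]]],
    gap: int = 0,
    max_retries: int = 2000,
) -> list[GenomicInterval]:
    """Place intervals uniformly at random, avoiding ``occupied`` (+gap).

    ``occupied`` is updated in place so successive calls share the layout.
    """
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for length in lengths:
        for attempt in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            size = chrom_sizes[chrom]
            if size < length:
                continue
            start = int(rng.integers(0, size - length + 1))
            end = start + length
            if all(
                end + gap <= s or start - gap >= e for s, e in occupied.get(chrom, [])
            ):
                occupied.setdefault(chrom, []).append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place interval of length {length} after {max_retries} "
                f"retries ({len(out)}/{len(lengths)} placed)"
            )
    return out


# ----------------------------------------------------------------------
# TAD calls


def generate_tad_calls(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, IntervalSet], GroundTruth]:
    """Four cell-type TAD tracks with a planted conserved fraction.

    A set of archetype domains is replicated into every cell type with
    rounded-Gaussian boundary jitter (sd ``boundary_jitter_sd``, clipped
    at 4 sd, which the inter-archetype spacing absorbs); the remaining
    TADs are independent per cell type.  TADs never overlap within a cell
    type.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n_cons = int(round(cfg.conserved_fraction * cfg.n_tads_per_celltype))
    margin = max(1, 4 * cfg.boundary_jitter_sd)
    lo, hi = cfg.tad_length_range

    arch_lengths = rng.integers(lo, hi + 1, size=n_cons)
    occupied_template: dict[str, list[tuple[int, int]]] = {}
    archetypes = _place_nonoverlapping(
        rng, cfg.chrom_sizes, arch_lengths.tolist(), occupied_template, gap=2 * margin + 1
    )

    truth = GroundTruth()
    tad_sets: dict[str, IntervalSet] = {}
    basis_conserved: list[tuple[str, GenomicInterval]] = []
    for label in _CELL_LABELS:
        ivs: list[GenomicInterval] = []
        occupied: dict[str, list[tuple[int, int]]] = {}
        for k, arch in enumerate(archetypes):
            if cfg.boundary_jitter_sd > 0:
                js, je = np.clip(
                    np.round(rng.normal(0, cfg.boundary_jitter_sd, size=2)),
                    -margin,
                    margin,
                ).astype(int)
            else:
                js = je = 0
            start = max(0, arch.start + int(js))
            end = min(cfg.chrom_sizes[arch.chrom], arch.end + int(je))
            iv = GenomicInterval(arch.chrom, start, end)
            ivs.append(iv)
            occupied.setdefault(arch.chrom, []).append((start, end))
        ids = [f"tad_c{k:03d}" for k in range(n_cons)]
        n_decoys = cfg.n_tads_per_celltype - n_cons
        decoy_lengths = rng.integers(lo, hi + 1, size=n_decoys)
        decoys = _place_nonoverlapping(
            rng, cfg.chrom_sizes, decoy_lengths.tolist(), occupied, gap=0
        )
        ivs.extend(decoys)
        ids.extend(f"tad_r{k:03d}" for k in range(n_decoys))
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start))
        tad_sets[label] = IntervalSet(
            [ivs[i] for i in order], label=label, ids=[ids[i] for i in order]
        )
        if label == _CELL_LABELS[0]:
            basis_conserved = [(f"tad_c{k:03d}", ivs[k]) for k in range(n_cons)]

    truth.conserved_tad_ids = [i for i, _ in basis_conserved]
    truth.conserved_tads = dict(basis_conserved)
    return tad_sets, truth


# ----------------------------------------------------------------------
# genes and DMRs


def _overlaps_genes(iv: GenomicInterval, gene_set: IntervalSet) -> bool:
    return bool(
        gene_set.overlaps_any(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
    )


def generate_genes_and_dmrs(
    cfg: SimulationConfig,
    genome: Genome,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneModel], list[DMRRecord]]:
    """Genes and DMRs with planted placement structure.

    DMR mixture: ``frac_dmrs_genic`` of DMRs sit inside gene bodies; of
    the non-genic remainder, ``frac_dmrs_boundary_proximal`` are planted
    within 50 kb of a conserved TAD boundary (counting the spatial-link
    DMRs toward that quota) and the rest land uniformly away from genes.
    ``n_spatial_link_pairs`` DMR–gene pairs occupy opposite anchors of
    large conserved TADs with anchor offsets summing below 50 kb, so they
    are linkable only through spatial distance; other genes are kept out
    of those TADs so each planted pair is unambiguous.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    chrom_sizes = cfg.chrom_sizes
    glo, ghi = cfg.gene_length_range
    dlo, dhi = cfg.dmr_length_range

    big_tads = [
        (tid, iv)
        for tid, iv in truth.conserved_tads.items()
        if iv.length >= 300_000
    ]
    n_pairs = min(cfg.n_spatial_link_pairs, len(big_tads))
    if n_pairs < cfg.n_spatial_link_pairs:
        logger.warning(
            "only %d conserved TADs >= 300 kb available for %d requested spatial pairs",
            len(big_tads),
            cfg.n_spatial_link_pairs,
        )
    chosen = [big_tads[i] for i in rng.choice(len(big_tads), size=n_pairs, replace=False)] if n_pairs else []

    # anchor offsets start beyond the jitter clip bound, so planted elements
    # stay inside even the intersection boundary variant; the offset sum
    # stays below 48 kb so the spatial distance clears the 50 kb threshold
    jitter_margin = 4 * cfg.boundary_jitter_sd
    off_span = max(2_000, 48_000 - 2 * jitter_margin)
    if 2 * jitter_margin + 2_000 > 48_000:
        logger.warning(
            "boundary jitter sd %d is too large to guarantee planted spatial "
            "links under the 50 kb threshold",
            cfg.boundary_jitter_sd,
        )
    genes: list[GeneModel] = []
    planted_dmrs: list[tuple[GenomicInterval, GeneModel]] = []
    planted_tad_spans: list[GenomicInterval] = []
    for tid, tad in chosen:
        gene_len = int(rng.integers(glo, min(ghi, tad.length // 3) + 1))
        off_gene = jitter_margin + int(rng.integers(0, off_span // 2 + 1))
        gene_iv = GenomicInterval(
            tad.chrom, tad.end - off_gene - gene_len, tad.end - off_gene
        )
        off_dmr = jitter_margin + int(rng.integers(0, off_span // 2 + 1))
        dmr_len = int(rng.integers(dlo, dhi + 1))
        dmr_iv = GenomicInterval(tad.chrom, tad.start + off_dmr, tad.start + off_dmr + dmr_len)
        gene = GeneModel(gene_iv, gene_id=f"gene_{len(genes):04d}", name=f"planted_{tid}")
        genes.append(gene)
        planted_dmrs.append((dmr_iv, gene))
        planted_tad_spans.append(tad)

    # uniform genes, non-overlapping, kept out of the planted-pair TADs
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        occupied.setdefault(g.interval.chrom, []).append((g.interval.start, g.interval.end))
    for tad in planted_tad_spans:
        occupied.setdefault(tad.chrom, []).append((tad.start, tad.end))
    n_uniform_genes = max(0, cfg.n_genes - len(genes))
    gene_lengths = rng.integers(glo, ghi + 1, size=n_uniform_genes)
    for iv in _place_nonoverlapping(rng, chrom_sizes, gene_lengths.tolist(), occupied):
        genes.append(GeneModel(iv, gene_id=f"gene_{len(genes):04d}"))
    gene_set = IntervalSet([g.interval for g in genes], label="genes")

    # DMR quotas
    n_genic = int(round(cfg.frac_dmrs_genic * cfg.n_dmrs))
    n_nongenic = cfg.n_dmrs - n_genic
    n_prox_total = int(round(cfg.frac_dmrs_boundary_proximal * n_nongenic))
    n_prox_extra = max(0, n_prox_total - n_pairs)
    cons = list(truth.conserved_tads.values())
    if not cons:  # nothing to be proximal to
        n_prox_extra = 0
    n_uniform = n_nongenic - n_pairs - n_prox_extra
    if n_uniform < 0:
        raise ValueError("spatial-link pairs exceed the non-genic DMR budget")

    placements: list[tuple[GenomicInterval, str]] = []  # (interval, category)
    for iv, gene in planted_dmrs:
        placements.append((iv, "planted_pair"))

    def _try_place(make, category: str, n: int, max_retries: int = 2000) -> None:
        placed = 0
        for _ in range(n * max_retries):
            iv = make()
            if iv is None:
                continue
            if not _overlaps_genes(iv, gene_set):
                placements.append((iv, category))
                placed += 1
                if placed == n:
                    return
        raise RuntimeError(
            f"placed only {placed}/{n} {category} DMRs within the retry budget"
        )

    def _make_proximal() -> GenomicInterval | None:
        tad = cons[int(rng.integers(0, len(cons)))]
        length = int(rng.integers(dlo, dhi + 1))
        if tad.length < length + 40_000:
            return None
        off = int(rng.integers(0, 40_001))
        if rng.random() < 0.5:
            start = tad.start + off
        else:
            start = tad.end - off - length
        return GenomicInterval(tad.chrom, start, start + length)

    def _make_uniform() -> GenomicInterval | None:
        chroms = list(chrom_sizes)
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(dlo, dhi + 1))
        start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
        return GenomicInterval(chrom, start, start + length)

    if n_prox_extra:
        _try_place(_make_proximal, "proximal", n_prox_extra)
    if n_uniform:
        _try_place(_make_uniform, "uniform", n_uniform)
    for _ in range(n_genic):
        gene = genes[int(rng.integers(0, len(genes)))]
        length = min(int(rng.integers(dlo, dhi + 1)), gene.interval.length)
        start = gene.interval.start + int(
            rng.integers(0, gene.interval.length - length + 1)
        )
        placements.append((GenomicInterval(gene.interval.chrom, start, start + length), "genic"))

    # canonical order, then ids; resolve planted identities afterwards
    order = sorted(range(len(placements)), key=lambda i: (placements[i][0].chrom, placements[i][0].start, placements[i][0].end))
    dmrs: list[DMRRecord] = []
    id_of_index: dict[int, str] = {}
    for rank, i in enumerate(order):
        iv, category = placements[i]
        gc, cpg = genome.gc_cpg(iv.chrom, iv.start, iv.end)
        dmr_id = f"dmr_{rank:04d}"
        id_of_index[i] = dmr_id
        dmrs.append(
            DMRRecord(
                interval=iv,
                id=dmr_id,
                gc_fraction=gc,
                cpg_density=cpg,
                is_genic=_overlaps_genes(iv, gene_set),
            )
        )

    truth.planted_link_pairs = [
        (id_of_index[i], planted_dmrs[i][1].gene_id, "spatial")
        for i in range(len(planted_dmrs))
    ]
    truth.boundary_proximal_dmr_ids = sorted(
        id_of_index[i]
        for i, (_, cat) in enumerate(placements)
        if cat in ("planted_pair", "proximal")
    )
    return genes, dmrs


# ----------------------------------------------------------------------
# organ annotations


def generate_organ_annotations(
    cfg: SimulationConfig,
    gene_ids: Sequence[str],
    dmg_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene→organ table with planted enrichment among true DMGs.

    For a planted organ at fold ``F`` with base rate ``f``, DMG genes are
    annotated with probability ``F*f`` and the remaining genes with a
    compensating rate so the organ's overall background fraction stays at
    ``f`` — the expected enrichment ratio of the DMG list is then ``F``
    rather than a diluted value.  Infeasible folds (``F*n > N``) are
    capped with a warning.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    gene_ids = list(gene_ids)
    dmg_set = set(dmg_ids) & set(gene_ids)
    n, big_n = len(dmg_set), len(gene_ids)
    planted = dict(cfg.planted_enriched_organs)
    f = cfg.organ_base_rate

    rows: list[tuple[str, str]] = []
    enriched: list[str] = []
    for k in range(cfg.organ_count):
        organ = f"organ_{k + 1:02d}"
        fold = planted.get(organ, 1.0)
        if fold != 1.0 and n > 0:
            p1 = fold * f
            p0 = f * (big_n - fold * n) / (big_n - n) if big_n > n else p1
            if p1 > 1 or p0 < 0:
                logger.warning(
                    "organ %s: fold %.2f infeasible for list size %d of %d; capped",
                    organ,
                    fold,
                    n,
                    big_n,
                )
                p1, p0 = min(p1, 1.0), max(p0, 0.0)
            if fold > 1:
                enriched.append(organ)
        else:
            p1 = p0 = f
        for g in gene_ids:
            if rng.random() < (p1 if g in dmg_set else p0):
                rows.append((g, organ))
    return pd.DataFrame(rows, columns=["gene_id", "organ"]), enriched


# ----------------------------------------------------------------------
# whole datasets


def generate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate every input the pipeline needs, with ground truth.

    Independent random streams are spawned from the single config seed,
    so changing e.g. the number of DMRs does not perturb the genome.
    """
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_genome, rng_tads, rng_gd, rng_organs = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    genome = generate_genome(cfg, rng_genome)
    tad_sets, truth = generate_tad_calls(cfg, rng_tads)
    genes, dmrs = generate_genes_and_dmrs(cfg, genome, truth, rng_gd)

    gene_set = IntervalSet([g.interval for g in genes], label="genes")
    genic_dmg_ids = set()
    for d in dmrs:
        if not d.is_genic:
            continue
        iv = d.interval
        starts, ends, idx = gene_set.chrom_arrays(iv.chrom)
        hit = (starts < iv.end) & (ends > iv.start)
        for j in idx[hit]:
            genic_dmg_ids.add(genes[int(j)].gene_id)
    true_dmgs = sorted(genic_dmg_ids | {g for _, g, _ in truth.planted_link_pairs})
    truth.true_dmg_ids = true_dmgs

    annotations, enriched = generate_organ_annotations(
        cfg, [g.gene_id for g in genes], true_dmgs, rng_organs
    )
    truth.enriched_organs = enriched
    return SyntheticDataset(
        cfg=cfg,
        genome=genome,
        tad_sets=tad_sets,
        basis_label=_CELL_LABELS[0],
        genes=genes,
        dmrs=dmrs,
        annotations=annotations,
        truth=truth,
    )
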