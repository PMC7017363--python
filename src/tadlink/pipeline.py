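"""End-to-end orchestration: consensus → placement → linking → enrichment.

``run_pipeline`` reads every input, runs each stage for the requested
TAD boundary variant(s), writes every intermediate artifact under the
output directory, and returns (and writes) a machine-readable summary.
All randomness flows from the single config seed, so reruns are
idempotent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .consensus import ConsensusConfig, ConsensusTAD, call_consensus_tads
from .enrichment import organ_enrichment_test
from .intervals import IntervalSet
from .linking import LinkConfig, link_dmrs_to_genes, merge_dmg_lists
from .placement import (
    MatchTolerance,
    assign_containing_tads,
    boundary_distance,
    boundary_proximity_test,
    inside_tad_test,
)
from .simulate import SimulationConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger("tadlink.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "write_dataset"]

_VARIANTS = ("intersection", "union")


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    out_dir: str = "tadlink_out"
    # inputs (ignored when simulate=True)
    tad_beds: list[str] = field(default_factory=list)  # basis may be any; most TADs wins
    chrom_sizes: str = ""
    genome_fasta: str = ""
    dmr_table: str = ""
    genes_bed: str = ""
    annotations: str = ""
    prior_dmgs: str = ""  # optional: one gene id per line
    # stage parameters
    min_tad_length: int = 100_000
    score_threshold: float = 0.5
    q_threshold: float = 0.05
    n_permutations: int = 1000
    gc_abs_tol: float = 0.05
    cpg_abs_tol: float = 0.005
    n_sims_inside: int = 200
    n_sims_boundary: int = 10_000
    proximal_cutoff: int = 50_000
    max_link_distance: int = 50_000
    n_enrichment_draws: int = 10_000
    tad_variant: str = "both"  # intersection | union | both
    simulate: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def variants(self) -> list[str]:
        if self.tad_variant == "both":
            return list(_VARIANTS)
        if self.tad_variant not in _VARIANTS:
            raise ValueError(f"unknown tad_variant {self.tad_variant!r}")
        return [self.tad_variant]


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Emit every synthetic input file; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    io.write_fasta(ds.genome, out / "genome.fa")
    paths["genome_fasta"] = str(out / "genome.fa")
    io.write_chrom_sizes(ds.cfg.chrom_sizes, out / "chrom.sizes")
    paths["chrom_sizes"] = str(out / "chrom.sizes")
    tad_paths = []
    for label, ivset in ds.tad_sets.items():
        p = out / f"tads_{label}.bed"
        io.write_bed(ivset, p)
        tad_paths.append(str(p))
    paths["tad_beds"] = tad_paths  # type: ignore[assignment]
    io.write_genes_bed(ds.genes, out / "genes.bed")
    paths["genes_bed"] = str(out / "genes.bed")
    io.write_dmr_table(ds.dmrs, out / "dmrs.bed")
    paths["dmr_table"] = str(out / "dmrs.bed")
    io.write_annotations(ds.annotations, out / "annotations.tsv")
    paths["annotations"] = str(out / "annotations.tsv")
    io.write_json(ds.truth.to_dict(), out / "ground_truth.json")
    return paths


def _consensus_variant_set(tads: list[ConsensusTAD], variant: str) -> IntervalSet:
    ivs = [t.intersection_iv if variant == "intersection" else t.union_iv for t in tads]
    return IntervalSet(ivs, label=f"consensus_{variant}", ids=[t.id for t in tads])


def _write_consensus(tads: list[ConsensusTAD], out: Path) -> None:
    with open(out / "consensus_tads.tsv", "w") as fh:
        fh.write(
            "id\tchrom\tsrc_start\tsrc_end\tint_start\tint_end\tuni_start\tuni_end\tscore\tp\tq\n"
        )
        for t in tads:
            fh.write(
                f"{t.id}\t{t.source_tad.chrom}\t{t.source_tad.start}\t{t.source_tad.end}\t"
                f"{t.intersection_iv.start}\t{t.intersection_iv.end}\t"
                f"{t.union_iv.start}\t{t.union_iv.end}\t"
                f"{t.score:.6f}\t{t.p_value:.6g}\t{t.q_value:.6g}\n"
            )
    for variant in _VARIANTS:
        io.write_bed(_consensus_variant_set(tads, variant), out / f"consensus_{variant}.bed")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the summary dictionary.

    With ``cfg.simulate`` the inputs are generated first (seeded by
    ``cfg.seed``) under ``out_dir/inputs``; otherwise every configured
    input path must exist before any compute starts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        logger.info("[simulate] generating synthetic dataset (seed=%d)", cfg.seed)
        ds = generate_dataset(SimulationConfig(seed=cfg.seed))
        paths = write_dataset(ds, out / "inputs")
        cfg = dataclasses.replace(
            cfg,
            tad_beds=list(paths["tad_beds"]),
            chrom_sizes=paths["chrom_sizes"],
            genome_fasta=paths["genome_fasta"],
            dmr_table=paths["dmr_table"],
            genes_bed=paths["genes_bed"],
            annotations=paths["annotations"],
        )

    # fail fast on missing inputs, before any compute
    required = {
        "chrom_sizes": cfg.chrom_sizes,
        "genome_fasta": cfg.genome_fasta,
        "dmr_table": cfg.dmr_table,
        "genes_bed": cfg.genes_bed,
        "annotations": cfg.annotations,
    }
    for stage, p in required.items():
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"[{stage}] input path missing or absent: {p!r}")
    if len(cfg.tad_beds) != 4:
        raise ValueError(f"[consensus] need 4 TAD BED files, got {len(cfg.tad_beds)}")
    for p in cfg.tad_beds:
        if not Path(p).exists():
            raise FileNotFoundError(f"[consensus] TAD BED missing: {p}")

    summary: dict = {"seed": cfg.seed}

    # ---- consensus ----------------------------------------------------
    logger.info("[consensus] reading TAD calls")
    sets = [io.read_bed(p) for p in cfg.tad_beds]
    counts = [len(s) for s in sets]
    basis_idx = int(np.argmax(counts))  # basis = cell type with most TADs
    basis = sets[basis_idx]
    others = [s for i, s in enumerate(sets) if i != basis_idx]
    chrom_sizes = io.read_chrom_sizes(cfg.chrom_sizes)
    ccfg = ConsensusConfig(
        min_length=cfg.min_tad_length,
        score_threshold=cfg.score_threshold,
        q_threshold=cfg.q_threshold,
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
    )
    logger.info("[consensus] scoring %d basis TADs (%s)", len(basis), basis.label)
    consensus = call_consensus_tads(basis, others, chrom_sizes, ccfg)
    _write_consensus(consensus, out)
    summary["basis_celltype"] = basis.label
    summary["n_basis_tads"] = len(basis)
    summary["n_consensus_tads"] = len(consensus)
    summary["consensus_fraction_of_basis"] = round(len(consensus) / len(basis), 6)
    genome_bp = sum(chrom_sizes.values())
    for variant in _VARIANTS:
        span = _consensus_variant_set(consensus, variant).total_span()
        summary[f"{variant}_genome_span_fraction"] = round(span / genome_bp, 6)

    # ---- placement -----------------------------------------------------
    genome = io.read_genome(cfg.genome_fasta)
    dmrs = io.read_dmr_table(cfg.dmr_table)
    tol = MatchTolerance(gc_abs_tol=cfg.gc_abs_tol, cpg_abs_tol=cfg.cpg_abs_tol)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2 * len(cfg.variants()) + 2)
    summary["n_dmrs"] = len(dmrs)

    placement: dict = {}
    for vi, variant in enumerate(cfg.variants()):
        tad_set = _consensus_variant_set(consensus, variant)
        logger.info("[placement] %s-TADs: inside-TAD test (%d sims)", variant, cfg.n_sims_inside)
        inside = inside_tad_test(
            dmrs,
            tad_set,
            genome,
            n_sims=cfg.n_sims_inside,
            tol=tol,
            seed=np.random.default_rng(seeds[2 * vi]),
        )
        logger.info(
            "[placement] %s-TADs: boundary-proximity test (%d sims)",
            variant,
            cfg.n_sims_boundary,
        )
        boundary = boundary_proximity_test(
            dmrs,
            tad_set,
            n_sims=cfg.n_sims_boundary,
            proximal_cutoff=cfg.proximal_cutoff,
            seed=np.random.default_rng(seeds[2 * vi + 1]),
        )
        placement[variant] = {
            "inside_tad": inside.to_dict(),
            "boundary_proximity": boundary.to_dict(),
        }
        with open(out / f"boundary_distances_{variant}.tsv", "w") as fh:
            fh.write("dmr_id\ttad_id\tdistance\n")
            for d, tad in assign_containing_tads(dmrs, tad_set):
                fh.write(f"{d.id}\t{tad.chrom}:{tad.start}-{tad.end}\t{boundary_distance(d, tad)}\n")
    io.write_json(placement, out / "placement_tests.json")
    summary["placement"] = placement

    # ---- linking + enrichment -----------------------------------------
    genes = io.read_genes_bed(cfg.genes_bed)
    annotations = io.read_annotations(cfg.annotations)
    ngdmrs = [d for d in dmrs if not d.is_genic]
    summary["n_ngdmrs"] = len(ngdmrs)

    if cfg.prior_dmgs:
        prior = sorted(
            {l.strip() for l in open(cfg.prior_dmgs) if l.strip()}
        )
    else:
        # genes overlapping genic DMRs stand in for the prior DMG list
        gene_set = IntervalSet([g.interval for g in genes], ids=[g.gene_id for g in genes])
        prior_set: set[str] = set()
        for d in dmrs:
            if not d.is_genic:
                continue
            starts, ends, idx = gene_set.chrom_arrays(d.interval.chrom)
            hit = (starts < d.interval.end) & (ends > d.interval.start)
            prior_set.update(gene_set.ids[int(j)] for j in idx[hit])
        prior = sorted(prior_set)
    summary["n_prior_dmgs"] = len(prior)

    for vi, variant in enumerate(cfg.variants()):
        logger.info("[linking] %s-TADs", variant)
        links = link_dmrs_to_genes(
            ngdmrs,
            genes,
            consensus,
            LinkConfig(max_distance=cfg.max_link_distance, tad_variant=variant),
        )
        merged = merge_dmg_lists(links, prior)
        with open(out / f"links_{variant}.tsv", "w") as fh:
            fh.write("dmr_id\tgene_id\ttad_id\tdistance\tkind\tis_new_dmg\n")
            for l in merged.links:
                fh.write(
                    f"{l.dmr_id}\t{l.gene_id}\t{l.tad_id}\t{l.distance}\t{l.kind}\t{int(l.is_new_dmg)}\n"
                )
        logger.info("[enrichment] %s-TADs: %d combined DMGs", variant, len(merged.genes))
        enr = organ_enrichment_test(
            merged.genes,
            annotations,
            n_draws=cfg.n_enrichment_draws,
            seed=np.random.default_rng(seeds[-2 if variant == "intersection" else -1]),
        )
        enr.to_frame().to_csv(out / f"organ_enrichment_{variant}.tsv", sep="\t", index=False)
        summary[variant] = {
            "n_links": merged.n_linked_dmrs,
            "n_dmgs": merged.n_dmgs,
            "n_new_dmgs": merged.n_new,
            "n_already_present": merged.n_already_present,
            "n_spatial_links": sum(1 for l in merged.links if l.kind == "spatial"),
            "n_combined_dmgs": len(merged.genes),
            "significant_organs": sorted(r.organ for r in enr.rows if r.significant),
        }

    io.write_json(summary, out / "summary.json")
    logger.info("[done] summary written to %s", out / "summary.json")
    return summary
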