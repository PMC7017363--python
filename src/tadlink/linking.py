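"""Assignment of non-genic DMRs to genes through consensus TADs.

Two distances are defined between a DMR and a gene, both conditional on a
shared TAD:

* **linear** — the gap along the chromosome between their nearest edges,
  defined only when both overlap the same TAD;
* **spatial** — the two boundaries (loop anchors) of a TAD are brought
  together in 3D, so a DMR near one anchor sits physically close to a
  gene near the other.  The spatial distance is the smaller, over the two
  anchor pairings, of the DMR's clamped distance to one anchor plus the
  gene's clamped distance to the opposite anchor.

A DMR is linked to the gene minimizing the smaller of the two distances
over every shared TAD, provided that minimum is strictly below the link
threshold (default 50 kb, the typical upper range of enhancer–target
separations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus import ConsensusTAD
from .intervals import GenomicInterval
from .placement import DMRRecord

logger = logging.getLogger("tadlink.linking")

__all__ = [
    "GeneModel",
    "LinkConfig",
    "DMRGeneLink",
    "DMGMergeResult",
    "linear_distance",
    "spatial_distance",
    "link_dmrs_to_genes",
    "merge_dmg_lists",
]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene body with a unique identifier."""

    interval: GenomicInterval
    gene_id: str
    name: str = ""
    strand: str = "+"


@dataclass
class LinkConfig:
    max_distance: int = 50_000  # strict upper bound
    tad_variant: str = "intersection"  # or "union"
    use_tss: bool = False  # measure gene distance to the TSS instead of the body edge

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.tad_variant not in ("intersection", "union"):
            raise ValueError(f"unknown tad_variant {self.tad_variant!r}")


@dataclass
class DMRGeneLink:
    dmr_id: str
    gene_id: str
    tad_id: str
    distance: int
    kind: str  # "linear" | "spatial"
    is_new_dmg: bool = False


@dataclass
class DMGMergeResult:
    """Combined DMG list after merging new links with a prior gene list."""

    genes: list[str]
    n_linked_dmrs: int
    n_dmgs: int
    n_new: int
    n_already_present: int
    links: list[DMRGeneLink]


def _overlaps(iv: GenomicInterval, tad: GenomicInterval) -> bool:
    return iv.chrom == tad.chrom and min(iv.end, tad.end) > max(iv.start, tad.start)


def _gene_span(gene: GeneModel, use_tss: bool) -> tuple[int, int]:
    if not use_tss:
        return gene.interval.start, gene.interval.end
    tss = gene.interval.start if gene.strand != "-" else gene.interval.end - 1
    return tss, tss + 1


def linear_distance(
    dmr: DMRRecord, gene: GeneModel, tad: GenomicInterval, use_tss: bool = False
) -> int | None:
    """Edge-to-edge gap between DMR and gene, if both lie in ``tad``.

    Returns None when either does not overlap the TAD; 0 when they touch
    or overlap.
    """
    iv = dmr.interval
    gs, ge = _gene_span(gene, use_tss)
    if not _overlaps(iv, tad) or not _overlaps(GenomicInterval(gene.interval.chrom, gs, ge), tad):
        return None
    return max(0, max(iv.start, gs) - min(iv.end, ge))


def spatial_distance(
    dmr: DMRRecord, gene: GeneModel, tad: GenomicInterval, use_tss: bool = False
) -> int | None:
    """Anchor-mediated distance between DMR and gene across ``tad``.

    With dL/dR the clamped distances of an element's nearest edge to the
    left/right TAD boundary, the value is
    ``min(dL(dmr) + dR(gene), dR(dmr) + dL(gene))`` — each element reaches
    one anchor, and the two anchors touch in 3D.
    """
    iv = dmr.interval
    gs, ge = _gene_span(gene, use_tss)
    if not _overlaps(iv, tad) or not _overlaps(GenomicInterval(gene.interval.chrom, gs, ge), tad):
        return None
    d_left_dmr = max(0, iv.start - tad.start)
    d_right_dmr = max(0, tad.end - iv.end)
    d_left_gene = max(0, gs - tad.start)
    d_right_gene = max(0, tad.end - ge)
    return min(d_left_dmr + d_right_gene, d_right_dmr + d_left_gene)


_KIND_RANK = {"linear": 0, "spatial": 1}


def link_dmrs_to_genes(
    ngdmrs: Sequence[DMRRecord],
    genes: Sequence[GeneModel],
    tads: Sequence[ConsensusTAD],
    cfg: LinkConfig | None = None,
) -> list[DMRGeneLink]:
    """Link each non-genic DMR to at most one gene via shared TADs.

    The effective DMR–gene distance is the minimum, over all TADs
    containing both, of min(linear, spatial).  A link is emitted when the
    effective distance is strictly below ``cfg.max_distance``.  Ties are
    broken deterministically: smaller distance, then lexicographic
    gene_id, then linear before spatial, then tad_id.
    """
    cfg = cfg or LinkConfig()
    if len({g.gene_id for g in genes}) != len(genes):
        raise ValueError("gene ids are not unique")
    genic = [d for d in ngdmrs if d.is_genic]
    if genic:
        raise ValueError(f"{len(genic)} input DMRs are flagged genic; pass ngDMRs only")

    # group candidates per TAD once, then examine pairs inside each TAD
    links: dict[str, tuple[int, str, int, str]] = {}
    for tad in tads:
        tad_iv = tad.intersection_iv if cfg.tad_variant == "intersection" else tad.union_iv
        in_dmrs = [d for d in ngdmrs if _overlaps(d.interval, tad_iv)]
        if not in_dmrs:
            continue
        in_genes = [g for g in genes if _overlaps(g.interval, tad_iv)]
        for d in in_dmrs:
            for g in in_genes:
                lin = linear_distance(d, g, tad_iv, cfg.use_tss)
                spa = spatial_distance(d, g, tad_iv, cfg.use_tss)
                for dist, kind in ((lin, "linear"), (spa, "spatial")):
                    if dist is None or dist >= cfg.max_distance:
                        continue
                    cand = (dist, g.gene_id, _KIND_RANK[kind], tad.id)
                    if d.id not in links or cand < links[d.id]:
                        links[d.id] = cand
    out = [
        DMRGeneLink(dmr_id=dmr_id, gene_id=c[1], tad_id=c[3], distance=c[0], kind="linear" if c[2] == 0 else "spatial")
        for dmr_id, c in links.items()
    ]
    out.sort(key=lambda l: (l.dmr_id, l.gene_id))
    return out


def merge_dmg_lists(
    new_links: Sequence[DMRGeneLink], prior_dmgs: Sequence[str]
) -> DMGMergeResult:
    """Merge newly linked genes with a previously identified DMG list.

    Flags each link's gene as new when it is absent from the prior list
    and reports the combined unique gene list with summary counts.
    """
    prior = set(prior_dmgs)
    if len(prior) != len(list(prior_dmgs)):
        logger.warning("prior DMG list contains duplicates; deduplicated")
    linked_genes = {l.gene_id for l in new_links}
    for l in new_links:
        l.is_new_dmg = l.gene_id not in prior
    combined = sorted(prior | linked_genes)
    return DMGMergeResult(
        genes=combined,
        n_linked_dmrs=len(new_links),
        n_dmgs=len(linked_genes),
        n_new=len(linked_genes - prior),
        n_already_present=len(linked_genes & prior),
        links=list(new_links),
    )
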