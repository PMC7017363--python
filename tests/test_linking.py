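import numpy as np
import pytest

from tadlink.consensus import ConsensusTAD
from tadlink.intervals import GenomicInterval
from tadlink.linking import (
    DMRGeneLink,
    GeneModel,
    LinkConfig,
    linear_distance,
    link_dmrs_to_genes,
    merge_dmg_lists,
    spatial_distance,
)
from tadlink.placement import DMRRecord

from helpers import oracle_links, random_linking_instance


def _dmr(chrom, start, end, id="d0"):
    return DMRRecord(GenomicInterval(chrom, start, end), id, 0.4, 0.01)


def _gene(chrom, start, end, gene_id="g0"):
    return GeneModel(GenomicInterval(chrom, start, end), gene_id)


def _ctad(iv, id="t0"):
    return ConsensusTAD(id, iv, iv, iv, 1.0, 0.001, 0.01)


def test_linear_distance_examples():
    tad = GenomicInterval("chr1", 0, 1_000_000)
    dmr = _dmr("chr1", 100_000, 102_000)
    assert linear_distance(dmr, _gene("chr1", 140_000, 160_000), tad) == 38_000
    # gene outside the TAD: undefined
    assert linear_distance(dmr, _gene("chr1", 1_200_000, 1_300_000), tad) is None
    # abutting: zero
    assert linear_distance(dmr, _gene("chr1", 102_000, 120_000), tad) == 0


def test_spatial_distance_anchor_geometry():
    tad = GenomicInterval("chr1", 0, 1_000_000)
    # DMR 10 kb from the left anchor, gene ending 20 kb from the right anchor:
    # spatially 30 kb apart while ~870 kb apart along the chromosome
    dmr = _dmr("chr1", 10_000, 12_000)
    gene = _gene("chr1", 900_000, 980_000)
    assert spatial_distance(dmr, gene, tad) == 30_000
    assert linear_distance(dmr, gene, tad) == 888_000
    # both elements at the left anchor: the pairing forces one across the TAD
    near_gene = _gene("chr1", 20_000, 40_000)
    assert spatial_distance(dmr, near_gene, tad) == pytest.approx(970_000, abs=30_000)
    # DMR straddling the left anchor, gene ending at the right anchor: zero
    tad2 = GenomicInterval("chr1", 11_000, 1_000_000)
    gene2 = _gene("chr1", 900_000, 1_000_000)
    assert spatial_distance(dmr, gene2, tad2) == 0


def test_link_prefers_smallest_distance_and_is_strict():
    tad = _ctad(GenomicInterval("chr1", 0, 1_000_000))
    dmr = _dmr("chr1", 100_000, 102_000)
    near = _gene("chr1", 140_000, 160_000, "near")
    far = _gene("chr1", 170_000, 190_000, "far")
    links = link_dmrs_to_genes([dmr], [near, far], [tad], LinkConfig())
    assert len(links) == 1 and links[0].gene_id == "near"
    assert links[0].kind == "linear" and links[0].distance == 38_000
    # exactly at the threshold: excluded (strict <)
    at_thresh = _dmr("chr1", 100_000, 102_000, "d1")
    only_far = _gene("chr1", 152_000, 160_000, "g")
    links = link_dmrs_to_genes([at_thresh], [only_far], [tad], LinkConfig(max_distance=50_000))
    assert links == []


def test_link_tbx3_like_geometry_is_spatial():
    """Gene and DMR at opposite anchors of a >1 Mb TAD link spatially."""
    tad = _ctad(GenomicInterval("chr1", 2_000_000, 3_300_000))
    dmr = _dmr("chr1", 2_010_000, 2_012_000)
    gene = _gene("chr1", 3_250_000, 3_280_000, "TBX3-like")
    links = link_dmrs_to_genes([dmr], [gene], [tad], LinkConfig())
    assert len(links) == 1
    (l,) = links
    assert l.kind == "spatial" and l.distance == 10_000 + 20_000
    # the linear route would have been ~1.2 Mb, far over the threshold
    assert linear_distance(dmr, gene, tad.intersection_iv) > 1_000_000


def test_no_link_outside_tads():
    tad = _ctad(GenomicInterval("chr1", 0, 1_000_000))
    lone = _dmr("chr2", 100_000, 101_000)
    gene = _gene("chr2", 140_000, 150_000)
    assert link_dmrs_to_genes([lone], [gene], [tad], LinkConfig()) == []


def test_link_rejects_genic_dmrs_and_duplicate_genes():
    tad = _ctad(GenomicInterval("chr1", 0, 1_000_000))
    genic = DMRRecord(GenomicInterval("chr1", 1, 2), "d", 0.4, 0.01, is_genic=True)
    with pytest.raises(ValueError):
        link_dmrs_to_genes([genic], [], [tad], LinkConfig())
    dup = [_gene("chr1", 0, 10, "g"), _gene("chr1", 20, 30, "g")]
    with pytest.raises(ValueError):
        link_dmrs_to_genes([], dup, [tad], LinkConfig())


@pytest.mark.parametrize("variant", ["intersection", "union"])
def test_links_match_bruteforce_oracle(variant):
    rng = np.random.default_rng(17)
    for _ in range(30):
        dmrs, genes, tads = random_linking_instance(rng)
        links = link_dmrs_to_genes(
            dmrs, genes, tads, LinkConfig(tad_variant=variant)
        )
        got = {l.dmr_id: (l.distance, l.gene_id, l.kind) for l in links}
        assert got == oracle_links(dmrs, genes, tads, 50_000, variant)


def test_link_monotone_in_max_distance():
    rng = np.random.default_rng(23)
    dmrs, genes, tads = random_linking_instance(rng, n_dmrs=40)
    small = link_dmrs_to_genes(dmrs, genes, tads, LinkConfig(max_distance=20_000))
    large = link_dmrs_to_genes(dmrs, genes, tads, LinkConfig(max_distance=50_000))
    assert {l.dmr_id for l in small} <= {l.dmr_id for l in large}
    assert all(l.distance < 20_000 for l in small)
    # a spatial link's linear distance, when defined, is never smaller
    for l in large:
        if l.kind != "spatial":
            continue
        d = next(x for x in dmrs if x.id == l.dmr_id)
        g = next(x for x in genes if x.gene_id == l.gene_id)
        t = next(x for x in tads if x.id == l.tad_id)
        tad_iv = t.intersection_iv
        lin = linear_distance(d, g, tad_iv)
        assert lin is None or lin >= l.distance or lin >= 50_000


def _link(dmr_id, gene_id):
    return DMRGeneLink(dmr_id, gene_id, "t0", 1_000, "linear")


def test_merge_dmg_lists():
    res = merge_dmg_lists([_link("d1", "B"), _link("d2", "C")], ["A", "B"])
    assert res.genes == ["A", "B", "C"]
    assert (res.n_new, res.n_already_present) == (1, 1)
    # empty prior: everything is new
    res = merge_dmg_lists([_link("d1", "X")], [])
    assert res.n_new == 1 and res.links[0].is_new_dmg
    # two DMRs sharing one gene: unique-gene count drops below link count
    links = [_link(f"d{i}", f"g{i}") for i in range(69)] + [_link("d69", "g0")]
    res = merge_dmg_lists(links, [])
    assert res.n_linked_dmrs == 70 and res.n_dmgs == 69
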