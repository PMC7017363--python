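# tadlink

Linking differentially methylated regions (DMRs) to genes through 3D
genome organization.

Comparative epigenomics can call DMRs between modern and archaic humans,
but a DMR that overlaps no promoter or gene body (a *non-genic DMR*,
ngDMR) cannot be assigned to a target gene by position alone. `tadlink`
assigns such DMRs using topologically associating domains (TADs): a TAD
that is conserved across cell types defines a shared regulatory
territory, and its two boundaries (loop anchors) are brought into
physical contact, so a DMR near one anchor can regulate a gene near the
other even when they are megabases apart on the chromosome.

The package is aimed at researchers with per-cell-type TAD calls (BED),
a DMR list, gene models, a reference sequence, and a gene→body-part
annotation table, who want conserved consensus TADs, placement
statistics, DMR–gene links, and organ-level enrichment of the resulting
gene list.

## Method

**Consensus TADs.** With cell type A as basis and B, C, D as the others,
each basis TAD T_i is scored

    S_i = median( max_{T∈B} J(T_i,T), max_{T∈C} J(T_i,T), max_{T∈D} J(T_i,T) )

where J is the Jaccard overlap (intersection length / union length).
Significance comes from a permutation test replacing T_i with
uniform-random same-length intervals on its chromosome, with
Benjamini–Hochberg FDR across tested TADs. A conserved TAD needs length
≥ 100 kb, S_i > 0.5 and q < 0.05, and is reported in two boundary
variants: the **intersection** and the **union** of the basis TAD with
its best match in each other cell type.

**Placement tests.** Whether DMRs fall inside consensus TADs is tested
against a Monte Carlo null that re-allocates each DMR to a random
genomic interval of identical length and similar GC content and CpG
density (rejection sampling). Whether inside-TAD DMRs sit within 50 kb
of a TAD boundary is tested against uniform repositioning within their
TAD. Both report an empirical p-value and a two-cell χ² against the
simulation mean.

**DMR–gene linking.** For each ngDMR–gene pair sharing a TAD, the
*linear* distance is the edge-to-edge gap along the chromosome, and the
*spatial* distance is min(dL(DMR)+dR(gene), dR(DMR)+dL(gene)), the sum
of clamped distances to opposite anchors. An ngDMR links to the closest
gene if either distance is below 50 kb; newly linked genes are merged
with a prior differentially-methylated-gene (DMG) list.

**Organ enrichment.** Against a gene→organ table, each organ's expected
count is |list|·|organ genes|/|background|, the enrichment ratio is
observed/expected, and p-values come from random same-size gene sets
(or an exact hypergeometric tail), BH-corrected across organs.

A fully seeded synthetic-data generator (`tadlink.simulate`) produces
genomes, four-cell-type TAD tracks, genes, DMRs and annotations with
planted ground truth for every stage.

## Worked example

Run the whole pipeline on the default synthetic dataset (2 chromosomes
× 20 Mb, 60 TADs per cell type of which half are conserved with 5 kb
boundary jitter, 200 genes, 150 DMRs):

```bash
tadlink run-all --simulate --out-dir demo --seed 7
```

The summary (`demo/summary.json`) from that exact command contains:

```
"n_basis_tads": 60,
"n_consensus_tads": 30,
"intersection": {
  "n_links": 21, "n_dmgs": 14, "n_new_dmgs": 8,
  "n_spatial_links": 13, "significant_organs": ["organ_01"]
},
"union": {
  "n_links": 15, "n_dmgs": 11, "n_new_dmgs": 8, "n_spatial_links": 6
}
```

All 30 planted conserved TADs are recovered and no decoy is called. Of
the 50 non-genic DMRs, 21 link to genes through intersection-TADs (13 of
them only via the spatial, anchor-mediated distance — including every
planted anchor-opposite pair), and the one organ planted at 2-fold
enrichment among the true DMGs is the only organ significant at
FDR < 0.05. The placement report (`demo/placement_tests.json`) shows the
DMR inside-TAD fraction and boundary-proximal count both exceeding every
simulation (empirical p = 1/201 and 1/10001 scale respectively, with
concordant χ² p-values).

Each stage is also available standalone (`tadlink simulate`,
`consensus-tads`, `placement-test`, `link`, `enrich`) on the files the
previous stage wrote, and as library functions.

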