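# Methods

## Model and assumptions

The analysis treats a TAD as a linear interval with two boundary
anchors. Three modelling assumptions drive everything downstream:

1. **Conservation implies presence.** A TAD found at similar
   coordinates in several unrelated cell types is assumed to be present
   in unobserved tissues as well; the conservation score quantifies
   "similar coordinates" as the median, over the three non-basis cell
   types, of the best Jaccard overlap against any TAD of that cell
   type. The basis cell type should be the one with the most TAD calls,
   and `run_pipeline` selects it that way automatically.
2. **TAD membership constrains regulation.** A DMR and a gene are only
   considered linkable when they share a conserved TAD; within one, a
   generous 50 kb cutoff (the typical upper range of enhancer–target
   separations) is applied to either the linear or the spatial distance.
3. **Anchors touch.** The spatial distance models loop formation as
   bringing the two TAD boundaries into contact, so an element's
   effective position is its clamped distance to an anchor, and two
   elements near opposite anchors are nearly adjacent in 3D.

Coordinates are 0-based half-open throughout; chromosome names are
matched as exact strings; intervals are unstranded. In the Jaccard
formula the "union" of two disjoint intervals is the sum of their
lengths (set union of bases), not the spanning interval — the choice
only matters for pairs that score zero overlap anyway.

## Statistical procedures

**Permutation test (consensus).** Each tested TAD is replaced by `n`
uniform-random intervals of the same length *on the same chromosome*
(preserving chromosome-level TAD density; the placement of the null
interval is otherwise unconstrained and may overlap other TADs). Only
TADs passing the length and score filters are tested, and
Benjamini–Hochberg FDR is computed over that tested set. Each TAD gets
an independent random stream seeded by (global seed, basis index), so
results are reproducible and order-independent. All Monte Carlo
p-values in the package use the (r+1)/(n+1) convention and are never 0.

**Composition-matched randomization.** "Similar" composition is
operationalized as absolute tolerances: GC fraction ± 0.05 and CpG
density ± 0.005 per bp, length preserved exactly. Candidates are drawn
uniformly over all genome positions admitting the length (chromosomes
weighted by available positions); if `max_tries` (1000) consecutive
candidates yield no acceptance the tolerances double, a warning is
logged and the relaxation is counted in the test result. Interval GC
and CpG counts come from per-chromosome prefix-sum arrays, making each
candidate O(1) and the 200-simulation default cheap.

**Boundary-proximity null.** The null repositions each participating
DMR uniformly *within its containing TAD* (largest-overlap assignment,
leftmost TAD on ties; DMRs longer than their TAD are excluded with a
warning). Conditioning on TAD membership isolates boundary preference
from the inside-TAD effect, which the first test already measures.
Proximity uses the closest-edge distance, clamped to 0 for DMRs
straddling a boundary.

**Two-cell χ².** Observed (inside, outside) or (proximal, non-proximal)
counts are compared to the simulation-mean expectation with a df=1
goodness-of-fit on counts, no continuity correction. Degenerate
expectations (0 or the full count) yield NaN rather than a fabricated
statistic.

**Linking tie-breaks.** The effective DMR–gene distance is the minimum
over shared TADs of min(linear, spatial). Candidates are ordered by
(distance, gene_id, linear-before-spatial, tad_id), making link sets
deterministic. Gene distance is measured to the nearest gene-body edge
(symmetric with the DMR treatment); a TSS mode exists as an option.
"Different ends of the same TAD" is not enforced as a hard eligibility
rule — the min-over-pairings formula plus the 50 kb threshold already
confines spatial links to near-anchor geometry without introducing an
arbitrary cutoff.

**Enrichment.** Expected counts are |list|·|organ|/|background| — the
only formula consistent with treating every background gene as
exchangeable — with a one-sided empirical p from 10,000 random
same-size gene sets and an exact hypergeometric alternative used as a
cross-check in the tests. Depletion is not tested by default. BH-FDR
spans all organs in the table.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the pipeline assumes:
four TAD tracks sharing a conserved fraction with rounded-Gaussian
boundary jitter (sd 5 kb by default, clipped at 4 sd and absorbed by
inter-TAD spacing), genes, a DMR mixture (67% genic, mirroring the
real DMR set's composition; half of the non-genic remainder within
50 kb of a conserved boundary), anchor-opposite DMR–gene pairs, and a
gene→organ table with planted enrichment. Defaults: 2 chromosomes ×
20 Mb, GC 0.41, CpG rate 0.01/bp, 60 TADs per cell type (120–500 kb),
200 genes (5–50 kb), 150 DMRs (0.5–2.5 kb), 5 spatial pairs, 15 organs
at base rate 0.2.

Genome sequences are drawn i.i.d. at the target GC and then edited to
the target CpG dinucleotide rate with composition-preserving CG→GC
swaps (or CG plants when below target); this hits both first-order
composition targets without sequential simulation. The genome is
homogeneous — it has no isochores, CpG islands, repeats or N-gaps — so
composition-matched randomization accepts at a high rate and the
matched null is nearly uniform. Passing calibration here shows the
machinery is correct, not that matched randomization is unbiased on a
real, heterogeneous genome where acceptance varies regionally.
Similarly, synthetic TADs are disjoint within a cell type and conserved
ones are exact replicas plus jitter; real TAD calls are nested,
resolution-dependent and noisier, so real sensitivity will be lower
than the planted-recovery figures.

Two planting details matter for interpretation. Spatial-pair anchor
offsets are drawn *beyond* the 4 sd jitter clip bound (with the offset
sum kept under 48 kb), so a planted element cannot fall outside the
intersection boundary variant; other genes are kept out of planted
TADs so each pair has a unique correct answer. And a planted organ at
fold F assigns the organ to DMG genes at rate F·f with a compensating
rate for the rest, keeping the background fraction at f so the
*expected* enrichment ratio equals F; folds with F·|list| > |background|
are infeasible and capped with a warning — with ~90 true DMGs out of
200 genes the default planted fold is therefore 2.0.

## Problem sizes in the test suite

Statistical tests run at sizes chosen for stable assertions: null
conservation calibration uses 180 query TADs (3 seeds × 60) drawn from
the same uniform law as the permutation null, making their p-values
exchangeable by construction, with 999 permutations each; planted
consensus recovery uses two default-scale datasets at 1000
permutations; inside-TAD type-I calibration uses 200 replicates of 40
uniform DMRs on a 2 × 4 Mb genome at 500 simulations per test; the
linking oracle covers 100 random instances up to 50 DMRs × 50 genes ×
10 TADs per boundary variant.

## Known limitations

* The spatial distance ignores intra-TAD contact frequency; it is a
  geometric proxy for anchor-mediated contact, not a polymer model.
* Promoter/genic classification of DMRs is an upstream input; the
  package trusts the flag column.
* The permutation scheme for TAD conservation fixes the chromosome but
  not the local TAD landscape; clustered TAD placement could make the
  null slightly liberal on real data.
* Organ annotations are flat labels; no ontology structure or
  gene-length bias correction is applied.
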