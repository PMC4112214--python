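# Methods

## Duplication-mode classification

Every gene receives exactly one mode by applying rules in a fixed
precedence order (`wgd_segmental > tandem > proximal > transposed >
dispersed`, singleton for genes with no evidence), mirroring the semantics
of the MCScanX family of classifiers that most published duplication
censuses rely on:

1. genes anchored in ≥ 1 within-genome collinear block are
   whole-genome/segmental duplicates;
2. homolog pairs at rank distance exactly 1 on one chromosome are tandem;
   arrays of adjacent homologs link transitively, so every member of a
   k-gene tandem array is tandem;
3. remaining same-chromosome pairs at rank distance 2..20 are proximal
   (the window is a parameter: published conventions disagree on whether
   the ≤ 20-gene window or its complement defines proximal, so
   `ClassificationParams.proximal_max_rank_distance` is exposed with
   default 20);
4. when a caller supplies an outgroup-anchored gene set (loci whose
   collinearity with an outgroup genome marks them ancestral), a pair with
   exactly one anchored member marks the *other* member transposed; the
   anchored member itself falls through to dispersed. Without that set the
   rule is skipped — full transposition dating needs multi-genome input
   that is out of scope;
5. everything else with a retained hit is dispersed.

A gene touched by several pair types takes its highest-precedence mode.
Rank distances are computed on 0-based per-chromosome gene orders assigned
by start coordinate (ties by end, then id); strand is carried but ignored,
since all distance rules are strand-blind. Homology input must first pass
the hit filter (self-hits removed, E ≤ 1e-5, best 5 per query, ties at the
boundary broken by subject id for determinism).

Duplication depth is the number of distinct blocks in which a gene is an
anchor; the median is reported over genes with depth ≥ 1 and is undefined
(reported absent) when there are no blocks.

Summary percentages use the mode-count column sum as denominator and are
rounded half-away-from-zero to one decimal; the "fraction duplicated"
headline, `100·(1 − singleton/total)`, is rounded to the nearest integer.

## Null models

**Tandem.** The expected number of within-window pairs in a family of size
N is estimated by placing N genes of size 1 kb uniformly at random in a
100,000 kb genome and counting unordered pairs whose starts differ by at
most 50 kb, averaged over 1000 replicates per size on the grid
N = 10..300 step 10; off-grid sizes are linearly interpolated. Genes may
overlap (no exclusion volume): the model is an idealised geometry, not a
packing simulation. The closed form `C(N,2)·(2w/L′ − (w/L′)²)` with
`L′ = genome_length − gene_size` (the band area around the diagonal of the
L′×L′ square) serves as an independent check; simulation and closed form
agree within 3 standard errors at every grid size tested.

**Segmental.** Under unbiased retention in a genome where ~75% of genes
lie in at least one segmentally duplicated block, a family of size N
expects `0.75·N` segmental members.

**Units.** The tandem simulation counts *pairs* while summary tables count
*genes*. `FamilyCounts` carries both (`observed` in genes,
`observed_tandem_pairs` in pairs); observed/expected ratios use pair units
when available, since that matches the simulation's unit system. Ratio
bands are assigned per axis from the median and sample SD (n−1) of the
per-family ratios; the box is the open interval (median−1SD, median+1SD)
and a ratio exactly on a ±1SD or ±2SD boundary belongs to the band farther
from the median.

## Enrichment statistics

Each (family, mode) cell is tested with a two-sided Fisher's exact test
(point-probability method, as in standard implementations) on the 2×2
collapse of the count matrix: the family against all other families in the
matrix, the mode against all other modes. P-values are Benjamini–Hochberg
corrected across all cells jointly (statsmodels' step-up); Pearson
residuals `(O − E)/√E` with `E = row·col/total` give direction and
strength. Cells on a zero margin are flagged degenerate with p = 1 and
residual 0. Phenotype-class enrichment applies the same machinery to a
focal gene set against the background, correcting across classes.

Calibration and power are established on sampled count matrices
(`sample_mode_counts`): under the global null the fraction of raw p ≤ 0.05
is ~0.04 over 200 replicates (Fisher is conservative on discrete tables);
a family of 60 genes given 3× the background tandem rate (background mode
probabilities fixed at the published genome-wide shares: segmental .26,
dispersed .41, proximal .046, tandem .10, singleton .184) inside a
3000-gene genome, tested against the aggregated remainder, is detected
(BH-adjusted p < 0.05, positive residual) in ≥ 90 of 100 replicates. The
phenotype power study samples 2000 genes from the class frequencies
observed among phenotype-annotated genes (conditional .45, morphological
.29, essential .18, cellular/biochemical .08) with a 150-gene focal set
whose essential odds are tripled; power is ~1.0.

## Synthetic genomes

The generator builds the study conditions the tests run under: by default
2550 ancestral genes on 5 chromosomes plus 50 events of each mode
(segmental blocks of 5 genes, so 3000 genes total). Events are planted
exactly as the classifier defines them — tandem copies adjacent, proximal
copies 2..20 ranks away, segmental events copying a run of consecutive
genes in order and emitting the corresponding collinear block, transposed
copies on another chromosome with the source recorded as the
outgroup-anchored ancestral locus, dispersed copies ≥ 21 ranks away. Each
gene participates in at most one event, so every planted mode is
unambiguous; insertion slots that would split a planted tandem pair or
push a proximal pair past the 20-rank window are rejected and resampled.
Coordinates are re-spaced uniformly (1 kb genes every 2 kb) after all
events, mirroring the null model's idealised geometry.

Derived generators share one seed with deterministic substreams:

* **hits** — a reciprocal below-cutoff hit per true pair plus a
  configurable rate of spurious hits with E-values log-uniform over
  1e-8..1e-3 (straddling the 1e-5 cutoff, so ~60% survive filtering);
* **expression** — ancestral genes get independent standard-normal
  profiles; a copy's profile is `ρ·source + √(1−ρ²)·noise` with ρ per mode
  (defaults 0.7 segmental, 0.4 tandem, 0.1 proximal, 0.0 transposed and
  dispersed, ordered to reflect the observed conservation gradient), so a
  planted pair's expected sample correlation is exactly ρ;
* **family trees** — ancestral members start as a root polytomy and each
  event replaces its source leaf with a `(source, copy)` cherry, so the
  MRCA of every planted pair is the node its event created;
* **phenotypes / interactions** — class labels with an optional planted
  focal enrichment, and Poisson-degree edges into a non-focal background
  with optional exact-degree hubs.

What the generator does **not** emulate: sequence evolution, gene loss and
pseudogenization after WGD, overlapping or nested events on one gene,
realistic branch lengths, and correlated noise structure in expression.
Passing tests therefore demonstrate that the pipeline's inference is
correct *given* evidence of the assumed form, not that real-genome
evidence takes that form; on real inputs the hit filter, block detection
quality and annotation completeness dominate accuracy.

## Phylogeny annotation and MRCA mapping

An unlabeled tip takes its sister clade's family when the sister clade's
labeled tips are unanimous; otherwise the smallest enclosing clade with
any labeled tips votes, requiring a strict > 50% majority (ties are
ambiguous). Existing labels are never changed: a labeled tip whose sister
clade unanimously carries another family is reported as a conflict for
expert review. Node support values are reported, not thresholded. Trees
whose seed node has more than two children and which carry branch lengths
are midpoint-rooted with a warning.

## Problem sizes and numerical choices

The default test and acceptance workloads are: 20 synthetic genomes of
3000 genes for classifier recovery, 1000 replicates per grid size for the
null simulation, 200 null and 100 planted replicates for enrichment
calibration, and 500 expression samples for coexpression recovery — sizes
at which every stochastic check sits several standard errors clear of its
threshold while the whole suite runs in well under a minute. Correlations
are pooled across all samples by default; a Fisher-z per-set average is
provided (`fisher_z_mean`) because multi-set expression compendia can also
be combined per set. Hierarchical clustering uses average linkage on
1 − r with genes pre-sorted lexicographically so merge ties are
deterministic. Hub calling uses degree ≥ 20: published hub lists include
proteins with exactly 20 partners, so the threshold is inclusive (and
configurable).
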