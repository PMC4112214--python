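# kinodup

Gene families expand by several distinct duplication mechanisms — tandem and
proximal duplication along a chromosome, whole-genome or large segmental
duplication that leaves collinear (synteny) blocks, transposition of a copy
to a new locus, and dispersed duplication with no positional signature.
Which mechanism a family retains its duplicates from correlates with its
biology: in plant kinomes, receptor-kinase families tend to keep tandem
duplicates while cytosolic kinase families keep segmental ones, and the two
routes differ in how strongly the duplicates conserve their expression.

`kinodup` is a tested, reusable implementation of that analysis for anyone
studying a gene family in a genome with annotated gene positions: it

* classifies every gene into one of six modes — `wgd_segmental`, `tandem`,
  `proximal`, `transposed`, `dispersed`, `singleton` — from gene order,
  filtered homology hits and collinear blocks (MCScanX `.collinearity`
  dialect is read directly);
* computes null expectations: a Monte Carlo model for tandem pair counts
  (N genes of 1 kb placed uniformly in a ~100,000 kb genome, pairs within a
  50 kb window, family sizes 10–300, 1000 replicates, with the closed form
  `C(N,2)·(2w/L′ − (w/L′)²)` as an independent check) and `0.75·N` for
  segmental counts;
* tests family × mode enrichment with two-sided Fisher's exact tests,
  Benjamini–Hochberg correction and Pearson residuals `(O − E)/√E`, and
  assigns observed/expected ratios to median ± 1/2 SD bands;
* quantifies expression divergence of duplicate pairs (Pearson correlation
  by mode against a random-pair baseline, plus clustering-vs-phylogeny gene
  orderings for heat maps);
* annotates unlabeled genes on a phylogeny from their sister clade or
  smallest labeled enclosing clade, and maps duplicate pairs to MRCA nodes;
* reports interaction-network degree statistics and hubs by mode;
* ships a synthetic-genome generator that plants duplication events of every
  mode with full ground truth — the oracle behind the entire test suite.

## Worked example

Generate a 3000-gene genome with 50 planted events per mode, classify it
from noisy homology evidence, and tabulate the summary:

```python
from kinodup import (SyntheticConfig, generate_genome, filter_hits,
                     classify_duplications, tabulate_summary)
from kinodup.simulate import generate_hits

cfg = SyntheticConfig(seed=1)
genome, truth = generate_genome(cfg)
hits = filter_hits(generate_hits(truth, noise=0.05))   # E ≤ 1e-5, top 5/query
labeling = classify_duplications(genome, hits, truth.planted_blocks,
                                 truth.outgroup_anchored)
summary = tabulate_summary(labeling)
for mode, cell in summary["all"].items():
    print(f"{mode:15s} {cell['count']:5d} ({cell['percent']}%)")
print("duplicated:", summary["fraction_duplicated"], "%")
agree = sum(labeling.mode_of[g] == m for g, m in truth.true_mode.items())
print(f"ground-truth agreement: {agree}/{len(truth.true_mode)}")
```

prints

```
wgd_segmental     500 (16.7%)
tandem            100 (3.3%)
proximal          102 (3.4%)
transposed         50 (1.7%)
dispersed         191 (6.4%)
singleton        2057 (68.6%)
duplicated: 31.0 %
ground-truth agreement: 2957/3000
```

The 500 segmental genes are the 50 planted blocks of 5 anchor pairs each;
the 43 disagreements are all caused by the 5% spurious-hit noise (at noise
0 the agreement is 3000/3000).

The same stages are available from a shell:

```sh
kinodup simulate --seed 1 --out sim/
kinodup classify --genes sim/genes.tsv --hits sim/hits.tsv \
    --collinearity sim/blocks.collinearity \
    --outgroup-anchored sim/outgroup_anchored.txt --out labels.tsv
kinodup run-all --seed 1 --out results/      # full pipeline, 9 outputs
```

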