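# isopipe

Downstream transcriptome analysis for a two-condition × two-cell-type bulk
RNA-seq design: isoform- and gene-level differential expression,
alternative-splicing event detection and structural classification,
functional enrichment, and DE-gene network assembly — driven end-to-end by
a synthetic-data generator that plants known effects, so every stage is
verifiable against ground truth without access to the original libraries.

The emulated experiment contrasts brain microglia and peritoneal
macrophages from mice challenged with BCG (Bacille Calmette-Guérin)
against saline controls, 12 animals per group: two challenge contrasts
(BCG vs Control within cell type) and two cell-type contrasts (within
challenge group).

## What it computes

- **Differential expression.** Genes with < 10 raw reads over a
  contrast's samples are dropped; libraries are upper-quartile
  normalized (factor = 75th percentile of nonzero counts / geometric mean
  of those percentiles) with a composition polish; each unit is tested
  with Welch's *t* on log2(normalized + 1); BH-adjusted *q* < 0.05 with
  log2FC = log2(B/A) defines over/under-expression. Gene abundance is the
  sum of isoform abundances.
- **Alternative splicing.** A gene is a candidate when it has ≥ 2
  isoforms, ≥ 1 DE isoform, and its isoforms do not all move in one
  direction. Discordant isoform pairs are classified by exon-chain
  comparison into six modes: cassette, tandem cassette, alternative 3′ /
  5′ splice site (strand-aware), intron retention, mutually exclusive
  exons.
- **Enrichment.** Hypergeometric over-representation with jackknifed
  EASE p-values, kappa-based annotation clustering scored by
  ES = −log10(geometric mean of member EASE p) with significance at
  ES > 2, and a weighted running-sum (GSEA-type) score with gene-set
  permutation significance.
- **Networks.** DE–DE interaction edges plus at most one non-measured
  connector gene bridging ≥ 2 DE genes; degree/hub reports; SIF and
  GraphML export with direction and significance as node attributes.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 2016; 300 genes, 48 samples) and write tables under
`results/`:

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_splicing_events.py
python analysis/04_enrichment.py
python analysis/05_network.py
```

`01` plants 31 DE genes (28 over-expressed) and 19 discordant splicing
genes. `02` then reports, among other lines:

```
microglia: BCG vs Control [gene]: 300 analyzed, 50 DE (47 over / 3 under, 94% over)
  recovery vs truth: sensitivity 1.00, empirical FDR 0.031
DE genes shared between the two challenge contrasts: 49
```

— the planted challenge effect is fully recovered in both cell types
(the cell-type contrasts are null by construction and yield 0 DE genes),
with the over-expression predominance and cross-cell overlap the design
planted. `03` recovers all 19 planted splicing genes and their modes:

```
qualifying splicing-candidate genes: 22
  tandem_cassette: 5 genes (23%)
  alt5: 5 genes (23%)
  cassette: 4 genes (18%)
planted-event recovery: sensitivity 1.00, mode accuracy 1.00 (19/19 genes)
```

`04` finds the three planted-signal gene sets as the top
over-representation hits (e.g. `SIGNAL_03: k=16/25, p_hyper=2.5e-08`)
and the top annotation cluster at ES 6.6; `05` assembles a 36-node
network (31 observed DE genes — 94% over-expressed — plus 5 external
connector genes) and lists its hubs.

The same machinery is available as a CLI
(`isopipe simulate|diffexpr|splicing|enrich|network|run-all`) and as
library functions (`isopipe.diffexpr`, `isopipe.splicing`,
`isopipe.enrichment`, `isopipe.network`, `isopipe.simulate`).

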