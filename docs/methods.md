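# Methods

`isopipe` re-creates, as tested library code, the downstream analysis of a
two-condition × two-cell-type bulk RNA-seq experiment: an immune challenge
(BCG vs saline Control, 12 animals per group) crossed with two innate
immune cell populations (brain microglia and peritoneal macrophages).
Because the original sequencing data are not redistributable, a synthetic
data generator plants known differential-expression and splicing effects
so every downstream stage can be verified against ground truth.

## Differential expression

Counts are isoform × sample. For each contrast the pipeline:

1. **Filters** genes with fewer than 10 raw mapped reads summed over the
   contrast's samples (all isoforms of a failing gene are dropped). The
   filter is contrast-local — applied to the raw counts of exactly the
   samples entering the comparison, before any normalization — which is
   why the number of analyzed units differs across contrasts.
2. **Normalizes** by the upper-quartile method: each library's factor is
   its 75th percentile of nonzero counts divided by the geometric mean of
   those percentiles across libraries, and counts are divided by the
   factor. Factors are geometric-mean-centered so normalized counts keep
   the raw magnitude.
3. **Polishes composition.** Quantile scaling is not robust to one-sided
   differential expression: when ~10% of genes rise four-fold in one
   group, the upper quartile rises with them and every unchanged gene
   inherits a spurious negative fold change (~−0.2 log2 under the default
   planted signal, measured). Two corrections restore calibration:
   a trimmed-mean-of-M-values factor per sample (trim 0.3, computed over
   units positive in every sample, in the edgeR TMM tradition), then a
   between-group recentering that zeros the *median* per-unit mean log2
   difference between the two groups. Genuinely changed units lie many
   standard errors from the null bulk, so the median ignores them; under
   a pure-null simulation the recentering is an approximate identity and
   the p-value distribution stays uniform (KS check in the test suite).
   The correction assumes most units are unchanged — the standard
   normalization assumption — and will mis-center if a majority of the
   transcriptome truly shifts one way.
4. **Tests** every unit with Welch's unequal-variance t on
   log2(normalized + 1) per sample. Gene-level abundance is the sum of
   the gene's isoform abundances. `log2fc = log2((mean_B + 1)/(mean_A + 1))`
   with B the second-named group (so challenge contrasts report
   log2(BCG/Control)). When both groups have zero variance, equal means
   give p = 1 and unequal means p = 0.
5. **Adjusts** p-values by Benjamini–Hochberg step-up, separately per
   contrast × level family (gene and isoform families are never pooled).
   A unit is `over` when q < 0.05 and log2fc > 0, `under` when q < 0.05
   and log2fc < 0, otherwise `non`. Alpha is configurable; 0.05 is the
   default throughout.

The percentage of over-expressed DE units is reported rounded to the
nearest integer (518 over of 562 DE → 92%).

## Alternative-splicing candidate rule

A gene qualifies in a contrast when it has ≥ 2 isoforms, ≥ 1 isoform
differentially expressed, and its isoforms are not all DE in one single
direction — i.e. some DE direction is witnessed while at least one other
isoform is non-DE or DE the other way. The returned direction is `over`,
`under`, or `either` when both directions witness the rule. The rule is
deliberately insensitive to isoform order and to how many isoforms carry
each status beyond the witness requirement.

## Structural event classification

Isoforms are exon chains (1-based inclusive genomic intervals) on a
strand. For a qualifying gene, every (DE isoform, status-non-concordant
isoform) pair is compared and per-pair modes are unioned per gene, so a
gene can carry several modes and mode frequencies may sum above 100%.
Modes, defined on shared internal structure:

- **cassette** — one internal exon of one chain absent from the other,
  its flanking exons shared and adjacent in the shorter chain;
  **tandem cassette** — the same with ≥ 2 consecutive internal exons;
- **alt3 / alt5** — two introns share one boundary and differ at the
  other, with the exons flanking the differing boundary overlapping
  (the overlap requirement distinguishes a shifted splice site from exon
  skipping). Resolved in transcript orientation: an acceptor-side
  difference is alt3, a donor-side difference alt5, so the labels swap
  under strand flip;
- **intron retention** — a single exon of one chain spanning exactly an
  exon–intron–exon triplet of the other, flanks agreeing at both
  boundaries (partial overlaps are left unclassified);
- **mutually exclusive exons** — each chain holds one internal exon
  absent from the other, the two exons non-overlapping, between shared
  flanks.

Differences confined to the outer boundary of first/last exons
(transcription start/end variation) are ignored: the taxonomy concerns
splice sites. Identical chains classify to the empty set. No precedence
is imposed when modes co-occur in one pair.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability of the
observed category overlap within a user-supplied universe; the EASE
variant removes one gene from the overlap first (a jackknife that
penalises single-gene categories; overlap ≤ 1 gives p = 1, and
EASE p ≥ hypergeometric p always). Categories are clustered greedily:
seed with the most significant unclustered category, absorb any category
whose Cohen's kappa (over membership indicator vectors on the universe)
with some member reaches 0.5, repeat. A cluster's Enrichment Score is
−log10 of the geometric mean of member EASE p-values, significant
strictly above 2 (uniform member p of 0.01 sits exactly at the boundary
and is not significant). The threshold follows the score formula, i.e.
geometric-mean p = 0.01 at ES 2; clustering composition is a documented
stand-in for proprietary annotation-clustering tools, and nothing
downstream depends on exact cluster membership.

The running-sum (GSEA-type) score walks the ranked gene list: hits add
|score|^w normalized by the hit total (w = 1 by default), misses subtract
1/(L−H); the score is the signed maximum deviation. Significance uses
gene-set permutation — random same-size draws from the ranked list — with
a smoothed permutation p ((c+1)/(n+1) over same-signed nulls), NES by
mean |same-signed null|, and BH q across sets. Gene-set (rather than
phenotype) permutation was chosen for desk-scale determinism; it is less
conservative on correlated data, which is immaterial for the synthetic
workloads here.

## Network assembly

From gene-level DE calls and an interaction edge list: edges joining two
DE genes are kept; a gene absent from the DE list enters only as a
*connector* when it joins ≥ 2 DE genes (the "at most one non-measured
gene between observed genes" convention, read strictly — measured but
non-DE genes are not used as connectors). Connector–connector edges
never occur by construction; isolated DE genes are dropped. Nodes carry
direction and p-value so GraphML exports can encode significance as node
size and direction as color; components under 6 nodes can be filtered
out for reporting.

## Synthetic data generator

What it emulates: the 2 × 2 study design with 12 replicates per
(challenge, cell) cell; overdispersed counts; a DE signal dominated by
over-expression; and genes whose isoforms respond discordantly while
realising a known structural mode.

- **Structures.** Genes are laid head-to-tail on one pseudo-chromosome
  (10 kb gaps; layout is cosmetic). Each gene draws an isoform count
  (default mixture 1–5, mean ≈ 2.3) and an exon chain (first exon
  180–280 bp, internal exons 80–200 bp, introns 250–500 bp). A gene
  drafted for a splicing event gets a second isoform differing from the
  base chain by exactly the drawn mode; all other isoforms differ only by
  transcription-start shifts, which the classifier ignores — so the
  planted mode is the only classifiable signal in the gene.
- **Counts.** Negative binomial with var = μ + φμ², φ = 0.1 by default
  (φ = 0 degenerates to Poisson). A gene's expected total is
  `baseline_mean × n_isoforms × LogNormal(0, 1.5)`, split across isoforms
  by a Dirichlet(5) draw. Per-sample library factors are log-uniform in
  [0.5, 2], so normalization has real work to do.
- **Planted effects.** DE genes (default 10% of genes, drawn among genes
  without a splicing event so the two truths stay disjoint) multiply all
  isoform means by 2^(±2) in BCG samples, over-expressed with
  probability 0.9. Splicing-event genes (default 10% of multi-isoform
  genes; studies of this kind typically report events in only a few
  percent of analyzed genes, so the default is generous while keeping
  enough planted events to measure recovery) move their structural pair
  discordantly: one isoform
  ×4, the other ×1/4, the rest flat. Effects ride the challenge axis in
  both cell types, leaving the cell-type contrasts null.
- **Determinism.** All draws flow through one seeded generator;
  identical configs give byte-identical GTF and count output.

What it does **not** emulate: read-level sampling, positional/GC bias,
isoform-share (usage) shifts without expression change, correlated genes,
batch structure, or the heavy-tailed isoform-count distribution of real
annotation. Passing recovery tests therefore demonstrates the pipeline's
correctness on its stated model, not performance on real libraries.

### Recovery evaluation

Gene-level sensitivity is the fraction of planted DE genes called at
q < 0.05; empirical FDR counts false positives among genes with *no*
planted effect (splicing-event genes are excluded from the null
denominator because their discordant isoform effects legitimately
perturb the gene-level sum). Splicing sensitivity is the fraction of
planted event genes whose per-gene call qualifies; mode accuracy is the
fraction of recovered genes whose planted mode appears in the call.

## Problem sizes and tolerances

Default simulations use 300 genes (~680 isoforms) × 48 samples — large
enough that recovery metrics are stable to ±0.03 across seeds while a
full five-seed recovery run completes in seconds. Hypergeometric values
are validated against exact integer-arithmetic summation to 1e-9
relative; the BH and running-sum implementations against brute-force
re-evaluation to float precision. Permutation analyses use 200–1000
permutations depending on context; determinism is exact given a seed.

## Known limitations

- The Welch test on log2 counts is a pragmatic stand-in for a count
  GLM; at very low counts (< ~5 per sample) it loses power and its
  p-values become conservative.
- The composition recentering assumes < 50% of units change in one
  direction.
- Alt3/alt5 classification requires exact agreement at the shared intron
  boundary; noisy annotations with near-matching boundaries are left
  unclassified rather than guessed.
- Connector selection is conservative (non-DE measured genes never
  bridge); a config flag relaxing it to the non-analyzed universe is
  provided on the network CLI.
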