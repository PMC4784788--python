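#!/usr/bin/env python
"""Generate the synthetic study data every later step analyses.

Emulates the study layout: two challenge groups (BCG vs saline Control,
12 mice each) by two cell types (microglia, peritoneal macrophages),
negative-binomial isoform counts, 10% of genes differentially expressed
at |log2FC| = 2 with 90% over-expressed, and 10% of multi-isoform genes
carrying a discordant isoform pair realising a known splicing mode.

Writes GTF, count matrix, design table and the planted-truth table under
results/sim/.
"""

from pathlib import Path

from isopipe import io
from isopipe.simulate import (
    SimulationConfig,
    generate_transcriptome,
    simulate_counts,
    simulate_edge_list,
    simulate_gene_sets,
)

SEED = 2016
OUT = Path("results/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    models, truth = generate_transcriptome(cfg)
    matrix, truth = simulate_counts(models, cfg, truth)

    io.write_gtf(models, OUT / "transcripts.gtf")
    io.write_counts(matrix, OUT / "counts.tsv", OUT / "design.tsv")
    io.write_truth_table(truth, OUT / "truth.tsv")

    genes = sorted({m.gene_id for m in models})
    io.write_gene_sets(
        simulate_gene_sets(genes, truth, seed=SEED), OUT / "gene_sets.gmt"
    )
    io.write_edge_list(
        simulate_edge_list(genes, truth, seed=SEED), OUT / "edges.tsv"
    )

    n_multi = sum(
        1 for g in genes
        if sum(m.gene_id == g for m in models) >= 2
    )
    print(f"wrote {OUT}/: {len(genes)} genes, {len(models)} isoforms "
          f"({n_multi} multi-isoform genes), {len(matrix.samples)} samples")
    print(f"planted: {len(truth.de_genes)} DE genes "
          f"({sum(1 for d in truth.de_genes.values() if d == 'over')} over), "
          f"{len(truth.as_genes)} discordant splicing genes")


if __name__ == "__main__":
    main()
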