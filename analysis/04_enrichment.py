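#!/usr/bin/env python
"""Functional enrichment of the microglia challenge-contrast DE genes.

Over-representation analysis (hypergeometric and jackknifed EASE p-values)
against the simulated gene-set catalogue, kappa-based annotation clustering
with cluster Enrichment Scores (-log10 geometric mean of member EASE p,
significant above 2), and the permutation-scored running-sum analysis over
the full log2FC ranking. Writes record and cluster tables under
results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from isopipe import io
from isopipe.enrichment import cluster_annotations, enrich_list, gsea_significance
from isopipe.pipeline import de_gene_set, enrichment_frame

DATA = Path("results/sim")
DE = Path("results/de")
OUT = Path("results/enrichment")
CONTRAST_SLUG = "microglia_BCG_vs_Control"
SEED = 2016


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gene_results = io.read_de_table(DE / f"de_{CONTRAST_SLUG}_gene.tsv")
    collection = io.read_gene_sets(DATA / "gene_sets.gmt")
    universe = sorted({r.gene_id for r in gene_results})
    de_genes = sorted(de_gene_set(gene_results))
    print(f"{len(de_genes)} DE genes over a universe of {len(universe)}")

    records = enrich_list(de_genes, collection, universe)
    enrichment_frame(records).to_csv(OUT / "ora.tsv", sep="\t", index=False)
    top = records[:3]
    for r in top:
        print(f"  {r.category_id}: k={r.k}/{r.K}, p_hyper={r.p_hyper:.2e}, "
              f"p_ease={r.p_ease:.2e}, q={r.q:.2e}")

    clusters = cluster_annotations(records, collection, universe)
    pd.DataFrame(
        [
            {"members": ";".join(c.members), "es": round(c.es, 3),
             "significant": c.significant}
            for c in clusters
        ]
    ).to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    n_sig = sum(c.significant for c in clusters)
    print(f"{len(clusters)} annotation clusters, {n_sig} with ES > 2")
    if clusters:
        best = clusters[0]
        print(f"  top cluster ES {best.es:.2f}: {', '.join(best.members)}")

    ranked = sorted(
        ((r.gene_id, r.log2fc) for r in gene_results), key=lambda t: -t[1]
    )
    gsea = gsea_significance(ranked, collection, n_perm=1000, seed=SEED)
    pd.DataFrame(
        [
            {"set": r.set_id, "es": round(r.es, 4), "nes": round(r.nes, 3),
             "p": r.p, "q": r.q, "n_hits": r.n_hits}
            for r in gsea
        ]
    ).to_csv(OUT / "gsea.tsv", sep="\t", index=False)
    ranked_sets = sorted(gsea, key=lambda r: r.p)
    n_nominal = sum(r.p < 0.05 for r in gsea)
    print(f"running-sum analysis: {n_nominal} of {len(gsea)} sets at "
          f"nominal p < 0.05; top sets:")
    for r in ranked_sets[:3]:
        print(f"  {r.set_id}: ES {r.es:.2f}, NES {r.nes:.2f}, "
              f"p {r.p:.4f}, q {r.q:.4f}")


if __name__ == "__main__":
    main()
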