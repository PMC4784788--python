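"""End-to-end orchestration of the four study contrasts.

Two challenge contrasts (BCG vs Control within each cell type) and two
cell-type contrasts (microglia vs macrophage within each challenge group)
are run at gene and isoform level; splicing calls, enrichment, and network
assembly follow on top. ``run_all`` drives either real input files or a
seeded simulation and writes a tab-delimited report bundle plus a
machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, io
from .diffexpr import (
    between_group_recenter,
    filter_low_expression,
    overlap_and_unique,
    summarize_contrast,
    test_two_group,
    tmm_polish,
    upper_quartile_normalize,
)
from .enrichment import cluster_annotations, enrich_list, gsea_significance
from .errors import ConfigurationError
from .models import CELLS, CHALLENGES, DEResult, ExpressionMatrix
from .network import build_network, component_filter, degree_report
from .simulate import (
    SimulationConfig,
    SimulationTruth,
    generate_transcriptome,
    simulate_counts,
    simulate_edge_list,
    simulate_gene_sets,
)
from .splicing import call_gene_events, summarize_modes

log = logging.getLogger(__name__)

#: (label, fixed design condition, (group A value, group B value), axis)
STUDY_CONTRASTS = [
    ("microglia: BCG vs Control", {"cell": "microglia"}, "challenge", ("Control", "BCG")),
    ("macrophage: BCG vs Control", {"cell": "macrophage"}, "challenge", ("Control", "BCG")),
    ("BCG: macrophage vs microglia", {"challenge": "BCG"}, "cell", ("microglia", "macrophage")),
    ("Control: macrophage vs microglia", {"challenge": "Control"}, "cell", ("microglia", "macrophage")),
]


@dataclass
class RunConfig:
    counts: Optional[str] = None
    design: Optional[str] = None
    gtf: Optional[str] = None
    gmt: Optional[str] = None
    edges: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    alpha: float = 0.05
    min_reads: int = 10
    min_component: int = 6
    n_perm: int = 200
    outdir: str = "results/run"
    seed: int = 0

    def validate(self) -> None:
        has_real = self.counts is not None and self.design is not None
        if not has_real and self.simulation is None:
            raise ConfigurationError(
                "either counts+design paths or a simulation block is required"
            )


def run_contrast(
    matrix: ExpressionMatrix,
    label: str,
    condition: dict,
    axis: str,
    groups: tuple[str, str],
    alpha: float = 0.05,
    min_reads: int = 10,
) -> dict:
    """Filter, normalize and test one contrast at both levels."""
    samples = matrix.samples_where(**condition)
    sub = matrix.select_samples(samples)
    sub = filter_low_expression(sub, min_reads=min_reads)
    norm, factors = upper_quartile_normalize(sub)
    norm, polish = tmm_polish(norm)
    factors = factors * polish
    group_a = norm.samples_where(**{axis: groups[0], **condition})
    group_b = norm.samples_where(**{axis: groups[1], **condition})
    norm, offset = between_group_recenter(norm, group_a, group_b)
    out = {
        "label": label, "factors": factors, "matrix": norm,
        "composition_offset": offset,
    }
    for level in ("gene", "isoform"):
        results = test_two_group(
            norm, group_a, group_b, level=level, contrast=label, alpha=alpha
        )
        out[level] = results
        out[f"{level}_summary"] = summarize_contrast(results, alpha=alpha)
    return out


def splicing_for_contrast(models_by_gene, isoform_results) -> list:
    """Per-gene splicing calls from isoform-level DE results."""
    status_by_iso = {r.unit_id: r.status for r in isoform_results}
    calls = []
    for gene, models in sorted(models_by_gene.items()):
        present = [m for m in models if m.transcript_id in status_by_iso]
        if not present:
            continue
        statuses = [status_by_iso[m.transcript_id] for m in present]
        calls.append(call_gene_events(present, statuses))
    return calls


def de_gene_set(results: list[DEResult]) -> set[str]:
    return {r.gene_id for r in results if r.status in ("over", "under")}


def evaluate_de_recovery(
    gene_results: list[DEResult], truth: SimulationTruth
) -> dict:
    """Sensitivity and empirical FDR of gene-level DE calls against truth.

    Genes carrying a planted splicing event are excluded from the
    false-positive tally: their discordant isoform effects shift the
    gene-level sum, so they are not null genes.
    """
    called = de_gene_set(gene_results)
    tested = {r.gene_id for r in gene_results}
    true_de = set(truth.de_genes) & tested
    as_genes = set(truth.as_genes)
    tp = len(called & true_de)
    fp = len(called - true_de - as_genes)
    sens = tp / len(true_de) if true_de else float("nan")
    fdr = fp / max(len(called - as_genes), 1)
    return {"sensitivity": sens, "fdr": fdr, "n_called": len(called),
            "n_true": len(true_de)}


def evaluate_as_recovery(calls, truth: SimulationTruth) -> dict:
    """Fraction of planted splicing genes recovered (qualifying call) and,
    among recovered genes, the fraction whose planted mode was classified."""
    by_gene = {c.gene_id: c for c in calls}
    planted = set(truth.as_genes) & set(by_gene)
    recovered = [g for g in planted if by_gene[g].qualifies]
    mode_ok = [
        g for g in recovered if truth.as_genes[g].mode in by_gene[g].modes
    ]
    sens = len(recovered) / len(planted) if planted else float("nan")
    mode_frac = len(mode_ok) / len(recovered) if recovered else float("nan")
    return {"sensitivity": sens, "mode_accuracy": mode_frac,
            "n_planted": len(planted), "n_recovered": len(recovered)}


def summary_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": s.contrast, "level": s.level,
                "analyzed": s.n_analyzed, "de": s.n_de, "over": s.n_over,
                "under": s.n_under,
                "pct_over": "" if s.pct_over is None else s.pct_over,
            }
            for s in summaries
        ]
    )


def as_calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene_id, "n_over": c.n_over, "n_under": c.n_under,
                "n_non": c.n_non, "qualifies": c.qualifies,
                "direction": c.direction, "modes": ",".join(sorted(c.modes)),
            }
            for c in calls
        ]
    )


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict bundle with per-contrast DE results, summaries, splicing
    calls, enrichment and network products, and (for simulated runs) the
    planted truth with recovery metrics.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    truth = None
    models = None
    if config.simulation is not None:
        log.info("simulating transcriptome and counts")
        models, truth = generate_transcriptome(config.simulation)
        matrix, truth = simulate_counts(models, config.simulation, truth)
        io.write_gtf(models, outdir / "simulated.gtf")
        io.write_counts(
            matrix, outdir / "simulated_counts.tsv", outdir / "simulated_design.tsv"
        )
        io.write_truth_table(truth, outdir / "simulated_truth.tsv")
    else:
        gene_map = None
        if config.gtf:
            models = io.read_gtf(config.gtf)
            gene_map = {m.transcript_id: m.gene_id for m in models}
        matrix = io.read_counts(config.counts, config.design, gene_map=gene_map)

    genes = sorted(set(matrix.unit_to_gene))
    if config.gmt:
        gene_sets = io.read_gene_sets(config.gmt)
    elif truth is not None:
        gene_sets = simulate_gene_sets(genes, truth, seed=config.seed)
    else:
        gene_sets = None
    if config.edges:
        edge_list = io.read_edge_list(config.edges)
    elif truth is not None:
        edge_list = simulate_edge_list(genes, truth, seed=config.seed)
    else:
        edge_list = None

    models_by_gene: dict[str, list] = {}
    for m in models or []:
        models_by_gene.setdefault(m.gene_id, []).append(m)

    bundle: dict = {"contrasts": {}, "truth": truth}
    summaries = []
    for label, condition, axis, groups in STUDY_CONTRASTS:
        log.info("contrast: %s", label)
        res = run_contrast(
            matrix, label, condition, axis, groups,
            alpha=config.alpha, min_reads=config.min_reads,
        )
        slug = label.replace(":", "").replace(" ", "_")
        for level in ("gene", "isoform"):
            io.write_de_table(res[level], outdir / f"de_{slug}_{level}.tsv")
            summaries.append(res[f"{level}_summary"])

        if models_by_gene:
            calls = splicing_for_contrast(models_by_gene, res["isoform"])
            res["splicing"] = calls
            res["mode_frequencies"] = summarize_modes(calls)
            as_calls_frame(calls).to_csv(
                outdir / f"splicing_{slug}.tsv", sep="\t", index=False
            )

        if gene_sets is not None:
            de_genes = sorted(de_gene_set(res["gene"]))
            universe = sorted({r.gene_id for r in res["gene"]})
            if de_genes:
                records = enrich_list(de_genes, gene_sets, universe)
                clusters = cluster_annotations(records, gene_sets, universe)
                res["enrichment"] = records
                res["clusters"] = clusters
                enrichment_frame(records).to_csv(
                    outdir / f"enrichment_{slug}.tsv", sep="\t", index=False
                )
            ranked = sorted(
                ((r.gene_id, r.log2fc) for r in res["gene"]),
                key=lambda t: -t[1],
            )
            res["gsea"] = gsea_significance(
                ranked, gene_sets, n_perm=config.n_perm, seed=config.seed
            )

        if edge_list is not None:
            de_only = [
                r for r in res["gene"] if r.status in ("over", "under")
            ]
            analyzed = {r.gene_id for r in res["gene"]}
            net = build_network(de_only, edge_list, connector_exclude=analyzed)
            big = component_filter(net, min_size=config.min_component)
            res["network"] = net
            res["network_filtered"] = big
            io.write_graph(net, outdir / f"network_{slug}.sif", "SIF")
            io.write_graph(net, outdir / f"network_{slug}.graphml", "GraphML")
            degree_report(net).to_csv(
                outdir / f"degree_{slug}.tsv", sep="\t", index=False
            )
        bundle["contrasts"][label] = res

    summary_df = summary_frame(summaries)
    summary_df.to_csv(outdir / "contrast_summary.tsv", sep="\t", index=False)
    bundle["summary"] = summary_df

    # overlap / unique-detection bookkeeping over the challenge contrasts
    de_sets = {
        label: de_gene_set(bundle["contrasts"][label]["gene"])
        for label, *_ in STUDY_CONTRASTS
    }
    detected = {}
    for challenge in CHALLENGES:
        per_cell = {}
        for cell in CELLS:
            samples = matrix.samples_where(challenge=challenge, cell=cell)
            if not samples:
                continue
            sub = filter_low_expression(
                matrix.select_samples(samples), min_reads=config.min_reads
            )
            per_cell[cell] = set(sub.unit_to_gene)
        if per_cell:
            detected[challenge] = per_cell
    overlaps, _ = overlap_and_unique(de_sets)
    uniques = {
        ch: overlap_and_unique({}, per_cell)[1]
        for ch, per_cell in detected.items()
    }
    bundle["overlaps"] = overlaps
    bundle["unique_detection"] = uniques

    if truth is not None:
        rec = {}
        for label in ("microglia: BCG vs Control", "macrophage: BCG vs Control"):
            res = bundle["contrasts"][label]
            rec[label] = {
                "de": evaluate_de_recovery(res["gene"], truth),
                "as": evaluate_as_recovery(res.get("splicing", []), truth),
            }
        bundle["recovery"] = rec
        with open(outdir / "recovery.json", "w", encoding="utf-8") as fh:
            json.dump(rec, fh, indent=2)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "min_reads": config.min_reads,
        "config_hash": hashlib.sha256(
            repr(config).encode("utf-8")
        ).hexdigest()[:16],
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle


def enrichment_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category_id, "name": r.name, "k": r.k,
                "K": r.K, "n": r.n, "N": r.N, "p_hyper": r.p_hyper,
                "p_ease": r.p_ease, "q": r.q,
            }
            for r in records
        ]
    )



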