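"""Readers and writers for every external representation the pipeline touches.

GTF (1-based inclusive, exon features only), tab-delimited count matrices and
design tables, GMT gene sets, interaction edge lists, DE-result tables, and
SIF/GraphML graph exports. All text I/O is UTF-8 with '.' decimal points.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, IntegrityError, ParseError, UsageError
from .models import (
    DEResult,
    EdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    Network,
    TranscriptModel,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

DE_TABLE_COLUMNS = [
    "unit_id", "gene_id", "level", "contrast",
    "mean_A", "mean_B", "log2fc", "p", "q", "status",
]


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: PathLike) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into TranscriptModels.

    Exons are returned sorted ascending by start; records violating the
    exon-chain invariants are rejected with the offending line number.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates")
            attrs = dict(_ATTR_RE.findall(fields[8]))
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise ParseError(f"line {lineno}: missing attribute {key}")
            tid = attrs["transcript_id"]
            rec = per_tx.get(tid)
            if rec is None:
                per_tx[tid] = rec = {
                    "gene_id": attrs["gene_id"],
                    "strand": fields[6],
                    "chrom": fields[0],
                    "exons": [],
                    "line": lineno,
                }
                order.append(tid)
            else:
                if rec["strand"] != fields[6]:
                    raise IntegrityError(
                        f"line {lineno}: transcript {tid} mixes strands"
                    )
                if rec["gene_id"] != attrs["gene_id"]:
                    raise IntegrityError(
                        f"line {lineno}: transcript {tid} mixes gene_ids"
                    )
            rec["exons"].append((start, end))

    models = []
    for tid in order:
        rec = per_tx[tid]
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=rec["gene_id"],
                    strand=rec["strand"],
                    exons=tuple(sorted(rec["exons"])),
                    chrom=rec["chrom"],
                )
            )
        except IntegrityError as exc:
            raise IntegrityError(
                f"transcript {tid} (first seen line {rec['line']}): {exc}"
            ) from exc
    return models


def write_gtf(models: Iterable[TranscriptModel], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\tisopipe\texon\t{start}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# count matrix + design

def read_counts(
    matrix_path: PathLike,
    design_path: PathLike,
    gene_map: Optional[Mapping[str, str]] = None,
) -> ExpressionMatrix:
    """Read an isoform x sample count matrix and its sample design table.

    The matrix may carry a ``gene_id`` column (as written by
    :func:`write_counts`); otherwise ``gene_map`` must supply isoform->gene.
    """
    try:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: {exc}") from exc
    if "gene_id" in mat.columns:
        genes = mat["gene_id"].astype(str)
        mat = mat.drop(columns=["gene_id"])
    elif gene_map is not None:
        try:
            genes = pd.Series({u: gene_map[u] for u in mat.index})
        except KeyError as exc:
            raise ConfigurationError(f"isoform {exc} absent from gene map")
    else:
        raise ConfigurationError(
            "count matrix has no gene_id column and no gene map was given"
        )
    num = mat.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = num.isna().stack()
        unit, sample = bad[bad].index[0]
        raise ParseError(f"non-numeric count at ({unit}, {sample})")
    if (num.to_numpy() < 0).any():
        raise ParseError("negative count in matrix")

    design = pd.read_csv(design_path, sep="\t")
    required = {"sample", "challenge", "cell"}
    if not required <= set(design.columns):
        raise ParseError(
            f"design table must have columns {sorted(required)}"
        )
    num.index.name = None
    design = design.set_index("sample")
    missing = set(num.columns) - set(design.index)
    if missing:
        raise ConfigurationError(
            f"samples absent from design: {sorted(missing)}"
        )
    return ExpressionMatrix(num.astype(float), genes, design.loc[num.columns])


def write_counts(matrix: ExpressionMatrix, matrix_path: PathLike,
                 design_path: Optional[PathLike] = None) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_id", matrix.unit_to_gene)
    out.index.name = "unit_id"
    out.to_csv(matrix_path, sep="\t")
    if design_path is not None:
        d = matrix.design.copy()
        d.index.name = "sample"
        d.to_csv(design_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gene_sets(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: per line ``id <tab> description <tab> members...``.

    Duplicate members within a line are collapsed (first occurrence kept);
    sets left empty are dropped with a logged warning.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"line {lineno}: GMT line needs >= 3 tab-separated fields"
                )
            set_id, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                log.warning("GMT line %d: set %s is empty, dropped", lineno, set_id)
                continue
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, (name, members) in collection.sets.items():
            fh.write("\t".join([set_id, name, *members]) + "\n")


# ---------------------------------------------------------------------------
# edge lists

def read_edge_list(path: PathLike) -> EdgeList:
    """Read a 2-column TSV (or 3-column SIF ``a link b``) of gene pairs."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                pairs.append((fields[0], fields[1]))
            elif len(fields) == 3:  # SIF: source relation target
                pairs.append((fields[0], fields[2]))
            else:
                raise ParseError(f"line {lineno}: expected 2 or 3 fields")
    return EdgeList.from_pairs(pairs)


def write_edge_list(edges: EdgeList, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in edges.edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# graphs

def write_graph(network: Network, path: PathLike, dialect: str = "SIF") -> None:
    """Export a network as SIF (``geneA link geneB`` lines) or GraphML.

    GraphML nodes carry ``direction`` (over/under/connector), ``p_value``
    and ``degree`` attributes mirroring the visual encoding where node size
    tracks significance and color tracks expression direction.
    """
    if dialect == "SIF":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(network.graph.edges()):
                fh.write(f"{a} link {b}\n")
    elif dialect == "GraphML":
        g = nx.Graph()
        for node, data in network.graph.nodes(data=True):
            direction = (
                "connector" if data.get("role") == "connector"
                else data.get("status", "n/a")
            )
            attrs = {
                "direction": direction,
                "degree": int(network.graph.degree(node)),
            }
            if "p_value" in data:
                attrs["p_value"] = float(data["p_value"])
            g.add_node(node, **attrs)
        g.add_edges_from(network.graph.edges())
        nx.write_graphml(g, str(path))
    else:
        raise UsageError(f"unknown graph dialect {dialect!r}")


# ---------------------------------------------------------------------------
# simulation truth tables

def write_truth_table(truth, path: PathLike) -> None:
    """Planted-effect table: one row per DE gene or splicing-event gene."""
    rows = [
        {"gene": g, "kind": "de", "direction": d, "mode": "", "up": "",
         "down": ""}
        for g, d in sorted(truth.de_genes.items())
    ] + [
        {
            "gene": g, "kind": "as", "direction": "discordant",
            "mode": t.mode, "up": t.up_isoform, "down": t.down_isoform,
        }
        for g, t in sorted(truth.as_genes.items())
    ]
    pd.DataFrame(
        rows, columns=["gene", "kind", "direction", "mode", "up", "down"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: PathLike):
    from .simulate import ASTruth, SimulationTruth

    truth = SimulationTruth()
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for row in df.itertuples():
        if row.kind == "de":
            truth.de_genes[row.gene] = row.direction
        else:
            truth.as_genes[row.gene] = ASTruth(
                mode=row.mode, up_isoform=row.up, down_isoform=row.down
            )
    return truth


# ---------------------------------------------------------------------------
# DE tables

def write_de_table(results: Iterable[DEResult], path: PathLike) -> None:
    rows = [
        {
            "unit_id": r.unit_id, "gene_id": r.gene_id, "level": r.level,
            "contrast": r.contrast, "mean_A": r.mean_a, "mean_B": r.mean_b,
            "log2fc": r.log2fc, "p": r.p, "q": r.q, "status": r.status,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=DE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_de_table(path: PathLike) -> list[DEResult]:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: DE table missing columns {sorted(missing)}")
    return [
        DEResult(
            unit_id=str(row.unit_id), gene_id=str(row.gene_id),
            level=row.level, contrast=row.contrast,
            mean_a=float(row.mean_A), mean_b=float(row.mean_B),
            log2fc=float(row.log2fc), p=float(row.p), q=float(row.q),
            status=row.status,
        )
        for row in df.itertuples()
    ]
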