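"""Domain types shared by the pipeline stages.

Coordinates are genomic, 1-based and inclusive throughout; an exon
``(start, end)`` covers both endpoints. Counts live in a pandas DataFrame
(isoform rows x sample columns) wrapped together with the isoform->gene map
and the sample design table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IntegrityError, UsageError

Exon = tuple[int, int]

#: the six structural event modes recognised by the splicing classifier
EVENT_MODES = (
    "cassette",
    "tandem_cassette",
    "alt3",
    "alt5",
    "intron_retention",
    "mutually_exclusive",
)

CHALLENGES = ("Control", "BCG")
CELLS = ("microglia", "macrophage")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: an ordered exon chain on a strand."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[Exon, ...]
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise IntegrityError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise IntegrityError(f"{self.transcript_id}: empty exon chain")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        for start, end in self.exons:
            if start > end:
                raise IntegrityError(
                    f"{self.transcript_id}: exon ({start}, {end}) has start > end"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2 - 1:
                raise IntegrityError(
                    f"{self.transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) "
                    "overlap or abut; introns must have positive length"
                )

    @property
    def introns(self) -> tuple[Exon, ...]:
        """Boundary pairs (end of upstream exon, start of downstream exon)."""
        return tuple(
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> Exon:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class ExpressionMatrix:
    """Isoform x sample count table with design metadata.

    ``values`` rows are isoform ids, columns sample ids. ``unit_to_gene``
    maps every row to its gene. ``design`` is indexed by sample with columns
    ``challenge`` (BCG/Control) and ``cell`` (microglia/macrophage).
    """

    values: pd.DataFrame
    unit_to_gene: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.unit_to_gene.index)
        if missing:
            raise IntegrityError(
                f"units without gene assignment: {sorted(missing)[:5]}"
            )
        missing_s = set(self.values.columns) - set(self.design.index)
        if missing_s:
            raise IntegrityError(
                f"samples without design entry: {sorted(missing_s)[:5]}"
            )
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise IntegrityError("counts must be finite and >= 0")
        self.unit_to_gene = self.unit_to_gene.loc[self.values.index]

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)].copy(),
            self.unit_to_gene.copy(),
            self.design.loc[list(samples)].copy(),
        )

    def samples_where(self, **conditions: str) -> list[str]:
        """Samples whose design matches all given column=value conditions."""
        mask = pd.Series(True, index=self.design.index)
        for col, val in conditions.items():
            mask &= self.design[col] == val
        return list(self.design.index[mask])

    def gene_sums(self) -> pd.DataFrame:
        """Per-gene column sums over the gene's isoforms."""
        return self.values.groupby(self.unit_to_gene).sum()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with an optional background universe."""

    sets: dict[str, tuple[str, tuple[str, ...]]]  # id -> (name, members)
    universe: Optional[tuple[str, ...]] = None

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EdgeList:
    """Deduplicated unordered gene pairs, no self-loops."""

    edges: tuple[tuple[str, str], ...]

    @classmethod
    def from_pairs(cls, pairs) -> "EdgeList":
        seen = set()
        out = []
        for a, b in pairs:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
        return cls(tuple(out))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class DEResult:
    """Per-unit two-group contrast outcome."""

    unit_id: str
    gene_id: str
    level: str  # "gene" | "isoform"
    contrast: str
    mean_a: float
    mean_b: float
    log2fc: float
    p: float
    q: float
    status: str  # "over" | "under" | "non"


@dataclass
class ContrastSummary:
    contrast: str
    level: str
    n_analyzed: int
    n_de: int
    n_over: int
    n_under: int
    pct_over: Optional[int]  # rounded to nearest integer; None when n_de = 0


@dataclass
class ASCall:
    """Per-gene alternative-splicing verdict for one contrast."""

    gene_id: str
    n_over: int
    n_under: int
    n_non: int
    qualifies: bool
    direction: str  # over | under | either | none
    modes: frozenset[str] = frozenset()
    evidence: tuple[tuple[tuple[str, str], frozenset[str]], ...] = ()


@dataclass
class ModeFrequencies:
    n_genes: int
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class EnrichmentRecord:
    category_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_hyper: float
    p_ease: float
    q: float = float("nan")
    overlap_genes: tuple[str, ...] = ()


@dataclass
class AnnotationCluster:
    members: tuple[str, ...]
    es: float
    significant: bool


@dataclass
class GseaRecord:
    set_id: str
    es: float
    nes: float
    p: float
    q: float
    n_hits: int
    weight_exponent: float


@dataclass
class Network:
    """DE-gene association graph; connectors bridge observed genes."""

    graph: nx.Graph

    def validate(self) -> None:
        g = self.graph
        for node, data in g.nodes(data=True):
            role = data.get("role")
            if role == "connector":
                nbrs = list(g.neighbors(node))
                if len(nbrs) < 2:
                    raise IntegrityError(f"connector {node} has degree < 2")
                for nb in nbrs:
                    if g.nodes[nb].get("role") != "observed":
                        raise IntegrityError(
                            f"connector {node} adjacent to non-observed {nb}"
                        )
            elif role == "observed":
                if data.get("status") not in ("over", "under"):
                    raise IntegrityError(f"observed node {node} lacks status")
                if "p_value" not in data:
                    raise IntegrityError(f"observed node {node} lacks p-value")
            else:
                raise UsageError(f"node {node} has unknown role {role!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()
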