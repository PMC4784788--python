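"""Assembly of DE-gene association networks under the one-connector rule.

Edges between two differentially expressed genes are kept as-is; a gene
absent from the DE list enters only as a *connector* when it joins at least
two DE genes, mirroring the convention of admitting at most one non-measured
gene between observed genes. Observed nodes carry their expression
direction and p-value so exports can encode significance as node size and
direction as color.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import UsageError
from .models import DEResult, EdgeList, Network


def build_network(
    de_results: Sequence[DEResult],
    edges: EdgeList,
    connector_exclude: set[str] | None = None,
) -> Network:
    """Assemble the association network from DE genes and an edge list.

    ``de_results`` must contain only significant (over/under) gene-level
    results; one result per gene. Isolated DE genes are dropped.
    ``connector_exclude`` lists genes barred from serving as connectors
    (pass the analyzed universe for the strict policy where only truly
    non-measured genes may bridge).
    """
    de_info: dict[str, DEResult] = {}
    for r in de_results:
        if r.status not in ("over", "under"):
            raise UsageError(
                f"{r.unit_id}: build_network expects DE-only results"
            )
        de_info[r.gene_id] = r
    de_genes = set(de_info)
    barred = (set(connector_exclude) if connector_exclude else set()) - de_genes

    g = nx.Graph()
    neighbors_of_connector: dict[str, set[str]] = {}
    for a, b in edges.edges:
        a_de, b_de = a in de_genes, b in de_genes
        if a_de and b_de:
            g.add_edge(a, b)
        elif a_de != b_de:
            conn, obs = (b, a) if a_de else (a, b)
            if conn not in barred:
                neighbors_of_connector.setdefault(conn, set()).add(obs)

    for conn, obs_set in sorted(neighbors_of_connector.items()):
        if len(obs_set) >= 2:
            for obs in sorted(obs_set):
                g.add_edge(conn, obs)

    for node in g.nodes:
        if node in de_genes:
            r = de_info[node]
            g.nodes[node].update(
                role="observed", status=r.status, p_value=r.p, q_value=r.q
            )
        else:
            g.nodes[node].update(role="connector", status="n/a")
    net = Network(g)
    net.validate()
    return net


def degree_report(network: Network) -> pd.DataFrame:
    """Per-node degree table sorted by degree descending, gene ascending."""
    rows = [
        {
            "gene": node,
            "degree": int(network.graph.degree(node)),
            "role": data.get("role"),
            "status": data.get("status"),
        }
        for node, data in network.graph.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene", "degree", "role", "status"])
    return df.sort_values(
        ["degree", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def component_filter(network: Network, min_size: int = 6) -> Network:
    """Drop connected components with fewer than ``min_size`` nodes."""
    g = network.graph
    keep: set[str] = set()
    for comp in nx.connected_components(g):
        if len(comp) >= min_size:
            keep |= comp
    sub = Network(g.subgraph(keep).copy())
    sub.validate()
    return sub
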