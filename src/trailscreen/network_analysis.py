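"""Interaction-network analysis of called hit genes.

Maps hit genes onto a user-supplied undirected interaction edge list (SIF or
two-column TSV), extracts the largest connected component of the induced
subgraph and reports hub nodes by degree (default: seven or more distinct
neighbours), optionally annotated with cross-assay corroboration status.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_edge_list",
    "write_sif",
    "hit_subgraph",
    "largest_component",
    "hub_nodes",
]

logger = logging.getLogger(__name__)

DEFAULT_HUB_DEGREE = 7


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected simple graph from SIF or two-column TSV.

    SIF lines are ``source<tab>relation<tab>target[<tab>target2 ...]`` (a
    relation column whose value is preserved as an edge attribute); plain
    two-column files are ``source<tab>target``.  Whitespace-separated files
    are accepted.  Duplicate edges (either orientation) collapse to one;
    self-loops are dropped with a logged count.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                pairs = [(parts[0], parts[1], None)]
            elif len(parts) >= 3:
                src, rel = parts[0], parts[1]
                pairs = [(src, tgt, rel) for tgt in parts[2:]]
            else:
                raise ValueError(f"{path}:{lineno}: malformed edge line: {line!r}")
            for u, v, rel in pairs:
                if u == v:
                    n_self += 1
                    continue
                if rel is None:
                    g.add_edge(u, v)
                else:
                    g.add_edge(u, v, relation=rel)
    if n_self:
        logger.info("dropped %d self-loop(s) while reading %s", n_self, path)
    return g


def write_sif(graph: nx.Graph, path: str | Path, default_relation: str = "pp") -> None:
    """Write a graph as SIF with a deterministic (sorted) edge order."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in graph.edges()):
            rel = graph.edges[u, v].get("relation", default_relation)
            fh.write(f"{u}\t{rel}\t{v}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\n")


def hit_subgraph(graph: nx.Graph, hit_genes) -> tuple[nx.Graph, list[str]]:
    """Induced subgraph on hit genes plus the list of hits absent from the graph."""
    hits = set(map(str, hit_genes))
    mapped = hits & set(graph.nodes)
    unmapped = sorted(hits - mapped)
    return nx.Graph(graph.subgraph(mapped)), unmapped


def largest_component(graph: nx.Graph) -> set[str]:
    """Node set of the maximum-cardinality connected component.

    Ties between equal-sized components are broken deterministically in
    favour of the component containing the lexicographically smallest node.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("largest_component of an empty graph is undefined")
    comps = [set(c) for c in nx.connected_components(graph)]
    return min(comps, key=lambda c: (-len(c), min(map(str, c))))


def hub_nodes(
    graph: nx.Graph,
    min_degree: int = DEFAULT_HUB_DEGREE,
    corroboration: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-node report with degree, component membership and hub status.

    Degree counts distinct neighbours within ``graph`` (typically the
    hit-induced subgraph).  ``corroboration`` may supply per-gene columns
    (indexed or keyed by ``gene_id``) merged into the report.  Returns all
    nodes sorted by descending degree then gene_id; hubs are the rows with
    ``is_hub``.
    """
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["gene_id", "degree", "in_largest_component", "is_hub"]
        )
    lcc = largest_component(graph)
    rows = [
        {
            "gene_id": str(node),
            "degree": int(deg),
            "in_largest_component": node in lcc,
            "is_hub": deg >= min_degree,
        }
        for node, deg in graph.degree()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["degree", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if corroboration is not None and len(corroboration):
        cor = corroboration.reset_index() if corroboration.index.name == "gene_id" else corroboration
        out = out.merge(cor, on="gene_id", how="left")
    return out
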