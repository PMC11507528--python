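"""Protein-protein interaction network parsing, filtering, and distances.

Edges arrive in the STRING file dialect: whitespace- or tab-separated
columns ``protein1 protein2 combined_score`` with integer scores on the
0-999 scale (700 = the conventional "high confidence" 0.7).  Protein IDs
are mapped to gene symbols through an alias table, duplicate undirected
pairs are collapsed keeping the maximum score, and the network is filtered
to edges at or above the confidence threshold.  Distances are unweighted
hop counts; the distance of a gene to a signature set is the minimum over
single-source BFS distances, computed with a multi-source BFS.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "read_string_edges",
    "filter_by_score",
    "multi_source_distance",
    "direct_neighbors",
]

logger = logging.getLogger(__name__)


@dataclass
class InteractionNetwork:
    """Undirected simple graph over gene symbols with combined scores."""

    graph: nx.Graph
    min_score: int = 700
    n_input_edges: int = 0

    @property
    def retained_fraction(self) -> float:
        """Fraction of input edges surviving the confidence filter."""
        if self.n_input_edges == 0:
            return float("nan")
        return self.graph.number_of_edges() / self.n_input_edges

    def stats(self) -> dict:
        return {
            "nodes": self.graph.number_of_nodes(),
            "edges_retained": self.graph.number_of_edges(),
            "edges_input": self.n_input_edges,
            "retained_pct": round(100.0 * self.retained_fraction, 2),
            "min_score": self.min_score,
        }


def read_string_edges(path, aliases_path=None) -> pd.DataFrame:
    """Parse a STRING-dialect edge file into a symbol-keyed edge table.

    ``aliases_path`` maps protein IDs to gene symbols (two columns,
    ``protein_id`` then ``gene_symbol``; header optional).  Rows with an
    endpoint missing from the alias table are dropped and counted.  When no
    alias table is given, identifiers are taken as symbols directly.
    Duplicate undirected pairs (including reversed order) collapse to one
    edge keeping the maximum combined score; self-loops are dropped.
    """
    edges = pd.read_csv(path, sep=r"\s+")
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(edges.columns):
        # header-less file: assume the canonical column order
        edges = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["protein1", "protein2", "combined_score"],
        )
    if edges["combined_score"].dtype.kind not in "iu":
        raise ValueError("combined_score must be integer (STRING 0-999 scale)")
    if aliases_path is not None:
        alias = pd.read_csv(aliases_path, sep=r"\s+")
        if not {"protein_id", "gene_symbol"} <= set(alias.columns):
            alias = pd.read_csv(
                aliases_path, sep=r"\s+", header=None,
                names=["protein_id", "gene_symbol"],
            )
        mapping = dict(zip(alias["protein_id"], alias["gene_symbol"]))
        a = edges["protein1"].map(mapping)
        b = edges["protein2"].map(mapping)
        mappable = a.notna() & b.notna()
        n_dropped = int((~mappable).sum())
        if n_dropped:
            logger.info("dropped %d edge(s) with unmappable endpoints", n_dropped)
        edges = pd.DataFrame(
            {
                "gene1": a[mappable].astype(str).str.upper(),
                "gene2": b[mappable].astype(str).str.upper(),
                "combined_score": edges.loc[mappable, "combined_score"],
            }
        )
    else:
        edges = pd.DataFrame(
            {
                "gene1": edges["protein1"].astype(str).str.upper(),
                "gene2": edges["protein2"].astype(str).str.upper(),
                "combined_score": edges["combined_score"],
            }
        )
    edges = edges[edges["gene1"] != edges["gene2"]]
    # canonical undirected key, keep max score across duplicates
    key = edges[["gene1", "gene2"]].apply(lambda r: tuple(sorted(r)), axis=1)
    edges = edges.assign(_key=key)
    edges = (
        edges.groupby("_key", as_index=False)
        .agg(combined_score=("combined_score", "max"))
        .assign(
            gene1=lambda d: d["_key"].str[0],
            gene2=lambda d: d["_key"].str[1],
        )[["gene1", "gene2", "combined_score"]]
        .sort_values(["gene1", "gene2"], ignore_index=True)
    )
    return edges


def filter_by_score(edges: pd.DataFrame, min_score: int = 700) -> InteractionNetwork:
    """Build the high-confidence interaction network.

    Retains edges with ``combined_score >= min_score`` and reports the
    retained count and percentage of the input through
    :meth:`InteractionNetwork.stats`.
    """
    scores = edges["combined_score"]
    if (scores < 0).any() or (scores > 999).any():
        raise ValueError("combined scores must lie in [0, 999]")
    kept = edges[scores >= min_score]
    g = nx.Graph()
    g.add_weighted_edges_from(
        kept[["gene1", "gene2", "combined_score"]].itertuples(index=False),
        weight="combined_score",
    )
    net = InteractionNetwork(graph=g, min_score=min_score,
                             n_input_edges=len(edges))
    logger.info(
        "score filter >= %d: retained %d of %d edges (%.2f%%)",
        min_score, g.number_of_edges(), len(edges),
        100.0 * net.retained_fraction if len(edges) else float("nan"),
    )
    return net


def multi_source_distance(net: InteractionNetwork, sources) -> dict[str, int]:
    """Hop distance from every graph gene to the nearest source gene.

    Source genes map to 0 whether or not they appear in the graph
    (set membership is definitional); genes unreachable from every source
    are absent from the returned dict.
    """
    sources = {s.upper() for s in sources}
    if not sources:
        raise ValueError("source set must be non-empty")
    g = net.graph
    dist: dict[str, int] = {s: 0 for s in sources}
    queue = deque(sources & set(g.nodes))
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def direct_neighbors(net: InteractionNetwork, sets) -> set[str]:
    """Candidate pool: all signature genes plus their 1-hop neighbors."""
    sig = set()
    for s in sets:
        sig |= {g.upper() for g in (s.genes if hasattr(s, "genes") else s)}
    pool = set(sig)
    for g in sig & set(net.graph.nodes):
        pool |= set(net.graph.neighbors(g))
    return pool
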