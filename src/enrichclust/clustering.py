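"""Gene-overlap term graph construction and Walktrap community detection.

Retained terms become nodes of a weighted undirected graph; edge weights are
Jaccard similarities between the terms' gene sets (the genes each term
matched in the input lists, unioned across conditions and regulations).
Edges below a user threshold ``ts`` are pruned, communities are found with
the Walktrap random-walk agglomeration, and the merge level with maximal
weighted Newman modularity is reported. A threshold sweep supports choosing
``ts`` from cluster count, component count and modularity profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import igraph as ig
import networkx as nx
import pandas as pd

from .exceptions import ConfigurationError, ConsistencyError, DomainError
from .enrich import EnrichmentHit

TermGeneMap = dict[str, frozenset[str]]


@dataclass(frozen=True)
class ClusterAssignment:
    """Term -> cluster-id labels plus the partition's modularity.

    Cluster ids are contiguous positive integers, numbered by decreasing
    cluster size with ties broken by the lexicographically smallest member
    term, so identical inputs always yield identical labels.
    """

    labels: Mapping[str, int]
    modularity_value: float

    def clusters(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for term, cid in self.labels.items():
            out.setdefault(cid, set()).add(term)
        return {cid: frozenset(terms) for cid, terms in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def build_term_gene_map(hits: Sequence[EnrichmentHit]) -> TermGeneMap:
    """Union each term's overlap genes over all rows mentioning it."""
    acc: dict[str, set[str]] = {}
    for h in hits:
        acc.setdefault(h.term, set()).update(h.overlap_genes)
    return {term: frozenset(genes) for term, genes in acc.items()}


def build_term_gene_map_full(
    hits: Sequence[EnrichmentHit], library_sets: Mapping[str, frozenset[str]]
) -> TermGeneMap:
    """Alternative map using the terms' full library gene sets."""
    return {h.term: frozenset(library_sets[h.term]) for h in hits}


def jaccard_similarity(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|a ∩ b| / |a ∪ b| for two non-empty gene sets."""
    if not a or not b:
        raise DomainError("Jaccard similarity is undefined for empty sets")
    inter = len(set(a) & set(b))
    if inter == 0:
        return 0.0
    return inter / len(set(a) | set(b))


def build_term_graph(term_gene_map: TermGeneMap, ts: float) -> nx.Graph:
    """Weighted term-similarity graph with edges of Jaccard >= ts.

    Terms with no retained edge stay as isolated nodes. The threshold is
    recorded as graph attribute ``ts``. Only pairs sharing at least one gene
    can be connected (Jaccard > 0), so ts = 0 yields the full overlap graph.
    """
    if not 0 <= ts <= 1:
        raise ConfigurationError(f"ts must lie in [0, 1], got {ts}")
    g = nx.Graph(ts=ts)
    for term in sorted(term_gene_map):
        g.add_node(term, n_genes=len(term_gene_map[term]))
    for u, v in combinations(sorted(term_gene_map), 2):
        w = jaccard_similarity(term_gene_map[u], term_gene_map[v])
        if w > 0 and w >= ts:
            g.add_edge(u, v, weight=w)
    return g


def modularity(graph: nx.Graph, assignment: ClusterAssignment | Mapping[str, int]) -> float:
    """Weighted Newman modularity Q = sum_c (e_cc - a_c^2).

    e_cc is the fraction of total edge weight falling inside cluster c and
    a_c the fraction of total weighted degree attached to c. Undefined (and
    an error) for an edgeless graph.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    total_w = graph.size(weight="weight")
    if total_w == 0:
        raise DomainError("modularity is undefined for an edgeless graph")
    within: dict[int, float] = {}
    degree: dict[int, float] = {}
    for u, v, w in graph.edges(data="weight", default=1.0):
        cu, cv = labels[u], labels[v]
        if cu == cv:
            within[cu] = within.get(cu, 0.0) + w
        degree[cu] = degree.get(cu, 0.0) + w
        degree[cv] = degree.get(cv, 0.0) + w
    q = 0.0
    clusters = set(labels[n] for n in graph.nodes)
    for c in clusters:
        e_cc = within.get(c, 0.0) / total_w
        a_c = degree.get(c, 0.0) / (2.0 * total_w)
        q += e_cc - a_c * a_c
    return q


def _relabel(groups: Sequence[set[str]]) -> dict[str, int]:
    """Deterministic 1..C labels: decreasing size, then smallest member."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    labels: dict[str, int] = {}
    for cid, group in enumerate(ordered, start=1):
        for term in group:
            labels[term] = cid
    return labels


def walktrap_cluster(graph: nx.Graph, walk_length: int = 4) -> ClusterAssignment:
    """Walktrap (Pons–Latapy) communities at the maximum-modularity level.

    The random-walk agglomeration is run over the whole graph (isolated
    nodes become singleton clusters). Every merge level of the dendrogram is
    scored with weighted modularity and the best level is returned; ties go
    to the coarser partition (fewer clusters). For an edgeless graph every
    node is its own cluster and the modularity value is reported as 0.
    """
    if walk_length < 1:
        raise ConfigurationError(f"walk_length must be >= 1, got {walk_length}")
    if graph.number_of_nodes() == 0:
        raise DomainError("graph has no nodes")
    nodes = sorted(graph.nodes)
    if graph.number_of_edges() == 0:
        return ClusterAssignment(
            labels=_relabel([{n} for n in nodes]), modularity_value=0.0
        )
    index = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(n=len(nodes))
    edges, weights = [], []
    for u, v, w in graph.edges(data="weight", default=1.0):
        edges.append((index[u], index[v]))
        weights.append(float(w))
    g.add_edges(edges)
    dendrogram = g.community_walktrap(weights=weights, steps=walk_length)
    n_components = len(g.connected_components())
    best_labels, best_q, best_k = None, -float("inf"), None
    # cut the dendrogram at every achievable cluster count, coarsest first
    for k in range(n_components, len(nodes) + 1):
        try:
            membership = dendrogram.as_clustering(n=k).membership
        except (ig.InternalError, ValueError):
            continue
        labels = {n: membership[index[n]] for n in nodes}
        q = modularity(graph, labels)
        if q > best_q + 1e-12:  # strict improvement: ties keep coarser cut
            best_q, best_labels, best_k = q, labels, k
    assert best_labels is not None
    groups: dict[int, set[str]] = {}
    for n, c in best_labels.items():
        groups.setdefault(c, set()).add(n)
    return ClusterAssignment(
        labels=_relabel(list(groups.values())), modularity_value=best_q
    )


@dataclass(frozen=True)
class ThresholdProfile:
    """Sweep of graph/cluster statistics over pruning thresholds."""

    table: pd.DataFrame  # columns: ts, n_edges, n_clusters, n_components, modularity

    def __post_init__(self):
        ts = self.table["ts"].to_numpy()
        if len(ts) and not (ts[1:] > ts[:-1]).all():
            raise ConfigurationError("ts values must be strictly increasing")


def evaluate_thresholds(
    term_gene_map: TermGeneMap,
    ts_grid: Sequence[float],
    walk_length: int = 4,
) -> ThresholdProfile:
    """Cluster count, component count and modularity for each threshold.

    Modularity is reported as 0 for thresholds that prune every edge.
    """
    if len(ts_grid) == 0:
        raise ConfigurationError("ts_grid must be non-empty")
    if any(not 0 <= t <= 1 for t in ts_grid):
        raise ConfigurationError("ts_grid values must lie in [0, 1]")
    rows = []
    for ts in sorted(set(float(t) for t in ts_grid)):
        g = build_term_graph(term_gene_map, ts)
        assignment = walktrap_cluster(g, walk_length=walk_length)
        rows.append(
            {
                "ts": ts,
                "n_edges": g.number_of_edges(),
                "n_clusters": assignment.n_clusters,
                "n_components": nx.number_connected_components(g),
                "modularity": assignment.modularity_value,
            }
        )
    return ThresholdProfile(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def graph_to_node_link(
    graph: nx.Graph, assignment: ClusterAssignment | None = None
) -> dict:
    """JSON-serialisable node-link dialect for interactive viewers."""
    nodes = []
    for term in sorted(graph.nodes):
        node = {"term": term, "n_genes": int(graph.nodes[term].get("n_genes", 0))}
        if assignment is not None:
            if term not in assignment.labels:
                raise ConsistencyError(f"term {term!r} missing from assignment")
            node["cluster_id"] = int(assignment.labels[term])
        nodes.append(node)
    links = [
        {"source": u, "target": v, "weight": float(w)}
        for u, v, w in sorted(graph.edges(data="weight", default=1.0))
    ]
    return {"ts": graph.graph.get("ts"), "nodes": nodes, "links": links}


def write_node_link_json(
    graph: nx.Graph, path: str | Path, assignment: ClusterAssignment | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph_to_node_link(graph, assignment), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_node_link_json(path: str | Path) -> tuple[nx.Graph, dict[str, int] | None]:
    """Re-read a node-link export; returns the graph and cluster labels."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    g = nx.Graph(ts=payload.get("ts"))
    labels: dict[str, int] = {}
    for node in payload["nodes"]:
        g.add_node(node["term"], n_genes=node["n_genes"])
        if "cluster_id" in node:
            labels[node["term"]] = node["cluster_id"]
    for link in payload["links"]:
        g.add_edge(link["source"], link["target"], weight=link["weight"])
    return g, (labels or None)


def write_graphml(
    graph: nx.Graph, path: str | Path, assignment: ClusterAssignment | None = None
) -> None:
    """GraphML export with cluster_id / n_genes node attributes."""
    g = graph.copy()
    if assignment is not None:
        for term in g.nodes:
            if term not in assignment.labels:
                raise ConsistencyError(f"term {term!r} missing from assignment")
            g.nodes[term]["cluster_id"] = int(assignment.labels[term])
    nx.write_graphml(g, path)
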