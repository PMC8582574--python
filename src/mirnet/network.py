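"""Bipartite miRNA-mRNA networks, unipartite projection, centralities, hubs.

The bipartite graph has miRNA and mRNA node classes and one edge per
surviving inverse-correlation pair. "Core" miRNAs are those regulating more
than ``min_degree`` mRNAs (default 20 for tumor data, 100 for cell lines).
The unipartite projection connects two miRNAs when they share at least one
mRNA partner, weighted by the shared-partner count; hubs are the connected
components of the core bipartite graph — the parameter-free formalization of
"no shared mRNA associations with other miRNAs".

Centrality conventions
----------------------
degree
    Bipartite miRNA degree (number of inversely correlated mRNAs).
betweenness
    Unnormalized shortest-path betweenness on the *unweighted* projection
    skeleton, with credit split equally among equally short paths — this is
    the convention that yields half-integer scores. Projection weights count
    shared partners, so treating them as distances would rank strongly
    coupled miRNAs as far apart, which is semantically backwards.
closeness
    Harmonic closeness (sum of inverse distances; disconnected pairs
    contribute zero). The projection is typically disconnected — isolated
    hubs are the object of interest — so the classic closeness, undefined
    across components, is not usable.
eigenvector
    Principal eigenvector of the *weighted* adjacency, scaled so the
    maximum entry is exactly 1. On a disconnected graph the principal
    eigenvector concentrates on the component with the largest spectral
    radius; other components score 0. Spectral-radius ties are broken
    deterministically (larger component, then smallest node label).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import bipartite as nx_bipartite

from .correlation import CorrelationEdgeSet
from .io import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "UnipartiteProjection",
    "Hub",
    "build_bipartite",
    "mirna_degree",
    "filter_core",
    "project_unipartite",
    "centralities",
    "find_hubs",
    "summarize_network",
    "export_bipartite_graphml",
    "export_projection_graphml",
]


@dataclass
class BipartiteNetwork:
    """Wrapper around an undirected graph with 'mirna' / 'mrna' partitions."""

    graph: nx.Graph

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("part") == "mirna"}

    @property
    def mrna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("part") == "mrna"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class UnipartiteProjection:
    """miRNA-only graph; edge weight = number of shared mRNA partners."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def weight(self, a: str, b: str) -> int:
        if self.graph.has_edge(a, b):
            return int(self.graph.edges[a, b]["weight"])
        return 0


@dataclass(frozen=True)
class Hub:
    """A connected component of the core bipartite network."""

    member_mirnas: frozenset[str]
    edge_count: int
    edge_fraction: float
    label: str | None = None


def build_bipartite(edge_set: CorrelationEdgeSet) -> BipartiteNetwork:
    """Build the bipartite graph from a filtered edge set.

    Node sets are exactly the edge endpoints; edge count is preserved.
    An identifier appearing on both the miRNA and mRNA side would collapse
    the partitions and is rejected.
    """
    g = nx.Graph()
    seen: set[tuple[str, str]] = set()
    for e in edge_set.edges:
        key = (e.mirna_id, e.mrna_id)
        if key in seen:
            raise ValidationError(f"duplicate edge {key}")
        seen.add(key)
        g.add_node(e.mirna_id, part="mirna")
        g.add_node(e.mrna_id, part="mrna")
        g.add_edge(e.mirna_id, e.mrna_id, rho=e.rho)
    mirnas = {e.mirna_id for e in edge_set.edges}
    mrnas = {e.mrna_id for e in edge_set.edges}
    overlap = mirnas & mrnas
    if overlap:
        raise ValidationError(f"identifiers on both sides of the bipartition: {sorted(overlap)}")
    return BipartiteNetwork(graph=g)


def mirna_degree(network: BipartiteNetwork) -> dict[str, int]:
    """Number of inversely correlated mRNAs per miRNA."""
    return {m: int(network.graph.degree[m]) for m in network.mirna_nodes}


def filter_core(
    network: BipartiteNetwork, min_degree: int, keep_equal: bool = False
) -> BipartiteNetwork:
    """Restrict to core miRNAs (degree > ``min_degree``) and their edges.

    The default is the strict inequality (a core miRNA regulates *more than*
    ``min_degree`` mRNAs); ``keep_equal=True`` switches to >=, the other
    reading of "remove miRNAs with fewer than N associations". mRNAs left
    without edges are dropped.
    """
    if min_degree < 0:
        raise ValidationError("min_degree must be >= 0")
    degrees = mirna_degree(network)
    if keep_equal:
        keep = {m for m, d in degrees.items() if d >= min_degree}
    else:
        keep = {m for m, d in degrees.items() if d > min_degree}
    g = nx.Graph()
    for m, gene, data in network.graph.edges(data=True):
        # edge tuples may come in either orientation
        mirna, mrna = (m, gene) if network.graph.nodes[m]["part"] == "mirna" else (gene, m)
        if mirna in keep:
            g.add_node(mirna, part="mirna")
            g.add_node(mrna, part="mrna")
            g.add_edge(mirna, mrna, **data)
    log.info(
        "filter_core: kept %d/%d miRNAs (degree %s %d), %d/%d edges",
        len(keep),
        len(degrees),
        ">=" if keep_equal else ">",
        min_degree,
        g.number_of_edges(),
        network.n_edges,
    )
    return BipartiteNetwork(graph=g)


def project_unipartite(network: BipartiteNetwork) -> UnipartiteProjection:
    """Project onto miRNAs: edge (a, b) iff a and b share >= 1 mRNA partner.

    Edge weight is the shared-partner count. miRNAs sharing no partner with
    anyone remain as isolated nodes.
    """
    mirnas = sorted(network.mirna_nodes)
    if not mirnas:
        return UnipartiteProjection(graph=nx.Graph())
    proj = nx_bipartite.weighted_projected_graph(network.graph, mirnas, ratio=False)
    return UnipartiteProjection(graph=proj)


def _principal_component_eigen(
    adjacency: np.ndarray, nodes: list[str], components: list[list[str]]
) -> dict[str, float]:
    """Eigenvector centrality: Perron vector of the winning component.

    Per component, the Perron vector is found by shifted power iteration
    (the shift removes the +/- lambda oscillation of bipartite-like
    components). The winner has the largest spectral radius, ties broken by
    component size then smallest node label; losing components score 0.
    """
    index = {n: i for i, n in enumerate(nodes)}
    results = []
    for comp in components:
        idx = np.array([index[n] for n in comp])
        sub = adjacency[np.ix_(idx, idx)]
        if len(comp) == 1 or sub.max() == 0.0:
            lam, vec = 0.0, np.ones(len(comp))
        else:
            shift = float(sub.sum(axis=1).max()) + 1.0
            v = np.ones(len(comp)) / np.sqrt(len(comp))
            for _ in range(10000):
                w = sub @ v + shift * v
                w /= np.linalg.norm(w)
                if np.linalg.norm(w - v) < 1e-14:
                    v = w
                    break
                v = w
            vec = np.abs(v)
            lam = float(vec @ (sub @ vec))
        results.append((lam, len(comp), min(comp), comp, vec))
    lam_max = max(r[0] for r in results)
    if lam_max <= 0.0:
        # edgeless graph: the adjacency is the zero matrix and every vector
        # is an eigenvector; score every node 1 (fully degenerate tie)
        return {n: 1.0 for n in nodes}
    tol = 1e-9 * max(lam_max, 1.0)
    tied = [r for r in results if r[0] >= lam_max - tol]
    tied.sort(key=lambda r: (-r[1], r[2]))
    winner = tied[0]
    scores = {n: 0.0 for n in nodes}
    _, _, _, comp, vec = winner
    peak = vec.max()
    if peak > 0:
        for n, v in zip(comp, vec / peak):
            scores[n] = float(v)
    else:  # no-edge graph: degenerate, every node is an eigenvector of 0
        scores = {n: 1.0 for n in nodes}
    return scores


def centralities(
    projection: UnipartiteProjection,
    bipartite_degrees: Mapping[str, int],
) -> pd.DataFrame:
    """Centrality table for every miRNA in the projection.

    Columns: ``degree`` (bipartite miRNA degree), ``betweenness``,
    ``closeness`` (harmonic), ``eigenvector``. Empty projection gives an
    empty table.
    """
    g = projection.graph
    nodes = sorted(g.nodes)
    if not nodes:
        return pd.DataFrame(columns=["degree", "betweenness", "closeness", "eigenvector"])
    missing = [n for n in nodes if n not in bipartite_degrees]
    if missing:
        raise ValidationError(f"no bipartite degree for projected miRNAs: {missing}")
    betweenness = nx.betweenness_centrality(g, normalized=False, weight=None)
    closeness = nx.harmonic_centrality(g)
    adjacency = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    components = [sorted(c) for c in nx.connected_components(g)]
    eigen = _principal_component_eigen(adjacency, nodes, components)
    return pd.DataFrame(
        {
            "degree": [int(bipartite_degrees[n]) for n in nodes],
            "betweenness": [float(betweenness[n]) for n in nodes],
            "closeness": [float(closeness[n]) for n in nodes],
            "eigenvector": [eigen[n] for n in nodes],
        },
        index=pd.Index(nodes, name="mirna_id"),
    )


def find_hubs(core: BipartiteNetwork) -> list[Hub]:
    """Hubs = connected components of the core bipartite graph.

    Each hub carries its miRNA members, its edge count and its fraction of
    all core edges; hubs are ordered by descending edge count, then by
    member names for determinism.
    """
    total_edges = core.n_edges
    hubs = []
    for comp in nx.connected_components(core.graph):
        sub = core.graph.subgraph(comp)
        members = frozenset(
            n for n in comp if core.graph.nodes[n].get("part") == "mirna"
        )
        if not members:
            continue
        edge_count = sub.number_of_edges()
        hubs.append(
            Hub(
                member_mirnas=members,
                edge_count=edge_count,
                edge_fraction=edge_count / total_edges if total_edges else 0.0,
            )
        )
    hubs.sort(key=lambda h: (-h.edge_count, tuple(sorted(h.member_mirnas))))
    return hubs


def summarize_network(
    network: BipartiteNetwork,
    core: BipartiteNetwork,
    hubs: Iterable[Hub],
    centrality_table: pd.DataFrame,
    top_k: int = 5,
) -> dict:
    """Aggregate counts, core share and top-k centrality listings.

    The core edge share is reported as an integer percent of all edges, the
    convention used when describing how much of the association landscape
    the core miRNAs account for.
    """
    hubs = list(hubs)
    total_edges = network.n_edges
    core_edges = core.n_edges
    top: dict[str, list] = {}
    for col in ("degree", "betweenness", "closeness", "eigenvector"):
        if len(centrality_table):
            ranked = centrality_table[col].sort_values(ascending=False, kind="mergesort")
            top[col] = [[str(i), float(v)] for i, v in ranked.head(top_k).items()]
        else:
            top[col] = []
    return {
        "total_edges": total_edges,
        "total_mirnas": len(network.mirna_nodes),
        "total_mrnas": len(network.mrna_nodes),
        "core_mirna_count": len(core.mirna_nodes),
        "core_edge_count": core_edges,
        "core_edge_share_pct": int(round(100.0 * core_edges / total_edges)) if total_edges else 0,
        "hubs": [
            {
                "members": sorted(h.member_mirnas),
                "edge_count": h.edge_count,
                "edge_fraction": h.edge_fraction,
                "label": h.label,
            }
            for h in hubs
        ],
        "top_centralities": top,
    }


def export_bipartite_graphml(
    network: BipartiteNetwork, path: str | Path, plot_min_degree: int = 15
) -> None:
    """Write the bipartite graph as GraphML for external visualization.

    Only miRNAs with more than ``plot_min_degree`` mRNA associations (and
    their edges) are exported — a display threshold, independent of the
    analytic core filter.
    """
    display = filter_core(network, plot_min_degree)
    nx.write_graphml(display.graph, str(path))


def export_projection_graphml(
    projection: UnipartiteProjection,
    path: str | Path,
    centrality_table: pd.DataFrame | None = None,
) -> None:
    """Write the weighted projection as GraphML, with optional centralities."""
    g = projection.graph.copy()
    if centrality_table is not None:
        for col in centrality_table.columns:
            for node, value in centrality_table[col].items():
                if node in g:
                    g.nodes[node][col] = float(value)
    nx.write_graphml(g, str(path))
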