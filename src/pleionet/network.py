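"""Interactome construction and per-node centrality measures.

The interactome is an undirected simple graph: self-interactions are removed
and duplicate pairs collapsed. Four centrality measures are computed on
unweighted hop distances:

- degree: number of interaction partners;
- closeness: reciprocal mean shortest-path distance to the other nodes of
  the node's connected component (0 for isolated nodes);
- betweenness: fraction of shortest paths between other node pairs passing
  through the node (endpoints excluded), normalized per component by
  (n-1)(n-2)/2 so values lie in [0, 1];
- eccentricity: hop distance to the farthest node of the component.

The clustering coefficient — the fraction of realized edges among a node's
neighbors — is undefined for degree < 2 and reported as NaN there, so class
means are not deflated by leaves and isolates.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSet, InteractionEdgeList

log = logging.getLogger("pleionet")

#: Above this node count, betweenness switches to k-pivot sampling unless
#: exact computation is forced. Exact is the default for this package's
#: problem sizes; the flag exists for very large graphs.
BETWEENNESS_SAMPLING_THRESHOLD = 50_000


def build_graph(edges: InteractionEdgeList) -> nx.Graph:
    """Build the simple undirected interactome and label components.

    Removed self-loops and collapsed duplicate edges are counted in
    ``G.graph``; each node gets a ``component`` attribute (components are
    numbered by decreasing size, ties broken by smallest member).
    """
    if not edges.edges:
        raise ValueError("empty edge list")
    G = nx.Graph()
    n_self = 0
    n_dup = 0
    for a, b in edges.edges:
        if a == b:
            n_self += 1
            G.add_node(a)
            continue
        if G.has_edge(a, b):
            n_dup += 1
            continue
        G.add_edge(a, b)
    comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    for cid, comp in enumerate(comps):
        for node in comp:
            G.nodes[node]["component"] = cid
    G.graph["n_self_loops_removed"] = n_self
    G.graph["n_duplicate_edges_removed"] = n_dup
    G.graph["n_components"] = len(comps)
    log.info("build_graph: %d nodes, %d edges, %d components "
             "(%d self-loops, %d duplicates removed)",
             G.number_of_nodes(), G.number_of_edges(), len(comps), n_self, n_dup)
    return G


def clustering_coefficient(G: nx.Graph, undefined_as_zero: bool = False) -> pd.Series:
    """Per-node clustering coefficient; NaN for degree < 2 unless toggled."""
    cc = pd.Series(nx.clustering(G), dtype=float)
    if not undefined_as_zero:
        deg = pd.Series(dict(G.degree()), dtype=float)
        cc[deg < 2] = np.nan
    return cc.sort_index()


def compute_centralities(G: nx.Graph, betweenness_pivots: int | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Degree, closeness, betweenness, eccentricity, clustering per node.

    Closeness and eccentricity are computed within each node's connected
    component; betweenness uses Brandes accumulation per component with
    endpoint-excluding normalization by (n-1)(n-2)/2. ``betweenness_pivots``
    enables pivot-sampling approximation for very large graphs (exact by
    default).
    """
    closeness = nx.closeness_centrality(G, wf_improved=False)
    betweenness: dict = {}
    eccentricity: dict = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if betweenness_pivots is not None and sub.number_of_nodes() > betweenness_pivots:
            bc = nx.betweenness_centrality(sub, k=betweenness_pivots,
                                           normalized=True, seed=seed)
        else:
            bc = nx.betweenness_centrality(sub, normalized=True)
        betweenness.update(bc)
        eccentricity.update(nx.eccentricity(sub))
    df = pd.DataFrame({
        "degree": pd.Series(dict(G.degree()), dtype=int),
        "closeness": pd.Series(closeness, dtype=float),
        "betweenness": pd.Series(betweenness, dtype=float),
        "eccentricity": pd.Series(eccentricity, dtype=int),
        "clustering": clustering_coefficient(G),
        "component_id": pd.Series(nx.get_node_attributes(G, "component"), dtype=int),
    }).sort_index()
    df.index.name = "gene_id"
    return df


def disease_interactor_fraction(G: nx.Graph, genes: GeneSet,
                                disease_genes: GeneSet) -> pd.Series:
    """Per gene, the fraction of its interactors that are disease genes.

    Genes absent from the graph are skipped; isolated genes (no interactors)
    are excluded. Skip counts are logged.
    """
    if not genes.ids:
        raise ValueError("empty gene set")
    fractions = {}
    missing = 0
    isolated = 0
    for g in sorted(genes.ids):
        if g not in G:
            missing += 1
            continue
        nbrs = set(G.neighbors(g))
        if not nbrs:
            isolated += 1
            continue
        fractions[g] = len(nbrs & disease_genes.ids) / len(nbrs)
    if missing or isolated:
        log.info("disease_interactor_fraction: skipped %d genes absent from graph, "
                 "%d with no interactors", missing, isolated)
    return pd.Series(fractions, dtype=float).sort_index()
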