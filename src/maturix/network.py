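"""Hard-thresholded Pearson relevance network with modularity communities.

Genes are nodes; an edge joins two genes when the absolute Pearson
correlation of their expression across all samples exceeds a hard
threshold (0.98 by default, which at these sample sizes keeps only
near-deterministic co-expression).  Communities are found by the
fast-greedy modularity agglomeration of Clauset, Newman and Moore: start
from singletons, repeatedly merge the connected pair of communities with
the largest modularity gain, and cut the merge sequence at its first
modularity maximum.  Hub genes are ranked by degree and betweenness
centrality (raw bridge counts, unnormalized).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

DEFAULT_THRESHOLD = 0.98


def correlation_matrix(expr: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pearson correlation between genes (columns) across samples (rows).

    Zero-variance genes are excluded with a warning; the result is
    symmetric with unit diagonal.
    """
    if isinstance(expr, pd.DataFrame):
        X = expr.to_numpy(dtype=float)
        names = list(expr.columns)
    else:
        X = np.asarray(expr, dtype=float)
        names = list(range(X.shape[1]))
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate genes")
    var = X.var(axis=0)
    keep = var > 1e-14
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance gene(s)", stacklevel=2)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    S = np.atleast_2d(np.corrcoef(X, rowvar=False))
    S = np.clip(S, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=names, columns=names)


def threshold_adjacency(S: pd.DataFrame | np.ndarray, r0: float = DEFAULT_THRESHOLD):
    """Binary adjacency: edge iff |r| strictly exceeds ``r0`` (off-diagonal)."""
    if not 0.0 < r0 < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {r0}")
    A = (np.abs(np.asarray(S, dtype=float)) > r0).astype(int)
    np.fill_diagonal(A, 0)
    if isinstance(S, pd.DataFrame):
        return pd.DataFrame(A, index=S.index, columns=S.columns)
    return A


def graph_from_adjacency(A, S=None) -> nx.Graph:
    """Simple undirected graph; edges carry the correlation when S given."""
    if isinstance(A, pd.DataFrame):
        names = list(A.index)
        arr = A.to_numpy()
    else:
        arr = np.asarray(A)
        names = list(range(arr.shape[0]))
    G = nx.Graph()
    G.add_nodes_from(names)
    ii, jj = np.nonzero(np.triu(arr, k=1))
    for i, j in zip(ii, jj):
        r = float(np.asarray(S)[i, j]) if S is not None else None
        if r is None:
            G.add_edge(names[i], names[j])
        else:
            G.add_edge(names[i], names[j], r=r)
    return G


def largest_connected_component(G: nx.Graph) -> nx.Graph:
    """Induced subgraph of the largest component.

    Size ties are broken toward the component containing the
    lexicographically smallest node id, for determinism.
    """
    if G.number_of_nodes() == 0:
        return G.copy()
    comps = [sorted(c, key=str) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: (-len(c), str(c[0])))
    return G.subgraph(comps[0]).copy()


def modularity(G: nx.Graph, partition) -> float:
    """Newman modularity Q of a node partition (0 for an edgeless graph)."""
    m = G.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        comm = set(comm)
        inside = sum(1 for u, v in G.edges(comm) if u in comm and v in comm)
        deg = sum(d for _, d in G.degree(comm))
        q += inside / m - (deg / (2.0 * m)) ** 2
    return q


def fastgreedy_communities(G: nx.Graph) -> tuple[list[set], float]:
    """Clauset-Newman-Moore agglomerative modularity optimisation.

    Starts from singleton communities, repeatedly merges the connected pair
    with the largest modularity gain (ties toward the smallest pair of
    community indices, indices assigned in sorted node order), and returns
    the partition at the first maximum of Q along the merge sequence,
    together with that Q.  An edgeless graph returns singletons and Q = 0.
    """
    nodes = sorted(G.nodes, key=str)
    m = G.number_of_edges()
    if m == 0:
        return [{v} for v in nodes], 0.0
    idx = {v: i for i, v in enumerate(nodes)}
    members: dict[int, set] = {i: {v} for i, v in enumerate(nodes)}
    deg = {i: G.degree(nodes[i]) for i in members}
    inside = {i: 0 for i in members}
    between: dict[int, dict[int, int]] = {i: {} for i in members}
    for u, v in G.edges:
        i, j = idx[u], idx[v]
        if i == j:
            continue
        i, j = min(i, j), max(i, j)
        between[i][j] = between[i].get(j, 0) + 1
        between[j][i] = between[j].get(i, 0) + 1

    def q_now() -> float:
        return sum(inside[c] / m - (deg[c] / (2.0 * m)) ** 2 for c in members)

    best_q = q_now()
    best_partition = [set(s) for s in members.values()]
    next_index = len(nodes)
    while True:
        best_gain, best_pair = None, None
        for i in members:
            for j, b in between[i].items():
                if j <= i:
                    continue
                gain = b / m - 2.0 * (deg[i] / (2.0 * m)) * (deg[j] / (2.0 * m))
                if best_gain is None or gain > best_gain + 1e-15 or (
                    abs(gain - best_gain) <= 1e-15 and (i, j) < best_pair
                ):
                    best_gain, best_pair = gain, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        new = next_index
        next_index += 1
        members[new] = members.pop(i) | members.pop(j)
        inside[new] = inside.pop(i) + inside.pop(j) + between[i].get(j, 0)
        deg[new] = deg.pop(i) + deg.pop(j)
        nb = {}
        for old in (i, j):
            for k, b in between.pop(old).items():
                if k in (i, j):
                    continue
                nb[k] = nb.get(k, 0) + b
                between[k].pop(old, None)
                between[k][new] = between[k].get(new, 0) + b
        between[new] = nb
        q = q_now()
        if q > best_q + 1e-12:
            best_q = q
            best_partition = [set(s) for s in members.values()]
    best_partition.sort(key=lambda s: str(min(s, key=str)))
    return best_partition, best_q


def centralities(G: nx.Graph) -> pd.DataFrame:
    """Degree and unnormalized betweenness (Brandes) per node."""
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(G, normalized=False)
    nodes = sorted(G.nodes, key=str)
    return pd.DataFrame(
        {"degree": [deg[v] for v in nodes], "betweenness": [btw[v] for v in nodes]},
        index=pd.Index(nodes, name="gene"),
    )


def hub_report(G: nx.Graph, partition=None) -> pd.DataFrame:
    """Per-gene table with degree, betweenness, ranks and community label.

    Sorted by degree (descending) with ties broken by gene id; rank columns
    give the position under each criterion.
    """
    tab = centralities(G)
    if partition is not None:
        comm = {}
        for c, nodes in enumerate(partition, start=1):
            for v in nodes:
                comm[v] = c
        tab["community"] = [comm.get(v, 0) for v in tab.index]
    tab = tab.loc[sorted(tab.index, key=lambda v: (-tab.at[v, "degree"], str(v)))]
    tab["degree_rank"] = np.arange(1, len(tab) + 1)
    order_b = sorted(tab.index, key=lambda v: (-tab.at[v, "betweenness"], str(v)))
    tab["betweenness_rank"] = pd.Series(
        np.arange(1, len(tab) + 1), index=order_b
    ).reindex(tab.index)
    return tab


class RelevanceNetwork(BaseEstimator):
    """Build and analyse the hard-thresholded correlation network.

    Parameters
    ----------
    threshold : float
        Hard |r| threshold for edges (strict inequality).
    community_scope : {"largest_component", "full"}
        Whether communities are found within the largest connected
        component (as when reporting one interpretable module map) or on
        the full thresholded graph.

    Attributes
    ----------
    graph_ : the full thresholded graph (edges carry ``r``).
    largest_component_ : induced subgraph of the largest component.
    communities_ : list of node sets partitioning the scope graph.
    modularity_ : Q of that partition.
    hub_table_ : degree/betweenness report over the scope graph.
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD,
                 community_scope: str = "largest_component"):
        self.threshold = threshold
        self.community_scope = community_scope

    def fit(self, X, y=None):
        """``X``: samples x genes expression (DataFrame columns = gene ids)."""
        if self.community_scope not in ("largest_component", "full"):
            raise ValueError(f"unknown community_scope: {self.community_scope!r}")
        S = correlation_matrix(X)
        A = threshold_adjacency(S, self.threshold)
        self.correlation_ = S
        self.adjacency_ = A
        self.graph_ = graph_from_adjacency(A, S)
        self.largest_component_ = largest_connected_component(self.graph_)
        scope = self.largest_component_ if self.community_scope == "largest_component" else self.graph_
        self.communities_, self.modularity_ = fastgreedy_communities(scope)
        self.hub_table_ = hub_report(scope, self.communities_)
        return self

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"gene_a": str(u), "gene_b": str(v), "r": d.get("r", np.nan)}
            for u, v, d in sorted(self.graph_.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
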