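"""Five node-centrality measures on connected simple undirected graphs.

These are the measures classically used to rank proteins in
protein-protein interaction networks: degree (hubs), betweenness
(bottlenecks), closeness, eigenvector centrality, and the centroid
value. All are implemented here directly — Brandes' accumulation
algorithm over all-pairs BFS for betweenness, per-node BFS distance sums
for closeness, shifted power iteration for the eigenvector, and the
pairwise gamma-table definition for the centroid value — so that their
normalizations and tie conventions are fully pinned down:

* degree: raw neighbor count (integer);
* betweenness: fraction of shortest paths through the node, normalized
  by (n-1)(n-2)/2, in [0, 1];
* closeness: (n-1) / sum of shortest-path distances, in (0, 1];
* eigenvector: nonnegative principal eigenvector of the adjacency
  matrix with unit Euclidean norm;
* centroid value: raw signed integer min_u [gamma_v(u) - gamma_u(v)],
  where gamma_v(u) counts the nodes strictly closer to v than to u
  (endpoints included: d(v,v)=0 always counts for v; distance ties count
  for neither side). A node with positive centroid value wins the
  pairwise "closer to more of the network" contest against every other
  node.

Graphs are treated as unweighted; edge weights, if present, are ignored.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
import pandas as pd
from scipy import sparse

MEASURES = ("degree", "betweenness", "closeness", "centroid_value", "eigenvector")

#: Column order of the centrality table.
TABLE_COLUMNS = ["node", "degree", "betweenness", "closeness", "centroid_value", "eigenvector"]


def _sorted_adjacency(graph):
    nodes = sorted(graph)
    adj = {v: sorted(graph[v]) for v in nodes}
    return nodes, adj


def _bfs_distances(adj, source, nodes):
    dist = {v: -1 for v in nodes}
    dist[source] = 0
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def _require_connected(adj, nodes, caller):
    if not nodes:
        raise ValueError(f"{caller}: empty graph")
    dist = _bfs_distances(adj, nodes[0], nodes)
    if any(d < 0 for d in dist.values()):
        raise ValueError(f"{caller}: graph is disconnected; restrict to a connected component")


def degree_centrality(graph) -> dict:
    """Number of distinct neighbors of each node."""
    return {v: len(set(graph[v]) - {v}) for v in graph}


def betweenness_centrality(graph) -> dict:
    """Normalized betweenness via Brandes' dependency accumulation.

    Raw value for v is the sum over unordered pairs {s,t} (both != v) of
    the fraction of s-t shortest paths through v; the normalizer is
    (n-1)(n-2)/2. Graphs with n < 3 have no interior pairs and return
    all zeros with a warning.
    """
    nodes, adj = _sorted_adjacency(graph)
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    if n < 3:
        warnings.warn("betweenness undefined for n < 3; returning zeros", RuntimeWarning)
        return bc
    for s in nodes:
        stack: list = []
        preds = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0)
        sigma[s] = 1
        dist = dict.fromkeys(nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered {s,t} pair is accumulated from both endpoints
    norm = (n - 1) * (n - 2)
    return {v: bc[v] / norm for v in nodes}


def closeness_centrality(graph) -> dict:
    """(n-1) / (sum of shortest-path distances to every other node)."""
    nodes, adj = _sorted_adjacency(graph)
    n = len(nodes)
    if n < 2:
        raise ValueError("closeness needs at least 2 nodes")
    out = {}
    for v in nodes:
        dist = _bfs_distances(adj, v, nodes)
        if any(d < 0 for d in dist.values()):
            raise ValueError("closeness requires a connected graph")
        out[v] = (n - 1) / sum(dist.values())
    return out


def eigenvector_centrality(graph, tol: float = 1e-12, max_iter: int = 10_000) -> dict:
    """Principal adjacency eigenvector by shifted power iteration.

    Iterates x <- (A + I) x / ||(A + I) x|| from the uniform positive
    vector until the max successive-iterate difference drops below
    ``tol``. The identity shift makes every adjacency eigenvalue
    nonnegative after shifting, so the iteration converges on bipartite
    graphs (where +lambda and -lambda are otherwise tied). The result
    has unit Euclidean norm and nonnegative components.
    """
    nodes, adj = _sorted_adjacency(graph)
    _require_connected(adj, nodes, "eigenvector")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for v in nodes:
        for w in adj[v]:
            rows.append(index[v])
            cols.append(index[w])
    A = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = x + A @ x
        y /= np.linalg.norm(y)
        residual = np.abs(y - x).max()
        x = y
        if residual < tol:
            x = np.abs(x)
            x /= np.linalg.norm(x)
            return {v: float(x[index[v]]) for v in nodes}
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})"
    )


def _distance_matrix(adj, nodes):
    n = len(nodes)
    D = np.empty((n, n), dtype=np.int32)
    for i, v in enumerate(nodes):
        dist = _bfs_distances(adj, v, nodes)
        row = np.fromiter((dist[w] for w in nodes), dtype=np.int32, count=n)
        if (row < 0).any():
            raise ValueError("distance matrix requires a connected graph")
        D[i] = row
    return D


def centroid_value(graph) -> dict:
    """Centroid value: min over u != v of gamma_v(u) - gamma_u(v).

    gamma_v(u) counts all nodes w (v and u included) with
    d(w, v) < d(w, u); ties contribute to neither count. Values lie in
    [-(n-1), n-2].
    """
    nodes, adj = _sorted_adjacency(graph)
    n = len(nodes)
    if n < 2:
        raise ValueError("centroid value needs at least 2 nodes")
    D = _distance_matrix(adj, nodes)  # D[w, v] = d(w, v) after transpose-symmetry
    gamma = np.empty((n, n), dtype=np.int64)
    for j in range(n):
        # gamma[j, u] = #{w : d(w, nodes[j]) < d(w, nodes[u])}
        gamma[j] = (D[:, [j]] < D).sum(axis=0)
    f = gamma - gamma.T
    np.fill_diagonal(f, np.iinfo(np.int64).max)
    values = f.min(axis=1)
    return {v: int(values[i]) for i, v in enumerate(nodes)}


def compute_all(graph, tol: float = 1e-12, max_iter: int = 10_000) -> pd.DataFrame:
    """All five measures for every node of a connected simple graph.

    Returns a DataFrame with columns ``node, degree, betweenness,
    closeness, centroid_value, eigenvector``, one row per node, sorted
    by node symbol.
    """
    nodes, adj = _sorted_adjacency(graph)
    if len(nodes) < 2:
        raise ValueError("centrality analysis needs at least 2 nodes")
    _require_connected(adj, nodes, "compute_all")
    deg = degree_centrality(graph)
    btw = betweenness_centrality(graph)
    clo = closeness_centrality(graph)
    cen = centroid_value(graph)
    eig = eigenvector_centrality(graph, tol=tol, max_iter=max_iter)
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "centroid_value": [cen[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
        }
    )


def write_centrality_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g", columns=TABLE_COLUMNS)


def read_centrality_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"centrality table missing columns: {sorted(missing)}")
    return table
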