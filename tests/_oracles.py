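"""Independent brute-force oracles used by the test suite.

Deliberately naive: direct definitions and exhaustive enumeration via
third-party machinery (networkx path enumeration, dense eigensolve,
scipy's hypergeometric distribution), never the package's own code
paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import stats


def oracle_degree(graph):
    return {v: len(set(graph[v]) - {v}) for v in graph}


def oracle_betweenness(graph):
    """Exhaustive shortest-path enumeration over all unordered pairs."""
    nodes = sorted(graph)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(graph, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            raw[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: raw[v] / norm for v in nodes}


def oracle_closeness(graph):
    n = graph.number_of_nodes()
    out = {}
    for v in graph:
        dist = nx.single_source_shortest_path_length(graph, v)
        assert len(dist) == n, "oracle requires a connected graph"
        out[v] = (n - 1) / sum(dist.values())
    return out


def oracle_eigenvector(graph):
    """Principal eigenvector from a dense symmetric eigensolve."""
    nodes = sorted(graph)
    A = nx.to_numpy_array(graph, nodelist=nodes)
    eigenvalues, eigenvectors = np.linalg.eigh(A)
    principal = eigenvectors[:, np.argmax(eigenvalues)]
    principal = np.abs(principal)
    principal /= np.linalg.norm(principal)
    return {v: principal[i] for i, v in enumerate(nodes)}


def oracle_centroid(graph):
    """O(n^3) gamma-table computation straight from the definition.

    gamma_v(u) = #{w : d(w,v) < d(w,u)}, endpoints included, ties count
    for neither; centroid(v) = min over u != v of gamma_v(u) - gamma_u(v).
    Also asserts the antisymmetry f(v,u) = -f(u,v).
    """
    nodes = sorted(graph)
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    gamma = {
        (v, u): sum(1 for w in nodes if dist[w][v] < dist[w][u])
        for v in nodes
        for u in nodes
    }
    f = {(v, u): gamma[v, u] - gamma[u, v] for v in nodes for u in nodes}
    for v in nodes:
        for u in nodes:
            assert f[v, u] == -f[u, v]
    return {v: min(f[v, u] for u in nodes if u != v) for v in nodes}


def oracle_fisher_two_sided(a, b, c, d, rel_tol=1e-7):
    """Full hypergeometric enumeration via scipy's distribution object."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, col1, row1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + rel_tol)].sum()))


def random_connected_graph(n, p, seed):
    """Erdos-Renyi graph conditioned on connectivity, symbol-labeled."""
    for attempt in itertools.count():
        graph = nx.gnp_random_graph(n, p, seed=seed * 1000 + attempt)
        if nx.is_connected(graph):
            return nx.relabel_nodes(graph, {i: f"N{i:03d}" for i in graph})
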