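"""Independent oracles used by the test suite.

Everything here recomputes quantities by brute force (truncated series,
exhaustive BFS/path enumeration, direct set comprehensions) so that the
package's linear-algebra and graph-library implementations are checked
against a second, method-independent route.
"""

from __future__ import annotations

import math
from collections import deque

import networkx as nx
import numpy as np


def random_graph(rng: np.random.Generator, max_nodes: int = 12,
                 edge_prob: float = 0.35) -> nx.Graph:
    """Random labeled graph (possibly disconnected) with 3..max_nodes nodes."""
    n = int(rng.integers(3, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(f"v{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                g.add_edge(f"v{i}", f"v{j}")
    return g


# -- diffusion: truncated Taylor series of the heat kernel -------------------

def series_heat(graph: nx.Graph, seeds, tau: float, terms: int = 40) -> dict[str, float]:
    nodes = list(graph.nodes)
    w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    lap = np.diag(w.sum(axis=1)) - w
    h = np.array([1.0 if n in set(seeds) else 0.0 for n in nodes])
    out = h.copy()
    term = h.copy()
    for k in range(1, terms + 1):
        term = (-tau / k) * (lap @ term)
        out = out + term
    return dict(zip(nodes, out))


# -- topology: exhaustive BFS / path-enumeration oracle ----------------------

def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def adjacency(graph: nx.Graph) -> dict[str, set[str]]:
    return {n: set(graph.neighbors(n)) for n in graph.nodes}


def components(adj: dict[str, set[str]]) -> list[set[str]]:
    seen, comps = set(), []
    for n in adj:
        if n in seen:
            continue
        comp = set(bfs_distances(adj, n))
        comps.append(comp)
        seen |= comp
    return comps


def oracle_path_metrics(graph: nx.Graph) -> tuple[float, float]:
    """(diameter, mean shortest path length) on the largest component."""
    adj = adjacency(graph)
    comp = max(components(adj), key=lambda c: (len(c), sorted(c)))
    if len(comp) == 1:
        return 0.0, 0.0
    dists = []
    for s in comp:
        d = bfs_distances({n: adj[n] & comp for n in comp}, s)
        dists.extend(v for k, v in d.items() if k != s)
    return float(max(dists)), float(sum(dists) / len(dists))


def _all_shortest_paths(adj, s, t):
    """Enumerate every shortest s-t path by depth-first walking the BFS levels."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nxt in sorted(adj[node]):
            if dist.get(nxt, -1) == dist[node] + 1 and dist[nxt] <= dist[t]:
                walk(nxt, path + [nxt])

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def oracle_betweenness(graph: nx.Graph) -> dict[str, float]:
    """Normalized node betweenness by explicit shortest-path enumeration."""
    adj = adjacency(graph)
    nodes = sorted(adj)
    bc = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t not in dist or t == s:
                continue
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                frac = sum(v in p for p in paths) / len(paths)
                bc[v] += frac
    n = len(nodes)
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: bc[v] * norm for v in nodes}


def oracle_transitivity(graph: nx.Graph) -> float:
    adj = adjacency(graph)
    closed = 0
    triples = 0
    for v in adj:
        neigh = sorted(adj[v])
        for i in range(len(neigh)):
            for j in range(i + 1, len(neigh)):
                triples += 1
                if neigh[j] in adj[neigh[i]]:
                    closed += 1
    return closed / triples if triples else 0.0


def oracle_density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    return 2 * graph.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0


# -- propagation rule: direct set-comprehension oracle -----------------------

def oracle_propagation_members(graph: nx.Graph, lnc_edges: set[frozenset],
                               status: dict[str, str], kinds: dict[str, str],
                               seed: str, route_nodes: set[str]) -> set[str]:
    """Brute-force reapplication of the three subnetwork rules.

    (1) candidates: lncRNA-layer interactors of the seed with matching DE
    status; (2) the route is taken as given (recomputed by the caller);
    (3) keep candidates that are route nodes or adjacent to a non-seed
    route node; lncRNAs on the route are retained.
    """
    interactors = {next(iter(e - {seed})) for e in lnc_edges if seed in e}
    candidates = {p for p in interactors if status.get(p) == status[seed]}
    core = route_nodes - {seed}
    kept = set()
    for p in candidates:
        if p in route_nodes:
            kept.add(p)
        elif any(nb in core for nb in graph.neighbors(p)):
            kept.add(p)
    route_lnc = {n for n in route_nodes if kinds.get(n) == "lncRNA"}
    return {seed} | kept | route_lnc
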