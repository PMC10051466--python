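"""Heat diffusion on interaction networks and lncRNA propagation analysis.

Signal spread from a seed set is modeled as heat diffusion under the graph
Laplacian: h(tau) = exp(-tau * L) h0 with L = D - W on the undirected view
of the network and h0 the indicator vector of the seeds.  Because L is
symmetric, total heat is conserved and heats stay nonnegative; the kernel
is computed exactly by symmetric eigendecomposition.

The propagation analysis seeds diffusion at a differentially expressed
lncRNA, extracts the "relevant route" (the connected high-heat subgraph
containing the seed), and keeps the seed's DE-concordant interactors that
lie on or immediately around that route — reproducing the construction in
which, of the upregulated interactors A, B, C, D of an upregulated lncRNA
X, only A and D surround the route from X to another lncRNA Y, so the
subnetwork is {X, Y, A, D}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import DETable
from .network import MultiLayerNetwork


@dataclass
class HeatVector:
    """Per-node heat after diffusing for time tau from a seed set."""

    heat: pd.Series          # indexed by node id
    tau: float
    seeds: frozenset[str]

    @property
    def total(self) -> float:
        return float(self.heat.sum())

    def nonseed(self) -> pd.Series:
        return self.heat.drop(index=list(self.seeds))

    def delivered(self) -> float:
        """Total heat delivered outside the seed set (relevance score)."""
        return float(self.nonseed().sum())


@dataclass
class PropagationSubnetwork:
    seed: str
    route_nodes: set[str]
    surrounding: set[str]    # DE-concordant interactors kept by the rule
    members: set[str] = field(default_factory=set)
    edges: list[tuple[str, str]] = field(default_factory=list)


def _laplacian(graph: nx.Graph, nodes: list[str]) -> np.ndarray:
    w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    return np.diag(w.sum(axis=1)) - w


def diffuse(graph: nx.Graph | MultiLayerNetwork, seeds, tau: float = 0.1,
            weight_by_probability: bool = False) -> HeatVector:
    """Exact Laplacian heat kernel applied to the seed indicator vector.

    ``graph`` may be a networkx graph or a :class:`MultiLayerNetwork`
    (converted to its undirected view, optionally probability-weighted).
    """
    if isinstance(graph, MultiLayerNetwork):
        graph = graph.to_undirected(weight_by_probability=weight_by_probability)
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    missing = seeds - set(graph.nodes)
    if missing:
        raise ValueError(f"seeds not in graph: {sorted(missing)}")

    nodes = list(graph.nodes)
    lap = _laplacian(graph, nodes)
    h0 = np.array([1.0 if n in seeds else 0.0 for n in nodes])
    # symmetric eigendecomposition: exp(-tau L) = V exp(-tau lambda) V'
    lam, vec = np.linalg.eigh(lap)
    h = vec @ (np.exp(-tau * lam) * (vec.T @ h0))
    h = np.maximum(h, 0.0)
    return HeatVector(pd.Series(h, index=nodes), tau, seeds)


def extract_routes(heat: HeatVector, graph: nx.Graph | MultiLayerNetwork,
                   quantile: float = 0.9) -> nx.Graph:
    """Connected high-heat subgraph(s) containing at least one seed.

    The hot set is every non-seed node whose heat reaches the given quantile
    of non-seed heats; the returned subgraph is the union of connected
    components of the graph induced on seeds + hot set that contain a seed.
    """
    if isinstance(graph, MultiLayerNetwork):
        graph = graph.to_undirected()
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    nonseed = heat.nonseed()
    nonseed = nonseed[nonseed.index.isin(graph.nodes)]
    if len(nonseed):
        cut = float(np.quantile(nonseed.to_numpy(), quantile))
        hot = set(nonseed.index[nonseed >= cut])
    else:
        hot = set()
    keep = hot | set(heat.seeds)
    sub = graph.subgraph(keep)
    route_nodes: set[str] = set()
    for comp in nx.connected_components(sub):
        if comp & heat.seeds:
            route_nodes |= comp
    return graph.subgraph(route_nodes).copy()


def propagation_subnetwork(net: MultiLayerNetwork, de: DETable, seed_lncrna: str,
                           tau: float = 0.1, quantile: float = 0.9,
                           weight_by_probability: bool = False) -> PropagationSubnetwork:
    """LncRNA propagation analysis for one seed.

    1. Candidate proteins are the seed's lncRNA-layer interactors whose DE
       status matches the seed's.
    2. Heat is diffused from the seed and the relevant route extracted.
    3. Candidates are kept iff they are route nodes or adjacent to a
       non-seed route node; lncRNAs lying on the route are retained.
    """
    status = de.status_of(seed_lncrna)
    if status == "ns":
        raise ValueError(f"seed {seed_lncrna!r} is not differentially expressed")
    interactors = net.neighbors(seed_lncrna, layer="lncrna_protein")
    candidates = {p for p in interactors if de.status_of(p) == status}
    if not interactors:
        warnings.warn(f"seed {seed_lncrna!r} has no interactors; empty subnetwork")
        return PropagationSubnetwork(seed_lncrna, set(), set(), {seed_lncrna})

    graph = net.to_undirected(weight_by_probability=weight_by_probability)
    heat = diffuse(graph, {seed_lncrna}, tau)
    route = extract_routes(heat, graph, quantile)
    route_nodes = set(route.nodes)

    core = route_nodes - {seed_lncrna}  # "surrounding" excludes the seed's own adjacency
    kept = {p for p in candidates
            if p in route_nodes or any(r in core for r in graph.neighbors(p))}
    route_lncrnas = {n for n in route_nodes if net.node_kinds.get(n) == "lncRNA"}

    members = {seed_lncrna} | kept | route_lncrnas
    sub = graph.subgraph(members)
    return PropagationSubnetwork(seed_lncrna, route_nodes, kept, members,
                                 sorted(sub.edges))


def guilt_by_association(target_sets: dict[str, set[str]],
                         annotations: dict[str, str | set[str]]) -> pd.DataFrame:
    """Assign lncRNA functions from the annotations of their target proteins.

    ``target_sets`` maps lncRNA -> target proteins; ``annotations`` maps
    protein -> term (or set of terms).  Returns a table with per-lncRNA term
    frequencies and the top category; unannotated proteins count as
    "unknown" and lncRNAs without targets are "unassigned".
    """
    rows = []
    for lnc in sorted(target_sets):
        counts: dict[str, int] = {}
        for p in sorted(target_sets[lnc]):
            terms = annotations.get(p, "unknown")
            if isinstance(terms, str):
                terms = {terms}
            for term in sorted(terms):
                counts[term] = counts.get(term, 0) + 1
        total = sum(counts.values())
        if total == 0:
            rows.append((lnc, "unassigned", np.nan, {}))
            continue
        top = max(sorted(counts), key=lambda k: counts[k])
        rows.append((lnc, top, counts[top] / total, counts))
    return pd.DataFrame(rows, columns=["lncrna", "top_term", "top_fraction", "frequencies"])
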