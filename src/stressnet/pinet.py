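"""Pathway-integrated network (PINET) analysis.

Essential pathways and their member genes are modeled jointly as nodes:
pathways connect only through shared genes or gene–gene edges.  On top of
that structure the module clusters z-scored treatment time courses
(seedable k-medoids with Pearson distance), classifies each pathway's
aggregated time course as activation ("up and stable"), deactivation
("down and stable"), stable, or other, maps pathway-to-pathway information
flow by heat diffusion from each pathway's member genes, and ranks the
mediator genes that carry flow between a pathway pair (the CTA1/SUI2-type
bridges between signaling and downstream systems).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import HeatVector, diffuse
from .io import ExpressionSeries
from .network import MultiLayerNetwork

PROFILE_LABELS = ("activation", "deactivation", "stable", "other")


@dataclass
class Pinet:
    """Pathway nodes + gene nodes, membership edges, inherited gene edges."""

    pathways: dict[str, set[str]]
    gene_graph: nx.Graph

    def __post_init__(self) -> None:
        for p, members in self.pathways.items():
            if not members:
                warnings.warn(f"pathway {p!r} is empty; kept as an isolated node")
            self.gene_graph.add_nodes_from(members)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_graph.nodes)

    def membership_edges(self) -> list[tuple[str, str]]:
        return [(g, p) for p, members in self.pathways.items() for g in sorted(members)]

    def graph(self) -> nx.Graph:
        """Joint graph: genes + pathway nodes, membership + gene-gene edges."""
        g = self.gene_graph.copy()
        for p in self.pathways:
            g.add_node(p, kind="pathway")
        g.add_edges_from(self.membership_edges())
        return g

    def exclusive_members(self, pathway: str, other: str) -> set[str]:
        return self.pathways[pathway] - self.pathways[other]


def build_pinet(pathways: Mapping[str, set[str]], gene_edges) -> Pinet:
    """Integrate pathways through their genes.

    ``gene_edges`` may be a networkx graph, an (source, target) DataFrame,
    or a :class:`MultiLayerNetwork` (its undirected gene-level view is used,
    pathway-membership edges excluded).
    """
    if len(pathways) < 2:
        raise ValueError("need at least two pathways to integrate")
    if isinstance(gene_edges, MultiLayerNetwork):
        g = gene_edges.to_undirected()
        g.remove_nodes_from(gene_edges.nodes_of_kind("pathway"))
    elif isinstance(gene_edges, pd.DataFrame):
        g = nx.from_pandas_edgelist(gene_edges, "source", "target")
    else:
        g = nx.Graph(gene_edges)
    return Pinet({p: set(m) for p, m in pathways.items()}, g)


# ---------------------------------------------------------------------------
# Profile classification
# ---------------------------------------------------------------------------

def zscore_profile(series: Sequence[float]) -> np.ndarray:
    """Z-score a time profile; constant profiles map to all zeros."""
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def classify_profile(series: Sequence[float], epsilon: float = 0.25) -> str:
    """Classify a (z-scored) time course by its consecutive deltas.

    activation: first delta > epsilon, later deltas within +-epsilon
    ("up and stable"); deactivation is the mirror image; stable: all deltas
    within +-epsilon; anything else is "other".
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 time points")
    d = np.diff(x)
    later_flat = np.all(np.abs(d[1:]) <= epsilon)
    if abs(d[0]) <= epsilon and later_flat:
        return "stable"
    if d[0] > epsilon and later_flat:
        return "activation"
    if d[0] < -epsilon and later_flat:
        return "deactivation"
    return "other"


@dataclass
class PathwayProfile:
    pathway: str
    profile: pd.Series       # aggregated z-scored mean expression per time point
    label: str
    epsilon: float


def pathway_profiles(expression: ExpressionSeries, pathways: Mapping[str, set[str]],
                     condition: str = "treatment", epsilon: float = 0.25
                     ) -> dict[str, PathwayProfile]:
    """Aggregate member-gene z-scored time courses and classify each pathway."""
    tc = expression.timecourse(condition)
    out = {}
    for p, members in pathways.items():
        present = sorted(set(members) & set(tc.index))
        if not present:
            continue
        z = np.vstack([zscore_profile(tc.loc[g].to_numpy()) for g in present])
        agg = pd.Series(z.mean(axis=0), index=tc.columns)
        out[p] = PathwayProfile(p, agg, classify_profile(agg.to_numpy(), epsilon), epsilon)
    return out


# ---------------------------------------------------------------------------
# k-medoids time-course clustering
# ---------------------------------------------------------------------------

def _pearson_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson r; constant profiles are distance 0 to each other, 1 to the rest."""
    n = len(profiles)
    sd = profiles.std(axis=1)
    const = sd == 0
    z = np.where(const[:, None], 0.0,
                 (profiles - profiles.mean(axis=1, keepdims=True))
                 / np.where(sd[:, None] == 0, 1.0, sd[:, None]))
    r = (z @ z.T) / (profiles.shape[1])
    d = 1.0 - np.clip(r, -1.0, 1.0)
    for i in range(n):
        if const[i]:
            d[i, :] = np.where(const, 0.0, 1.0)
            d[:, i] = d[i, :]
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ClusterResult:
    assignment: pd.Series     # feature -> cluster index
    medoids: list[str]
    prototypes: pd.DataFrame  # cluster x time, mean z-scored profile
    cost: float


def cluster_timecourses(expression: ExpressionSeries, net: Pinet | None = None,
                        k: int = 8, seed: int = 0, condition: str = "treatment",
                        n_restarts: int = 5) -> ClusterResult:
    """Seedable k-medoids (PAM-style alternation) on z-scored time profiles.

    Distance is 1 - Pearson correlation between z-scored treatment time
    courses.  When a PINET is given, clustering is restricted to its genes
    (merging the network with the time-course data); several seeded restarts
    keep the best total cost, so results are deterministic under a fixed seed.
    """
    tc = expression.timecourse(condition)
    if tc.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    if net is not None:
        keep = sorted(net.genes & set(tc.index))
        tc = tc.loc[keep]
    features = list(tc.index)
    if k > len(features):
        raise ValueError(f"k={k} exceeds the {len(features)} available features")
    profiles = np.vstack([zscore_profile(tc.loc[f].to_numpy()) for f in features])
    dist = _pearson_distance_matrix(np.asarray(tc, dtype=float))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        medoids = list(rng.choice(len(features), size=k, replace=False))
        for _ in range(100):
            assign = np.argmin(dist[:, medoids], axis=1)
            new_medoids = []
            for c in range(k):
                members = np.flatnonzero(assign == c)
                if len(members) == 0:
                    new_medoids.append(medoids[c])
                    continue
                within = dist[np.ix_(members, members)].sum(axis=0)
                new_medoids.append(int(members[np.argmin(within)]))
            if new_medoids == medoids:
                break
            medoids = new_medoids
        assign = np.argmin(dist[:, medoids], axis=1)
        cost = float(dist[np.arange(len(features)), [medoids[c] for c in assign]].sum())
        if best is None or cost < best[0]:
            best = (cost, medoids, assign)
    cost, medoids, assign = best

    prototypes = pd.DataFrame(
        [profiles[assign == c].mean(axis=0) if np.any(assign == c) else profiles[medoids[c]]
         for c in range(k)],
        columns=tc.columns,
    )
    return ClusterResult(pd.Series(assign, index=features), [features[m] for m in medoids],
                         prototypes, cost)


# ---------------------------------------------------------------------------
# Pathway-to-pathway flow and mediators
# ---------------------------------------------------------------------------

@dataclass
class FlowMap:
    weights: dict[tuple[str, str], float]
    threshold: float
    heats: dict[str, HeatVector] = field(default_factory=dict)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(s, t, w) for (s, t), w in sorted(self.weights.items())
                if w >= self.threshold and w > 0]

    def weight(self, source: str, target: str) -> float:
        return self.weights.get((source, target), 0.0)


def pathway_flow(pin: Pinet, tau: float = 0.1, threshold: float | None = None) -> FlowMap:
    """Directed pathway-to-pathway information flow by member-seeded diffusion.

    For each source pathway, heat diffuses from its member genes over the
    gene layer; the flow to a target pathway is the mean heat over the
    target's exclusive members, normalized by the initial heat mass.  The
    reporting threshold defaults to the 75th percentile of nonzero weights.
    """
    weights: dict[tuple[str, str], float] = {}
    heats: dict[str, HeatVector] = {}
    graph = pin.gene_graph
    for src, members in pin.pathways.items():
        seeds = set(members) & set(graph.nodes)
        if not seeds:
            for tgt in pin.pathways:
                if tgt != src:
                    weights[(src, tgt)] = 0.0
            continue
        heat = diffuse(graph, seeds, tau)
        heats[src] = heat
        for tgt, tgt_members in pin.pathways.items():
            if tgt == src:
                continue
            exclusive = sorted((tgt_members - members) & set(graph.nodes))
            if not exclusive:
                weights[(src, tgt)] = 0.0
                continue
            w = float(heat.heat[exclusive].mean()) / heat.total
            weights[(src, tgt)] = w if w > 1e-12 else 0.0
    if threshold is None:
        nonzero = [w for w in weights.values() if w > 0]
        threshold = float(np.percentile(nonzero, 75)) if nonzero else 0.0
    return FlowMap(weights, threshold, heats)


def identify_mediators(pin: Pinet, source: str, target: str,
                       heat: HeatVector | None = None, tau: float = 0.1,
                       max_len: int = 6) -> pd.DataFrame:
    """Rank genes that carry flow between two pathways.

    Candidates are the interior nodes of shortest paths between the two
    pathways' member sets (paths capped at ``max_len`` edges), ranked by
    diffusion heat from the source members; ties break lexicographically.
    Returns an empty table when no path connects the pathways.
    """
    graph = pin.gene_graph
    a = sorted(set(pin.pathways[source]) & set(graph.nodes))
    b = sorted(set(pin.pathways[target]) & set(graph.nodes))
    if heat is None and a:
        heat = diffuse(graph, set(a), tau)
    candidates: set[str] = set()
    for s in a:
        lengths, paths = nx.single_source_dijkstra(graph, s, weight=None, cutoff=max_len)
        for t in b:
            if t in paths and t != s:
                # all shortest s-t paths, interior nodes only
                for path in nx.all_shortest_paths(graph, s, t):
                    if len(path) - 1 <= max_len:
                        candidates.update(path[1:-1])
    rows = [(g, float(heat.heat.get(g, 0.0))) for g in sorted(candidates)]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "heat"])
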