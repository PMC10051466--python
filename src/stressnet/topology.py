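"""Topology statistics for condition-network comparison.

Ethanol stress rewires the strain networks: in most emulated treated
networks the diameter, characteristic path length and betweenness rise
while density, transitivity, edge count and eigenvector centrality fall,
and stressed low-tolerance strains lose more of their hubs.  This module
computes those metrics, the treatment-minus-control deltas with a flag for
that qualitative rewiring pattern, hub loss, and a paired sign test across
strains for each metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .network import ConditionNetwork, MultiLayerNetwork

#: metric -> expected sign of (treatment - control) under the stress-rewiring pattern
REWIRING_PATTERN = {
    "diameter": +1,
    "mean_path_length": +1,
    "mean_betweenness": +1,
    "density": -1,
    "transitivity": -1,
    "n_edges": -1,
    "mean_eigenvector": -1,
}


@dataclass
class TopologyReport:
    diameter: float
    mean_path_length: float
    mean_betweenness: float
    density: float
    transitivity: float
    n_edges: int
    mean_eigenvector: float
    n_nodes: int
    n_components: int

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _as_graph(net) -> nx.Graph:
    if isinstance(net, ConditionNetwork):
        return net.to_undirected()
    if isinstance(net, MultiLayerNetwork):
        return net.to_undirected()
    return nx.Graph(net)


def compute_topology(net) -> TopologyReport:
    """All metrics of a condition network; path metrics on the largest component."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=lambda c: (len(c), sorted(c)))).copy()

    if giant.number_of_nodes() > 1:
        diameter = float(nx.diameter(giant))
        mean_path = float(nx.average_shortest_path_length(giant))
    else:
        diameter = 0.0
        mean_path = 0.0
    betw = nx.betweenness_centrality(g, normalized=True)
    if giant.number_of_nodes() > 1:
        # leading eigenvector of the adjacency matrix, unit 2-norm,
        # computed densely (robust for the tiny components that arise here)
        a = nx.to_numpy_array(giant)
        _, vec = np.linalg.eigh(a)
        lead = np.abs(vec[:, -1])
        mean_eig = float(np.mean(lead / np.linalg.norm(lead)))
    else:
        mean_eig = 1.0
    return TopologyReport(
        diameter=diameter,
        mean_path_length=mean_path,
        mean_betweenness=float(np.mean(list(betw.values()))),
        density=float(nx.density(g)),
        transitivity=float(nx.transitivity(g)),
        n_edges=g.number_of_edges(),
        mean_eigenvector=mean_eig,
        n_nodes=g.number_of_nodes(),
        n_components=len(components),
    )


@dataclass
class ConditionComparison:
    deltas: dict[str, float]          # treatment - control per metric
    matches_pattern: dict[str, bool]  # strict per-metric agreement with the pattern
    pattern_holds: bool               # every metric moved the expected way


def compare_conditions(control: TopologyReport, treatment: TopologyReport) -> ConditionComparison:
    """Signed metric deltas plus a flag for the stress-rewiring direction pattern."""
    c, t = control.as_dict(), treatment.as_dict()
    deltas = {m: t[m] - c[m] for m in REWIRING_PATTERN}
    matches = {m: bool(np.sign(deltas[m]) == REWIRING_PATTERN[m]) for m in REWIRING_PATTERN}
    return ConditionComparison(deltas, matches, all(matches.values()))


def hub_loss(control_net, treatment_net, decile: float = 0.1) -> tuple[int, list[str]]:
    """Hubs of the control network missing from the treatment network.

    Hubs are the top ``decile`` fraction of control nodes by degree; ties at
    the boundary degree are all included.
    """
    if not 0 < decile <= 1:
        raise ValueError("decile must lie in (0, 1]")
    gc = _as_graph(control_net)
    gt = _as_graph(treatment_net)
    degrees = dict(gc.degree())
    if not degrees:
        return 0, []
    n_top = max(1, math.ceil(decile * len(degrees)))
    ordered = sorted(degrees, key=lambda n: (-degrees[n], n))
    threshold = degrees[ordered[n_top - 1]]
    hubs = [n for n in ordered if degrees[n] >= threshold]
    lost = sorted(h for h in hubs if h not in gt.nodes)
    return len(lost), lost


def paired_sign_test(reports: Mapping[str, tuple[TopologyReport, TopologyReport]]
                     ) -> dict[str, dict[str, float]]:
    """Two-sided sign test per metric across strains (control vs treatment pairs).

    ``reports`` maps strain -> (control report, treatment report).  Ties are
    dropped, as usual for the sign test.
    """
    out: dict[str, dict[str, float]] = {}
    for metric in REWIRING_PATTERN:
        diffs = [tr.as_dict()[metric] - co.as_dict()[metric]
                 for co, tr in reports.values()]
        pos = sum(d > 0 for d in diffs)
        neg = sum(d < 0 for d in diffs)
        n = pos + neg
        p = float(stats.binomtest(pos, n, 0.5).pvalue) if n else float("nan")
        out[metric] = {"n_increased": pos, "n_decreased": neg, "p_value": p}
    return out


def export_graphml(net, path) -> None:
    nx.write_graphml(_as_graph(net), path)
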