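"""Multi-layer interaction networks and condition-specific subnetworks.

The pipeline unifies four experimentally grounded interaction layers for
yeast — protein–protein interactions (``ppi``), a signed gene-regulatory
network (``grn``), metabolic links (``metabolic``) and probabilistic
lncRNA–protein interactions (``lncrna_protein``) — into one typed graph,
applies the interaction-probability filter to the lncRNA layer, and derives
control/treatment ("condition") networks from expression data by dropping
nodes whose mean expression falls below a floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

NODE_KINDS = {"gene", "protein", "lncRNA", "metabolite", "pathway"}
EDGE_LAYERS = {"ppi", "grn", "metabolic", "lncrna_protein", "pathway_membership"}
EDGE_COLUMNS = ["source", "target", "layer", "sign", "probability", "directed"]

#: layers whose edges are directed by construction
DIRECTED_LAYERS = {"grn"}


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass
class MultiLayerNetwork:
    """Typed nodes plus typed, optionally signed/probabilistic edges.

    Parameters
    ----------
    node_kinds
        Mapping of node id to kind (one of ``gene``, ``protein``, ``lncRNA``,
        ``metabolite``, ``pathway``).
    edges
        DataFrame with columns ``source, target, layer, sign, probability,
        directed``.  ``sign`` is +1/-1 on ``grn`` edges and 0 elsewhere;
        ``probability`` is NaN where the layer carries none.
    """

    node_kinds: dict[str, str]
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.edges = self.edges.reindex(columns=EDGE_COLUMNS)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        unknown = set(self.node_kinds.values()) - NODE_KINDS
        if unknown:
            raise NetworkValidationError(f"unknown node kinds: {sorted(unknown)}")
        e = self.edges
        bad_layer = set(e["layer"]) - EDGE_LAYERS
        if bad_layer:
            raise NetworkValidationError(f"unknown edge layers: {sorted(bad_layer)}")
        grn = e[e["layer"] == "grn"]
        if grn["sign"].isna().any() or not set(grn["sign"]).issubset({1, -1, 1.0, -1.0}):
            raise NetworkValidationError("grn edges must carry sign in {+1, -1}")
        lnc = e[e["layer"] == "lncrna_protein"]
        if lnc["probability"].isna().any():
            raise NetworkValidationError("lncrna_protein edges must carry a probability")
        if ((lnc["probability"] < 0) | (lnc["probability"] > 1)).any():
            raise NetworkValidationError("interaction probabilities must lie in [0, 1]")
        selfloops = e[(e["source"] == e["target"]) & (e["layer"] != "grn")]
        if len(selfloops):
            raise NetworkValidationError(
                f"self-loops only allowed on the grn layer: {selfloops['source'].tolist()}"
            )
        missing = (set(e["source"]) | set(e["target"])) - set(self.node_kinds)
        if missing:
            raise NetworkValidationError(f"edges reference unknown nodes: {sorted(missing)[:5]}")

    # -- basic accessors ----------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.node_kinds)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, k in self.node_kinds.items() if k == kind]

    def layer(self, name: str) -> pd.DataFrame:
        return self.edges[self.edges["layer"] == name]

    def neighbors(self, node: str, layer: str | None = None) -> set[str]:
        e = self.edges if layer is None else self.layer(layer)
        out = set(e.loc[e["source"] == node, "target"])
        out |= set(e.loc[e["target"] == node, "source"])
        out.discard(node)
        return out

    def to_undirected(self, weight_by_probability: bool = False) -> nx.Graph:
        """Undirected networkx view (all layers); used for diffusion/topology.

        With ``weight_by_probability`` edges carrying a probability use it as
        weight; all other edges get weight 1.
        """
        g = nx.Graph()
        g.add_nodes_from(self.node_kinds)
        for row in self.edges.itertuples(index=False):
            if row.source == row.target:
                continue
            w = 1.0
            if weight_by_probability and np.isfinite(row.probability):
                w = float(row.probability)
            prev = g.get_edge_data(row.source, row.target)
            if prev is None or prev["weight"] < w:
                g.add_edge(row.source, row.target, weight=w, layer=row.layer)
        return g

    def subnetwork(self, keep: Iterable[str]) -> "MultiLayerNetwork":
        keep = set(keep)
        e = self.edges
        mask = e["source"].isin(keep) & e["target"].isin(keep)
        return MultiLayerNetwork(
            {n: k for n, k in self.node_kinds.items() if n in keep},
            e[mask].reset_index(drop=True),
        )

    def __len__(self) -> int:
        return len(self.node_kinds)


@dataclass
class ConditionNetwork:
    """Induced subgraph of a parent network under one experimental condition."""

    parent: MultiLayerNetwork
    condition: str
    retained: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        extra = self.retained - set(self.parent.node_kinds)
        if extra:
            raise NetworkValidationError(f"retained nodes not in parent: {sorted(extra)[:5]}")

    @property
    def network(self) -> MultiLayerNetwork:
        return self.parent.subnetwork(self.retained)

    def to_undirected(self, **kw) -> nx.Graph:
        return self.network.to_undirected(**kw)


def merge_layers(layers: Iterable[pd.DataFrame],
                 node_kinds: Mapping[str, str] | None = None) -> MultiLayerNetwork:
    """Unify per-layer edge tables into one MultiLayerNetwork.

    Duplicate ``(source, target, layer)`` triples collapse to a single edge
    keeping the maximum probability.  Node kinds are taken from ``node_kinds``
    when given, otherwise inferred (``lncrna_protein`` sources are lncRNAs,
    everything else defaults to ``gene``).
    """
    frames = [df.reindex(columns=EDGE_COLUMNS) for df in layers]
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=EDGE_COLUMNS)
    grn = merged[merged["layer"] == "grn"]
    if grn["sign"].isna().any():
        raise NetworkValidationError("grn edge without sign in merged layers")

    if len(merged):
        # undirected duplicates are collapsed irrespective of orientation
        key = merged.apply(
            lambda r: (r["source"], r["target"], r["layer"])
            if r["layer"] in DIRECTED_LAYERS or r["source"] <= r["target"]
            else (r["target"], r["source"], r["layer"]),
            axis=1,
        )
        merged = (
            merged.assign(_key=key)
            .sort_values("probability", na_position="first")
            .groupby("_key", as_index=False, sort=False)
            .last()
            .drop(columns="_key")
        )
        merged = merged.sort_values(["layer", "source", "target"]).reset_index(drop=True)

    if node_kinds is None:
        node_kinds = {}
        for row in merged.itertuples(index=False):
            if row.layer == "lncrna_protein":
                node_kinds.setdefault(row.source, "lncRNA")
                node_kinds.setdefault(row.target, "gene")
            elif row.layer == "metabolic":
                node_kinds.setdefault(row.source, "gene")
                node_kinds.setdefault(row.target, "gene")
            else:
                node_kinds.setdefault(row.source, "gene")
                node_kinds.setdefault(row.target, "gene")
    else:
        node_kinds = dict(node_kinds)
        for n in set(merged["source"]) | set(merged["target"]):
            node_kinds.setdefault(n, "gene")
    return MultiLayerNetwork(node_kinds, merged)


def filter_lncrna_edges(net: MultiLayerNetwork, threshold: float = 0.95) -> MultiLayerNetwork:
    """Drop lncRNA–protein edges with interaction probability < ``threshold``.

    The cut is inclusive (probability >= threshold survives); all other
    layers pass through untouched.  Idempotent, monotone in ``threshold``.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    e = net.edges
    keep = (e["layer"] != "lncrna_protein") | (e["probability"] >= threshold)
    return MultiLayerNetwork(dict(net.node_kinds), e[keep].reset_index(drop=True))


def emulate_condition_network(net: MultiLayerNetwork, expression, condition: str,
                              floor: float | None = None) -> ConditionNetwork:
    """Derive a condition-specific network by expression-floor node retention.

    A gene/protein/lncRNA node is retained iff its mean expression under
    ``condition`` exceeds ``floor`` (log2 units).  ``floor=None`` uses the
    5th percentile of all condition means.  Nodes absent from the expression
    table (e.g. metabolites, pathways) are retained unchanged.
    """
    if condition not in set(expression.samples["condition"]):
        raise ValueError(f"unknown condition {condition!r}")
    means = expression.condition_means(condition)
    if floor is None:
        floor = float(np.percentile(means.to_numpy(), 5))
    retained = set()
    for node in net.node_kinds:
        if node in means.index:
            if means[node] > floor:
                retained.add(node)
        else:
            retained.add(node)  # unmapped nodes kept (warning left to caller)
    return ConditionNetwork(net, condition, retained)
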