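import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import stressnet as sn
from stressnet.network import EDGE_COLUMNS


@pytest.fixture(scope="session")
def noiseless_study() -> sn.SyntheticStudy:
    """Default study conditions at zero replicate noise (exact planted recovery)."""
    return sn.generate_study(sn.SyntheticScenario(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_study() -> sn.SyntheticStudy:
    return sn.generate_study(sn.SyntheticScenario(seed=1))


def make_worked_example() -> tuple[sn.MultiLayerNetwork, sn.DETable]:
    """The schematic propagation fixture.

    The upregulated lncRNA X interacts with the upregulated genes A, B, C
    and D; the route from X runs through A to the lncRNA Y; D hangs off A;
    B and C drain their heat into pendant sink genes, so only A and D
    surround the relevant route and the subnetwork is {X, Y, A, D}.
    """
    rows = [
        ("X", "A", "lncrna_protein", np.nan, 0.96, False),
        ("X", "B", "lncrna_protein", np.nan, 0.96, False),
        ("X", "C", "lncrna_protein", np.nan, 0.96, False),
        ("X", "D", "lncrna_protein", np.nan, 0.96, False),
        ("Y", "A", "lncrna_protein", np.nan, 0.96, False),
        ("A", "D", "ppi", np.nan, np.nan, False),
    ]
    for n in "BC":
        for i in range(5):
            rows.append((n, f"{n}s{i}", "ppi", np.nan, np.nan, False))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    kinds = {"X": "lncRNA", "Y": "lncRNA"}
    for r in rows:
        for n in (r[0], r[1]):
            kinds.setdefault(n, "gene")
    net = sn.merge_layers([edges], node_kinds=kinds)
    de_rows = [(n, 1.0, 0.001, "up") for n in "XABCD"]
    de_rows += [(n, 0.0, 0.5, "ns") for n in net.nodes if n not in set("XABCD")]
    de = sn.DETable(pd.DataFrame(de_rows, columns=["id", "log2FC", "padj", "status"]))
    return net, de


@pytest.fixture()
def worked_example():
    return make_worked_example()


def make_hub_pair():
    """Control = lollipop core + 3 global hubs; treatment = core after hub loss."""
    import networkx as nx

    base = nx.lollipop_graph(4, 16)
    base = nx.relabel_nodes(base, {i: f"n{i:02d}" for i in base.nodes})
    control = base.copy()
    hubs = ["h0", "h1", "h2"]
    for h in hubs:
        for n in base.nodes:
            control.add_edge(h, n)
    for i in range(3):
        for j in range(i + 1, 3):
            control.add_edge(hubs[i], hubs[j])
    return control, base, hubs


@pytest.fixture()
def hub_pair():
    return make_hub_pair()
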