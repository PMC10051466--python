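"""Synthetic study generator with planted ground truth.

Emulates the inputs of a time-course ethanol-stress experiment on yeast:
log2 expression for coding genes and lncRNAs under control/treatment at
t = 0, 1, 2, 4 h with replicate noise; pathways with planted activation
("up and stable"), deactivation ("down and stable") or stable profiles;
a multi-layer interaction network (PPI, signed GRN, metabolic,
probabilistic lncRNA–protein) with planted high-probability diffusion
routes from seed lncRNAs; and a differential-expression table derived from
the planted labels.  Every quantity downstream stages are meant to recover
is recorded in a :class:`GroundTruth` object so tests can assert exact
recovery at zero noise.

Conventions: expression is on the log2 scale with Gaussian replicate noise;
lncRNA baselines are drawn strictly below coding baselines (lncRNAs are
expressed below coding genes); decoy lncRNA–protein probabilities live in
[0.3, 0.94] so the 0.95 interaction-probability filter has an unambiguous
planted boundary; each lncRNA targets ~8 proteins by default, the scale
reported for yeast lncRNA–protein interactomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DETable, ExpressionSeries, sample_id, write_de, write_expression, write_edges, write_gmt
from .network import EDGE_COLUMNS, MultiLayerNetwork, merge_layers
from .ode import RegulatoryODEModel, two_repressor_motif

PROFILE_CLASSES = ("activation", "deactivation", "stable")


class InvalidScenarioError(ValueError):
    pass


def gene_id(i: int) -> str:
    return f"g{i:03d}"


def lnc_id(i: int) -> str:
    return f"lnc{i:02d}"


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic strain.

    Defaults emulate the study design: time course at 0/1/2/4 h, three
    replicates per condition, six pathways cycling through the three
    planted profile classes, two planted lncRNA diffusion routes, and a
    two-repressor regulatory motif as the planted ODE ground truth.
    """

    n_genes: int = 120
    n_lncrnas: int = 15
    n_pathways: int = 6
    time_points: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    n_replicates: int = 3
    noise_sd: float = 0.25
    planted_profiles: dict[str, str] | None = None
    planted_routes: list[list[str]] | None = None
    planted_ode: RegulatoryODEModel | None = None
    n_off_genes: int = 10          # genes silenced under treatment
    avg_targets_per_lncrna: int = 8
    effect_size: float = 2.0       # log2 step of planted up/down profiles
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_lncrnas, self.n_pathways) <= 0:
            raise InvalidScenarioError("counts must be positive")
        tp = tuple(float(t) for t in self.time_points)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])) or tp[0] != 0.0:
            raise InvalidScenarioError("time_points must be strictly increasing and start at 0")
        if self.n_replicates < 2:
            raise InvalidScenarioError("need at least 2 replicates per condition")
        if self.noise_sd < 0:
            raise InvalidScenarioError("noise_sd must be nonnegative")
        self.time_points = tp
        if self.planted_ode is None:
            self.planted_ode = two_repressor_motif()
        if self.planted_profiles is None:
            self.planted_profiles = {
                self.pathway_name(i): PROFILE_CLASSES[i % 3] for i in range(self.n_pathways)
            }
        if self.planted_routes is None:
            self.planted_routes = self._default_routes()
        member_sets = self.pathway_members()
        all_nodes = {gene_id(i) for i in range(self.n_genes)} | {
            lnc_id(i) for i in range(self.n_lncrnas)}
        for route in self.planted_routes:
            if len(route) < 2:
                raise InvalidScenarioError(f"route too short: {route}")
            if not set(route) <= all_nodes:
                raise InvalidScenarioError(f"route nodes missing from scenario: {route}")
        if self.n_off_genes > len(self.background_genes()):
            raise InvalidScenarioError("not enough background genes for n_off_genes")
        _ = member_sets

    # -- deterministic layout -------------------------------------------------
    @staticmethod
    def pathway_name(i: int) -> str:
        return f"pathway_{i + 1:02d}"

    def pathway_members(self) -> dict[str, list[str]]:
        """Disjoint gene blocks per pathway; the tail of the gene list is background."""
        block = self.n_genes // (self.n_pathways + 1)
        if block < 1:
            raise InvalidScenarioError("too few genes for the requested pathways")
        return {
            self.pathway_name(p): [gene_id(p * block + j) for j in range(block)]
            for p in range(self.n_pathways)
        }

    def background_genes(self) -> list[str]:
        block = self.n_genes // (self.n_pathways + 1)
        return [gene_id(i) for i in range(self.n_pathways * block, self.n_genes)]

    def off_genes(self) -> list[str]:
        return self.background_genes()[: self.n_off_genes]

    def _default_routes(self) -> list[list[str]]:
        members = self.pathway_members()
        activation = [p for p, c in self.planted_profiles.items() if c == "activation"]
        routes = []
        for i in range(min(2, self.n_lncrnas, len(activation))):
            genes = members[activation[i]][:3]
            if len(genes) == 3:
                routes.append([lnc_id(i)] + genes)
        return routes

    def route_seeds(self) -> list[str]:
        return [r[0] for r in self.planted_routes]


@dataclass
class GroundTruth:
    """Planted labels recorded alongside the generated data."""

    de_status: dict[str, str]
    pathway_labels: dict[str, str]
    pathway_members: dict[str, list[str]]
    route_nodes: list[list[str]]
    off_genes: list[str]
    ode_basal: dict[str, float]
    ode_decay: dict[str, float]
    ode_edges: list[list]  # [source, target, weight, sign]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def status_counts(self) -> dict[str, int]:
        out = {"up": 0, "down": 0, "ns": 0}
        for s in self.de_status.values():
            out[s] += 1
        return out


def _ground_truth(scenario: SyntheticScenario) -> GroundTruth:
    members = scenario.pathway_members()
    labels = dict(scenario.planted_profiles)
    off = set(scenario.off_genes())
    seeds = set(scenario.route_seeds())
    status: dict[str, str] = {}
    for p, genes in members.items():
        cls = labels[p]
        for g in genes:
            status[g] = {"activation": "up", "deactivation": "down", "stable": "ns"}[cls]
    for i in range(scenario.n_genes):
        status.setdefault(gene_id(i), "ns")
    for g in off:
        status[g] = "down"
    for i in range(scenario.n_lncrnas):
        status[lnc_id(i)] = "up" if lnc_id(i) in seeds else "ns"
    ode = scenario.planted_ode
    return GroundTruth(
        de_status=status,
        pathway_labels=labels,
        pathway_members={p: list(g) for p, g in members.items()},
        route_nodes=[list(r) for r in scenario.planted_routes],
        off_genes=sorted(off),
        ode_basal=dict(ode.basal),
        ode_decay=dict(ode.decay),
        ode_edges=[[s, t, w, sg] for (s, t), (w, sg) in sorted(ode.edges.items())],
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(scenario: SyntheticScenario) -> tuple[ExpressionSeries, GroundTruth]:
    """Planted time-course expression matrix plus its ground truth.

    Treatment means follow the planted pathway profile (a log2 step of
    ``effect_size`` after t=0, then flat); control means are flat at the
    baseline.  Replicates add Gaussian noise of sd ``noise_sd``.
    """
    truth = _ground_truth(scenario)
    rng = np.random.default_rng([scenario.seed, 0])

    genes = [gene_id(i) for i in range(scenario.n_genes)]
    lncs = [lnc_id(i) for i in range(scenario.n_lncrnas)]
    features = genes + lncs
    base = np.concatenate([
        rng.uniform(7.0, 10.0, scenario.n_genes),   # coding baselines
        rng.uniform(2.0, 5.0, scenario.n_lncrnas),  # lncRNAs strictly below
    ])
    baseline = dict(zip(features, base))

    off = set(truth.off_genes)
    step = {"up": scenario.effect_size, "down": -scenario.effect_size, "ns": 0.0}

    def treatment_mean(f: str, t: float) -> float:
        if f in off:
            return baseline[f] - 6.0  # silenced throughout treatment
        return baseline[f] + (step[truth.de_status[f]] if t > 0 else 0.0)

    columns, data = [], []
    for cond in ("control", "treatment"):
        for t in scenario.time_points:
            for rep in range(1, scenario.n_replicates + 1):
                columns.append(sample_id(cond, t, rep))
                mean = np.array([
                    baseline[f] if cond == "control" else treatment_mean(f, t)
                    for f in features
                ])
                noise = rng.normal(0.0, scenario.noise_sd, len(features)) \
                    if scenario.noise_sd > 0 else 0.0
                data.append(mean + noise)

    values = pd.DataFrame(np.column_stack(data), index=features, columns=columns)
    ann = {}
    for col in columns:
        cond, t, rep = col.rsplit("_", 2)
        ann[col] = (cond, float(t), int(rep))
    samples = pd.DataFrame.from_dict(ann, orient="index",
                                     columns=["condition", "time", "replicate"])
    return ExpressionSeries(values, samples), truth


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def generate_networks(scenario: SyntheticScenario) -> MultiLayerNetwork:
    """Multi-layer network with planted high-probability diffusion routes.

    Planted route edges carry interaction probability >= 0.95 (the first hop
    on the lncRNA–protein layer, subsequent hops on the PPI layer); decoy
    lncRNA–protein edges draw probabilities in [0.3, 0.94].
    """
    rng = np.random.default_rng([scenario.seed, 1])
    genes = [gene_id(i) for i in range(scenario.n_genes)]
    lncs = [lnc_id(i) for i in range(scenario.n_lncrnas)]
    n_mets = max(3, scenario.n_pathways // 2)
    mets = [f"met{i:02d}" for i in range(n_mets)]

    kinds = {g: "gene" for g in genes}
    kinds |= {l: "lncRNA" for l in lncs}
    kinds |= {m: "metabolite" for m in mets}

    rows: list[tuple] = []
    # planted routes are dedicated corridors: random edges avoid their genes
    # so the high-probability path is the only strong conduit from each seed
    route_genes = {n for r in scenario.planted_routes for n in r[1:]}

    def add(s, t, layer, sign=np.nan, prob=np.nan, directed=False):
        rows.append((s, t, layer, sign, prob, directed))

    # planted routes first: lncRNA->first gene on the lncrna_protein layer,
    # gene->gene hops on the ppi layer, all with probability >= 0.95
    route_first_targets: dict[str, str] = {}
    for route in scenario.planted_routes:
        seed, rest = route[0], route[1:]
        add(seed, rest[0], "lncrna_protein", prob=float(rng.uniform(0.95, 0.995)))
        route_first_targets[seed] = rest[0]
        for a, b in zip(rest, rest[1:]):
            add(a, b, "ppi", prob=float(rng.uniform(0.95, 0.995)))

    # ppi: within-pathway chain plus random cross edges
    for members in scenario.pathway_members().values():
        for a, b in zip(members, members[1:]):
            add(a, b, "ppi")
    n_cross = 2 * scenario.n_genes
    src = rng.integers(0, scenario.n_genes, n_cross)
    dst = rng.integers(0, scenario.n_genes, n_cross)
    for i, j in zip(src, dst):
        a, b = gene_id(i), gene_id(j)
        if i != j and a not in route_genes and b not in route_genes:
            add(a, b, "ppi")

    # grn: random directed signed edges
    src = rng.integers(0, scenario.n_genes, scenario.n_genes)
    dst = rng.integers(0, scenario.n_genes, scenario.n_genes)
    signs = rng.choice([1, -1], scenario.n_genes)
    for i, j, sg in zip(src, dst, signs):
        a, b = gene_id(i), gene_id(j)
        if i != j and a not in route_genes and b not in route_genes:
            add(a, b, "grn", sign=int(sg), directed=True)

    # metabolic: each metabolite touches two random genes
    for m in mets:
        for j in rng.choice(scenario.n_genes, 2, replace=False):
            g = gene_id(j)
            if g not in route_genes:
                add(m, g, "metabolic")

    # lncrna_protein decoys: ~avg_targets_per_lncrna targets each, prob < 0.95
    for l in lncs:
        k = scenario.avg_targets_per_lncrna - (1 if l in route_first_targets else 0)
        targets = rng.choice(scenario.n_genes, size=min(k, scenario.n_genes), replace=False)
        for j in targets:
            g = gene_id(j)
            if route_first_targets.get(l) == g:
                continue
            add(l, g, "lncrna_protein", prob=float(rng.uniform(0.3, 0.94)))

    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return merge_layers([edges], node_kinds=kinds)


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

def generate_de_table(expression: ExpressionSeries, truth: GroundTruth,
                      padj_de: float = 0.001, padj_ns: float = 0.5) -> DETable:
    """DE table from planted labels; log2FC is treatment mean minus control mean."""
    missing = set(truth.de_status) - set(expression.features)
    extra = set(expression.features) - set(truth.de_status)
    if missing or extra:
        raise ValueError(f"expression/ground-truth id mismatch: "
                         f"missing={sorted(missing)[:3]} extra={sorted(extra)[:3]}")
    lfc = expression.condition_means("treatment") - expression.condition_means("control")
    rows = []
    for f in expression.features:
        status = truth.de_status[f]
        rows.append((f, float(lfc[f]), padj_ns if status == "ns" else padj_de, status))
    return DETable(pd.DataFrame(rows, columns=["id", "log2FC", "padj", "status"]))


# ---------------------------------------------------------------------------
# Bundles and serialization
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Multi-strain cohort with a planted synergy-tolerance relationship."""

    tolerance: "object"                      # ToleranceTable
    top_lncrnas: dict[str, list[str]]        # strain -> ranked lncRNA ids
    subnetworks: dict[str, dict[str, set[str]]]  # strain -> lncRNA -> proteins
    membership: dict[str, str]               # protein -> system label
    planted_connecting: dict[str, int]       # strain -> lncRNAs spanning >=2 systems


def generate_tolerance_cohort(n_strains: int = 12, n_top: int = 30,
                              seed: int = 0,
                              systems: tuple[str, ...] = ("SG", "PSG", "PDNR"),
                              ) -> SyntheticCohort:
    """Cohort of strains whose synergistic-lncRNA share falls with tolerance.

    Each strain gets a maximum tolerated EtOH concentration (evenly spread
    over 14-36% v/v) and ``n_top`` relevant lncRNAs; the planted fraction of
    lncRNAs whose subnetwork proteins span two distinct storage systems
    decreases linearly with tolerance (from ~0.8 in the least tolerant
    strain to ~0.1 in the most tolerant), with small seeded jitter.
    """
    from .io import ToleranceTable  # local import to avoid a cycle at module load

    rng = np.random.default_rng([seed, 2])
    strains = [f"strain_{i + 1:02d}" for i in range(n_strains)]
    tolerances = np.round(np.linspace(14.0, 36.0, n_strains), 1)
    membership = {f"{sys}_p{j}": sys for sys in systems for j in range(10)}
    proteins = {sys: [p for p, s in membership.items() if s == sys] for sys in systems}

    top, subnets, planted = {}, {}, {}
    for strain, tol in zip(strains, tolerances):
        frac = 0.8 - 0.7 * (tol - tolerances.min()) / (tolerances.max() - tolerances.min())
        frac += float(rng.uniform(-0.05, 0.05))
        k = int(round(np.clip(frac, 0.0, 1.0) * n_top))
        lncs = [f"{strain}:lnc{i:02d}" for i in range(n_top)]
        sub = {}
        for i, lnc in enumerate(lncs):
            if i < k:  # spans two distinct systems of the category
                a, b = rng.choice(len(systems), 2, replace=False)
                sub[lnc] = {str(rng.choice(proteins[systems[a]])),
                            str(rng.choice(proteins[systems[b]]))}
            else:      # touches at most one system
                sys_ = systems[int(rng.integers(len(systems)))]
                sub[lnc] = {str(rng.choice(proteins[sys_]))}
        top[strain] = lncs
        subnets[strain] = sub
        planted[strain] = k
    tol_table = ToleranceTable(pd.DataFrame({"strain": strains, "tolerance": tolerances}))
    return SyntheticCohort(tol_table, top, subnets, membership, planted)


@dataclass
class SyntheticStudy:
    scenario: SyntheticScenario
    expression: ExpressionSeries
    truth: GroundTruth
    network: MultiLayerNetwork
    de: DETable

    @property
    def pathways(self) -> dict[str, set[str]]:
        return {p: set(m) for p, m in self.truth.pathway_members.items()}


def generate_study(scenario: SyntheticScenario) -> SyntheticStudy:
    expression, truth = generate_expression(scenario)
    network = generate_networks(scenario)
    de = generate_de_table(expression, truth)
    return SyntheticStudy(scenario, expression, truth, network, de)


def write_study(study: SyntheticStudy, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(study.expression, outdir / "expression.tsv")
    write_de(study.de, outdir / "de.tsv")
    write_edges(study.network, outdir / "edges.tsv")
    write_gmt(study.pathways, outdir / "pathways.gmt")
    study.truth.to_json(outdir / "ground_truth.json")
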