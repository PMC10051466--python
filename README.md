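# stressnet

Multi-layer network analysis of ethanol-stress tolerance in budding yeast.

Yeast strains differ widely in the maximum ethanol concentration they
survive, and part of that difference is systemic: under stress the
interaction network rewires, long noncoding RNAs (lncRNAs) act on proteins
in a strain-specific way, and a few mediator genes carry signaling between
life-essential pathways. `stressnet` implements the computational side of
that analysis as a reusable, tested pipeline for anyone studying
stress-response network biology in yeast (or any organism with comparable
data): multi-omics network assembly, diffusion-based lncRNA function
analysis, pathway-integrated time-course profiling, in-silico knockouts,
and tolerance phenotyping — together with a synthetic-data generator that
plants known structure so every stage can be validated end to end.

## What it computes

- **Phenotype partition.** Strains are split into higher- (HT) and
  lower-tolerant (LT) phenotypes by a median split of their maximum
  tolerated EtOH concentration (% v/v): HT iff tolerance > median.
- **Network assembly.** Protein–protein, signed gene-regulatory, metabolic
  and probabilistic lncRNA–protein layers are unified into one typed graph;
  lncRNA–protein edges are kept only at interaction probability ≥ 0.95.
  Control/treatment condition networks retain a node iff its mean log2
  expression under that condition exceeds a floor.
- **Rewiring statistics.** Diameter, characteristic path length,
  betweenness, density, transitivity, edge count and eigenvector centrality
  per condition network, signed treatment−control deltas, hub loss, and a
  paired sign test across strains.
- **Heat diffusion / lncRNA propagation.** Signal spread is the Laplacian
  heat kernel h(τ) = exp(−τL)·h₀ with L = D − W; total heat is conserved.
  Seeding at a differentially expressed lncRNA, the *relevant route* is the
  connected high-heat subgraph through the seed, and the propagation
  subnetwork keeps the seed's DE-concordant interactors on or adjacent to
  that route (plus route lncRNAs). Guilt-by-association then summarizes the
  target proteins' annotation terms per lncRNA.
- **Pathway-integrated network (PINET).** Pathways and genes are modeled
  jointly; time courses are clustered by seeded k-medoids with Pearson
  distance; each pathway's aggregated z-scored profile is classified as
  activation ("up and stable": Δ₁ > ε, later |Δ| ≤ ε), deactivation,
  stable, or other; pathway-to-pathway flow is measured by diffusion from
  member genes, and mediator genes (the CTA1/SUI2-type bridges) are ranked
  by heat along shortest inter-pathway paths.
- **Regulatory ODE knockouts.** A signed linear kinetic model
  dxᵢ/dt = βᵢ + Σⱼ sⱼᵢ wⱼᵢ xⱼ − δᵢ xᵢ (x ≥ 0) is fitted by gradient
  matching (NNLS per node) and integrated with fixed-step RK4; a virtual
  deletion clamps a node to zero, e.g. knocking out either of two
  repressors of a target raises its steady state — the stronger more.
- **Synergy analysis.** The percentage of the top-N heat-ranked lncRNAs
  whose subnetworks span ≥ 2 synergistic storage or degradation systems
  (SG/PSG/PDNR, PB/proteasome/PPPR) is related to strain tolerance by
  Spearman rank correlation.

## Worked example

```python
import numpy as np
import stressnet as sn

# phenotype partition of the bundled strain tolerance table
part = sn.partition_phenotypes(sn.bundled_tolerance_table())
print("HT:", part.strains("HT"))
print("LT:", part.strains("LT"))

# a synthetic study with planted structure, filtered and propagated
study = sn.generate_study(sn.SyntheticScenario(seed=1))
net = sn.filter_lncrna_edges(study.network, 0.95)
sub = sn.propagation_subnetwork(net, study.de, "lnc00")
print("route nodes:", sorted(sub.route_nodes)[:5], "...")

# pathway activation profiles under treatment
profs = sn.pathway_profiles(study.expression, study.pathways)
for p in sorted(profs):
    print(p, profs[p].label)

# virtual knockout of the strong repressor in a two-repressor motif
from stressnet.ode import simulate, two_repressor_motif, virtual_knockout
motif = two_repressor_motif()
x0 = {"target": 0.0, "rep_strong": 1.0, "rep_weak": 1.0}
grid = np.linspace(0, 15, 31)
wt = simulate(motif, x0, grid)["target"].iloc[-1]
ko = virtual_knockout(motif, ["rep_strong"], x0, grid)
print(f"target steady state: WT {wt:.3f} -> strong-repressor KO "
      f"{ko.mutant['target'].iloc[-1]:.3f}")
```

prints

```
HT: ['BMA64-1A', 'BY4742', 'X2180-1A']
LT: ['BY4741', 'S288C', 'SEY6210']
route nodes: ['g000', 'g001', 'g002', 'g003', 'g004'] ...
pathway_01 activation
pathway_02 deactivation
pathway_03 stable
pathway_04 activation
pathway_05 deactivation
pathway_06 other
target steady state: WT 0.700 -> strong-repressor KO 1.700
```

The partition splits the six strains 3/3 at the median tolerance; the
propagation subnetwork contains the planted diffusion route seeded at
`lnc00`; five of six planted pathway profiles are recovered despite the
default replicate noise (the sixth, a flat profile, lands in "other");
and deleting the strong repressor raises the target's steady state from
0.70 to 1.70, exactly the basal/decay ratio minus the remaining weak
repression.

A command-line interface mirrors the library:
`stressnet simulate | assemble | condition-net | topology | diffuse |
propagate | pinet | ode-fit | knockout | classify`, e.g.

```sh
stressnet simulate --seed 1 --out study/
stressnet classify
```

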