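# Methods

This note documents the models and procedures implemented in `stressnet`,
the defaults they use, the design choices that were genuinely open, and
what the synthetic-data validation does and does not establish.

## Data model

Expression is handled throughout on the log2 scale as an `ExpressionSeries`
(features × samples, each sample annotated with condition ∈
{control, treatment}, time in hours and replicate index). Differential
expression is an input, not something the package computes: a `DETable`
carries id, log2FC, adjusted p and a status in {up, down, ns}, with status
forced to `ns` wherever padj exceeds the significance level (default
α = 0.05). Strain tolerances are percent EtOH v/v in (0, 100].

Interactions form a `MultiLayerNetwork` with typed nodes (gene, protein,
lncRNA, metabolite, pathway) and typed edges: undirected `ppi` and
`metabolic`, directed signed `grn` (+1 activation / −1 repression,
mandatory), probabilistic `lncrna_protein` (probability mandatory), and
`pathway_membership`. Merging layers collapses duplicate
(source, target, layer) triples keeping the maximum probability; undirected
duplicates collapse regardless of orientation. Proteins inherit the
expression of their encoding gene (1:1 id mapping).

## Input-level filters

**lncRNA candidates.** A transcript passes iff length ≥ 200 nt, longest
ORF < 100 codons, and mean expression below the coding-gene median. The
length and ORF cutoffs are the common lncRNA conventions; both are
parameters. ORFs are detected as the longest ATG→stop frame on either
strand under the standard genetic code (an ORF requires an in-frame stop).

**Phenotype-specific metabolites.** A metabolite is phenotype-specific iff
it is differentially abundant *in the same direction* in at least two
strains of that phenotype. Requiring direction agreement prevents a
metabolite that goes up in one strain and down in another from counting as
a consistent phenotype marker.

**lncRNA–protein probability filter.** Edges with interaction
probability < 0.95 are dropped; the cut is inclusive (0.95 survives),
idempotent and monotone in the threshold.

## Condition networks

How expression defines the treated network was an open design point; the
package uses expression-floor node retention: a gene/protein/lncRNA node is
retained iff its mean log2 expression under the condition exceeds a floor
(default: the 5th percentile of all condition means, which is scale-free in
the input units). Only node removal is implemented — edges are never
reweighted — because it is the simplest scheme in which a stressed network
can lose hubs. Nodes with no expression mapping (metabolites, pathways) are
retained unchanged.

## Topology

Metrics per condition network: diameter and mean shortest path length on
the largest connected component (disconnected graphs are legal; the
component count is reported alongside), mean normalized betweenness,
density, transitivity, edge count, and the mean of the adjacency matrix's
leading eigenvector (unit 2-norm, computed by dense symmetric
eigendecomposition — exact and deterministic at these sizes). The
treatment−control comparison reports signed deltas per metric and flags the
stress-rewiring pattern (diameter/path length/betweenness up;
density/transitivity/edges/eigenvector down) only when *every* metric moves
the expected way. Hubs are the top decile of control-network degree (ties
at the boundary all included); hub loss counts hubs absent from the
treatment network. Across strains, a two-sided paired sign test per metric
summarizes direction consistency; the sign test was chosen because it makes
no distributional assumption about metric deltas of differently sized
graphs.

## Heat diffusion and lncRNA propagation

Diffusion uses the combinatorial Laplacian L = D − W of the undirected view
of the network (unit edge weights by default; optionally
probability-weighted) and the exact kernel h(τ) = exp(−τL)·h₀ via symmetric
eigendecomposition, with h₀ the indicator of the seed set. Symmetry of L
gives exact heat conservation and nonnegativity (clamped at −0 numerically);
the test suite checks the kernel against a 40-term Taylor series to 1e−8,
conservation to 1e−9, and the semigroup property. Default τ = 0.1, the
convention of diffusion-based prioritization tools; there is no single
correct value, and τ is exposed everywhere.

Route extraction takes the non-seed nodes whose heat reaches a quantile of
the non-seed heat distribution (default 0.9 — quantiles are scale-free,
unlike absolute heat cutoffs) and returns the connected components of
seeds ∪ hot set that contain a seed.

The propagation subnetwork for a differentially expressed seed lncRNA:
(1) candidates are the seed's lncRNA-layer interactors with the seed's DE
status; (2) the relevant route is extracted from seed-anchored diffusion;
(3) candidates are kept iff they are route nodes or adjacent to a non-seed
route node, and lncRNAs on the route are retained. "Surrounding" must
exclude the seed's own adjacency: every candidate is by definition adjacent
to the seed, so including the seed in the adjacency test would make rule (3)
vacuous; excluding it reproduces the intended behavior in which interactors
far from the route drop out. Up- and downregulated seeds can be diffused on
the same graph or on per-condition networks; both are supported (the caller
chooses the network).

Guilt-by-association summarizes annotation-term frequencies over each
lncRNA's target proteins; unannotated proteins count as "unknown",
target-less lncRNAs are "unassigned", and term groupings (e.g. four broad
functional categories) are arbitrary, supplied by the caller.

## Pathway-integrated network

Pathways and their member genes are nodes; membership edges plus inherited
gene–gene edges connect them, so pathways communicate only through shared
genes or gene-level interactions. Time-course clustering is a seeded
k-medoids (PAM-style alternation, several seeded restarts keeping the best
total cost) on z-scored treatment profiles with Pearson distance; constant
profiles are defined as distance 0 to each other and 1 to everything else,
so flat genes form their own cluster. A dedicated time-course network
clustering tool fills this role in interactive analyses; k-medoids
reproduces its function here — merging network genes with profile clusters —
in a fully seeded, dependency-free form.

Profile classification works on consecutive deltas dᵢ of the aggregated
z-scored pathway profile with threshold ε (default 0.25 on z-scores):
activation iff d₁ > ε and all later |dᵢ| ≤ ε ("up and stable");
deactivation is the mirror image; stable iff all |dᵢ| ≤ ε; anything else is
"other" — a fourth class added because the three named classes are not
exhaustive. The rule is shift-invariant and negation-equivariant by
construction.

Pathway-to-pathway flow diffuses from each source pathway's member genes
and scores a target pathway by the mean heat over its exclusive members
(members shared with the source would trivially self-report) normalized by
the seeded heat mass; weights below 1e−12 are treated as zero (disconnected
pathways). The reporting threshold defaults to the 75th percentile of
nonzero weights. Mediator genes between a pathway pair are the interior
nodes of shortest paths between the member sets (paths capped at 6 edges
for tractability), ranked by source-seeded heat with lexicographic
tie-breaks.

## Regulatory ODE and virtual knockouts

The kinetic model is linear with signs fixed by curation:

    dx_i/dt = β_i + Σ_j s_ji · w_ji · x_j − δ_i · x_i,   x_i ≥ 0

with β_i ≥ 0 (basal production), δ_i > 0 (first-order decay), w_ji ≥ 0 and
s_ji ∈ {+1, −1}. This is the minimal signed form supporting virtual
deletion experiments; with all weights zero each node relaxes to β/δ. A
Hill-type variant could be substituted behind the same interface, but the
qualitative knockout contracts tested here (removing a repressor raises its
target; the stronger of two repressors raises it more) hold for any
monotone kinetics, so the linear form is preferred as the identifiable one
at 3–4 observed time points.

Fitting is gradient matching: derivatives by second-order finite
differences (np.gradient on the, possibly non-uniform, time grid), then a
per-node nonnegativity-constrained least squares (NNLS) of dxᵢ/dt on
[1, sⱼᵢ·xⱼ…, −xᵢ]. Boundary derivative estimates are only first-order, so
when ≥ 5 time points are available the regression uses interior points
only; on a noiseless 17-point trajectory over 4 h this recovers all
parameters within ~3% relative error. Gradient matching is deterministic
and adequate for short time courses; it is *not* a substitute for
trajectory-fitting when data are noisy — a documented limitation. A
constant data matrix is a singular design and is rejected.

Simulation is fixed-step RK4 (default dt = 0.01 h) with post-step clamping
at zero; halving the step changes trajectories by < 1e−6 on the test
fixtures. A knockout clamps the deleted nodes to exactly zero throughout
(deletion-strain semantics), and the result reports wild-type and mutant
trajectories plus steady-state deltas. The fitted model follows the
statsmodels convention: `RegulatoryODE(timecourse, edges).fit()` returns a
results object with `params`, per-node residual norms, `summary()`, and
`simulate()`/`knockout()` methods.

## Phenotype partition and synergy

The tolerance partition is a median split: HT iff tolerance > median
(midpoint of the middle order statistics for even n). Among simple
unsupervised rules this is the one that reproduces both the six-strain 3/3
assignment and the assignment of the two additional strains (26% → HT,
20% → LT); exact 1-d 2-means on the same six values instead puts the
variance-optimal cut between 24 and 26 (a 2/4 split), so 2-means is offered
only as a pluggable alternative, not the default. The split is invariant to
strain order and to positive affine rescaling, and every HT tolerance
exceeds every LT tolerance by construction.

LncRNA relevance is the total heat delivered outside the seed set
(rank ties broken lexicographically); the top N = 30 are examined. A
lncRNA "connects" a synergistic category (storage = {SG, PSG, PDNR},
degradation = {PB, proteasome, PPPR}) iff its subnetwork proteins hit at
least two distinct systems of that category. The per-strain percentage of
connecting lncRNAs is related to maximum tolerated EtOH by Spearman rank
correlation — tolerance is ordinal by design — with constant inputs
reported as undefined rather than zero.

## Synthetic data: what it emulates and what it does not

The generator emulates one strain's study: log2 expression for 120 coding
genes and 15 lncRNAs under control/treatment at t = 0, 1, 2, 4 h, three
replicates per condition (replicate count is a convention; the time course
design fixes 0–4 h), Gaussian replicate noise (default sd 0.25 log2 units),
six pathways cycling through planted activation/deactivation/stable
profiles with a log2 step of 2.0 after t = 0, ten genes silenced under
treatment, coding baselines uniform on [7, 10] and lncRNA baselines on
[2, 5] (lncRNAs are expressed below coding genes), and a multi-layer
network in which each lncRNA targets ~8 proteins — the scale reported for
yeast lncRNA–protein interactomes. Planted diffusion routes are dedicated
high-probability corridors (route edges ≥ 0.95, decoy lncRNA–protein edges
uniform on [0.3, 0.94], random edges avoid route genes), giving the 0.95
filter and the route extractor unambiguous planted boundaries. DE labels
come from the planted truth with synthesized adjusted p values (0.001 for
up/down, 0.5 for ns): DE calling itself is out of scope. The multi-strain
synergy cohort plants a linearly decreasing fraction of category-spanning
lncRNAs across 12 strains with tolerances spread over 14–36% (twelve
strains keep the permutation null of the rank correlation informative; with
six the null mean |ρ| cannot fall below ~0.36).

Consequences for interpretation: passing the planted-recovery tests shows
the pipeline's rules are implemented correctly and are mutually consistent
at the planted effect sizes; it does **not** show that real stressed-yeast
networks satisfy those effect sizes, that real routes are degree-2
corridors, or that real DE labels are noiseless. Counts (genes, pathways,
strains) are desk-scale by design; all stages are O(n³) in the node count
at worst (dense eigendecompositions) and were sized accordingly.

## Numerical choices

- Heat kernel by `numpy.linalg.eigh` of L (exact for the graph sizes used);
  a truncated-series implementation exists only as a test oracle.
- Heats clamped at ≥ 0 after reconstruction; conservation tolerance 1e−9.
- Quantile thresholds use linear interpolation (`numpy.quantile`).
- k-medoids: 5 seeded restarts, 100 alternation iterations max,
  lowest-index tie-breaks — deterministic under a fixed seed.
- NNLS decay estimates are floored at 1e−12 to keep δ > 0.
- Median of an even strain count is the midpoint of the two middle order
  statistics (`numpy.median`).
- All generator randomness flows through `numpy.random.default_rng` seeded
  from the scenario seed, so outputs are byte-identical under a fixed seed.

## Known limitations

- The treated-network construction (expression-floor node retention) is one
  of several defensible schemes; edge reweighting is not implemented.
- Gradient matching biases ODE parameters when sampling is sparse or noisy;
  use dense time courses or treat fitted weights as qualitative.
- The diffusion graph treats all layers as a single undirected medium;
  regulatory edge direction is ignored during propagation.
- Guilt-by-association inherits every bias of the annotation map; it
  assigns association, not mechanism.
- The synergy analysis depends on the curated system-membership map;
  unknown labels are rejected rather than guessed.
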