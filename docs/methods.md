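# Methods

## The problem

Gene functional similarity networks assign every gene pair a similarity
in [0, 1], usually derived from Gene Ontology (GO) semantic similarity.
Because a similarity can be computed for *every* pair, the raw network
is fully connected, which contradicts the sparse, scale-free topology
of real biological networks and makes downstream use (module detection,
disease-gene prioritisation) unreliable. Global thresholds or k-nearest-
neighbour sparsification discard low similarities indiscriminately, even
though a low similarity between two interacting genes can be meaningful.

This package implements an alternative: prune the fully connected
similarity network against an independent *reference* network derived
from protein-protein interaction (PPI) data, keeping an edge only where
the two lines of evidence agree.

## Pipeline

### 1. Integrated gene functional similarity network (IGFSN)

Inputs are per-method, per-ontology similarity matrices (in the original
study: Resnik, Wang, GIC, SORA, WIS and TopoICSim, each scored under the
CC, MF and BP aspects; here they are consumed as precomputed matrices or
generated synthetically). Both integration steps use the complement
geometric mean

    merged(A, B) = 1 − ( Π_k (1 − s_k(A, B)) )^(1/K),

first over the three ontology aspects (K = 3) and then over the N
methods (K = N, any N ≥ 1). The combinator is symmetric, bounded by the
extreme inputs, monotone in each input, and treats a source at 1 as
absorbing. Products are evaluated in log space with (1 − s) floored at
1e-300 so values near 1 cannot underflow.

**Missing annotation.** When a pair has no similarity under one source,
the default treats that source as s = 0 (a neutral factor, fixed
exponent). The alternative — renormalising the exponent over present
sources — is available via `renormalize_exponent=True`.

### 2. Referenced gene-gene association network (RGAN)

PPI edge lists are unioned over a gene universe (the IGFSN gene list by
default), then each edge (x, y) is reweighted by its edge clustering
coefficient

    ECC(x, y) = z_xy / min(d_x − 1, d_y − 1) ∈ [0, 1],

with z_xy the number of triangles through the edge and ECC defined as 0
when the denominator vanishes. On this weighted graph nine topological
similarity indices are computed for every pair within three hops (all
other pairs score exactly 0): the additive common-neighbour scores WCN,
WRA, WAA; their reliable-route multiplicative variants rWCN, rWRA,
rWAA; and quasi-local variants rWCNLP, rWRALP, rWAALP that add
α · Σ w_xm · w_mn · w_ny over simple length-3 paths x–m–n–y (α = 0.5 by
default; degenerate walks with m = y, n = x or m = n are excluded, and
the Adamic-Adar denominators use the natural log of (1 + s_z), with
zero-strength or log-zero hubs contributing nothing).

**Scale.** The raw index scores are unbounded sums while similarities
live in [0, 1], and the downstream agreement filter compares the two on
one scale. Each index table is therefore divided by its maximum positive
score before the nine tables are combined with equal weights 1/9
(`normalize="max"`, the default; `"none"` and `"rank"` are provided for
sensitivity analysis). Max-normalisation preserves zeros and ratios but
ties the scale to the single highest-scoring pair; as a consequence most
pairs end up well below the typical functional-similarity level, which
makes the agreement filter aggressive (see Limitations).

### 3. Refinement (RGFSN)

    sim_RGFSN(A,B) = sim_IGFSN(A,B)  if |sim_IGFSN − sim_RGAN| < 0.1
                                        and sim_RGAN ≠ 0
                   = 0               otherwise

The inequality is strict and kept values are bit-identical to their
IGFSN values. Pruning strands genes and small components; with
`reconnect=True` (default) each connected component outside the largest
one is re-attached through exactly one IGFSN edge — the
(component gene, giant-component gene) pair with the highest IGFSN
similarity, ties broken lexicographically — so the result is a single
connected network and the process is deterministic. A component with no
positive IGFSN similarity toward the giant component is left stranded
with a warning. Attachment is per stranded *component* (one bridging
edge each); singleton components reduce to per-gene attachment.

### 4. Validation

*Topology summary* follows the Cytoscape NetworkAnalyzer conventions:
mean nodal clustering coefficient (degree < 2 contributes 0);
characteristic path length and shortest-path count over ordered
reachable pairs; centralization (n/(n−2))·(max_degree/(n−1) − density);
heterogeneity = coefficient of variation of the degree sequence. Path
metrics are computed on the largest connected component when the graph
is disconnected (logged); edge weights are ignored.

*Degree-distribution fitting* regresses node count on degree (raw,
unbinned, unweighted points; zero-degree nodes set aside) under four
forms: power law y = a·x^b; exponential y = y0 + A1·exp(x/t1); Gaussian
y = y0 + A/(ω√(π/2))·exp(−2((x−x_c)/ω)²); log-normal
y = y0 + A/(ωx√(2π))·exp(−ln²(x/x_c)/(2ω²)). Fits use
scipy's trust-region least squares with data-driven multi-starts
(log-log regression seeds the power law; method-of-moments seeds the
peaked models; the exponential tries both signs of t1 and two
baselines), tolerance 1e-10, at most 10,000 evaluations, and report
R² = 1 − SS_res/SS_tot with `converged=False` rather than garbage when
no start converges. Models are ranked by R², ties broken toward fewer
parameters. For the Gaussian and log-normal the location x_c is bounded
to the observed degree range and the width ω to positive values: outside
those bounds the peak collapses below the smallest degree and the curve
degenerates into a monotone power-law mimic with no reading as a
distribution peak.

*Complex evaluation* scores a predicted set K against a reference set R
by the Jaccard overlap |K∩R|/|K∪R|; a pair matches at score ≥ 0.25
(configurable, strict `>` available). Complex-level recall is the
matched fraction of the reference catalogue, precision the matched
fraction of the predictions, F their harmonic mean. Complexes with
fewer than two distinct members are dropped at parse time. No gene-
universe restriction is applied by default; an opt-in restriction to
the reference universe exists for sensitivity analysis.

## Synthetic data

`gfsn.fixtures` generates the study inputs so every stage runs offline:

- **PPI graphs** — preferential attachment (default, 3 edges per new
  node, grown from a 4-clique so every node has degree ≥ 3 and the
  degree histogram has no sub-m boundary bins), Erdős–Rényi, or
  Watts–Strogatz small-world; nodes are labelled `g0001`….
- **Method matrices** — each similarity is clamp(base(d) + noise) where
  d is PPI shortest-path distance, base(d) = 0.9·exp(−0.3·(d−1))
  (0.02 for disconnected pairs), and the noise of method m under
  ontology o is σ·(√a·C_o + √(1−a)·E_{m,o}) with shared and private
  standard-normal fields, so `sim_agreement` a ∈ [0,1] controls
  inter-method correlation. Defaults: 200 genes, σ = 0.05, a = 0.8.
- **Planted complexes** — disjoint reference gene sets (20 complexes of
  10 by default) and predictions obtained by swapping a (1 − overlap)
  fraction of members for genes from a disjoint replacement universe;
  overlap 0.8 guarantees every matched pair exceeds Jaccard 0.25.

Each generator draws from its own named stream derived from the single
spec seed (`SeedSequence((seed, tag))`), so outputs are bit-reproducible
and adding a generator never perturbs existing fixtures.

What the fixtures do *not* emulate: real GO DAG topology, annotation
shallowness, method-specific biases (e.g. the compressed ranges some
semantic-similarity methods produce), database-specific PPI noise, or
overlapping complexes. Passing tests therefore demonstrate the
correctness of the operations and the qualitative behaviour of the
pipeline, not performance on real human data.

## Numerical and design choices

- Duplicate PPI edges keep the maximum weight (union semantics across
  databases); self-loops are dropped and counted.
- Similarity input tolerances: asymmetry beyond 1e-9 and values beyond
  1e-9 outside [0, 1] are errors; smaller excursions are symmetrised
  and clamped; diagonals are forced to 1.
- The nine indices are computed for all pairs uniformly; a
  `lp_only_unconnected` switch restricts the length-3 path term to
  non-adjacent pairs for users who want the quasi-local indices only
  as an extension to unconnected genes.
- Writers sort nodes/edges lexicographically and print floats with 17
  significant digits, so write→read round-trips are exact and repeated
  runs are byte-identical; the run manifest's wall-clock timestamp is
  the one intentionally non-reproducible field (its artifact digests
  are reproducible).
- Problem sizes in the shipped tests and the acceptance script (200 and
  2000-node graphs, 20 planted complexes) were chosen so the whole
  pipeline exercises every code path at desk scale.

## Limitations

- With max-normalisation, the topological scores of typical adjacent
  pairs sit far below the ~0.9 functional-similarity baseline the
  generator assigns them, so the agreement window |Δ| < 0.1 is hit
  rarely and the refined network before repair is very sparse (the
  measured keep rate on the default fixture is 2/594 adjacent pairs;
  the original study similarly kept ~41.6k of ~38M candidate pairs and
  relied on the reconnection step). The appropriate common scale for
  the two networks is genuinely open; `normalize="rank"`/`"none"` let
  users explore alternatives.
- Reproducing the published network-level tables requires the external
  GO/GOA corpora, the four PPI databases and the six similarity tools;
  those are inputs, not part of this package.
- Legacy binary `.xls` catalogues are not readable; convert to `.xlsx`
  or TSV.
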