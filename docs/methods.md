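# Methods

## Problem setting

Each subject is represented by three symmetric weighted networks over a
common anatomical parcellation of N regions (default N = 76): a
gray-matter morphological similarity network (GM), an FA-weighted
structural connectome (DTI), and a resting-state functional correlation
network (FMRI).  GM and DTI entries live in [0, 1]; functional entries
are signed correlations in [-1, 1] until the absolute-value transform is
applied.  The package turns these networks into fixed-length feature
vectors — by persistent homology (Betti curves) or by node-level graph
metrics — and benchmarks how well the resulting representations separate
a patient group (PwMS) from healthy volunteers (HV) under repeated
cross-validation.  Because clinical matrices of this kind are generally
not redistributable, a synthetic generator reproduces the statistical
structure the pipeline relies on, and all acceptance checks run on
generated data.

## Preprocessing

Order of operations: absolute value of functional correlations, then
edge-wise covariate residualization, then (for homology only) edge
inversion.

*Residualization.*  For each modality and each edge independently,
ordinary least squares of edge weight on [intercept, age, sex(0/1)]
across subjects; each value is replaced by its residual plus the edge's
cross-subject mean.  The design matrix is applied through a
pseudoinverse-based projection, so rank-deficient designs (constant age
or sex) degrade gracefully to exact pass-through rather than erroring.
Residuals may leave [0, 1]; they are clamped with a logged count rather
than rescaled.  Absent clamping, the operation is idempotent to 1e-9 and
leaves in-sample edge–age correlations at numerical zero.  Whether
residualization should precede or follow the absolute-value transform is
genuinely open; this package fixes abs-first as its declared order.

*Inversion.*  ê = 1 − e maps connection strength to dissimilarity so
that tightly connected regions coalesce early in a filtration.  A
`space` flag (`raw`/`inverted`) prevents accidental double inversion.
Graph metrics always consume raw weights; only homology consumes
inverted ones.

*Supra-adjacency.*  The multilayer representation is the 2N × 2N block
matrix [[GM, DTI], [DTIᵀ, FMRI]]: morphology and function as intralayer
blocks, structural connectivity as interlayer links.  The coupling
between a region's two replicas defaults to the stored DTI diagonal
(zero), overridable by a constant `replica_coupling` in (0, 1] — the
literature does not fix one convention, so this one is explicit and
logged.

## Persistent homology

The filtration is the flag (clique) filtration of the inverted matrix:
vertices at 0, edge (i, j) at ê_ij, and each higher clique at the
maximum of its edge values, enumerated up to dimension
`max_hom_dim + 1 ≤ 3`.  Zero raw edges invert to exactly 1, so on dense
matrices the complex at threshold 1 is always the full simplex; absent
edges simply enter last.

Homology is over GF(2).  Dimension-0 pairs come from elder-rule
union-find on the edge sequence.  Dimensions 1 and 2 are reduced on the
anti-transposed (coboundary) matrix, columns in decreasing filtration
order, with clearing: the death simplices discovered in dimension d − 1
are skipped as columns in dimension d.  For flag filtrations this
orientation does the work where it is cheap — almost every processed
column terminates at a fresh pivot instead of reducing to zero — which
is what lets a dense 76-node subject with dimensions {0, 1, 2}
(~1.35 M simplices) finish in well under the declared 120 s envelope
(measured ≈ 16 s on one CPU).  The pairing of persistent cohomology is
canonically identical to that of standard boundary reduction, and the
package asserts this empirically against an independent brute-force
oracle that computes β_k = n_k − rank ∂_k − rank ∂_{k+1} by Gaussian
elimination at fixed thresholds.

Conventions: intervals are half-open [b, d); zero-persistence pairs are
dropped; ties in filtration value break by (dimension, lexicographic
vertex tuple), which diagrams are invariant to; infinite dimension-0
bars are retained, so β₀ at threshold 1 equals the number of components
of the final complex (1 for dense matrices).  The Betti curve samples
β_k on `grid_size` (default 100) equally spaced thresholds in [0, 1],
counting intervals with birth ≤ t < death.

The 2N-node supra complex grows as C(2N, 4) in dimension 2; a
`supra_dim_cap` config (default 1 in the workflow) caps multilayer
homology at dimensions {0, 1} with a logged notice.  The cap is a
computational choice, exposed, not hidden.

## Graph metrics

Degree (edge count above a threshold, default 0 — degenerate on fully
dense matrices, hence the exposed threshold), strength (row sums), local
efficiency (mean inverse shortest-path length inside each node's
neighborhood subgraph), betweenness (exact path counting, normalized by
(N−1)(N−2)/2), and component-scaled closeness.  Path metrics use edge
length 1/weight (configurable to 1 − weight); the field has no single
convention and 1/w is the most common in connectomics toolkits.
Betweenness and closeness are delegated to networkx and cross-checked in
tests against exhaustive simple-path enumeration on all graphs up to 7
nodes.  Multilayer variants evaluate the single-layer metric on the
supra graph and average each region's two replica values — a declared
supra-graph convention, flagged in logs, not a reimplementation of
layer-aware centralities.

## Feature assembly and reduction

Betti features: `grid_size × |dims|` columns per network (so 300 for
dims {0, 1, 2} at the default grid, 900 for the three-layer
concatenation).  Metric features: N columns per (network, metric), 5N
for all five (380 at N = 76).  Every column carries a provenance string
(layer | feature | index), asserted unique.

PCA (20 components) and random-forest importance selection (100 trees,
Gini, top 100 columns, ties by column index) are fitted on training rows
only.  Inside the benchmark they are re-fitted per cross-validation fold
— the defensible default where the original protocol is silent on
leakage control.  Standardization (per-column z-scoring, fitted per
training fold) precedes the NN/LR/SVM fits but not RF: Betti counts and
centralities live on very different scales and tree ensembles are
scale-invariant anyway.

## Benchmark

Four fixed (untuned) families: a (200, 100, 10) ReLU multilayer
perceptron (adam, max 500 epochs, early stopping on a 20% validation
split of the training folds — the architecture is fixed but no training
schedule is prescribed, so a bounded-budget schedule is declared here);
L2-penalized logistic regression; a 100-tree random forest; an RBF SVM
with scale-heuristic gamma and C = 1.0.  Stratified 4-fold CV repeated
10 times, fold assignment re-randomized each repeat from a master seed;
"repeated with random initializations of the subjects within each fold"
is read as re-randomized fold assignment.  AUC-ROC is computed from
continuous scores per held-out fold by an in-package ROC sweep
(trapezoidal area; verified to equal the Mann–Whitney statistic and an
independent library implementation to 1e-9).  Summaries report mean ±
population std over the 10 repeat-level means and flag cross-family
averages ≥ 0.70.

## Synthetic generator

Defaults define the study conditions: raw DTI ~ truncated normal(0.40,
0.10) on [0, 1] (inverted mass concentrated in 0.4–0.8), raw GM ~
truncated normal(0.60, 0.05) (inverted mass in 0.3–0.5), functional
magnitudes ~ Beta(1.2, 4.0) with random signs (inverted values spread
over [0, 1], skewed high).  Ages ~ U(25, 60) around a reference age of
42; sex ~ Bernoulli(0.6 female).  Covariate slopes (default 0.002/yr
age, 0.02 male offset) shift every edge linearly before clamping.  The
group effect subtracts `delta` from a seed-determined subset of target-
modality edges in patients only; the subset is fixed per cohort, not per
subject, so the affected subnetwork is consistent and learnable —
mirroring the premise that disease alters consistent pathways.  Each
subject draws from its own spawned RNG stream, so draws are independent
of cohort composition and fully reproducible under the seed.

What the generator does **not** emulate: lesion geometry, tractography
bias, realistic fMRI autocorrelation, inter-modality edge coupling, or
site effects.  Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it assumes (distributions, linear
covariates, a localized group effect) — not that it would achieve any
particular performance on clinical data.

## Validation experiments (all synthetic, all seeded)

* Dual-route homology: reduction-based Betti curves equal the GF(2) rank
  oracle at all 100 grid points, dimensions 0–2, on 50 random networks
  with 5–10 nodes; Euler characteristic and component-count identities
  hold at every threshold on 20 further instances.
* Path-metric duality: betweenness/closeness equal exhaustive
  enumeration on 50 random graphs with up to 7 nodes.
* Residualization recovery: an injected 0.004/yr age slope leaves
  maximum per-edge |corr(weight, age)| below 0.05 across 200 subjects.
* Effect localization: with a DTI-targeted delta of 0.15 on 30% of edges
  (30+30 subjects, 40 regions, Betti dims {0, 1}), structural and
  multilayer representations beat the functional-only representation by
  well over 0.15 grand-mean AUC, while a zero-delta cohort keeps every
  representation within 0.1 of chance.
* Harness null: label permutation on a signal-free 100-subject cohort
  keeps every family's grand-mean AUC within 0.08 of 0.5 over the 40
  (repeat, fold) cells.

Problem sizes in these experiments (40 regions for the ordering study,
20 for the nulls, 5–10 nodes for the oracles) are the package's own
validation choices: small enough to run routinely, large enough that
each property is non-trivial.

## Known limitations

* The supra-graph multilayer metrics are a convention, not the
  layer-aware centralities of the multilayer-network literature.
* Dimension-2 homology of the 152-node supra complex is feasible but
  expensive; the workflow caps it at dimension 1 by default.
* Degree on fully dense matrices is uninformative at threshold 0.
* The generator's group effect is additive and edge-local; interaction
  or topology-preserving effects are out of scope.
* A single label permutation on a small cohort retains chance
  association with the features; the harness null is therefore evaluated
  at 100 subjects, where that variance is small.
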