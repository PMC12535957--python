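# topoconnectome

Topological and graph-theoretical featurization of multimodal brain
networks, with a synthetic cohort generator and a repeated
cross-validation benchmark.

## What this is for

Multimodal MRI yields, per subject, several weighted networks over a
common anatomical parcellation: a gray-matter morphological similarity
network (GM), an FA-weighted structural connectome (DTI), and a
resting-state functional correlation network (fMRI).  A recurring
question in network neuroscience is which *representation* of these
networks — a single modality, a concatenation, or a genuinely multilayer
graph — and which *featurization* — topological summaries or classical
node centralities — best exposes disease-related alterations (the
motivating case is multiple sclerosis vs healthy volunteers) to a
supervised classifier.

This package implements the whole chain as a tested library:

1. **netio** — validated network/subject/cohort containers, delimited
   matrix files, JSON cohort manifests, results tables.
2. **synthetic** — a cohort generator whose inverted edge-weight
   histograms, covariate effects, and tunable group effect mimic the
   statistical structure of real multimodal cohorts (which are rarely
   redistributable), so everything downstream is testable.
3. **preprocess** — |r| transform for functional matrices, edge-wise
   age/sex residualization (OLS residuals re-centered at the edge mean),
   edge inversion ê = 1 − e, and the 2N-node supra-adjacency assembly
   [[GM, DTI], [DTIᵀ, fMRI]].
4. **homology** — from-scratch persistent homology of weighted-graph
   flag filtrations over GF(2), dimensions 0–2 (components, loops,
   voids): elder-rule union-find plus coboundary reduction with
   clearing, Betti-curve vectorization on a 100-point threshold grid,
   and an independent brute-force rank oracle
   (β_k = n_k − rank ∂_k − rank ∂_{k+1}) used to verify the reduction.
5. **graph_metrics** — degree, strength, local efficiency, betweenness,
   closeness (edge length = 1/weight), plus supra-graph multilayer
   counterparts, with exhaustive-enumeration oracles for the path
   metrics.
6. **features** — per-subject feature tables for every representation
   (e.g. 100 × |dims| Betti columns per layer; 5 × 76 = 380 columns for
   all metrics on a 76-region single layer), PCA-20 reduction and
   random-forest top-100 selection fitted on training rows only.
7. **evaluate** — NN / logistic regression / random forest / RBF-SVM,
   10 × 4-fold stratified CV with re-randomized folds, AUC-ROC from an
   in-package ROC sweep, mean ± std summary tables.
8. **workflow / cli** — `topoconnectome run` reproduces the full
   synthetic benchmark from one YAML config with cached homology.

The core quantity is the Betti curve: for a filtration threshold
t ∈ [0, 1] applied to inverted weights ê = 1 − e, β_k(t) counts the
k-dimensional holes (β₀ components, β₁ loops, β₂ voids) of the flag
complex at t; sampling t on 100 equally spaced values gives a fixed
100·|dims|-length vector per network.

## Worked example

Generate a 30-subject synthetic cohort (20 regions for speed) with a
structural (DTI-targeted) group effect, and benchmark three
representations of the Betti pipeline:

```python
from topoconnectome import (SyntheticConfig, generate_cohort, preprocess_cohort,
                            betti_features, repeated_cv, summarize)
from topoconnectome.synthetic import GroupEffect

cfg = SyntheticConfig(n_hv=15, n_pwms=15, parcellation_size=20, seed=42,
                      group_effect=GroupEffect("DTI", 0.3, 0.15))
cohort = preprocess_cohort(generate_cohort(cfg))

cache = {}
for rep in ("SL-DTI", "SL-FMRI", "multilayer"):
    fm = betti_features(cohort, rep, dims=(0, 1), grid_size=100, cache=cache)
    res = repeated_cv(fm, n_repeats=10, seed=7)
    print(rep)
    print(summarize(res)[["family", "mean", "std", "average", "flag"]].to_string(index=False))
```

Output (abridged):

```
SL-DTI
family     mean      std  average  flag
    LR 0.945312 0.025754 0.902409  True
    RF 0.943490 0.012760 0.902409  True
SL-FMRI
    LR 0.498958 0.064541 0.523958 False
    RF 0.541667 0.056745 0.523958 False
multilayer
    LR 0.710417 0.044573 0.677734 False
    RF 0.829688 0.037489 0.677734 False
```

Each `mean ± std` is over the 10 repeat-level mean AUCs of a 4-fold CV.
The generator placed the group effect on structural edges, and the
benchmark recovers exactly that: the DTI-bearing representations
(single-layer DTI, and the multilayer graph whose interlayer links are
DTI) separate the groups well, while the functional-only representation
stays at chance.  `flag` marks cross-family average AUC ≥ 0.70.

The same run from the shell:

```bash
topoconnectome run --config run.yaml --out results/
```

writes `betti_summary.csv`, `metrics_summary.csv`, per-fold
`cv_records.csv`, and a manifest recording every seed.

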