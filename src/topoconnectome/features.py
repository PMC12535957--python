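"""Per-subject feature assembly for every benchmark configuration.

Representations
---------------
``SL-DTI`` / ``SL-GM`` / ``SL-FMRI``
    one single-layer network per subject;
``concat-SL``
    the three single-layer feature vectors concatenated;
``multilayer``
    features computed on the 2N-node supra-adjacency network.

Two featurizations:

* Betti-curve features: Betti numbers on a uniform filtration grid
  (default 100 points) per homology dimension, concatenated over the
  requested dimension set — grid_size × |dims| columns per network;
* graph-metric features: one value per region per metric — N columns per
  (network, metric), 5N for ``ALL`` metrics (380 for the default
  76-region parcellation).

Dimensionality reduction (PCA to 20 components) and random-forest
importance selection (100 trees, Gini, top 100 columns) are fitted on
training rows only and applied to held-out rows, so they can sit inside
a cross-validation fold without leakage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from .graph_metrics import METRICS, compute_metric, multilayer_metric
from .homology import DEFAULT_GRID_SIZE, betti_curves_for_network
from .netio import Cohort, ValidationError
from .preprocess import absolute_correlations, build_supra_adjacency, invert_weights

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("SL-DTI", "SL-GM", "SL-FMRI", "concat-SL", "multilayer")
_SL_MODALITY = {"SL-DTI": "DTI", "SL-GM": "GM", "SL-FMRI": "FMRI"}


@dataclass
class FeatureMatrix:
    """Subjects × features with per-column provenance strings."""

    subject_ids: list[str]
    labels: list[str]
    X: np.ndarray
    feature_names: list[str]
    config_tag: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValidationError(
                f"feature matrix shape {self.X.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.feature_names)} names"
            )
        if len(self.labels) != len(self.subject_ids):
            raise ValidationError("one label per subject required")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("missing/non-finite feature values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature provenance strings must be unique")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows(self, idx: np.ndarray, tag_suffix: str = "") -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            [self.subject_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            self.X[idx],
            list(self.feature_names),
            self.config_tag + tag_suffix,
        )

    def with_columns(self, X: np.ndarray, names: list[str], tag_suffix: str) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.subject_ids), list(self.labels), X, names, self.config_tag + tag_suffix
        )

    def y(self) -> np.ndarray:
        """Binary target: patient group = 1, healthy volunteers = 0."""
        return np.array([1 if g == "PwMS" else 0 for g in self.labels])


def _subject_curve(subject, layer: str, dims, grid_size, replica_coupling, cache):
    """Betti curve for one subject and one layer (or the supra network),
    memoized across representations via ``cache``."""
    max_dim = max(dims)
    key = (subject.subject_id, layer, max_dim, grid_size, replica_coupling)
    if cache is not None and key in cache:
        return cache[key]
    if layer == "supra":
        nets = dict(subject.networks)
        if nets["FMRI"].weights.min() < 0:
            nets["FMRI"] = absolute_correlations(nets["FMRI"])
        from dataclasses import replace as _replace

        supra = build_supra_adjacency(_replace(subject, networks=nets), replica_coupling)
        net = invert_weights(supra.as_network())
    else:
        net = subject.networks[layer]
        if layer == "FMRI" and net.weights.min() < 0:
            net = absolute_correlations(net)
        net = invert_weights(net)
    curve = betti_curves_for_network(net, dims=tuple(range(max_dim + 1)), grid_size=grid_size)
    if cache is not None:
        cache[key] = curve
    return curve


def betti_features(
    cohort: Cohort,
    representation: str,
    dims: tuple[int, ...] = (0, 1, 2),
    grid_size: int = DEFAULT_GRID_SIZE,
    replica_coupling: float = 0.0,
    cache: dict | None = None,
    supra_dim_cap: int | None = None,
) -> FeatureMatrix:
    """Betti-curve feature table for one representation.

    Single layer: grid_size × |dims| columns; ``concat-SL`` three times
    that; ``multilayer`` computes the curves on the supra-adjacency
    complex.  Inversion (and the absolute-value transform for signed
    functional matrices) is handled internally; pass a residualized
    cohort.  ``cache`` (a plain dict) may be shared across calls to avoid
    recomputing per-subject homology.  ``supra_dim_cap`` optionally caps
    the homology dimension of the 2N-node supra complex (its clique
    enumeration grows steeply with N); the cap is logged.
    """
    dims = tuple(sorted(set(dims)))
    if not dims:
        raise ValidationError("dims must be non-empty")
    if any(d not in (0, 1, 2) for d in dims):
        raise ValidationError("homology dimensions are restricted to {0, 1, 2}")
    if representation not in REPRESENTATIONS:
        raise ValidationError(f"unknown representation {representation!r}")
    if (
        representation == "multilayer"
        and supra_dim_cap is not None
        and max(dims) > supra_dim_cap
    ):
        capped = tuple(d for d in dims if d <= supra_dim_cap)
        logger.warning(
            "multilayer homology capped at dimension %d (requested %s)",
            supra_dim_cap,
            dims,
        )
        dims = capped
    layers = (
        ["GM", "DTI", "FMRI"]
        if representation == "concat-SL"
        else ["supra"]
        if representation == "multilayer"
        else [_SL_MODALITY[representation]]
    )
    names = [
        f"{layer}|betti{d}|t{i:03d}" for layer in layers for d in dims for i in range(grid_size)
    ]
    rows = []
    for subject in cohort.subjects:
        parts = []
        for layer in layers:
            curve = _subject_curve(subject, layer, dims, grid_size, replica_coupling, cache)
            parts.append(curve.vector(dims))
        rows.append(np.concatenate(parts))
    tag = f"{representation}/betti-dims{''.join(map(str, dims))}"
    return FeatureMatrix(
        [s.subject_id for s in cohort.subjects], cohort.groups, np.stack(rows), names, tag
    )


def metric_features(
    cohort: Cohort,
    representation: str,
    metric: str = "ALL",
    replica_coupling: float = 0.0,
    degree_threshold: float = 0.0,
) -> FeatureMatrix:
    """Graph-metric feature table for one representation.

    One metric: N columns per network (so 3N for ``concat-SL``);
    ``ALL``: five metrics concatenated (5N per network).  Multilayer
    metrics are replica-mean aggregated back to length N.
    """
    if representation not in REPRESENTATIONS:
        raise ValidationError(f"unknown representation {representation!r}")
    metrics = list(METRICS) if metric == "ALL" else [metric]
    layers = (
        ["GM", "DTI", "FMRI"]
        if representation == "concat-SL"
        else ["supra"]
        if representation == "multilayer"
        else [_SL_MODALITY[representation]]
    )
    region_labels = cohort.region_labels
    names = [
        f"{layer}|{m}|{lab}" for layer in layers for m in metrics for lab in region_labels
    ]
    rows = []
    for subject in cohort.subjects:
        parts = []
        for layer in layers:
            if layer == "supra":
                nets = dict(subject.networks)
                if nets["FMRI"].weights.min() < 0:
                    nets["FMRI"] = absolute_correlations(nets["FMRI"])
                from dataclasses import replace as _replace

                supra = build_supra_adjacency(_replace(subject, networks=nets), replica_coupling)
                for m in metrics:
                    kwargs = {"edge_threshold": degree_threshold} if m == "degree" else {}
                    parts.append(multilayer_metric(supra, m, aggregate="mean", **kwargs).values)
            else:
                net = subject.networks[layer]
                if layer == "FMRI" and net.weights.min() < 0:
                    net = absolute_correlations(net)
                for m in metrics:
                    kwargs = {"edge_threshold": degree_threshold} if m == "degree" else {}
                    parts.append(compute_metric(net, m, **kwargs).values)
        rows.append(np.concatenate(parts))
    tag = f"{representation}/metric-{metric}"
    return FeatureMatrix(
        [s.subject_id for s in cohort.subjects], cohort.groups, np.stack(rows), names, tag
    )


def pca_reduce(
    train_X: FeatureMatrix, test_X: FeatureMatrix, n_components: int = 20
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Column-centered PCA fitted on training rows only, applied to both.

    If ``n_components`` exceeds what the training data supports it is
    reduced with a warning.  The fitted transform's cumulative
    explained-variance fraction is logged and attached to the tag.
    """
    max_c = min(train_X.X.shape)
    k = n_components
    if k > max_c:
        warnings.warn(f"n_components reduced from {k} to {max_c}")
        k = max_c
    pca = PCA(n_components=k, svd_solver="full")
    tr = pca.fit_transform(train_X.X)
    te = pca.transform(test_X.X)
    evr = float(pca.explained_variance_ratio_.sum())
    logger.info("PCA(%d) on %s: %.1f%% variance", k, train_X.config_tag, 100 * evr)
    names = [f"pc{i:02d}" for i in range(k)]
    return (
        train_X.with_columns(tr, names, f"/pca{k}"),
        test_X.with_columns(te, names, f"/pca{k}"),
    )


def rf_importance_select(
    train_X: FeatureMatrix,
    train_labels,
    test_X: FeatureMatrix,
    n_trees: int = 100,
    top_k: int = 100,
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Keep the top_k columns by Gini impurity importance of a random
    forest fitted on training rows only; ties broken by column index."""
    if top_k > train_X.n_features:
        raise ValidationError(
            f"top_k = {top_k} exceeds {train_X.n_features} available columns"
        )
    y = np.asarray([1 if g == "PwMS" else 0 for g in train_labels])
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    rf.fit(train_X.X, y)
    order = np.argsort(-rf.feature_importances_, kind="stable")[:top_k]
    order = np.sort(order)  # keep original column order for readability
    names = [train_X.feature_names[i] for i in order]
    return (
        train_X.with_columns(train_X.X[:, order], names, f"/rfsel{top_k}"),
        test_X.with_columns(test_X.X[:, order], names, f"/rfsel{top_k}"),
    )
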