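"""Supervised benchmark: four classifier families, repeated stratified
cross-validation, AUC-ROC scoring, and summary tables.

Protocol: stratified 4-fold cross-validation, repeated 10 times with the
fold assignment re-randomized each repeat from a master seed.  Any
fold-level transform (standardization, PCA, importance selection) is
fitted on the training folds only.  Classifiers produce continuous
scores (probabilities or decision values), never hard labels; each
held-out fold yields one AUC.  Summaries report, per configuration and
family, the mean and standard deviation over the 10 repeat-level means
(each repeat-level mean averaging its 4 folds), plus a cross-family
average flagged when it reaches 0.70.

The classifier families are fixed, not tuned:

* NN  -- fully connected net, hidden layers (200, 100, 10), ReLU;
* LR  -- logistic regression with an L2 penalty;
* RF  -- random forest, 100 fully grown trees;
* SVM -- RBF kernel, scale-heuristic gamma, C = 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix, pca_reduce, rf_importance_select
from .netio import ValidationError

logger = logging.getLogger(__name__)

FAMILIES = ("NN", "LR", "RF", "SVM")

#: families whose inputs are z-scored per training fold (tree ensembles
#: are scale-invariant and skip it)
SCALED_FAMILIES = frozenset({"NN", "LR", "SVM"})

AVERAGE_FLAG_THRESHOLD = 0.70


@dataclass
class ClassifierSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")

    def build(self, seed: int):
        hp = self.hyperparameters
        if self.family == "NN":
            return MLPClassifier(
                hidden_layer_sizes=hp.get("hidden_layer_sizes", (200, 100, 10)),
                activation="relu",
                solver="adam",
                max_iter=hp.get("max_iter", 500),
                early_stopping=True,
                validation_fraction=0.2,
                n_iter_no_change=hp.get("n_iter_no_change", 20),
                random_state=seed,
            )
        if self.family == "LR":
            # default penalty is the L2 (ridge) term; C controls its strength
            return LogisticRegression(C=hp.get("C", 1.0), max_iter=5000, random_state=seed)
        if self.family == "RF":
            return RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 100),
                criterion="gini",
                max_depth=None,
                random_state=seed,
                n_jobs=1,
            )
        return SVC(kernel="rbf", gamma="scale", C=hp.get("C", 1.0), random_state=seed)


def default_specs() -> list[ClassifierSpec]:
    return [ClassifierSpec(f) for f in FAMILIES]


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC sweep over all score thresholds.

    Returns an ordered array of (false-positive rate, true-positive rate)
    points from (0, 0) to (1, 1), with tied scores collapsed into single
    steps.  The trapezoidal area under these points is the AUC.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], pos[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep the last index of every tied block
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    pts = np.column_stack([fp[distinct] / n_neg, tp[distinct] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def auc_from_roc(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC from continuous scores (trapezoid over the ROC sweep)."""
    return auc_from_roc(roc_points(scores, labels))


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVRecord:
    repeat: int  # 1-based
    fold: int  # 1-based
    family: str
    configuration: str
    auc: float
    n_test: int


@dataclass
class CVResult:
    records: list[CVRecord]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def grand_mean(self, family: str | None = None, configuration: str | None = None) -> float:
        df = self.to_frame()
        if family is not None:
            df = df[df.family == family]
        if configuration is not None:
            df = df[df.configuration == configuration]
        return float(df.auc.mean())


def _continuous_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def _apply_transform(transform, train_fm, test_fm, seed):
    if transform is None:
        return train_fm, test_fm
    kind = transform[0]
    if kind == "pca":
        return pca_reduce(train_fm, test_fm, n_components=transform[1])
    if kind == "rf_select":
        return rf_importance_select(
            train_fm, train_fm.labels, test_fm, top_k=transform[1], seed=seed
        )
    raise ValidationError(f"unknown fold transform {transform!r}")


def repeated_cv(
    features: FeatureMatrix,
    specs: list[ClassifierSpec] | None = None,
    n_folds: int = 4,
    n_repeats: int = 10,
    seed: int = 0,
    transform: tuple | None = None,
    scale: bool = True,
) -> CVResult:
    """Repeated stratified K-fold benchmark of one feature configuration.

    ``transform`` is an optional per-fold reduction fitted on training
    rows: ``("pca", n_components)`` or ``("rf_select", top_k)``.  All
    randomness (fold shuffles, model initializations) derives from the
    master seed, so identical seeds give identical results.
    """
    specs = specs if specs is not None else default_specs()
    y = features.y()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        raise ValidationError(
            f"need at least {n_folds} subjects per class for {n_folds}-fold "
            f"stratified CV (class counts: {dict(zip(classes.tolist(), counts.tolist()))})"
        )
    master = np.random.SeedSequence(seed)
    records: list[CVRecord] = []
    for rep in range(n_repeats):
        rep_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        for fold, (tr_idx, te_idx) in enumerate(skf.split(features.X, y)):
            if len(np.unique(y[te_idx])) < 2:  # pragma: no cover - stratified
                raise ValidationError("fold with a single class despite stratification")
            fold_seed = (rep_seed + 7919 * fold) % (2**31 - 1)
            train_fm, test_fm = features.rows(tr_idx), features.rows(te_idx)
            train_fm, test_fm = _apply_transform(transform, train_fm, test_fm, fold_seed)
            X_tr, X_te = train_fm.X, test_fm.X
            for spec in specs:
                if scale and spec.family in SCALED_FAMILIES:
                    scaler = StandardScaler().fit(X_tr)
                    Xa, Xb = scaler.transform(X_tr), scaler.transform(X_te)
                else:
                    Xa, Xb = X_tr, X_te
                clf = spec.build(fold_seed)
                clf.fit(Xa, y[tr_idx])
                auc = auc_score(_continuous_scores(clf, Xb), y[te_idx])
                records.append(
                    CVRecord(rep + 1, fold + 1, spec.family, features.config_tag, auc, len(te_idx))
                )
    return CVResult(records, seed)


def summarize(results: CVResult | list[CVResult], architecture_of=None) -> pd.DataFrame:
    """Tidy summary: one row per (configuration, family).

    ``mean``/``std`` are taken over the repeat-level means (each repeat
    averaging its folds; std is the population std, matching the
    mean ± std convention of repeated-CV tables).  Adds the cross-family
    ``average`` per configuration and a boolean ``flag`` for
    average >= 0.70.  ``architecture_of`` optionally maps a configuration
    tag to an architecture name; by default the tag is split on '/'.
    """
    if isinstance(results, CVResult):
        results = [results]
    frames = [r.to_frame() for r in results if r.records]
    if not frames:
        raise ValidationError("no CV records to summarize")
    df = pd.concat(frames, ignore_index=True)
    expected = df.groupby(["configuration", "family"]).size()
    n_rep = df.repeat.max()
    n_fold = df.fold.max()
    if (expected != n_rep * n_fold).any():
        raise ValidationError("incomplete CV records (missing repeat/fold cells)")
    per_repeat = (
        df.groupby(["configuration", "family", "repeat"]).auc.mean().reset_index()
    )
    rows = []
    for (cfg, fam), grp in per_repeat.groupby(["configuration", "family"], sort=False):
        vals = grp.auc.to_numpy()
        rows.append(
            {
                "configuration": cfg,
                "family": fam,
                "mean": float(vals.mean()),
                "std": float(vals.std(ddof=0)),
            }
        )
    out = pd.DataFrame(rows)
    avg = out.groupby("configuration")["mean"].transform("mean")
    out["average"] = avg
    out["flag"] = out["average"] >= AVERAGE_FLAG_THRESHOLD

    def _arch(tag):
        if architecture_of is not None:
            return architecture_of(tag)
        return tag.split("/", 1)[0]

    out["architecture"] = out["configuration"].map(_arch)
    return out[["configuration", "architecture", "family", "mean", "std", "average", "flag"]]
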