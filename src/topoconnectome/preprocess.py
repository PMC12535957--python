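"""Network-level preprocessing.

Order of operations for a raw cohort, as applied by :func:`preprocess_cohort`:

1. absolute value of functional correlations (sign carries no strength);
2. edge-wise residualization of age and sex by ordinary least squares,
   residuals re-centered at each edge's cross-subject mean;
3. (only for persistent homology, applied downstream) edge inversion
   ê = 1 - e, turning connection strength into dissimilarity.

Graph-theoretical metrics consume the raw (non-inverted) weights;
inversion exists to adapt connectivity graphs to a filtration where
tight connections enter first.

The multilayer representation is a 2N-node supra-adjacency block matrix
[[GM, DTI], [DTIᵀ, FMRI]]: morphology and function are the two intralayer
blocks, structural connectivity supplies the interlayer links between a
region's two replicas and all other regions' replicas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .netio import Cohort, SubjectRecord, ValidationError, WeightedNetwork

logger = logging.getLogger(__name__)


def absolute_correlations(network: WeightedNetwork) -> WeightedNetwork:
    """Elementwise absolute value of a (possibly signed) correlation matrix."""
    w = network.weights
    if w.size and (w.min() < -1.0 or w.max() > 1.0):
        raise ValidationError("correlations must lie in [-1, 1]")
    return network.copy_with(weights=np.abs(w))


def residualize_edgewise(cohort: Cohort) -> Cohort:
    """Remove linear age and sex effects from every edge, per modality.

    For each modality and each edge independently, ordinary least squares
    of edge weight on [intercept, age, sex-indicator (F=0, M=1)] is fitted
    across subjects; each value is replaced by its residual plus that
    edge's cross-subject mean.  The pseudoinverse handles singular designs
    (e.g. constant covariates degrade to exact pass-through).  Residuals
    that leave [0, 1] are clamped, with the clamp count logged.
    """
    if len(cohort) < 3:
        raise ValidationError("residualization needs at least 3 subjects")
    n = cohort.parcellation_size
    iu = np.triu_indices(n, k=1)
    ages = np.array([s.age for s in cohort.subjects], dtype=float)
    sexes = np.array([1.0 if s.sex == "M" else 0.0 for s in cohort.subjects])
    X = np.column_stack([np.ones(len(cohort)), ages, sexes])
    hat = X @ np.linalg.pinv(X)  # projection onto the design's column space

    new_subjects = [replace(s, networks=dict(s.networks)) for s in cohort.subjects]
    for mod in ("GM", "DTI", "FMRI"):
        W = np.stack([s.networks[mod].weights[iu] for s in cohort.subjects])
        if mod == "FMRI" and W.min() < 0:
            raise ValidationError(
                "functional matrices carry signed correlations; apply "
                "absolute_correlations before residualization"
            )
        resid = W - hat @ W
        adjusted = resid + W.mean(axis=0, keepdims=True)
        n_clamped = int(np.sum((adjusted < 0) | (adjusted > 1)))
        if n_clamped:
            logger.info("residualize %s: clamped %d edge values to [0, 1]", mod, n_clamped)
        adjusted = np.clip(adjusted, 0.0, 1.0)
        for i, s in enumerate(new_subjects):
            w = np.zeros((n, n))
            w[iu] = adjusted[i]
            s.networks[mod] = cohort.subjects[i].networks[mod].copy_with(weights=w + w.T)
    return Cohort(new_subjects, cohort.parcellation_size, cohort.provenance)


def invert_weights(network: WeightedNetwork, force: bool = False) -> WeightedNetwork:
    """Edge inversion ê = 1 - e: strength to dissimilarity, off-diagonal only.

    Refuses double inversion via the ``space`` flag unless ``force`` is
    set (test hook for the involution property)."""
    if network.space == "inverted" and not force:
        raise ValidationError("network already inverted (set force=True to override)")
    if network.weights.size and network.weights.min() < 0:
        raise ValidationError("inversion expects nonnegative weights (apply abs first)")
    w = 1.0 - network.weights
    np.fill_diagonal(w, 0.0)
    new_space = "raw" if network.space == "inverted" else "inverted"
    return network.copy_with(weights=w, space=new_space)


@dataclass
class MultilayerNetwork:
    """2N-node supra-adjacency with layer bookkeeping.

    ``supra_weights`` is the symmetric block matrix [[GM, DTI], [DTIᵀ, FMRI]];
    node i < N is region i's morphology-layer replica, node N + i its
    functional-layer replica.
    """

    supra_weights: np.ndarray
    region_labels: list[str]
    space: str = "raw"
    replica_coupling: float = 0.0

    @property
    def n_regions(self) -> int:
        return self.supra_weights.shape[0] // 2

    @property
    def layer_of_node(self) -> list[str]:
        n = self.n_regions
        return ["GM-layer"] * n + ["FMRI-layer"] * n

    @property
    def anatomical_index(self) -> np.ndarray:
        n = self.n_regions
        return np.concatenate([np.arange(n), np.arange(n)])

    def blocks(self) -> dict[str, np.ndarray]:
        """Recover the three constituent matrices (replica coupling removed
        from the interlayer block's diagonal)."""
        n = self.n_regions
        s = self.supra_weights
        dti = s[:n, n:].copy()
        np.fill_diagonal(dti, 0.0)
        return {"GM": s[:n, :n].copy(), "DTI": dti, "FMRI": s[n:, n:].copy()}

    def as_network(self) -> WeightedNetwork:
        labels = [f"{lab}@{layer.split('-')[0]}" for layer, lab in
                  zip(self.layer_of_node, list(self.region_labels) * 2)]
        return WeightedNetwork(labels, self.supra_weights, "SUPRA", self.space)


def build_supra_adjacency(
    subject: SubjectRecord, replica_coupling: float = 0.0
) -> MultilayerNetwork:
    """Assemble the supra-adjacency matrix of one subject.

    The entry linking region i's two replicas defaults to the stored DTI
    diagonal, i.e. 0; ``replica_coupling`` in (0, 1] overrides it with a
    constant.  All three networks must share the parcellation and space.
    """
    gm = subject.networks["GM"]
    dti = subject.networks["DTI"]
    fmri = subject.networks["FMRI"]
    if not (gm.n == dti.n == fmri.n):
        raise ValidationError("mismatched parcellations across modalities")
    if fmri.weights.min() < 0:
        raise ValidationError("signed functional weights: apply absolute_correlations first")
    if not (gm.space == dti.space == fmri.space):
        raise ValidationError("all layers must be in the same space (raw or inverted)")
    if not 0.0 <= replica_coupling <= 1.0:
        raise ValidationError("replica_coupling must be in [0, 1]")
    n = gm.n
    inter = dti.weights.copy()
    if replica_coupling > 0.0:
        np.fill_diagonal(inter, replica_coupling)
    supra = np.block([[gm.weights, inter], [inter.T, fmri.weights]])
    logger.debug("supra assembly in %s space, replica coupling %g", gm.space, replica_coupling)
    return MultilayerNetwork(supra, gm.region_labels, gm.space, replica_coupling)


def preprocess_cohort(
    cohort: Cohort, abs_fmri: bool = True, residualize: bool = True
) -> Cohort:
    """Standard preprocessing: absolute value of FMRI, then edge-wise
    age/sex residualization.  Each step individually toggleable."""
    if abs_fmri:
        subjects = []
        for s in cohort.subjects:
            nets = dict(s.networks)
            nets["FMRI"] = absolute_correlations(nets["FMRI"])
            subjects.append(replace(s, networks=nets))
        cohort = Cohort(subjects, cohort.parcellation_size, cohort.provenance)
    if residualize:
        cohort = residualize_edgewise(cohort)
    return cohort
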