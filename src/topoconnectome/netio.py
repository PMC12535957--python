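"""Core network/cohort data model and on-disk formats.

A subject's brain is represented by three symmetric weighted adjacency
matrices over a common anatomical parcellation (default 76 regions):

* ``GM``   -- gray-matter morphological similarity, entries in [0, 1];
* ``DTI``  -- FA-weighted structural connectivity, entries in [0, 1];
* ``FMRI`` -- resting-state functional correlation; raw matrices may be
  signed in [-1, 1] until the absolute-value transform is applied.

Matrices live on disk as dense delimited text (CSV/TSV), one file per
subject per modality, tied together by a JSON cohort manifest.  The
parcellation is small (N <= 200), so everything is stored dense.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("GM", "DTI", "FMRI", "SUPRA")
SPACES = ("raw", "inverted")
GROUPS = ("HV", "PwMS")
SEXES = ("F", "M")

#: elementwise asymmetry above this marks a file as corrupt rather than
#: sloppily stored; all matrices here are symmetric by construction
ASYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """A network, subject, or cohort violates a structural invariant."""


@dataclass
class WeightedNetwork:
    """One modality's symmetric weighted adjacency over labeled regions.

    ``space`` records whether the edge-inversion ``ê = 1 - e`` has been
    applied (``"inverted"``) or not (``"raw"``).  Entries must lie in
    [0, 1], except raw functional matrices which may carry signed
    correlations in [-1, 1] until :func:`~topoconnectome.preprocess.absolute_correlations`
    is applied.
    """

    region_labels: list[str]
    weights: np.ndarray
    modality: str
    space: str = "raw"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.region_labels = list(self.region_labels)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        w = self.weights
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.space not in SPACES:
            raise ValidationError(f"unknown space {self.space!r}")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"weights must be square, got shape {w.shape}")
        if len(self.region_labels) != w.shape[0]:
            raise ValidationError(
                f"{len(self.region_labels)} labels for matrix of order {w.shape[0]}"
            )
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite entries in weight matrix")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > ASYMMETRY_TOL:
            raise ValidationError(f"asymmetric weights (max |w - w.T| = {asym:g})")
        if np.any(np.diag(w) != 0):
            raise ValidationError("nonzero diagonal")
        lo = -1.0 if self.allows_signed else 0.0
        if w.size and (w.min() < lo or w.max() > 1.0):
            raise ValidationError(
                f"entries outside [{lo:g}, 1] for modality {self.modality} "
                f"(range [{w.min():g}, {w.max():g}])"
            )

    @property
    def allows_signed(self) -> bool:
        """Signed entries are legal only for raw functional correlations."""
        return self.modality == "FMRI" and self.space == "raw"

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def copy_with(self, **changes) -> "WeightedNetwork":
        if "weights" not in changes:
            changes["weights"] = self.weights.copy()
        return replace(self, **changes)


@dataclass
class SubjectRecord:
    """One subject: three modality networks plus group/age/sex covariates."""

    subject_id: str
    group: str
    age: float
    sex: str
    networks: dict[str, WeightedNetwork]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        missing = {"GM", "DTI", "FMRI"} - set(self.networks)
        if missing:
            raise ValidationError(
                f"subject {self.subject_id}: missing networks {sorted(missing)}"
            )
        labels = None
        for mod in ("GM", "DTI", "FMRI"):
            net = self.networks[mod]
            if labels is None:
                labels = net.region_labels
            elif net.region_labels != labels:
                raise ValidationError(
                    f"subject {self.subject_id}: region labels of {mod} do not "
                    "match the other modalities (same order required)"
                )

    @property
    def region_labels(self) -> list[str]:
        return self.networks["GM"].region_labels

    @property
    def n_regions(self) -> int:
        return self.networks["GM"].n


@dataclass
class Cohort:
    """The benchmark population: a list of subjects over a shared parcellation."""

    subjects: list[SubjectRecord]
    parcellation_size: int = 76
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.subjects:
            return
        labels = self.subjects[0].region_labels
        for s in self.subjects:
            if s.region_labels != labels:
                raise ValidationError(
                    f"subject {s.subject_id}: parcellation labels differ from "
                    f"subject {self.subjects[0].subject_id}"
                )
            if s.n_regions != self.parcellation_size:
                raise ValidationError(
                    f"subject {s.subject_id}: {s.n_regions} regions, "
                    f"expected {self.parcellation_size}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def region_labels(self) -> list[str]:
        return self.subjects[0].region_labels

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    def require_both_groups(self) -> None:
        present = set(self.groups)
        if not set(GROUPS) <= present:
            raise ValidationError(
                f"benchmark needs at least one subject per group, found {sorted(present)}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def default_region_labels(n: int) -> list[str]:
    return [f"region_{i:03d}" for i in range(n)]


def read_square_matrix(
    path: str | Path,
    delimiter: str = ",",
    modality: str = "DTI",
    space: str = "raw",
    region_labels: list[str] | None = None,
) -> WeightedNetwork:
    """Read a dense delimited square matrix into a validated network.

    Asymmetry up to ``ASYMMETRY_TOL`` is repaired by averaging; anything
    larger rejects the file.  A nonzero diagonal is forced to zero with a
    logged warning.  Entries in [-1, 0) are accepted only for raw
    functional matrices.
    """
    path = Path(path)
    w = np.loadtxt(path, delimiter=delimiter, ndmin=2, dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValidationError(f"{path}: non-square matrix {w.shape}")
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > ASYMMETRY_TOL:
        raise ValidationError(
            f"{path}: asymmetry {asym:g} exceeds tolerance {ASYMMETRY_TOL:g}"
        )
    w = (w + w.T) / 2.0
    if np.any(np.diag(w) != 0):
        logger.warning("%s: nonzero diagonal forced to 0", path)
        np.fill_diagonal(w, 0.0)
    if region_labels is None:
        region_labels = default_region_labels(w.shape[0])
    return WeightedNetwork(region_labels, w, modality, space)


def write_square_matrix(network: WeightedNetwork, path: str | Path, delimiter: str = ",") -> None:
    np.savetxt(Path(path), network.weights, delimiter=delimiter, fmt="%.17g")


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a JSON manifest.

    Manifest layout::

        {
          "parcellation_size": 76,            # optional, inferred otherwise
          "region_labels": ["..."],           # optional shared labels
          "provenance": "...",                # optional
          "subjects": [
            {"subject_id": "s01", "group": "HV", "age": 41.0, "sex": "F",
             "paths": {"gm": "...", "dti": "...", "fmri": "..."},
             "region_labels": {"gm": [...], ...}}   # optional per-modality
          ]
        }

    Paths are resolved relative to the manifest.  Label order must agree
    across modalities and subjects.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    shared_labels = manifest.get("region_labels")
    subjects = []
    for entry in manifest.get("subjects", []):
        sid = entry.get("subject_id", "<unnamed>")
        paths = entry.get("paths", {})
        networks = {}
        for key, mod in (("gm", "GM"), ("dti", "DTI"), ("fmri", "FMRI")):
            if key not in paths:
                raise ValidationError(f"subject {sid}: manifest missing {key} path")
            labels = (entry.get("region_labels") or {}).get(key, shared_labels)
            net = read_square_matrix(
                base / paths[key],
                delimiter=_sniff_delimiter(paths[key]),
                modality=mod,
                space="raw",
                region_labels=labels,
            )
            networks[mod] = net
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=entry["group"],
                age=float(entry["age"]),
                sex=entry["sex"],
                networks=networks,
            )
        )
    if not subjects:
        raise ValidationError(f"{manifest_path}: manifest lists no subjects")
    size = manifest.get("parcellation_size", subjects[0].n_regions)
    return Cohort(subjects, parcellation_size=size, provenance=manifest.get("provenance", ""))


def _sniff_delimiter(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_cohort(cohort: Cohort, out_dir: str | Path, delimiter: str = ",") -> Path:
    """Write one matrix file per subject per modality plus a JSON manifest.

    Returns the manifest path.  Round-trips through :func:`read_cohort`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if delimiter == "\t" else "csv"
    entries = []
    for s in cohort.subjects:
        paths = {}
        for key, mod in (("gm", "GM"), ("dti", "DTI"), ("fmri", "FMRI")):
            fname = f"{s.subject_id}_{key}.{ext}"
            write_square_matrix(s.networks[mod], out_dir / fname, delimiter)
            paths[key] = fname
        entries.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "paths": paths,
            }
        )
    manifest = {
        "parcellation_size": cohort.parcellation_size,
        "region_labels": cohort.region_labels,
        "provenance": cohort.provenance,
        "subjects": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def write_results_table(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a benchmark summary as a wide CSV.

    ``summary`` is the tidy frame from :func:`topoconnectome.evaluate.summarize`
    with columns ``configuration, architecture, family, mean, std, ...``.
    The output has one row per (configuration, architecture), one
    ``mean±std`` column per model family, and a cross-family ``average``
    column, mirroring how such benchmarks are usually tabulated.
    """
    if summary is None or len(summary) == 0:
        raise ValidationError("empty summary: nothing to write")
    required = {"configuration", "architecture", "family", "mean", "std"}
    if not required <= set(summary.columns):
        raise ValidationError(f"summary must have columns {sorted(required)}")
    rows = []
    for (cfg, arch), grp in summary.groupby(["configuration", "architecture"], sort=False):
        row: dict[str, object] = {"configuration": cfg, "architecture": arch}
        for _, rec in grp.iterrows():
            row[rec["family"]] = f"{rec['mean']:.3f}±{rec['std']:.3f}"
        row["average"] = f"{grp['mean'].mean():.3f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`, splitting
    ``mean±std`` cells into numeric columns."""
    wide = pd.read_csv(Path(path))
    value_cols = [c for c in wide.columns if c not in ("configuration", "architecture", "average")]
    records = []
    for _, row in wide.iterrows():
        for fam in value_cols:
            cell = row[fam]
            if isinstance(cell, float) and math.isnan(cell):
                continue
            mean_s, std_s = str(cell).split("±")
            records.append(
                {
                    "configuration": row["configuration"],
                    "architecture": row["architecture"],
                    "family": fam,
                    "mean": float(mean_s),
                    "std": float(std_s),
                }
            )
    return pd.DataFrame(records)


def write_diagram_csv(diagram, path: str | Path) -> None:
    """Persistence diagram -> CSV with columns dim, birth, death ('inf' allowed)."""
    rows = [
        {"dim": d, "birth": b, "death": ("inf" if np.isinf(dd) else dd)}
        for d, b, dd in diagram.intervals
    ]
    pd.DataFrame(rows, columns=["dim", "birth", "death"]).to_csv(Path(path), index=False)
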