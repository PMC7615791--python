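"""Brain-functional-network construction and cohort serialization.

A cohort on disk is a CSV manifest (``subject_id, label, path_F, path_A``)
pointing at one TSV matrix file per subject per matrix, written with
17-significant-digit floats so round trips are lossless to text precision.
Class labels follow the convention control (NC) -> 0, patient (LMCI) -> 1,
with one-hot encoding [1, 0] and [0, 1] respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = ["Subject", "pearson_bfn", "five_fold_split", "read_cohort", "write_cohort",
           "validate_bfn"]

_SYM_TOL = 1e-10


def validate_bfn(a: np.ndarray, tol: float = _SYM_TOL) -> None:
    """Raise if ``a`` is not a valid functional network matrix."""
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"BFN must be square, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError("BFN contains non-finite entries")
    if np.abs(a - a.T).max() > tol:
        raise ValueError("BFN is not symmetric within tolerance")
    if np.abs(np.diag(a) - 1.0).max() > tol:
        raise ValueError("BFN diagonal is not 1")
    if a.min() < -1.0 - 1e-9 or a.max() > 1.0 + 1e-9:
        raise ValueError("BFN entries outside [-1, 1]")


@dataclass
class Subject:
    """One sample: ROI time series ``F`` (N x T), network ``A_ori`` (N x N),
    and binary class label ``y``."""

    id: str
    F: np.ndarray
    A_ori: np.ndarray
    y: int

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.A_ori = np.asarray(self.A_ori, dtype=float)
        if self.y not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.y!r}")
        if not np.isfinite(self.F).all():
            raise ValueError(f"subject {self.id}: F has non-finite entries")
        if self.F.shape[0] != self.A_ori.shape[0]:
            raise ValueError(f"subject {self.id}: F/A_ori row mismatch")
        validate_bfn(self.A_ori)

    @property
    def y_onehot(self) -> np.ndarray:
        return np.array([1.0, 0.0]) if self.y == 0 else np.array([0.0, 1.0])


def pearson_bfn(f: np.ndarray) -> np.ndarray:
    """Pearson-correlation network of the rows of ``f`` (N ROIs x T points).

    Zero-variance rows correlate 0 with everything (1 on the diagonal),
    keeping downstream graph-convolution inputs finite.
    """
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("feature matrix contains non-finite entries")
    if f.ndim != 2 or f.shape[1] < 3:
        raise ValueError("need an N x T matrix with T >= 3")
    centred = f - f.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = centred / safe[:, None]
    a = unit @ unit.T
    a[~ok, :] = 0.0
    a[:, ~ok] = 0.0
    a = np.clip(0.5 * (a + a.T), -1.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return a


def five_fold_split(subjects: list[Subject], seed: int, n_folds: int = 5):
    """Stratified fold assignment: disjoint folds with per-class counts
    differing by at most one; deterministic in ``seed``."""
    labels = np.array([s.y for s in subjects])
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort contains a single class; cannot stratify")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(subjects)), labels)]


def write_cohort(subjects: list[Subject], out_dir) -> Path:
    """Write TSV matrices plus the CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        path_f = out_dir / f"{s.id}_F.tsv"
        path_a = out_dir / f"{s.id}_A.tsv"
        np.savetxt(path_f, s.F, delimiter="\t", fmt="%.17g")
        np.savetxt(path_a, s.A_ori, delimiter="\t", fmt="%.17g")
        rows.append({"subject_id": s.id, "label": s.y,
                     "path_F": path_f.name, "path_A": path_a.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[Subject]:
    """Read a cohort back from its manifest, enforcing Subject invariants."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"subject_id", "label", "path_F", "path_A"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest missing columns {required - set(table.columns)}")
    base = manifest_path.parent
    subjects = []
    for row in table.itertuples(index=False):
        label = int(row.label)
        if label not in (0, 1):
            raise ValueError(f"subject {row.subject_id}: label {row.label!r} "
                             "outside {0, 1}")
        f = np.loadtxt(base / row.path_F, delimiter="\t", ndmin=2)
        a = np.loadtxt(base / row.path_A, delimiter="\t", ndmin=2)
        subjects.append(Subject(id=str(row.subject_id), F=f, A_ori=a, y=label))
    return subjects
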