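"""Synthetic two-class cohorts of ROI time series and functional networks.

Real resting-state cohorts are hard to share, so the package ships a
generator that emulates their statistical skeleton: each class has a modular
(block-structured) correlation template over ``n_rois`` regions; the disease
class differs from the control class by an additive shift on a seeded random
subset of inter-module edges, mimicking abnormal functional connections
between brain regions.  Per-subject BOLD-like time series are drawn from a
zero-mean multivariate normal whose covariance is the class template plus
subject-level jitter.  Series are white in time: the Pearson network is
invariant to temporal ordering, so autocorrelation would add no test power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bfn_io import Subject, pearson_bfn

__all__ = ["CohortSpec", "make_class_templates", "simulate_subject",
           "generate_cohort", "class_roi_shifts"]

#: lowest eigenvalue allowed before a template counts as repaired
_PSD_TOL = -1e-8
#: eigenvalue floor used in the nearest-correlation repair
_EIG_FLOOR = 1e-6


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    Defaults mirror the shapes of an AAL-parcellated resting-state study:
    90 regions, 187 retained volumes, 75 subjects per diagnostic class.
    """

    n_rois: int = 90
    n_timepoints: int = 187
    n_per_class: int = 75
    n_modules: int = 6
    within_corr: float = 0.5
    between_corr: float = 0.1
    effect_edges: float = 0.15
    effect_size: float = 0.3
    roi_shift_effect: float = 0.5
    subject_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.between_corr < self.within_corr <= 1.0):
            raise ValueError(
                "require 0 <= between_corr < within_corr <= 1; got "
                f"between_corr={self.between_corr}, within_corr={self.within_corr}"
            )
        if self.n_per_class < 2:
            raise ValueError(f"n_per_class must be >= 2, got {self.n_per_class}")
        if self.n_modules < 1 or self.n_modules > self.n_rois:
            raise ValueError(f"n_modules must be in [1, n_rois], got {self.n_modules}")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints < 3: Pearson correlation is degenerate")

    def module_labels(self) -> np.ndarray:
        """Module index per ROI; remainder ROIs join the last module."""
        size = self.n_rois // self.n_modules
        labels = np.repeat(np.arange(self.n_modules), size)
        if labels.size < self.n_rois:
            labels = np.concatenate(
                [labels, np.full(self.n_rois - labels.size, self.n_modules - 1)]
            )
        return labels


def nearest_correlation(mat: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix onto the valid correlation matrices.

    Negative eigenvalues are clipped to a small positive floor and the result
    rescaled back to unit diagonal — the simplest projection that guarantees
    positive semi-definiteness.
    """
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= _PSD_TOL:
        out = sym
    else:
        out = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    d = np.sqrt(np.diag(out))
    if np.any(d <= 0):
        raise ValueError("matrix cannot be repaired to a correlation matrix")
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def _pick_effect_edges(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded choice of the inter-module edges altered in class 1."""
    if spec.effect_size == 0.0 or spec.effect_edges <= 0.0:
        return np.array([], dtype=int), np.array([], dtype=int)
    labels = spec.module_labels()
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(spec.n_rois, k=1)
    inter = np.flatnonzero(~same[iu])
    n_pick = int(round(spec.effect_edges * inter.size))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE0]))
    picked = rng.choice(inter, size=n_pick, replace=False)
    return iu[0][picked], iu[1][picked]


def class_roi_shifts(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI baseline offsets of the two classes' time series.

    Regions incident to an altered edge also show a regional-amplitude
    abnormality in the patient class: a constant offset of
    ``roi_shift_effect`` added to their BOLD-like signal.  Pearson networks
    are invariant to per-row constant shifts, so this changes the marginal
    feature distributions (and hence the label prior) without touching the
    connectivity effect model.
    """
    zero = np.zeros(spec.n_rois)
    rows, cols = _pick_effect_edges(spec)
    shift = np.zeros(spec.n_rois)
    if rows.size:
        affected = np.unique(np.concatenate([rows, cols]))
        shift[affected] = spec.roi_shift_effect
    return zero, shift


def make_class_templates(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the class-0 and class-1 correlation templates.

    Class 0 is the pure block model (``within_corr`` inside modules,
    ``between_corr`` across).  Class 1 adds ``effect_size`` to a seeded random
    fraction ``effect_edges`` of the inter-module edges, clips off-diagonal
    values to [-0.95, 0.95], and both templates are repaired to valid
    correlation matrices.
    """
    labels = spec.module_labels()
    same = labels[:, None] == labels[None, :]
    base = np.where(same, spec.within_corr, spec.between_corr).astype(float)
    np.fill_diagonal(base, 1.0)

    shifted = base.copy()
    rows, cols = _pick_effect_edges(spec)
    if rows.size:
        shifted[rows, cols] += spec.effect_size
        shifted[cols, rows] += spec.effect_size
        off = ~np.eye(spec.n_rois, dtype=bool)
        shifted[off] = np.clip(shifted[off], -0.95, 0.95)

    try:
        t0 = nearest_correlation(base)
        t1 = nearest_correlation(shifted)
    except ValueError as exc:
        raise ValueError(
            "templates not repairable to correlation matrices; adjust "
            "within_corr/between_corr/effect_size"
        ) from exc
    return t0, t1


def simulate_subject(template: np.ndarray, spec: CohortSpec,
                     subject_seed: int,
                     roi_shift: np.ndarray | None = None) -> np.ndarray:
    """Draw one subject's ROI-by-time feature matrix F.

    The subject's covariance is the class template jittered by symmetric
    Gaussian noise of sd ``subject_noise_sd`` on the off-diagonal (then
    repaired); the T time points are i.i.d. draws from N(0, cov), plus the
    class's per-ROI baseline offsets (``roi_shift``), which the Pearson
    network does not see.
    """
    n = template.shape[0]
    if spec.n_timepoints < 3:
        raise ValueError("n_timepoints < 3: Pearson correlation is degenerate")
    rng = np.random.default_rng(subject_seed)
    cov = template
    if spec.subject_noise_sd > 0:
        noise = rng.normal(0.0, spec.subject_noise_sd, size=(n, n))
        noise = 0.5 * (noise + noise.T)
        np.fill_diagonal(noise, 0.0)
        cov = nearest_correlation(template + noise)
    root = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    z = rng.standard_normal((n, spec.n_timepoints))
    f = root @ z
    if roi_shift is not None:
        f = f + np.asarray(roi_shift)[:, None]
    return f


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate the full balanced cohort: 2 * n_per_class labelled subjects."""
    t0, t1 = make_class_templates(spec)
    shifts = class_roi_shifts(spec)
    ss = np.random.SeedSequence([spec.seed, 0x5C])
    seeds = ss.generate_state(2 * spec.n_per_class)
    subjects = []
    for idx in range(2 * spec.n_per_class):
        label = 0 if idx < spec.n_per_class else 1
        template = t0 if label == 0 else t1
        f = simulate_subject(template, spec, int(seeds[idx]),
                             roi_shift=shifts[label])
        subjects.append(
            Subject(id=f"sub-{idx:04d}", F=f, A_ori=pearson_bfn(f), y=label)
        )
    return subjects
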