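"""Class-conditional latent prior: dimension reduction + kernel density.

The adversarial game regularizes the graph encoder's latent node codes
toward an estimated *label distribution*: for each diagnostic class the
density of dimension-reduced node features, modelled by a Gaussian-kernel
KDE.  The reduction is a per-ROI PCA fitted on training subjects only — it
must exist before adversarial training starts, so it cannot depend on the
encoder.  Because the encoder's codes live in (-1, 1) (tanh output), reduced
coordinates are rescaled to sd ~= 1/3 per dimension so the prior occupies
the same bounded code space; without this the discriminator could separate
real from fake on magnitude alone and the adversarial game could never
approach its equilibrium.

Two granularities are supported.  ``per_roi`` (default) keeps one KDE per
ROI per class, so sampled rows preserve ROI identity — which the per-ROI
sub-network discriminator presupposes.  ``pooled`` collapses all ROIs of all
same-class subjects into one density over N * n_Y centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bfn_io import Subject

__all__ = ["Reducer", "fit_reducer", "LabelKDE", "fit_kde", "sample_matrix"]

#: sampled/reduced coordinates are scaled so per-dimension sd is about this
LATENT_SD = 1.0 / 3.0
_BW_FLOOR = 1e-6


@dataclass
class Reducer:
    """Per-ROI linear projection from the T-dim feature space to p dims."""

    components: np.ndarray  # (N, T, p), orthonormal columns per ROI
    means: np.ndarray       # (N, T)
    scales: np.ndarray      # (N, p) divisor applied after projection

    @property
    def p(self) -> int:
        return self.components.shape[2]

    def transform(self, f: np.ndarray) -> np.ndarray:
        """Reduce one subject's N x T feature matrix to N x p."""
        centred = f - self.means
        h = np.einsum("nt,ntp->np", centred, self.components)
        return h / self.scales

    def transform_cohort(self, subjects: list[Subject]) -> np.ndarray:
        """Stacked reduced features, shape (n_subjects, N, p)."""
        return np.stack([self.transform(s.F) for s in subjects])


def _principal_axes(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-p right singular axes of centred samples ``x`` (rows = samples),
    with the deterministic sign convention (largest-|loading| positive),
    plus the per-axis standard deviations."""
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    axes = vt[:p].T
    flip = np.sign(axes[np.abs(axes).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    sd = svals[:p] / np.sqrt(max(x.shape[0] - 1, 1))
    return axes * flip, sd


def fit_reducer(subjects: list[Subject], p: int, axes: str = "shared") -> Reducer:
    """Fit the PCA reduction on training subjects.

    ``axes="shared"`` (default) fits one T -> p basis on the T-vectors of
    all ROIs of all training subjects pooled; each ROI keeps its own mean,
    so per-ROI center distributions still differ while living in a common
    coordinate frame.  ``axes="per_roi"`` fits an independent basis per ROI.

    The shared frame matters for the adversarial game: with noise-like
    time series the per-ROI sample covariances are noise-dominated, so
    per-ROI bases are N mutually arbitrary rotations — and a weight-shared
    graph encoder cannot align its codes to N unrelated coordinate systems
    at once, which hands the per-ROI discriminator a free win.
    """
    if axes not in ("shared", "per_roi"):
        raise ValueError(f"unknown axes mode {axes!r}")
    if len(subjects) < 2:
        raise ValueError("need at least 2 training subjects")
    stack = np.stack([s.F for s in subjects])           # (S, N, T)
    n_sub, n_roi, n_t = stack.shape
    max_rank = n_t if axes == "shared" else min(n_t, n_sub)
    if p > max_rank:
        raise ValueError(f"p={p} exceeds min(T={n_t}, n_subjects={n_sub})")
    means = stack.mean(axis=0)                           # (N, T)
    centred = stack - means
    components = np.empty((n_roi, n_t, p))
    scales = np.empty((n_roi, p))
    if axes == "shared":
        basis, _ = _principal_axes(centred.reshape(-1, n_t), p)
        proj = centred @ basis                           # (S, N, p)
        sd = np.maximum(proj.reshape(-1, p).std(axis=0, ddof=1), _BW_FLOOR)
        components[:] = basis
        scales[:] = sd / LATENT_SD
    else:
        for i in range(n_roi):
            axes_i, sd = _principal_axes(centred[:, i, :], p)
            components[i] = axes_i
            scales[i] = np.maximum(sd, _BW_FLOOR) / LATENT_SD
    return Reducer(components=components, means=means, scales=scales)


@dataclass
class LabelKDE:
    """Gaussian-kernel density of latent node features, per class.

    In ``per_roi`` mode ``centers[y]`` has shape (N, n_Y, p) and
    ``bandwidth[y]`` shape (N,); in ``pooled`` mode centers are
    (N * n_Y, p) with a scalar bandwidth.  Scott's rule sets the bandwidth:
    b = sigma_hat * m**(-1/(p+4)) with m the number of centers and sigma_hat
    the mean per-dimension standard deviation.
    """

    mode: str
    centers: dict
    bandwidth: dict
    p: int

    def density(self, x: np.ndarray, y: int, roi: int | None = None) -> float:
        """Normalized kernel-sum density at point ``x`` (p-vector)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.mode == "per_roi":
            if roi is None:
                raise ValueError("per_roi mode needs a roi index")
            c = self.centers[y][roi]
            b = float(self.bandwidth[y][roi])
        else:
            c = self.centers[y]
            b = float(self.bandwidth[y])
        d2 = ((c - x) ** 2).sum(axis=1)
        norm = (2.0 * np.pi * b * b) ** (-0.5 * self.p)
        return float(norm * np.exp(-0.5 * d2 / (b * b)).mean())

    def classes(self):
        return sorted(self.centers)

    def save(self, path) -> None:
        arrays = {"mode": np.array(self.mode), "p": np.array(self.p)}
        for y in self.centers:
            arrays[f"centers_{y}"] = self.centers[y]
            arrays[f"bandwidth_{y}"] = np.atleast_1d(self.bandwidth[y])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "LabelKDE":
        with np.load(path, allow_pickle=False) as z:
            mode = str(z["mode"])
            p = int(z["p"])
            centers, bandwidth = {}, {}
            for key in z.files:
                if key.startswith("centers_"):
                    y = int(key.split("_")[1])
                    centers[y] = z[key]
                    bw = z[f"bandwidth_{y}"]
                    bandwidth[y] = bw if mode == "per_roi" else float(bw[0])
        return cls(mode=mode, centers=centers, bandwidth=bandwidth, p=p)


def _scott(centers_2d: np.ndarray) -> float:
    m, p = centers_2d.shape
    sigma = centers_2d.std(axis=0, ddof=1).mean()
    if sigma < _BW_FLOOR:
        import warnings

        warnings.warn("zero-variance KDE centers; bandwidth floored", stacklevel=3)
        sigma = _BW_FLOOR
    return float(sigma * m ** (-1.0 / (p + 4)))


def fit_kde(reduced: np.ndarray, labels: np.ndarray, mode: str = "per_roi") -> LabelKDE:
    """Fit the class-conditional KDE from reduced features (S, N, p)."""
    if mode not in ("per_roi", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels)
    p = reduced.shape[2]
    centers, bandwidth = {}, {}
    for y in np.unique(labels):
        y = int(y)
        block = reduced[labels == y]                     # (n_Y, N, p)
        if block.shape[0] < 2:
            raise ValueError(f"class {y}: need at least 2 subjects")
        if mode == "per_roi":
            per_roi = block.transpose(1, 0, 2)           # (N, n_Y, p)
            centers[y] = per_roi
            bandwidth[y] = np.array([_scott(per_roi[i]) for i in range(per_roi.shape[0])])
        else:
            flat = block.reshape(-1, p)                  # (N*n_Y, p)
            centers[y] = flat
            bandwidth[y] = _scott(flat)
    return LabelKDE(mode=mode, centers=centers, bandwidth=bandwidth, p=p)


def sample_matrix(kde: LabelKDE, y: int, n_rois: int,
                  rng: np.random.Generator,
                  variance_corrected: bool = True) -> np.ndarray:
    """Draw one latent matrix X (N x p) from the class-``y`` prior.

    Each row is a uniformly chosen kernel center plus isotropic Gaussian
    noise of sd equal to the bandwidth.  With ``variance_corrected`` (the
    default, used for generation) samples are shrunk toward the center mean
    by Silverman's smoothed-bootstrap factor (1 + b^2/sigma^2)^{-1/2} so the
    sampled distribution preserves the empirical mean and variance — in
    high latent dimension uncorrected kernel noise inflates every
    dimension's variance and concentrates on a detectable shell.  With
    ``variance_corrected=False`` the draw is the plain KDE sample, used for
    the discriminator's real stream where the fake stream receives the same
    kernel smoothing.
    """
    if y not in kde.centers:
        raise ValueError(f"KDE not fitted for class {y}")
    if kde.mode == "per_roi":
        c = kde.centers[y]
        if c.shape[0] != n_rois:
            raise ValueError(f"KDE fitted for {c.shape[0]} ROIs, asked for {n_rois}")
        picks = rng.integers(0, c.shape[1], size=n_rois)
        base = c[np.arange(n_rois), picks]
        b = kde.bandwidth[y][:, None]                     # (N, 1)
        mu = c.mean(axis=1)                               # (N, p)
        sigma2 = np.maximum(c.var(axis=(1, 2), ddof=1), _BW_FLOOR)[:, None]
    else:
        c = kde.centers[y]
        picks = rng.integers(0, c.shape[0], size=n_rois)
        base = c[picks]
        b = float(kde.bandwidth[y])
        mu = c.mean(axis=0)                               # (p,)
        sigma2 = max(float(c.var(ddof=1)), _BW_FLOOR)
    noise = rng.standard_normal((n_rois, kde.p)) * b
    if not variance_corrected:
        return base + noise
    shrink = 1.0 / np.sqrt(1.0 + b * b / sigma2)
    # written so that shrink == 1 (b = 0) returns the centers exactly
    return (base + noise) * shrink + mu * (1.0 - shrink)
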