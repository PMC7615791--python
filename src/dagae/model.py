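"""Model/Results facade over the adversarial graph autoencoder.

``DAGAE`` is constructed from a list of training subjects (ROI time series,
Pearson networks, binary labels); ``fit()`` fits the per-ROI PCA reducer and
the class-conditional KDE prior on those subjects, runs the alternating
adversarial optimization, and returns a ``DAGAEResults`` carrying the fitted
networks, the per-epoch loss history, convergence diagnostics and the
``augment`` sampler used for data augmentation.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bfn_io import Subject
from .kde import LabelKDE, Reducer, fit_kde, fit_reducer
from .networks import ModelConfig
from .nn import Tensor
from .training import (GeneratedBFN, Networks, TrainConfig, augment,
                       train_dagae)

__all__ = ["DAGAE", "DAGAEResults"]


class DAGAE:
    """Distribution-regularized adversarial graph autoencoder.

    Parameters
    ----------
    subjects
        Training subjects only; the KDE prior and the networks see nothing
        else, so held-out evaluation data stays untouched.
    config
        Architecture settings (defaults: 90 ROIs, 187 time points, p=32).
    kde_mode
        ``"per_roi"`` (one density per ROI per class, default) or
        ``"pooled"``.
    """

    def __init__(self, subjects: list[Subject], config: ModelConfig | None = None,
                 kde_mode: str = "per_roi"):
        if not subjects:
            raise ValueError("empty training set")
        self.subjects = list(subjects)
        n, t = subjects[0].F.shape
        self.config = config or ModelConfig(n_rois=n, n_timepoints=t)
        if (self.config.n_rois, self.config.n_timepoints) != (n, t):
            raise ValueError(
                f"config expects {self.config.n_rois}x{self.config.n_timepoints}"
                f" features, data is {n}x{t}")
        self.kde_mode = kde_mode
        self.n_per_class = {
            y: sum(1 for s in subjects if s.y == y) for y in (0, 1)}

    def fit(self, train_config: TrainConfig | None = None) -> "DAGAEResults":
        tc = train_config or TrainConfig()
        reducer = fit_reducer(self.subjects, self.config.latent_dim)
        reduced = reducer.transform_cohort(self.subjects)
        labels = np.array([s.y for s in self.subjects])
        kde = fit_kde(reduced, labels, mode=self.kde_mode)
        nets, history = train_dagae(self.subjects, kde, self.config, tc)
        return DAGAEResults(model=self, train_config=tc, reducer=reducer,
                            kde=kde, nets=nets, history=history)


@dataclass
class DAGAEResults:
    """Fitted networks, loss history and augmentation interface."""

    model: DAGAE
    train_config: TrainConfig
    reducer: Reducer
    kde: LabelKDE
    nets: Networks
    history: pd.DataFrame

    # ------------------------------------------------------------- queries
    def encode(self, subject: Subject) -> np.ndarray:
        dt = self.model.config.np_dtype
        h = self.nets.encoder.forward(
            Tensor(subject.A_ori.astype(dt)), Tensor(subject.F.astype(dt)))
        return np.asarray(h.data, dtype=float)

    def reconstruct(self, subject: Subject) -> np.ndarray:
        dt = self.model.config.np_dtype
        h = self.nets.encoder.forward(
            Tensor(subject.A_ori.astype(dt)), Tensor(subject.F.astype(dt)))
        a = self.nets.generator.forward(h).data
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 1.0)
        return np.asarray(a, dtype=float)

    def augment(self, k: float | None = None,
                seed: int | None = None) -> list[GeneratedBFN]:
        """Generate class-conditional networks: round(k * n_train) per class."""
        k = self.train_config.k if k is None else k
        seed = self.train_config.seed if seed is None else seed
        return augment(self.nets, self.kde, self.model.n_per_class, k, seed)

    # --------------------------------------------------------- diagnostics
    def convergence(self, window: int = 50) -> dict:
        """Equilibrium diagnostics over the last ``window`` epochs: at the
        adversarial optimum the discriminator outputs 0.5 on both streams."""
        tail = self.history.tail(window)
        return {
            "d_real": float(tail["d_real"].mean()),
            "d_fake": float(tail["d_fake"].mean()),
            "d_gap": float(abs(tail["d_real"].mean() - 0.5)
                           + abs(tail["d_fake"].mean() - 0.5)),
            "L_rec_final": float(tail["L_rec"].mean()),
            "L_total_drift": float(
                tail[["L_cla", "L_rec", "L_nrc"]].sum(axis=1).diff().abs().mean()),
            "window": int(len(tail)),
        }

    def summary(self, window: int = 50) -> str:
        conv = self.convergence(window)
        cfg, tc = self.model.config, self.train_config
        lines = [
            "Distribution-Regularized Adversarial Graph Autoencoder",
            "=" * 56,
            f"subjects: {len(self.model.subjects)}  "
            f"(per class: {self.model.n_per_class})",
            f"rois: {cfg.n_rois}  timepoints: {cfg.n_timepoints}  "
            f"latent dim: {cfg.latent_dim}",
            f"epochs: {tc.epochs}  batch: {tc.batch_size}  "
            f"variant: {tc.variant}",
            "-" * 56,
            f"final mean D(real prior sample): {conv['d_real']:.3f}",
            f"final mean D(fake encoder code): {conv['d_fake']:.3f}",
            f"equilibrium gap |D-0.5| summed:  {conv['d_gap']:.3f}",
            f"final reconstruction L1:         {conv['L_rec_final']:.4f}",
            f"(averaged over last {conv['window']} epochs)",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss and discriminator-output curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col in ("L_enc", "L_dis", "L_rec", "L_cla", "L_nrc"):
            ax.plot(self.history.index, self.history[col], label=col)
        ax.plot(self.history.index, self.history["d_real"], "--", label="D(real)")
        ax.plot(self.history.index, self.history["d_fake"], "--", label="D(fake)")
        ax.set_xlabel("epoch")
        ax.legend(fontsize=7)
        return ax

    # ------------------------------------------------------------- storage
    def save(self, path) -> None:
        path = Path(path)
        payload = {
            "config": self.model.config,
            "train_config": self.train_config,
            "state": self.nets.state_dict(),
            "reducer": self.reducer,
            "kde": self.kde,
            "history": self.history,
            "n_per_class": self.model.n_per_class,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load(path, subjects: list[Subject]) -> "DAGAEResults":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        model = DAGAE(subjects, config=payload["config"])
        nets = Networks.build(payload["config"], payload["train_config"].seed,
                              variant=payload["train_config"].variant)
        nets.load_state_dict(payload["state"])
        return DAGAEResults(model=model, train_config=payload["train_config"],
                            reducer=payload["reducer"], kde=payload["kde"],
                            nets=nets, history=payload["history"])
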