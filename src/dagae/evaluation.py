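"""Leakage-safe cross-validated augmentation studies.

For every fold the full pipeline runs on the four training folds only:
reducer + KDE prior + adversarial training + generation; the classifier is
fitted on original-plus-generated training networks and evaluated on the
held-out fold's *original* networks.  Generated data never enters a test
fold — an assertion guards this.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bfn_io import Subject, five_fold_split
from .classifiers import (GCNClassifier, dnn_fit, dnn_predict, svm_fit,
                          svm_predict)
from .metrics import MetricsReport, compute_metrics
from .model import DAGAE
from .networks import ModelConfig
from .training import TrainConfig

__all__ = ["CVResult", "cv_experiment", "k_sweep", "ablation_run"]

_ABLATION_VARIANTS = ("full", "no_encoder", "no_discriminator",
                      "no_classifier", "no_DU", "no_CT")


@dataclass
class CVResult:
    """Per-fold reports plus their mean for one experimental arm."""

    folds: list[MetricsReport]
    classifier: str
    augmented: bool

    @property
    def mean_acc(self) -> float:
        return float(np.mean([f.ACC for f in self.folds]))

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean([f.AUC for f in self.folds]))

    def table(self) -> pd.DataFrame:
        rows = [{"fold": i, "ACC": f.ACC, "SEN": f.SEN, "SPE": f.SPE,
                 "AUC": f.AUC} for i, f in enumerate(self.folds)]
        df = pd.DataFrame(rows).set_index("fold")
        df.loc["mean"] = df.mean()
        return df


def _fit_predict(tag: str, orig_nets, orig_labels, gen_nets, gen_labels,
                 test_nets, seed, n_rois, classifier_epochs):
    """Fit a classifier head and score the test networks.

    The graph-convolutional head pretrains on the original training set and
    fine-tunes on the original-plus-generated mixture (same epoch budget per
    stage); SVM/DNN fit the union jointly.
    """
    all_nets = list(orig_nets) + list(gen_nets)
    all_labels = np.concatenate([orig_labels, gen_labels]) if len(gen_labels) \
        else np.asarray(orig_labels)
    if tag == "gcn":
        clf = GCNClassifier(n_rois=n_rois, seed=seed,
                            epochs=classifier_epochs)
        clf.fit(orig_nets, orig_labels)
        if len(gen_nets):
            clf.fit(all_nets, all_labels)   # warm-start fine-tuning pass
        proba = clf.predict_proba(test_nets)[:, 1]
        return (proba >= 0.5).astype(int), proba
    if tag == "svm":
        return svm_predict(svm_fit(all_nets, all_labels, seed=seed),
                           test_nets)
    if tag == "dnn":
        return dnn_predict(dnn_fit(all_nets, all_labels, seed=seed),
                           test_nets)
    raise ValueError(f"unknown classifier {tag!r}")


def cv_experiment(subjects: list[Subject], classifier: str = "gcn",
                  config: ModelConfig | None = None,
                  train_config: TrainConfig | None = None,
                  augmenter: str = "dagae", k: float | None = None,
                  folds_seed: int = 0, classifier_epochs: int = 1000,
                  n_folds: int = 5,
                  _trained_cache: dict | None = None) -> CVResult:
    """Cross-validated classification with (or without) augmentation.

    ``augmenter`` is ``"dagae"`` or ``"none"`` (plain CV baseline).
    ``_trained_cache`` maps fold index -> fitted ``DAGAEResults`` so sweeps
    can reuse one adversarial training per fold.
    """
    if augmenter not in ("dagae", "none"):
        raise ValueError(f"unknown augmenter {augmenter!r}")
    tc = train_config or TrainConfig()
    folds = five_fold_split(subjects, seed=folds_seed, n_folds=n_folds)
    reports = []
    for fold_idx, test_idx in enumerate(folds):
        test_set = set(test_idx)
        train_subjects = [s for i, s in enumerate(subjects) if i not in test_set]
        test_subjects = [subjects[i] for i in test_idx]

        orig_nets = [s.A_ori for s in train_subjects]
        orig_labels = np.array([s.y for s in train_subjects])
        gen_nets, gen_labels = [], []
        if augmenter == "dagae":
            if _trained_cache is not None and fold_idx in _trained_cache:
                res = _trained_cache[fold_idx]
            else:
                res = DAGAE(train_subjects, config=config).fit(tc)
                if _trained_cache is not None:
                    _trained_cache[fold_idx] = res
            # leakage guard: augmentation saw only training subjects
            train_ids = {s.id for s in res.model.subjects}
            assert not train_ids & {s.id for s in test_subjects}, \
                "test subject leaked into augmentation input"
            for gen in res.augment(k=k, seed=tc.seed + fold_idx):
                gen_nets.append(gen.matrix)
                gen_labels.append(gen.y)

        preds, scores = _fit_predict(
            classifier, orig_nets, orig_labels, gen_nets,
            np.asarray(gen_labels), [s.A_ori for s in test_subjects], tc.seed,
            subjects[0].A_ori.shape[0], classifier_epochs)
        reports.append(compute_metrics(preds, [s.y for s in test_subjects],
                                       scores))
    return CVResult(folds=reports, classifier=classifier,
                    augmented=augmenter == "dagae")


def k_sweep(subjects: list[Subject], k_values, classifier: str = "gcn",
            config: ModelConfig | None = None,
            train_config: TrainConfig | None = None, folds_seed: int = 0,
            classifier_epochs: int = 1000, n_folds: int = 5) -> pd.DataFrame:
    """DeltaACC(k) = ACC with k-times augmentation minus the plain-CV ACC.

    One adversarial training per fold is shared across all k values.
    DeltaACC need not be monotone in k — large augmentation factors can
    degrade accuracy.
    """
    base = cv_experiment(subjects, classifier=classifier, config=config,
                         train_config=train_config, augmenter="none",
                         folds_seed=folds_seed,
                         classifier_epochs=classifier_epochs, n_folds=n_folds)
    cache: dict = {}
    rows = []
    for k in k_values:
        if k == 0:
            rows.append({"k": 0, "ACC": base.mean_acc, "DeltaACC": 0.0})
            continue
        arm = cv_experiment(subjects, classifier=classifier, config=config,
                            train_config=train_config, augmenter="dagae",
                            k=k, folds_seed=folds_seed,
                            classifier_epochs=classifier_epochs,
                            n_folds=n_folds, _trained_cache=cache)
        rows.append({"k": k, "ACC": arm.mean_acc,
                     "DeltaACC": arm.mean_acc - base.mean_acc})
    return pd.DataFrame(rows).set_index("k")


def ablation_run(subjects: list[Subject], variant: str,
                 classifier: str = "gcn", config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None, folds_seed: int = 0,
                 classifier_epochs: int = 1000, n_folds: int = 5) -> CVResult:
    """Cross-validated run of a reduced model.

    ``no_DU``/``no_CT`` reshape the generator; ``no_encoder``,
    ``no_discriminator``, ``no_classifier`` drop the corresponding loss
    terms / update steps from the alternating optimization.
    """
    if variant not in _ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose from {_ABLATION_VARIANTS}")
    tc = replace(train_config or TrainConfig(), variant=variant)
    return cv_experiment(subjects, classifier=classifier, config=config,
                         train_config=tc, augmenter="dagae",
                         folds_seed=folds_seed,
                         classifier_epochs=classifier_epochs, n_folds=n_folds)
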