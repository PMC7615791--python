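"""Downstream classifiers for augmentation benefit studies.

Three heads mirror common practice in connectome classification:

* ``GCNClassifier`` — two graph-convolution layers (32 and 16 hidden units),
  mean graph pooling and a two-unit softmax layer; node features are the
  rows of the network itself (connectivity profiles), since generated
  networks carry no time series.
* ``svm_fit``/``svm_predict`` — RBF support-vector machine with probability
  calibration on vectorized upper-triangle edges.
* ``dnn_fit``/``dnn_predict`` — feed-forward perceptron (128 -> 32 -> 2) on
  the same edge vectors.
"""

from __future__ import annotations

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import losses
from .metrics import vectorize_upper
from .networks import Module, _glorot, _zeros, gcn_layer
from .nn import Adam, Tensor, matmul, softmax

__all__ = ["GCNClassifier", "svm_fit", "svm_predict", "dnn_fit", "dnn_predict"]


class GCNClassifier(Module):
    """Graph-convolutional classifier over weighted networks."""

    def __init__(self, n_rois: int, hidden: tuple[int, int] = (32, 16),
                 seed: int = 0, lr: float = 1e-4, epochs: int = 1000,
                 batch_size: int = 16, dtype: str = "float32"):
        super().__init__()
        self.n_rois = n_rois
        self.hidden = hidden
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        self.seed = seed
        dt = np.dtype(dtype)
        self.dtype = dt
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6C]))
        h1, h2 = hidden
        self.add_param("w1", _glorot(rng, n_rois, h1, (n_rois, h1), dt))
        self.add_param("b1", _zeros((h1,), dt))
        self.add_param("w2", _glorot(rng, h1, h2, (h1, h2), dt))
        self.add_param("b2", _zeros((h2,), dt))
        self.add_param("w3", _glorot(rng, h2, 2, (h2, 2), dt))
        self.add_param("b3", _zeros((2,), dt))

    def forward(self, a: Tensor) -> Tensor:
        """a: (..., N, N) networks; returns class probabilities (..., 2)."""
        x = gcn_layer(a, a, self._params["w1"], "relu", self._params["b1"])
        x = gcn_layer(a, x, self._params["w2"], "relu", self._params["b2"])
        pooled = x.mean(axis=-2)                      # graph mean pooling
        logits = matmul(pooled, self._params["w3"]) + self._params["b3"]
        return softmax(logits, axis=-1)

    def fit(self, networks: list[np.ndarray], labels: np.ndarray) -> "GCNClassifier":
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("training set contains a single class")
        a_all = np.stack(networks).astype(self.dtype)
        y_all = np.eye(2, dtype=self.dtype)[labels]
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x6D]))
        opt = Adam(self.parameters(), lr=self.lr)
        n = len(networks)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                probs = self.forward(Tensor(a_all[idx]))
                loss = losses.loss_cla(probs, y_all[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict_proba(self, networks: list[np.ndarray]) -> np.ndarray:
        a = np.stack(networks).astype(self.dtype)
        return np.asarray(self.forward(Tensor(a)).data, dtype=float)

    def predict(self, networks: list[np.ndarray]) -> np.ndarray:
        return self.predict_proba(networks).argmax(axis=1)


def svm_fit(networks, labels, seed: int = 0) -> SVC:
    x = vectorize_upper(networks)
    clf = SVC(kernel="rbf", probability=True, random_state=seed)
    return clf.fit(x, np.asarray(labels))


def svm_predict(clf: SVC, networks) -> tuple[np.ndarray, np.ndarray]:
    x = vectorize_upper(networks)
    proba = clf.predict_proba(x)[:, list(clf.classes_).index(1)]
    return (proba >= 0.5).astype(int), proba


def dnn_fit(networks, labels, seed: int = 0, max_iter: int = 500) -> MLPClassifier:
    x = vectorize_upper(networks)
    clf = MLPClassifier(hidden_layer_sizes=(128, 32), random_state=seed,
                        max_iter=max_iter)
    return clf.fit(x, np.asarray(labels))


def dnn_predict(clf: MLPClassifier, networks) -> tuple[np.ndarray, np.ndarray]:
    x = vectorize_upper(networks)
    proba = clf.predict_proba(x)[:, list(clf.classes_).index(1)]
    return (proba >= 0.5).astype(int), proba
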