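"""Prediction metrics, weighted graph statistics and 2-D embedding.

Prediction metrics follow the confusion-count convention of the two-class
dementia setting: class 1 (patient, LMCI) is the positive class, with

* TL — patients correctly predicted, TN — controls correctly predicted,
* FN — controls incorrectly predicted, FL — patients incorrectly predicted,
* ACC = (TL+TN)/(TL+TN+FL+FN), SEN = TL/(TL+FN), SPE = TN/(TN+FL),

and AUC computed from predicted class-1 probabilities by the rank
(Mann-Whitney) formulation.  Degenerate denominators yield NaN (undefined),
never a silent 0.

Graph statistics are computed on absolute edge weights with a zero diagonal
(strengths and efficiencies are undefined for signed weights): Onnela
weighted clustering, node strength, Brandes betweenness on 1/weight
distances, Louvain modularity, and Latora-Marchiori global/local efficiency
on 1/weight distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.stats import rankdata

__all__ = ["MetricsReport", "compute_metrics", "GraphMetricProfile",
           "graph_metrics", "embed_2d", "vectorize_upper"]


# ------------------------------------------------------------ prediction

@dataclass
class MetricsReport:
    ACC: float
    SEN: float
    SPE: float
    AUC: float
    TL: int
    TN: int
    FL: int
    FN: int


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of class-1 scores; NaN when one class is absent."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def compute_metrics(predictions: np.ndarray, labels: np.ndarray,
                    scores: np.ndarray | None = None) -> MetricsReport:
    """Confusion counts and ACC/SEN/SPE (+AUC when scores given)."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    tl = int(((predictions == 1) & (labels == 1)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    fn = int(((predictions == 1) & (labels == 0)).sum())
    fl = int(((predictions == 0) & (labels == 1)).sum())
    auc = auc_rank(scores, labels) if scores is not None else float("nan")
    return MetricsReport(
        ACC=_ratio(tl + tn, tl + tn + fl + fn),
        SEN=_ratio(tl, tl + fn),
        SPE=_ratio(tn, tn + fl),
        AUC=auc, TL=tl, TN=tn, FL=fl, FN=fn,
    )


# ----------------------------------------------------------- graph metrics

@dataclass
class GraphMetricProfile:
    clustering: float
    strength: float
    betweenness: float
    modularity: float
    local_efficiency: float
    global_efficiency: float

    def as_array(self) -> np.ndarray:
        return np.array([self.clustering, self.strength, self.betweenness,
                         self.modularity, self.local_efficiency,
                         self.global_efficiency])

    FIELDS = ("clustering", "strength", "betweenness", "modularity",
              "local_efficiency", "global_efficiency")


def _efficiency_from_weights(w: np.ndarray) -> float:
    """Mean inverse shortest-path length on 1/weight distances."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(dist, 0.0)
    d = shortest_path(dist, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def graph_metrics(a: np.ndarray, seed: int = 0) -> GraphMetricProfile:
    """Six weighted statistics of one network (absolute weights, zero diag)."""
    a = np.asarray(a, dtype=float)
    w = np.abs(0.5 * (a + a.T))
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    if w.max() == 0.0:
        warnings.warn("all-zero network; metrics are zero", stacklevel=2)
        return GraphMetricProfile(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    g = nx.from_numpy_array(w)
    for _, _, data in g.edges(data=True):
        data["distance"] = 1.0 / data["weight"]

    clustering = float(nx.average_clustering(g, weight="weight"))
    strength = float(w.sum(axis=1).mean())
    bc = nx.betweenness_centrality(g, weight="distance", normalized=False)
    betweenness = float(np.mean(list(bc.values())))
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    modularity = float(nx.community.modularity(g, communities, weight="weight"))
    global_eff = _efficiency_from_weights(w)
    local = []
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            local.append(0.0)
            continue
        local.append(_efficiency_from_weights(w[np.ix_(nbrs, nbrs)]))
    return GraphMetricProfile(
        clustering=clustering, strength=strength, betweenness=betweenness,
        modularity=modularity, local_efficiency=float(np.mean(local)),
        global_efficiency=global_eff,
    )


# -------------------------------------------------------------- embedding

def vectorize_upper(matrices) -> np.ndarray:
    """Stack strict upper triangles: (n_networks, N(N-1)/2) features."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    n = mats[0].shape[0]
    iu = np.triu_indices(n, k=1)
    return np.stack([m[iu] for m in mats])


def embed_2d(matrices, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """t-SNE embedding of vectorized networks, for qualitative overlap plots."""
    from sklearn.manifold import TSNE

    x = vectorize_upper(matrices)
    if x.shape[0] < 5:
        raise ValueError("need at least 5 networks to embed")
    if perplexity is None:
        perplexity = min(30.0, (x.shape[0] - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(x)
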