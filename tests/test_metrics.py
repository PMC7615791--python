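"""Prediction metrics and weighted graph statistics against hand arithmetic
and exhaustive brute-force oracles (graphs of <= 8 nodes)."""

from itertools import combinations, permutations

import numpy as np
import pytest

from dagae.metrics import (GraphMetricProfile, compute_metrics, embed_2d,
                           graph_metrics, vectorize_upper, auc_rank)

# ----------------------------------------------------------------- oracles


def oracle_shortest(w):
    """All-pairs weighted shortest paths by exhaustive simple-path search.

    Returns dists and the list of optimal paths per pair (for betweenness).
    """
    n = w.shape[0]
    nodes = range(n)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    best_paths = {}
    for s, t in combinations(nodes, 2):
        paths = []
        # all simple paths from s to t
        others = [v for v in nodes if v not in (s, t)]
        for r in range(len(others) + 1):
            for mid in permutations(others, r):
                path = (s, *mid, t)
                if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                    length = sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
                    paths.append((length, path))
        if paths:
            d = min(p[0] for p in paths)
            dist[s, t] = dist[t, s] = d
            best_paths[(s, t)] = [p for l, p in paths if abs(l - d) < 1e-12]
    return dist, best_paths


def oracle_efficiency(w):
    n = w.shape[0]
    if n < 2:
        return 0.0
    dist, _ = oracle_shortest(w)
    inv = [1.0 / dist[i, j] for i in range(n) for j in range(n)
           if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0]
    return sum(inv) / (n * (n - 1))


def oracle_betweenness(w):
    n = w.shape[0]
    _, best = oracle_shortest(w)
    bc = np.zeros(n)
    for (s, t), paths in best.items():
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    return bc


def oracle_clustering(w):
    """Onnela geometric-mean triangle intensity, hat-weights w / max(w)."""
    n = w.shape[0]
    w_hat = w / w.max()
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and w[j, h] > 0:
                    total += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        cs.append(total / (k * (k - 1)))
    return np.mean(cs)


def oracle_modularity(w, labels):
    m2 = w.sum()  # = 2m
    k = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / m2
    return q / m2


def all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [[first] + block] + part[i + 1:]
        yield [[first]] + part


def random_weighted(n, seed, density=0.7):
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.1, 1.0, (n, n))
    mask = rng.uniform(size=(n, n)) < density
    w = np.triu(w * mask, k=1)
    w = w + w.T
    return w


# ------------------------------------------------------- prediction metrics


class TestPredictionMetrics:
    def test_hand_confusion_table(self):
        # counts TL=12, FN=3, TN=13, FL=2 -> SEN 0.8000, SPE 0.8667, ACC 0.8333
        labels = np.array([1] * 12 + [0] * 3 + [0] * 13 + [1] * 2)
        preds = np.array([1] * 12 + [1] * 3 + [0] * 13 + [0] * 2)
        r = compute_metrics(preds, labels)
        assert (r.TL, r.FN, r.TN, r.FL) == (12, 3, 13, 2)
        assert r.SEN == pytest.approx(0.8000, abs=1e-9)
        assert r.SPE == pytest.approx(13 / 15, abs=1e-9)
        assert r.ACC == pytest.approx(25 / 30, abs=1e-9)

    def test_all_correct(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        r = compute_metrics(labels, labels, scores)
        assert r.ACC == r.SEN == r.SPE == r.AUC == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 40)
        preds = rng.integers(0, 2, 40)
        r = compute_metrics(preds, labels)
        r_swap = compute_metrics(1 - preds, 1 - labels)
        assert r.SEN == pytest.approx(r_swap.SPE)
        assert r.SPE == pytest.approx(r_swap.SEN)
        assert r.ACC == pytest.approx(r_swap.ACC)

    def test_degenerate_denominator_is_nan_not_zero(self):
        r = compute_metrics(np.array([0, 0]), np.array([0, 0]))
        assert np.isnan(r.SEN)  # no predicted patients at all
        assert r.SPE == 1.0

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 60)
        scores = rng.uniform(size=60)
        assert auc_rank(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


# ------------------------------------------------------------ graph metrics


class TestGraphMetricOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances_match_brute_force(self, seed):
        w = random_weighted(6, seed)
        prof = graph_metrics(w + np.eye(6))  # diag is zeroed internally
        assert prof.clustering == pytest.approx(oracle_clustering(w), abs=1e-8)
        assert prof.strength == pytest.approx(w.sum(axis=1).mean(), abs=1e-8)
        assert prof.betweenness == pytest.approx(
            oracle_betweenness(w).mean(), abs=1e-8)
        assert prof.global_efficiency == pytest.approx(
            oracle_efficiency(w), abs=1e-8)
        # local efficiency: oracle on each neighborhood subgraph
        loc = []
        for i in range(6):
            nbrs = np.flatnonzero(w[i] > 0)
            loc.append(oracle_efficiency(w[np.ix_(nbrs, nbrs)])
                       if nbrs.size >= 2 else 0.0)
        assert prof.local_efficiency == pytest.approx(np.mean(loc), abs=1e-8)

    def test_modularity_value_matches_formula_on_found_partition(self):
        import networkx as nx

        w = random_weighted(7, 5)
        g = nx.from_numpy_array(w)
        comms = nx.community.louvain_communities(g, weight="weight", seed=0)
        labels = np.empty(7, dtype=int)
        for ci, block in enumerate(comms):
            for v in block:
                labels[v] = ci
        prof = graph_metrics(w, seed=0)
        assert prof.modularity == pytest.approx(
            oracle_modularity(w, labels), abs=1e-8)

    def test_two_cliques_modularity_found_by_exhaustive_search(self):
        # two disconnected 4-cliques: optimal partition is the cliques, Q = 0.5
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 1.0
        def labels_of(part):
            lab = [0] * 8
            for ci, blk in enumerate(part):
                for v in blk:
                    lab[v] = ci
            return lab

        best_q = max(oracle_modularity(w, labels_of(part))
                     for part in all_partitions(list(range(8))))
        assert best_q == pytest.approx(0.5, abs=1e-12)
        prof = graph_metrics(w)
        assert prof.modularity == pytest.approx(0.5, abs=1e-8)

    def test_complete_graph_unit_weights(self):
        w = 1.0 - np.eye(5)
        prof = graph_metrics(w)
        assert prof.clustering == pytest.approx(1.0, abs=1e-12)
        assert prof.global_efficiency == pytest.approx(1.0, abs=1e-12)
        assert prof.strength == pytest.approx(4.0, abs=1e-12)

    def test_star_center_betweenness(self):
        # 5-node star: center lies on all 6 leaf-pair shortest paths
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        bc = oracle_betweenness(w)
        assert bc[0] == pytest.approx(6.0)
        prof = graph_metrics(w)
        assert prof.betweenness == pytest.approx(6.0 / 5.0, abs=1e-8)

    def test_all_zero_matrix_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="all-zero"):
            prof = graph_metrics(np.zeros((4, 4)))
        assert prof.as_array().tolist() == [0.0] * 6

    def test_absolute_weight_convention(self):
        w = random_weighted(5, 7)
        signs = np.sign(np.random.default_rng(8).standard_normal((5, 5)))
        signs = np.triu(signs, 1) + np.triu(signs, 1).T + np.eye(5)
        prof_signed = graph_metrics(w * signs)
        prof_abs = graph_metrics(w)
        np.testing.assert_allclose(prof_signed.as_array(), prof_abs.as_array(),
                                   atol=1e-12)


# --------------------------------------------------------------- embedding


class TestEmbedding:
    def _nets(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            m = rng.uniform(-1, 1, (6, 6))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 1.0)
            out.append(m)
        return out

    def test_row_count_and_determinism(self):
        nets = self._nets()
        e1 = embed_2d(nets, seed=4)
        e2 = embed_2d(nets, seed=4)
        assert e1.shape == (12, 2)
        np.testing.assert_array_equal(e1, e2)

    def test_duplicates_map_close(self):
        nets = self._nets(8)
        coords = embed_2d(nets + nets, seed=1)
        span = np.linalg.norm(coords.max(0) - coords.min(0))
        for i in range(8):
            d = np.linalg.norm(coords[i] - coords[i + 8])
            assert d < 0.1 * span

    def test_vectorize_upper_length(self):
        nets = [np.eye(90)]
        assert vectorize_upper(nets).shape == (1, 4005)

    def test_too_few_networks_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            embed_2d(self._nets(3))
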