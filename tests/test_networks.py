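"""Architecture contracts of the four networks."""

import numpy as np
import pytest

from dagae.bfn_io import pearson_bfn
from dagae.networks import (Classifier, Discriminator, GraphEncoder,
                            ModelConfig, TransformerGenerator, attention,
                            _split_heads, _merge_heads, ct_layer_forward,
                            gcn_layer, normalize_adjacency)
from dagae.nn import Tensor


def cfg64(**over):
    base = dict(n_rois=6, n_timepoints=10, latent_dim=4, enc_hidden=8,
                cla_hidden=(12, 10, 8, 6), ct_heads=(2, 2, 2), du_dims=(6, 10),
                dtype="float64")
    base.update(over)
    return ModelConfig(**base)


class TestGCNLayer:
    def test_isolated_nodes_reduce_to_dense_layer(self):
        # zero off-diagonal with unit diagonal: degrees |A|+1 = 2, and
        # (A + I) has diagonal 2, so Ahat = I exactly
        a = np.eye(4)
        x = np.random.default_rng(0).standard_normal((4, 3))
        w = np.random.default_rng(1).standard_normal((3, 5))
        out = gcn_layer(a, x, w, "linear")
        np.testing.assert_allclose(out.data, x @ w, atol=1e-12)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((3, 7))
        a = pearson_bfn(f)
        x = rng.standard_normal((3, 4))
        w = rng.standard_normal((4, 2))
        # brute-force: build Ahat elementwise, then triple-loop the products
        deg = [sum(abs(a[i, j]) for j in range(3)) + 1 for i in range(3)]
        ahat = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ahat[i, j] = (a[i, j] + (1.0 if i == j else 0.0)) / np.sqrt(
                    deg[i] * deg[j])
        expected = np.zeros((3, 2))
        for i in range(3):
            for k in range(2):
                expected[i, k] = sum(ahat[i, j] * x[j, m] * w[m, k]
                                     for j in range(3) for m in range(4))
        out = gcn_layer(a, x, w, "linear")
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        a = pearson_bfn(rng.standard_normal((5, 9)))
        x = rng.standard_normal((5, 4))
        w = rng.standard_normal((4, 3))
        perm = rng.permutation(5)
        p = np.eye(5)[perm]
        out = gcn_layer(a, x, w, "relu").data
        out_p = gcn_layer(p @ a @ p.T, p @ x, w, "relu").data
        np.testing.assert_allclose(out_p, p @ out, atol=1e-10)

    def test_asymmetric_adjacency_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            gcn_layer(a, np.ones((3, 2)), np.ones((2, 2)))


class TestEncoder:
    def test_output_shape_and_tanh_range(self):
        cfg = ModelConfig()  # default 90 x 187, p=32
        rng = np.random.default_rng(0)
        enc = GraphEncoder(cfg, rng)
        f = rng.standard_normal((90, 187)).astype(np.float32)
        a = pearson_bfn(f).astype(np.float32)
        h = enc.forward(Tensor(a), Tensor(f))
        assert h.shape == (90, 32)
        assert np.abs(h.data).max() < 1.0

    def test_zero_weights_give_zero_codes(self):
        cfg = cfg64()
        enc = GraphEncoder(cfg, np.random.default_rng(0))
        for p in enc.parameters():
            p.data = np.zeros_like(p.data)
        rng = np.random.default_rng(1)
        f = rng.standard_normal((6, 10))
        h = enc.forward(Tensor(pearson_bfn(f)), Tensor(f))
        np.testing.assert_array_equal(h.data, 0.0)


class TestDiscriminator:
    def test_zero_weights_output_half(self):
        cfg = cfg64()
        dis = Discriminator(cfg, np.random.default_rng(0))
        for p in dis.parameters():
            p.data = np.zeros_like(p.data)
        m = np.random.default_rng(1).standard_normal((6, 4))
        assert dis.forward(Tensor(m)).item() == pytest.approx(0.5)

    def test_output_bounded_for_random_inputs(self):
        cfg = cfg64()
        for seed in range(10):
            dis = Discriminator(cfg, np.random.default_rng(seed))
            m = np.random.default_rng(seed + 100).standard_normal((3, 6, 4))
            out = dis.forward(Tensor(m)).data
            assert out.shape == (3,)
            assert (out >= 0).all() and (out <= 1).all()

    def test_hand_computed_two_roi_forward(self):
        cfg = ModelConfig(n_rois=2, n_timepoints=10, latent_dim=1,
                          dis_hidden=(1, 1), cla_hidden=(4, 4, 4, 4),
                          ct_heads=(1, 1, 1), du_dims=(2, 10), dtype="float64")
        dis = Discriminator(cfg, np.random.default_rng(0))
        # sub-network i: sigmoid(relu(relu(x * w1) * w2) * w3), hand-set
        dis.w1.data = np.array([[[2.0]], [[1.0]]])
        dis.w2.data = np.array([[[1.0]], [[-1.0]]])
        dis.w3.data = np.array([[[0.5]], [[3.0]]])
        for b in (dis.b1, dis.b2, dis.b3):
            b.data = np.zeros_like(b.data)
        m = np.array([[1.0], [2.0]])
        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))
        row0 = sig(max(max(1.0 * 2.0, 0) * 1.0, 0) * 0.5)      # sigmoid(1)
        row1 = sig(max(max(2.0 * 1.0, 0) * -1.0, 0) * 3.0)     # sigmoid(0)
        expected = 0.5 * (row0 + row1)
        assert dis.forward(Tensor(m)).item() == pytest.approx(expected, rel=1e-12)

    def test_wrong_row_count_rejected(self):
        dis = Discriminator(cfg64(), np.random.default_rng(0))
        with pytest.raises(ValueError, match="rows"):
            dis.forward(Tensor(np.ones((5, 4))))


class TestClassifier:
    def test_softmax_properties_and_uniform_at_zero_head(self):
        cfg = cfg64()
        cla = Classifier(cfg, np.random.default_rng(0))
        last = cla.depth - 1
        cla._params[f"w{last}"].data = np.zeros_like(cla._params[f"w{last}"].data)
        cla._params[f"b{last}"].data = np.zeros_like(cla._params[f"b{last}"].data)
        h = np.random.default_rng(1).standard_normal((3, 6, 4))
        out = cla.forward(Tensor(h)).data
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_probabilities_sum_to_one(self):
        cfg = cfg64()
        cla = Classifier(cfg, np.random.default_rng(5))
        h = np.random.default_rng(2).standard_normal((4, 6, 4))
        out = cla.forward(Tensor(h)).data
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-12)
        assert (out > 0).all() and (out < 1).all()

    def test_five_layers(self):
        cla = Classifier(ModelConfig(), np.random.default_rng(0))
        assert cla.depth == 5


class TestTransformer:
    def test_attention_oracle_two_tokens(self):
        # identity Q,K,V: attention weights are softmax(M M^T / sqrt(d_head))
        m = np.array([[1.0, 0.0], [0.5, -0.5]])
        q = _split_heads(Tensor(m), 1)
        out, w = attention(q, q, q)
        scores = m @ m.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        expected = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w.data[0], expected, atol=1e-12)
        np.testing.assert_allclose(out.data[0], expected @ m, atol=1e-12)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        q = Tensor(rng.standard_normal((2, 3, 5, 4)))
        _, w = attention(q, q, q)
        np.testing.assert_allclose(w.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_single_token_attention_is_identity_weight(self):
        rng = np.random.default_rng(1)
        q = Tensor(rng.standard_normal((1, 1, 4)))
        out, w = attention(q, q, q)
        np.testing.assert_allclose(w.data, 1.0)
        np.testing.assert_allclose(out.data, q.data)

    def test_ct_layer_preserves_shape_and_heads_divisibility(self):
        cfg = cfg64()
        gen = TransformerGenerator(cfg, np.random.default_rng(0))
        m = Tensor(np.random.default_rng(1).standard_normal((6, 4)))
        out = gen._ct(0, m)
        assert out.shape == (6, 4)
        with pytest.raises(ValueError, match="divide"):
            params = {k[4:]: v for k, v in gen._params.items()
                      if k.startswith("ct0_")}
            ct_layer_forward(params, m, heads=3)

    def test_head_split_merge_round_trip(self):
        x = Tensor(np.arange(24.0).reshape(2, 3, 4))
        back = _merge_heads(_split_heads(x, 2))
        np.testing.assert_array_equal(back.data, x.data)

    def test_generated_network_contracts(self):
        cfg = cfg64()
        gen = TransformerGenerator(cfg, np.random.default_rng(0))
        m = Tensor(np.random.default_rng(2).standard_normal((6, 4)))
        a = gen.forward(m).data
        np.testing.assert_array_equal(a, a.T)
        np.testing.assert_array_equal(np.diag(a), 1.0)
        off = a[~np.eye(6, dtype=bool)]
        assert (np.abs(off) < 1.0).all()

    def test_default_head_divisibility_and_build_error(self):
        cfg = ModelConfig()
        assert cfg.latent_dim % cfg.ct_heads[0] == 0
        assert cfg.du_dims[0] % cfg.ct_heads[1] == 0
        assert cfg.du_dims[1] % cfg.ct_heads[2] == 0
        with pytest.raises(ValueError, match="divide"):
            ModelConfig(latent_dim=30)  # not a multiple of 4 heads

    def test_no_ct_variant_is_two_affine_layers(self):
        cfg = cfg64()
        gen = TransformerGenerator(cfg, np.random.default_rng(0), variant="no_CT")
        assert set(gen._params) == {"du0_w", "du0_b", "du1_w", "du1_b"}

    def test_no_du_variant_keeps_constant_width(self):
        cfg = cfg64()
        gen = TransformerGenerator(cfg, np.random.default_rng(0), variant="no_DU")
        m = Tensor(np.random.default_rng(1).standard_normal((6, 4)))
        assert gen.node_map(m).shape == (6, 4)


class TestComposition:
    def test_encode_generate_valid_over_many_seeds(self):
        cfg = cfg64()
        rng_data = np.random.default_rng(0)
        f = rng_data.standard_normal((6, 10))
        a_ori = pearson_bfn(f)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            enc = GraphEncoder(cfg, rng)
            gen = TransformerGenerator(cfg, rng)
            h = enc.forward(Tensor(a_ori), Tensor(f))
            a = gen.forward(h).data
            assert np.isfinite(a).all()
            assert np.abs(a - a.T).max() == 0.0
            assert np.abs(a).max() <= 1.0
            np.testing.assert_array_equal(np.diag(a), 1.0)
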