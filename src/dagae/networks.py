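"""The four networks of the adversarial graph autoencoder.

* ``GraphEncoder`` — two graph-convolution layers (T -> 64 -> p) with ReLU
  then tanh, mapping (A_ori, F) to latent node codes H in (-1, 1)^{N x p}.
* ``Discriminator`` — N independent per-ROI sub-networks (p -> 32 -> 64 -> 1,
  sigmoid); its output is the mean of the N sub-network outputs, judging
  whether a latent matrix row-wise resembles the KDE prior.
* ``Classifier`` — a five-layer perceptron on the flattened codes with a
  two-way softmax head, keeping the codes class-discriminative.
* ``TransformerGenerator`` — three connectivity-transformer (multi-head
  self-attention over the N node tokens) layers interleaved with two
  dimension-upscaling affine layers (p -> 64 -> T); connectivity is predicted
  by the scaled inner product tanh(M' M'^T / d) with the diagonal forced
  to 1.

Graph convolution uses Kipf-style symmetric normalization with self-loops;
degrees are computed from |A| because Pearson weights are signed and signed
degrees can make the D^{-1/2} scaling undefined, while the signed A is kept
in the propagation product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, concat, layer_norm, matmul, softmax

__all__ = [
    "ModelConfig", "GraphEncoder", "Discriminator",
    "ConditionalDiscriminator", "Classifier",
    "TransformerGenerator", "gcn_layer", "normalize_adjacency",
    "ct_layer_forward", "attention",
]

_SYM_TOL = 1e-8


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults follow the 90-ROI, 187-point
    resting-state setting with latent width p = 32."""

    n_rois: int = 90
    n_timepoints: int = 187
    latent_dim: int = 32
    enc_hidden: int = 64
    dis_hidden: tuple[int, int] = (32, 64)
    cla_hidden: tuple[int, ...] = (1024, 256, 64, 16)
    ct_heads: tuple[int, int, int] = (4, 8, 11)
    du_dims: tuple[int, int] = (64, 187)
    dtype: str = "float32"

    def __post_init__(self):
        dims = (self.latent_dim, self.du_dims[0], self.du_dims[1])
        for d, h in zip(dims, self.ct_heads):
            if d % h != 0:
                raise ValueError(
                    f"head count {h} must divide its transformer width {d}"
                )

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple, dtype) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(dtype),
                  requires_grad=True)


def _zeros(shape, dtype) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def _ones(shape, dtype) -> Tensor:
    return Tensor(np.ones(shape, dtype=dtype), requires_grad=True)


class Module:
    """Minimal parameter container."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def add_param(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self._params[k].data = np.asarray(v, dtype=self._params[k].data.dtype)


# --------------------------------------------------------------------- GCN

def normalize_adjacency(a: Tensor) -> Tensor:
    """Â = D̃^{-1/2} (A + I) D̃^{-1/2}; D̃ from row sums of |A| + I."""
    n = a.shape[-1]
    eye = np.eye(n, dtype=a.data.dtype)
    deg = a.abs().sum(axis=-1, keepdims=True) + 1.0
    dinv = deg ** -0.5
    return (a + eye) * dinv * dinv.swap_last()


def gcn_layer(a: Tensor | np.ndarray, x: Tensor | np.ndarray,
              w: Tensor | np.ndarray, activation: str = "relu",
              bias: Tensor | None = None) -> Tensor:
    """One graph-convolution layer: activation(Â x w [+ bias])."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    x = x if isinstance(x, Tensor) else Tensor(x)
    w = w if isinstance(w, Tensor) else Tensor(w)
    if np.abs(a.data - np.swapaxes(a.data, -1, -2)).max() > _SYM_TOL:
        raise ValueError("adjacency is not symmetric within tolerance")
    out = matmul(matmul(normalize_adjacency(a), x), w)
    if bias is not None:
        out = out + bias
    if activation == "relu":
        return out.relu()
    if activation == "tanh":
        return out.tanh()
    if activation == "linear":
        return out
    raise ValueError(f"unknown activation {activation!r}")


class GraphEncoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dt = cfg.np_dtype
        t, h, p = cfg.n_timepoints, cfg.enc_hidden, cfg.latent_dim
        self.w1 = self.add_param("w1", _glorot(rng, t, h, (t, h), dt))
        self.b1 = self.add_param("b1", _zeros((h,), dt))
        self.w2 = self.add_param("w2", _glorot(rng, h, p, (h, p), dt))
        self.b2 = self.add_param("b2", _zeros((p,), dt))

    def forward(self, a: Tensor, f: Tensor) -> Tensor:
        x = gcn_layer(a, f, self.w1, "relu", self.b1)
        return gcn_layer(a, x, self.w2, "tanh", self.b2)


class Discriminator(Module):
    """N per-ROI sub-networks; sub-network i consumes only row i."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dt = cfg.np_dtype
        n, p = cfg.n_rois, cfg.latent_dim
        h1, h2 = cfg.dis_hidden
        self.n_rois = n
        self.w1 = self.add_param("w1", _glorot(rng, p, h1, (n, p, h1), dt))
        self.b1 = self.add_param("b1", _zeros((n, 1, h1), dt))
        self.w2 = self.add_param("w2", _glorot(rng, h1, h2, (n, h1, h2), dt))
        self.b2 = self.add_param("b2", _zeros((n, 1, h2), dt))
        self.w3 = self.add_param("w3", _glorot(rng, h2, 1, (n, h2, 1), dt))
        self.b3 = self.add_param("b3", _zeros((n, 1, 1), dt))

    def forward(self, m: Tensor) -> Tensor:
        """m: (..., N, p) -> mean sub-network output, shape (...,)."""
        if m.shape[-2] != self.n_rois:
            raise ValueError(f"expected {self.n_rois} rows, got {m.shape[-2]}")
        # ROI-major layout: one GEMM per ROI over the whole batch
        unbatched = m.ndim == 2
        if unbatched:
            m = m.reshape(1, *m.shape)
        x = m.transpose(1, 0, 2)                             # (N, B, p)
        x = (matmul(x, self.w1) + self.b1).relu()
        x = (matmul(x, self.w2) + self.b2).relu()
        x = (matmul(x, self.w3) + self.b3).sigmoid()         # (N, B, 1)
        out = x.reshape(self.n_rois, -1).mean(axis=0)        # (B,)
        return out.reshape(()) if unbatched else out


class ConditionalDiscriminator(Module):
    """Class-conditioned per-ROI discriminator: each sub-network receives
    the sample's class label (+-1 coded) as one extra input feature.

    A label-blind discriminator can only match the class *mixture* of
    encoder codes to the prior, leaving the per-class mode pairing
    unidentified — class-conditional generation then fails or inverts.
    Conditioning the judge on the label enforces alignment of each
    conditional distribution separately, at unchanged capacity.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dt = cfg.np_dtype
        n, p = cfg.n_rois, cfg.latent_dim
        h1, h2 = cfg.dis_hidden
        self.n_rois = n
        self.w1 = self.add_param("w1", _glorot(rng, p + 1, h1, (n, p + 1, h1), dt))
        self.b1 = self.add_param("b1", _zeros((n, 1, h1), dt))
        self.w2 = self.add_param("w2", _glorot(rng, h1, h2, (n, h1, h2), dt))
        self.b2 = self.add_param("b2", _zeros((n, 1, h2), dt))
        self.w3 = self.add_param("w3", _glorot(rng, h2, 1, (n, h2, 1), dt))
        self.b3 = self.add_param("b3", _zeros((n, 1, 1), dt))

    def forward(self, m: Tensor, labels: np.ndarray) -> Tensor:
        """m: (B, N, p), labels: (B,) in {0, 1} -> per-sample outputs (B,)."""
        labels = np.asarray(labels)
        unbatched = m.ndim == 2
        if unbatched:
            m = m.reshape(1, *m.shape)
            labels = np.atleast_1d(labels)
        code = (2.0 * labels - 1.0).astype(m.data.dtype)     # (B,)
        tag = np.broadcast_to(code[:, None, None],
                              (m.shape[0], m.shape[1], 1)).astype(m.data.dtype)
        x = concat([m, Tensor(tag)], axis=-1)                # (B, N, p+1)
        x = x.transpose(1, 0, 2)                             # (N, B, p+1)
        x = (matmul(x, self.w1) + self.b1).relu()
        x = (matmul(x, self.w2) + self.b2).relu()
        x = (matmul(x, self.w3) + self.b3).sigmoid()         # (N, B, 1)
        out = x.reshape(self.n_rois, -1).mean(axis=0)
        return out.reshape(()) if unbatched else out


class Classifier(Module):
    """Five-layer perceptron on flattened codes, two-way softmax output."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        dt = cfg.np_dtype
        widths = (cfg.n_rois * cfg.latent_dim,) + tuple(cfg.cla_hidden) + (2,)
        self.widths = widths
        for i, (din, dout) in enumerate(zip(widths[:-1], widths[1:])):
            self.add_param(f"w{i}", _glorot(rng, din, dout, (din, dout), dt))
            self.add_param(f"b{i}", _zeros((dout,), dt))
        self.depth = len(widths) - 1

    def forward(self, h: Tensor) -> Tensor:
        """h: (..., N, p) -> class probabilities (..., 2)."""
        x = h.reshape(*h.shape[:-2], h.shape[-2] * h.shape[-1])
        for i in range(self.depth):
            x = matmul(x, self._params[f"w{i}"]) + self._params[f"b{i}"]
            if i < self.depth - 1:
                x = x.relu()
        return softmax(x, axis=-1)


# ------------------------------------------------------------- transformer

def attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention over node tokens.

    q, k, v: (..., heads, N, d_head).  Returns (output, attention weights);
    weight rows sum to 1.
    """
    d_head = q.shape[-1]
    scores = matmul(q, k.swap_last()) * (1.0 / np.sqrt(d_head))
    weights = softmax(scores, axis=-1)
    return matmul(weights, v), weights


def _split_heads(x: Tensor, heads: int) -> Tensor:
    *lead, n, d = x.shape
    x = x.reshape(*lead, n, heads, d // heads)
    axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    return x.transpose(*axes)                       # (..., heads, N, d_head)


def _merge_heads(x: Tensor) -> Tensor:
    *lead, h, n, dh = x.shape
    axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    return x.transpose(*axes).reshape(*lead, n, h * dh)


def ct_layer_forward(params: dict[str, Tensor], m: Tensor, heads: int) -> Tensor:
    """Connectivity-transformer layer: pre-norm multi-head self-attention
    with a residual connection; output shape equals input shape."""
    d = m.shape[-1]
    if d % heads != 0:
        raise ValueError(f"head count {heads} must divide width {d}")
    normed = layer_norm(m, params["ln_g"], params["ln_b"])
    q = _split_heads(matmul(normed, params["wq"]) + params["bq"], heads)
    k = _split_heads(matmul(normed, params["wk"]) + params["bk"], heads)
    v = _split_heads(matmul(normed, params["wv"]) + params["bv"], heads)
    out, _ = attention(q, k, v)
    out = matmul(_merge_heads(out), params["wo"]) + params["bo"]
    return m + out


class TransformerGenerator(Module):
    """CT1 -> DU1 -> CT2 -> DU2 -> CT3 -> inner-product connectivity head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 variant: str = "full"):
        super().__init__()
        if variant not in ("full", "no_DU", "no_CT"):
            raise ValueError(f"unknown generator variant {variant!r}")
        self.variant = variant
        dt = cfg.np_dtype
        p = cfg.latent_dim
        if variant == "no_DU":
            dims = (p, p, p)
            heads = tuple(h if p % h == 0 else max(
                hh for hh in range(1, h + 1) if p % hh == 0)
                for h in cfg.ct_heads)
        else:
            dims = (p, cfg.du_dims[0], cfg.du_dims[1])
            heads = cfg.ct_heads
        self.dims, self.heads = dims, heads
        if variant != "no_CT":
            for i, d in enumerate(dims):
                self._add_ct(f"ct{i}", d, rng, dt)
        if variant != "no_DU":
            self.add_param("du0_w", _glorot(rng, dims[0], dims[1],
                                            (dims[0], dims[1]), dt))
            self.add_param("du0_b", _zeros((dims[1],), dt))
            self.add_param("du1_w", _glorot(rng, dims[1], dims[2],
                                            (dims[1], dims[2]), dt))
            self.add_param("du1_b", _zeros((dims[2],), dt))

    def _add_ct(self, prefix: str, d: int, rng, dt) -> None:
        self.add_param(f"{prefix}_ln_g", _ones((d,), dt))
        self.add_param(f"{prefix}_ln_b", _zeros((d,), dt))
        for nm in ("wq", "wk", "wv", "wo"):
            self.add_param(f"{prefix}_{nm}", _glorot(rng, d, d, (d, d), dt))
            self.add_param(f"{prefix}_b{nm[1]}", _zeros((d,), dt))

    def _ct(self, i: int, m: Tensor) -> Tensor:
        pre = f"ct{i}_"
        params = {k[len(pre):]: v for k, v in self._params.items()
                  if k.startswith(pre)}
        return ct_layer_forward(params, m, self.heads[i])

    def _du(self, i: int, m: Tensor) -> Tensor:
        out = matmul(m, self._params[f"du{i}_w"]) + self._params[f"du{i}_b"]
        return out.relu()

    def node_map(self, m: Tensor) -> Tensor:
        """Latent codes (..., N, p) -> connection embeddings (..., N, d_out)."""
        if self.variant == "no_CT":
            return self._du(1, self._du(0, m))
        x = self._ct(0, m)
        if self.variant == "no_DU":
            return self._ct(2, self._ct(1, x))
        return self._ct(2, self._du(1, self._ct(1, self._du(0, x))))

    def forward(self, m: Tensor) -> Tensor:
        """Latent codes -> network: tanh(M' M'^T / sqrt(d)) with unit diagonal.

        The inner product is scaled by the embedding width d, i.e. the head
        predicts the mean elementwise product of the two node embeddings.
        This keeps predicted connectivity intensive (independent of d) and
        the tanh in its sensitive range: raw inner products of d-dimensional
        rows grow linearly with d (the upstream ReLU makes embeddings
        positive-mean, so terms do not cancel), which otherwise saturates
        the tanh at initialization and freezes the generator's gradients.
        """
        mp = self.node_map(m)
        scale = 1.0 / mp.shape[-1]
        a = (matmul(mp, mp.swap_last()) * scale).tanh()
        n = a.shape[-1]
        eye = np.eye(n, dtype=a.data.dtype)
        return a * (1.0 - eye) + eye
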