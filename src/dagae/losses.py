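"""Objective terms of the adversarial graph autoencoder.

Conventions: discriminator outputs are probabilities in (0, 1), clamped to
(eps, 1 - eps) before any logarithm; the classifier term is the standard
negative log-likelihood (cross-entropy), minimized; reconstruction and
node-representation-consistency terms are mean elementwise L1 distances.
"""

from __future__ import annotations

from .nn import Tensor

__all__ = ["loss_enc", "loss_dis", "loss_cla", "loss_rec", "loss_nrc", "EPS"]

EPS = 1e-7


def _clamp(p: Tensor) -> Tensor:
    return p.clip(EPS, 1.0 - EPS)


def loss_enc(d_fake: Tensor) -> Tensor:
    """Encoder's adversarial term: mean log(1 - D(H)); minimized when the
    discriminator is fooled (D(H) -> 1)."""
    return (1.0 - _clamp(d_fake)).log().mean()


def loss_dis(d_fake: Tensor, d_real: Tensor) -> Tensor:
    """Discriminator term: mean of -log(1 - D(H)) - log(D(X)); minimized
    when fakes score 0 and prior samples score 1."""
    fake = -(1.0 - _clamp(d_fake)).log()
    real = -_clamp(d_real).log()
    return fake.mean() + real.mean()


def loss_cla(probs: Tensor, y_onehot: Tensor) -> Tensor:
    """Cross-entropy of predicted class probabilities against one-hot labels."""
    ll = (Tensor._coerce(y_onehot) * _clamp(probs).log()).sum(axis=-1)
    return -ll.mean()


def loss_rec(a_ori: Tensor, a_rec: Tensor) -> Tensor:
    """Mean elementwise |A_ori - A_rec| (L1 normalized by element count)."""
    return (Tensor._coerce(a_ori) - a_rec).abs().mean()


def loss_nrc(h: Tensor, h_hat: Tensor) -> Tensor:
    """Node-representation consistency: mean |H - E(G(H))|."""
    return (h_hat - h).abs().mean()
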