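"""Alternating adversarial optimization and class-conditional augmentation.

Each iteration first takes ``t_dis`` discriminator steps (real = latent
matrices sampled from the class-matched KDE prior, fake = encoder codes of
the batch subjects; both streams kernel-smoothed with the prior's
bandwidth), then one pass updating encoder, classifier and generator on
the adversarial-encoder, cross-entropy, reconstruction and
node-representation-consistency terms.  Under the default ``staged``
scheme the encoder is driven by the adversarial and classification terms
(plus the consistency re-encoding) while reconstruction shapes the
generator on detached codes — encoder and discriminator/classifier first,
generator second; ``joint`` additionally feeds reconstruction gradients to
the encoder.  The discriminator is excluded from these updates and vice
versa.  Training runs a fixed number of epochs for determinism;
convergence (discriminator outputs near 0.5, stable total loss) is
reported post hoc from the history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import losses
from .bfn_io import Subject, validate_bfn
from .kde import LabelKDE, sample_matrix
from .networks import (Classifier, ConditionalDiscriminator, GraphEncoder,
                       ModelConfig, TransformerGenerator)
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "Networks", "train_dagae", "augment", "GeneratedBFN"]

HISTORY_COLUMNS = ["L_enc", "L_dis", "L_cla", "L_rec", "L_nrc",
                   "d_real", "d_fake"]


@dataclass
class TrainConfig:
    """Optimization settings (Adam throughout)."""

    epochs: int = 500
    t_dis: int = 1
    batch_size: int = 16
    lr_enc: float = 1e-3
    lr_dis: float = 1e-4
    lr_cla: float = 1e-4
    lr_gen: float = 1e-4
    k: float = 1.0
    seed: int = 0
    loss_weights: dict = field(default_factory=lambda: {
        "enc": 1.0, "cla": 1.0, "rec": 1.0, "nrc": 1.0})
    update_scheme: str = "staged"   # staged: encoder driven by the
                            # adversarial + classification terms, generator
                            # by reconstruction + consistency; joint:
                            # encoder also receives rec/nrc gradients
    variant: str = "full"   # full | no_DU | no_CT | no_encoder |
                            # no_discriminator | no_classifier

    def __post_init__(self):
        for name in ("lr_enc", "lr_dis", "lr_cla", "lr_gen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.t_dis < 1:
            raise ValueError("t_dis must be >= 1")
        if self.update_scheme not in ("staged", "joint"):
            raise ValueError(f"unknown update_scheme {self.update_scheme!r}")


@dataclass
class Networks:
    """The four parameterized networks plus their architecture config."""

    config: ModelConfig
    encoder: GraphEncoder
    discriminator: ConditionalDiscriminator
    classifier: Classifier
    generator: TransformerGenerator

    @classmethod
    def build(cls, config: ModelConfig, seed: int,
              variant: str = "full") -> "Networks":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11]))
        gen_variant = variant if variant in ("no_DU", "no_CT") else "full"
        return cls(
            config=config,
            encoder=GraphEncoder(config, rng),
            discriminator=ConditionalDiscriminator(config, rng),
            classifier=Classifier(config, rng),
            generator=TransformerGenerator(config, rng, variant=gen_variant),
        )

    def state_dict(self) -> dict:
        return {
            "encoder": self.encoder.state_dict(),
            "discriminator": self.discriminator.state_dict(),
            "classifier": self.classifier.state_dict(),
            "generator": self.generator.state_dict(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.encoder.load_state_dict(state["encoder"])
        self.discriminator.load_state_dict(state["discriminator"])
        self.classifier.load_state_dict(state["classifier"])
        self.generator.load_state_dict(state["generator"])


def _bandwidth_rows(kde: LabelKDE, y: int) -> np.ndarray:
    """Per-row smoothing bandwidths of the class-``y`` prior, shape (N, 1)."""
    if kde.mode == "per_roi":
        return np.asarray(kde.bandwidth[y])[:, None]
    return np.full((1, 1), float(kde.bandwidth[y]))


def _batch_arrays(subjects: list[Subject], idx: np.ndarray, dtype):
    a = np.stack([subjects[i].A_ori for i in idx]).astype(dtype)
    f = np.stack([subjects[i].F for i in idx]).astype(dtype)
    y = np.stack([subjects[i].y_onehot for i in idx]).astype(dtype)
    labels = np.array([subjects[i].y for i in idx])
    return a, f, y, labels


def train_dagae(subjects: list[Subject], kde: LabelKDE, config: ModelConfig,
                train_config: TrainConfig,
                nets: Networks | None = None) -> tuple[Networks, pd.DataFrame]:
    """Run the alternating optimization; returns networks and history.

    The KDE prior must have been fitted on these (training) subjects only —
    augmentation leakage into any test fold is the caller's responsibility
    to avoid, and the evaluation harness enforces it.
    """
    tc = train_config
    variant = tc.variant
    if variant not in ("full", "no_DU", "no_CT", "no_encoder",
                       "no_discriminator", "no_classifier"):
        raise ValueError(f"unknown variant {variant!r}")
    if nets is None:
        nets = Networks.build(config, tc.seed, variant=variant)
    dtype = config.np_dtype
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 0x22]))

    # one optimizer per learning rate, acting on disjoint parameter sets
    opt_dis = Adam(nets.discriminator.parameters(), lr=tc.lr_dis)
    opt_enc = Adam(nets.encoder.parameters(), lr=tc.lr_enc)
    opt_cla = Adam(nets.classifier.parameters(), lr=tc.lr_cla)
    opt_gen = Adam(nets.generator.parameters(), lr=tc.lr_gen)

    w = tc.loss_weights
    use_adv = variant != "no_discriminator"
    use_enc_loss = use_adv and variant != "no_encoder" and w["enc"] != 0
    use_cla = variant != "no_classifier" and w["cla"] != 0

    n = len(subjects)
    history = []
    for _epoch in range(tc.epochs):
        order = rng.permutation(n)
        sums = np.zeros(len(HISTORY_COLUMNS))
        n_batches = 0
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            a_np, f_np, y_np, labels = _batch_arrays(subjects, idx, dtype)
            a, f = Tensor(a_np), Tensor(f_np)

            # the encoder does not change during the discriminator steps, so
            # one forward pass serves both phases of the iteration
            h = nets.encoder.forward(a, f)

            d_real_val = d_fake_val = l_dis_val = np.nan
            if use_adv:
                # both streams receive the same kernel smoothing: the game
                # then compares the kernel-density estimates of the code and
                # label distributions, and the discriminator cannot memorize
                # the finite set of (deterministic) encoder codes
                bw = np.stack([_bandwidth_rows(kde, int(lab))
                               for lab in labels]).astype(dtype)   # (B, N, 1)
                h_det = h.detach()
                for _ in range(tc.t_dis):
                    x_np = np.stack([
                        sample_matrix(kde, int(lab), config.n_rois, rng,
                                      variance_corrected=False)
                        for lab in labels]).astype(dtype)
                    fake_np = h_det.data + bw * rng.standard_normal(
                        h_det.shape).astype(dtype)
                    d_fake = nets.discriminator.forward(Tensor(fake_np), labels)
                    d_real = nets.discriminator.forward(Tensor(x_np), labels)
                    l_dis = losses.loss_dis(d_fake, d_real)
                    opt_dis.zero_grad()
                    l_dis.backward()
                    opt_dis.step()
                d_real_val = float(d_real.data.mean())
                d_fake_val = float(d_fake.data.mean())
                l_dis_val = l_dis.item()

            # joint update of encoder, classifier, generator
            total = None
            l_enc_val = l_cla_val = np.nan
            if use_enc_loss:
                smooth = Tensor(bw * rng.standard_normal(h.shape).astype(dtype))
                l_enc = losses.loss_enc(
                    nets.discriminator.forward(h + smooth, labels))
                total = w["enc"] * l_enc
                l_enc_val = l_enc.item()
            if use_cla:
                l_cla = losses.loss_cla(nets.classifier.forward(h), y_np)
                total = w["cla"] * l_cla if total is None else total + w["cla"] * l_cla
                l_cla_val = l_cla.item()
            # staged scheme: reconstruction/consistency shape the generator
            # only, so the encoder is free to settle onto the prior
            h_for_gen = h.detach() if tc.update_scheme == "staged" else h
            a_rec = nets.generator.forward(h_for_gen)
            l_rec = losses.loss_rec(a, a_rec)
            h_hat = nets.encoder.forward(a_rec, f)
            l_nrc = losses.loss_nrc(h_for_gen, h_hat)
            rest = w["rec"] * l_rec + w["nrc"] * l_nrc
            total = rest if total is None else total + rest

            for opt in (opt_enc, opt_cla, opt_gen):
                opt.zero_grad()
            for p_ in nets.discriminator.parameters():
                p_.grad = None  # D receives gradients here but is never stepped
            total.backward()
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    "non-finite joint loss; aborting with last-good parameters")
            for opt in (opt_enc, opt_cla, opt_gen):
                opt.step()

            sums += np.array([l_enc_val, l_dis_val, l_cla_val, l_rec.item(),
                              l_nrc.item(), d_real_val, d_fake_val])
            n_batches += 1
        history.append(sums / n_batches)
    hist = pd.DataFrame(history, columns=HISTORY_COLUMNS)
    hist.index.name = "epoch"
    return nets, hist


@dataclass
class GeneratedBFN:
    """A synthetic network with its class label."""

    matrix: np.ndarray
    y: int

    @property
    def y_onehot(self) -> np.ndarray:
        return np.array([1.0, 0.0]) if self.y == 0 else np.array([0.0, 1.0])


def augment(nets: Networks, kde: LabelKDE, n_train_per_class: dict[int, int],
            k: float, seed: int) -> list[GeneratedBFN]:
    """Generate round(k * n_train_class) networks per class from the prior."""
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x33]))
    dtype = nets.config.np_dtype
    out = []
    for y in sorted(n_train_per_class):
        n_gen = int(round(k * n_train_per_class[y]))
        if n_gen == 0:
            continue
        x = np.stack([sample_matrix(kde, y, nets.config.n_rois, rng)
                      for _ in range(n_gen)]).astype(dtype)
        a_gen = nets.generator.forward(Tensor(x)).data
        for i in range(n_gen):
            mat = np.asarray(a_gen[i], dtype=float)
            mat = 0.5 * (mat + mat.T)            # exact symmetry after float32
            np.fill_diagonal(mat, 1.0)
            validate_bfn(mat, tol=1e-6)
            out.append(GeneratedBFN(matrix=mat, y=y))
    return out
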