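"""Conditional Wasserstein GAN with gradient penalty for scalogram augmentation.

The generator maps a latent vector concatenated with a one-hot class label
(102 input channels for latent dimension 100 and two labels) through five
transposed-convolution stages — channel sequence 102-256-128-64-32-16 with
kernel/stride pairs (3,2),(3,2),(5,3),(3,3),(3,2) — to a 139x139 feature
map, then through a 1x1 projection convolution and a saturating activation
affinely mapped to [0,1], and finally a bilinear resize to the working image
size. The critic applies two strided convolutions (1-128-256, kernel 4,
stride 2), adaptively average-pools to a 2x2 grid so the flattened feature
width is exactly 1024 for any input size, concatenates the one-hot label,
and scores through 1026-64-1 linear layers.

Training follows the WGAN-GP recipe: five critic updates (RMSprop) per
generator update (Adam), critic loss ``mean D(fake) - mean D(real) +
lambda * mean (||grad_xhat D(xhat)|| - 1)^2`` with ``xhat`` drawn uniformly
on segments between real and fake samples. The penalty value uses an exact
backward pass to the input; its parameter gradient is accumulated with a
central finite-difference Hessian-vector product (two extra weighted
backward passes along the detached unit gradient direction), so only
first-order machinery is ever required.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    AdaptiveAvgPool2d,
    Adam,
    BatchNorm2d,
    BilinearResize,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Flatten,
    Layer,
    LeakyReLU,
    Linear,
    ReLU,
    RMSprop,
    Sequential,
    Tanh,
)
from .types import LeakageError, REAL, SYNTHETIC, Scalogram

_BACKBONE_OUT = 139  # five tabulated stages expand a 1x1 latent to 139x139


@dataclass
class GanTrainConfig:
    epochs: int = 151
    batch_size: int = 32
    lr_generator: float = 8e-5
    lr_critic: float = 6.7e-6
    critic_steps_per_gen: int = 5
    latent_dim: int = 100
    n_labels: int = 2
    gp_lambda: float = 10.0
    seed: int = 0
    image_size: int = 200
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "critic_steps_per_gen", "latent_dim",
                     "n_labels", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gp_lambda < 0:
            raise ValueError("gp_lambda must be non-negative")


class _AffineToUnit(Layer):
    """Map the saturating (-1, 1) activation output affinely onto [0, 1]."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return 0.5 * (x + 1.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return 0.5 * dout


def one_hot(labels: np.ndarray, n_labels: int) -> np.ndarray:
    out = np.zeros((len(labels), n_labels))
    out[np.arange(len(labels)), np.asarray(labels, dtype=int)] = 1.0
    return out


class Generator:
    """Label-conditioned scalogram generator."""

    def __init__(self, config: GanTrainConfig, rng: np.random.Generator) -> None:
        self.config = config
        c_in = config.latent_dim + config.n_labels
        self.net = Sequential([
            ConvTranspose2d(c_in, 256, 3, 2, rng), BatchNorm2d(256), ReLU(),
            ConvTranspose2d(256, 128, 3, 2, rng), BatchNorm2d(128), ReLU(),
            ConvTranspose2d(128, 64, 5, 3, rng), BatchNorm2d(64), ReLU(),
            ConvTranspose2d(64, 32, 3, 3, rng), BatchNorm2d(32), ReLU(),
            ConvTranspose2d(32, 16, 3, 2, rng), Tanh(),
            Conv2d(16, 1, 1, 1, rng), Tanh(), _AffineToUnit(),
            BilinearResize((_BACKBONE_OUT, _BACKBONE_OUT),
                           (config.image_size, config.image_size)),
        ])

    @property
    def first_stage_in_channels(self) -> int:
        return self.net.layers[0].params["W"].shape[0]

    def forward(self, z: np.ndarray, labels_onehot: np.ndarray,
                train: bool = False) -> np.ndarray:
        x = np.concatenate([z, labels_onehot], axis=1)[:, :, None, None]
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


class Critic:
    """Label-conditioned Wasserstein critic producing one unbounded score."""

    def __init__(self, config: GanTrainConfig, rng: np.random.Generator) -> None:
        self.config = config
        self.conv = Sequential([
            Conv2d(1, 128, 4, 2, rng), BatchNorm2d(128), LeakyReLU(0.2),
            Conv2d(128, 256, 4, 2, rng), BatchNorm2d(256), LeakyReLU(0.2),
            AdaptiveAvgPool2d((2, 2)), Flatten(),
        ])
        self.head = Sequential([
            Linear(256 * 2 * 2 + config.n_labels, 64, rng), LeakyReLU(0.2),
            Dropout(config.dropout_p, rng), Linear(64, 1, rng),
        ])
        min_size = 2 * 2 + 2 + 2 + 2  # two k4/s2 convs must leave >= 2x2
        if config.image_size < min_size:
            raise ValueError(f"image_size must be at least {min_size}")

    def forward(self, images: np.ndarray, labels_onehot: np.ndarray,
                train: bool = False) -> np.ndarray:
        feat = self.conv.forward(images, train)
        self._n_feat = feat.shape[1]
        scores = self.head.forward(np.concatenate([feat, labels_onehot], axis=1), train)
        return scores[:, 0]

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        dcat = self.head.backward(np.asarray(dscores)[:, None])
        return self.conv.backward(dcat[:, : self._n_feat])

    @property
    def flatten_width(self) -> int:
        """Flattened convolutional feature width before label concatenation,
        as measured on the most recent forward pass (1024 by construction)."""
        flat = self.conv.layers[-1]
        if flat.last_width is None:
            probe = np.zeros((1, 1, self.config.image_size, self.config.image_size))
            self.forward(probe, np.zeros((1, self.config.n_labels)))
        return int(self.conv.layers[-1].last_width)

    # -- helpers used by the gradient penalty ------------------------------
    def score(self, images, labels_onehot, train: bool = False) -> np.ndarray:
        return self.forward(images, labels_onehot, train)

    def input_gradient(self, images, labels_onehot, train: bool = False) -> np.ndarray:
        """Gradient of the summed scores w.r.t. the input images; parameter
        gradients are left untouched."""
        saved = [(g, g.copy()) for seq in (self.conv, self.head)
                 for layer in seq.layers for g in layer.grads.values()]
        scores = self.forward(images, labels_onehot, train)
        dimages = self.backward(np.ones_like(scores))
        for g, snapshot in saved:
            g[...] = snapshot
        return dimages

    def zero_grad(self) -> None:
        self.conv.zero_grad()
        self.head.zero_grad()

    def _seqs(self) -> Tuple[Sequential, Sequential]:
        return self.conv, self.head


def build_generator(config: GanTrainConfig, seed: Optional[int] = None) -> Generator:
    return Generator(config, np.random.default_rng(config.seed if seed is None else seed))


def build_critic(config: GanTrainConfig, seed: Optional[int] = None) -> Critic:
    return Critic(config, np.random.default_rng(config.seed if seed is None else seed))


def interpolate_samples(real: np.ndarray, fake: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """xhat = eps*real + (1-eps)*fake with one uniform eps per sample."""
    eps = rng.random((len(real),) + (1,) * (real.ndim - 1))
    return eps * real + (1.0 - eps) * fake


def gradient_penalty(critic, real_batch: np.ndarray, fake_batch: np.ndarray,
                     labels_onehot: np.ndarray, gp_lambda: float = 10.0,
                     rng: Optional[np.random.Generator] = None,
                     train: bool = False,
                     xhat: Optional[np.ndarray] = None) -> float:
    """WGAN-GP penalty ``lambda * mean_b (||grad_xhat D(xhat_b)|| - 1)^2``.

    ``critic`` is any object with an ``input_gradient(x, labels, train)``
    method returning the per-sample gradient of its summed scores.
    """
    real_batch = np.asarray(real_batch, dtype=float)
    fake_batch = np.asarray(fake_batch, dtype=float)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must have identical shapes")
    if len(labels_onehot) != len(real_batch):
        raise ValueError("labels must align with the batches")
    if xhat is None:
        xhat = interpolate_samples(real_batch, fake_batch,
                                   rng or np.random.default_rng(0))
    g = critic.input_gradient(xhat, labels_onehot, train=train)
    norms = np.sqrt(np.sum(g.reshape(len(g), -1) ** 2, axis=1))
    return float(gp_lambda * np.mean((norms - 1.0) ** 2))


def _accumulate_penalty_param_grads(critic: Critic, xhat: np.ndarray,
                                    labels_onehot: np.ndarray,
                                    gp_lambda: float, h: float = 1e-4) -> float:
    """Add d(penalty)/d(theta) to the critic's gradients and return the
    penalty value.

    With g = grad_x of the summed scores S and per-sample blocks g_b, the
    chain rule gives dP/dtheta = <V, dg/dtheta> for the constant direction
    V with rows 2*lambda*(||g_b||-1)/B * g_b/||g_b||. Since g = grad_x S,
    that inner product is the theta-gradient of the directional derivative
    of S along V, evaluated here by central finite differences: two
    ordinary backward passes at xhat +/- h'*V (h' scaled so the largest
    per-sample step is ``h``). Batch-norm running statistics are frozen and
    dropout masks replayed across the passes so the differenced function is
    smooth; the formulation stays exact under the batch coupling that batch
    norm introduces because the whole batch is perturbed jointly.
    """
    conv, head = critic._seqs()
    for seq in (conv, head):
        seq.set_update_stats(False)
    critic.forward(xhat, labels_onehot, train=True)  # draw dropout masks once
    for seq in (conv, head):
        seq.set_reuse_dropout(True)
    try:
        g = critic.input_gradient(xhat, labels_onehot, train=True)
        flat = g.reshape(len(g), -1)
        norms = np.sqrt(np.sum(flat**2, axis=1))
        penalty = float(gp_lambda * np.mean((norms - 1.0) ** 2))
        safe = np.maximum(norms, 1e-12)
        coef = 2.0 * gp_lambda * (norms - 1.0) / len(g)
        v = (coef / safe)[:, None] * flat
        scale = np.abs(coef).max()
        if scale > 0:
            step = (h / scale) * v.reshape(g.shape)
            for sign in (1.0, -1.0):
                critic.forward(xhat + sign * step, labels_onehot, train=True)
                critic.backward(np.full(len(g), sign * scale / (2.0 * h)))
    finally:
        for seq in (conv, head):
            seq.set_reuse_dropout(False)
            seq.set_update_stats(True)
    return penalty


@dataclass
class GanCheckpoint:
    generator_state: Dict[str, np.ndarray]
    critic_conv_state: Dict[str, np.ndarray]
    critic_head_state: Dict[str, np.ndarray]
    config: GanTrainConfig
    epoch: int
    critic_losses: List[float] = field(default_factory=list)
    generator_losses: List[float] = field(default_factory=list)

    def save(self, path: str) -> None:
        arrays = {}
        for prefix, state in (("gen", self.generator_state),
                              ("cconv", self.critic_conv_state),
                              ("chead", self.critic_head_state)):
            for k, v in state.items():
                arrays[f"{prefix}::{k}"] = v
        meta = json.dumps({"config": asdict(self.config), "epoch": self.epoch,
                           "critic_losses": self.critic_losses,
                           "generator_losses": self.generator_losses})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "GanCheckpoint":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            states = {"gen": {}, "cconv": {}, "chead": {}}
            for key in f.files:
                if key == "__meta__":
                    continue
                prefix, name = key.split("::", 1)
                states[prefix][name] = f[key]
        return cls(
            generator_state=states["gen"],
            critic_conv_state=states["cconv"],
            critic_head_state=states["chead"],
            config=GanTrainConfig(**meta["config"]),
            epoch=meta["epoch"],
            critic_losses=meta["critic_losses"],
            generator_losses=meta["generator_losses"],
        )

    def restore_generator(self) -> Generator:
        gen = build_generator(self.config)
        gen.net.load_state_dict(self.generator_state)
        return gen

    def restore_critic(self) -> Critic:
        critic = build_critic(self.config)
        critic.conv.load_state_dict(self.critic_conv_state)
        critic.head.load_state_dict(self.critic_head_state)
        return critic


def _validate_gan_inputs(scalograms: Sequence[Scalogram], config: GanTrainConfig,
                         train_subjects) -> None:
    labels_seen = set()
    for s in scalograms:
        if s.provenance != REAL:
            raise LeakageError("the GAN trains on real scalograms only")
        if train_subjects is not None and s.subject_id not in train_subjects:
            raise LeakageError(
                f"scalogram of held-out subject {s.subject_id!r} in GAN training set")
        labels_seen.add(s.label)
    missing = set(range(config.n_labels)) - labels_seen
    if missing:
        raise ValueError(f"missing label class(es) {sorted(missing)} in GAN input")


def train_cwgan(scalograms: Sequence[Scalogram], config: GanTrainConfig,
                train_subjects=None) -> GanCheckpoint:
    """Train the conditional WGAN-GP on training-subject scalograms.

    ``train_subjects``, when given, is the allowed subject set from the
    split plan; any scalogram outside it raises :class:`LeakageError`.
    """
    scalograms = list(scalograms)
    _validate_gan_inputs(scalograms, config, train_subjects)
    size = config.image_size
    for s in scalograms:
        if s.pixels.shape != (size, size):
            raise ValueError(
                f"scalogram shape {s.pixels.shape} != configured image size {size}")
    x = np.stack([s.pixels for s in scalograms])[:, None]  # (N, 1, H, W)
    y = np.array([s.label for s in scalograms])

    rng = np.random.default_rng(config.seed)
    gen = build_generator(config, seed=int(rng.integers(2**31)))
    critic = build_critic(config, seed=int(rng.integers(2**31)))
    opt_g = Adam(gen.net, config.lr_generator)
    opt_c = RMSprop(critic.conv, config.lr_critic)
    opt_c_head = RMSprop(critic.head, config.lr_critic)

    n = len(x)
    bs = min(config.batch_size, n)
    critic_losses: List[float] = []
    gen_losses: List[float] = []

    def real_batch():
        idx = rng.choice(n, size=bs, replace=bs > n)
        return x[idx], y[idx]

    def fake_batch(labels):
        z = rng.standard_normal((len(labels), config.latent_dim))
        return gen.forward(z, one_hot(labels, config.n_labels), train=True), z

    steps_per_epoch = max(1, n // (bs * config.critic_steps_per_gen))
    for epoch in range(config.epochs):
        for _ in range(steps_per_epoch):
            for _ in range(config.critic_steps_per_gen):
                xb, yb = real_batch()
                onehot = one_hot(yb, config.n_labels)
                fake, _ = fake_batch(yb)
                critic.zero_grad()
                s_real = critic.forward(xb, onehot, train=True)
                critic.backward(np.full(bs, -1.0 / bs))
                s_fake = critic.forward(fake, onehot, train=True)
                critic.backward(np.full(bs, 1.0 / bs))
                xhat = interpolate_samples(xb, fake, rng)
                gp = _accumulate_penalty_param_grads(
                    critic, xhat, onehot, config.gp_lambda)
                opt_c.step()
                opt_c_head.step()
                critic_losses.append(float(s_fake.mean() - s_real.mean() + gp))
            # one generator step
            _, yb = real_batch()
            onehot = one_hot(yb, config.n_labels)
            gen.net.zero_grad()
            critic.zero_grad()
            fake, _ = fake_batch(yb)
            s = critic.forward(fake, onehot, train=True)
            dfake = critic.backward(np.full(bs, -1.0 / bs))
            gen.backward(dfake)
            opt_g.step()
            gen_losses.append(float(-s.mean()))

    return GanCheckpoint(
        generator_state=gen.net.state_dict(),
        critic_conv_state=critic.conv.state_dict(),
        critic_head_state=critic.head.state_dict(),
        config=config,
        epoch=config.epochs,
        critic_losses=critic_losses,
        generator_losses=gen_losses,
    )


def synthesize(checkpoint: GanCheckpoint, label: int, n: int, seed: int) -> List[Scalogram]:
    """Draw ``n`` synthetic scalograms of the requested label."""
    config = checkpoint.config
    if not (0 <= label < config.n_labels):
        raise ValueError(f"label {label} out of range for {config.n_labels} classes")
    gen = checkpoint.restore_generator()
    rng = np.random.default_rng(seed)
    out: List[Scalogram] = []
    labels = np.full(n, label)
    for start in range(0, n, 64):
        batch_labels = labels[start : start + 64]
        z = rng.standard_normal((len(batch_labels), config.latent_dim))
        images = gen.forward(z, one_hot(batch_labels, config.n_labels), train=False)
        for img in images[:, 0]:
            out.append(Scalogram(pixels=np.clip(img, 0.0, 1.0), label=label,
                                 provenance=SYNTHETIC))
    return out


def augment_training_set(real: Sequence[Scalogram], checkpoint: GanCheckpoint,
                         mode: str = "percent_increase", amount: float = 0.0,
                         seed: int = 0) -> List[Scalogram]:
    """Combine real scalograms with generator output.

    ``percent_increase`` adds ``round(amount/100 * len(real))`` synthetic
    scalograms split evenly across labels; ``balance_to_equal`` first adds
    per-class counts until class totals match, then (if ``amount`` requests
    a larger overall increase) tops both classes up evenly.
    """
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if mode not in ("percent_increase", "balance_to_equal"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    real = list(real)
    n_labels = checkpoint.config.n_labels
    counts = {lbl: sum(1 for s in real if s.label == lbl) for lbl in range(n_labels)}
    add = {lbl: 0 for lbl in range(n_labels)}
    if mode == "percent_increase":
        total = round(amount / 100.0 * len(real))
        add[0] = total // 2
        add[1] = total - total // 2
    else:
        top = max(counts.values())
        for lbl in counts:
            add[lbl] = top - counts[lbl]
        requested = round(amount / 100.0 * len(real))
        extra = requested - sum(add.values())
        if extra > 0:
            add[0] += extra // 2
            add[1] += extra - extra // 2
    combined = list(real)
    for lbl, n_add in add.items():
        if n_add > 0:
            combined.extend(synthesize(checkpoint, lbl, n_add, seed + lbl))
    return combined
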