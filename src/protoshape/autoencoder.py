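"""Convolutional autoencoder on binary object masks.

The encoder half, frozen after training, supplies the shape branch of
the few-shot classifier: a 128x128 binary mask is mapped to the
flattened bottleneck activation. Architecture is a small grid: 3-5
convolutional blocks, with or without max pooling (stride-2 convolution
when pooling is off), mirrored by transposed-convolution blocks and a
sigmoid output. Training minimizes MSE with Adam; reconstruction
quality is scored by SSIM and by Dice on the binarized output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from . import nn

__all__ = [
    "AEConfig", "Autoencoder", "ShapeEncoder", "build", "train",
    "reconstruct", "binarize", "dice", "ssim", "grid_search",
    "save_checkpoint", "load_checkpoint",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AEConfig:
    """Autoencoder architecture + optimization settings.

    `latent_dim` is determined by the bottleneck: with `n_blocks` halvings
    of a 128x128 input and `base_channels * 2**(n_blocks-1)` bottleneck
    channels, the flattened activation has
    channels * (input_size / 2**n_blocks)**2 entries.
    """

    n_blocks: int = 3
    use_pooling: bool = False
    base_channels: int = 4
    input_size: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 20
    epochs: int = 50

    def __post_init__(self):
        if not 3 <= self.n_blocks <= 5:
            raise ValueError("n_blocks must be in 3..5")
        if self.input_size % (2 ** self.n_blocks):
            raise ValueError("input_size must be divisible by 2**n_blocks")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2 ** i for i in range(self.n_blocks))

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // 2 ** self.n_blocks

    @property
    def latent_dim(self) -> int:
        return self.channels[-1] * self.bottleneck_size ** 2


class Autoencoder:
    """Encoder/decoder pair over (N, 1, S, S) mask batches."""

    def __init__(self, config: AEConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        enc = []
        in_ch = 1
        for ch in config.channels:
            if config.use_pooling:
                enc += [nn.Conv2d(in_ch, ch, 3, stride=1, pad=1, rng=rng),
                        nn.ReLU(), nn.MaxPool2d()]
            else:
                enc += [nn.Conv2d(in_ch, ch, 3, stride=2, pad=1, rng=rng),
                        nn.ReLU()]
            in_ch = ch
        dec = []
        rev = list(config.channels[::-1])
        for i, ch in enumerate(rev):
            out_ch = rev[i + 1] if i + 1 < len(rev) else 1
            dec.append(nn.ConvTranspose2d(ch, out_ch, 3, stride=2, pad=1,
                                          output_padding=1, rng=rng))
            dec.append(nn.ReLU() if i + 1 < len(rev) else nn.Sigmoid())
        self.encoder = nn.Sequential(*enc)
        self.decoder = nn.Sequential(*dec)
        self.net = nn.Sequential(self.encoder, self.decoder)

    def n_parameters(self) -> int:
        return sum(p.size for l in self.net.layers() for p in l.params.values())

    def forward(self, x, train=False):
        return self.net.forward(x, train)

    def encode(self, x):
        z = self.encoder.forward(x, train=False)
        return z.reshape(z.shape[0], -1)


def build(config: AEConfig, seed: int = 0) -> Autoencoder:
    """Instantiate the architecture described by `config` (seeded init)."""
    return Autoencoder(config, seed=seed)


# ------------------------------------------------------------------- training

def _as_batch(masks) -> np.ndarray:
    x = np.asarray(masks, dtype=float)
    if x.ndim == 3:
        x = x[:, None]
    return x


def train(masks, config: AEConfig, seed: int = 0, n_steps: int | None = None,
          model: Autoencoder | None = None, dtype=np.float32):
    """Train with Adam on MSE; returns (ShapeEncoder, loss history).

    `n_steps` overrides the epoch budget with a raw step count over the
    full batch (used for capacity checks); otherwise `config.epochs`
    epochs of shuffled `config.batch_size` minibatches are run.
    Training runs in float32 by default; results are deterministic for a
    fixed seed either way.
    """
    x_all = _as_batch(masks).astype(dtype)
    model = model or build(config, seed=seed)
    model.net.astype(dtype)
    opt = nn.Adam(model.net, lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(seed + 1)
    history = []

    def step(xb):
        y = model.forward(xb, train=True)
        diff = y - xb
        loss = float(np.mean(diff ** 2))
        if not np.isfinite(loss):
            raise RuntimeError("autoencoder training diverged (loss is not finite)")
        model.net.backward(2.0 * diff / diff.size)
        opt.step()
        opt.zero_grad()
        return loss

    if n_steps is not None:
        for _ in range(n_steps):
            history.append(step(x_all))
    else:
        n = x_all.shape[0]
        for _ in range(config.epochs):
            order = rng.permutation(n)
            losses = [step(x_all[order[i:i + config.batch_size]])
                      for i in range(0, n, config.batch_size)]
            history.append(float(np.mean(losses)))
    return ShapeEncoder(model), history


class ShapeEncoder:
    """Frozen encoder: mask (or batch of masks) -> flat shape embedding."""

    def __init__(self, model: Autoencoder):
        self.model = model
        self.latent_dim = model.config.latent_dim

    def embed(self, masks) -> np.ndarray:
        x = _as_batch(masks)
        return self.model.encode(x)


# -------------------------------------------------------------------- metrics

def reconstruct(model: Autoencoder, masks) -> np.ndarray:
    """Continuous [0,1] reconstruction of one mask or a batch."""
    x = _as_batch(masks)
    y = model.forward(x, train=False)[:, 0]
    return y if np.asarray(masks).ndim == 3 else y[0]


def binarize(r, threshold: float = 0.5) -> np.ndarray:
    return (np.asarray(r) >= threshold).astype(np.uint8)


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def ssim(a, b) -> float:
    """SSIM with an 11x11 Gaussian window (sigma 1.5), data range 1."""
    return float(structural_similarity(
        np.asarray(a, dtype=float), np.asarray(b, dtype=float),
        win_size=11, gaussian_weights=True, sigma=1.5, data_range=1.0))


def _eval_model(model: Autoencoder, masks) -> tuple[float, float]:
    recon = reconstruct(model, masks)
    ssims = [ssim(m, r) for m, r in zip(np.asarray(masks, dtype=float), recon)]
    dices = [dice(m, binarize(r)) for m, r in zip(masks, recon)]
    return float(np.mean(ssims)), float(np.mean(dices))


# ---------------------------------------------------------------- grid search

def grid_search(train_masks, val_masks, base: AEConfig | None = None,
                blocks=(3, 4, 5), pooling=(False, True), seed: int = 0,
                epochs: int | None = None, epochs_by_cell: dict | None = None):
    """Train every (n_blocks, use_pooling) cell; pick the best by val SSIM.

    Ties are broken in favor of fewer parameters. Returns
    (best AEConfig, report DataFrame with one row per cell).
    """
    base = base or AEConfig()
    rows = []
    for nb in blocks:
        for pool in pooling:
            cfg_kwargs = {**asdict(base), "n_blocks": nb, "use_pooling": pool}
            if epochs is not None:
                cfg_kwargs["epochs"] = epochs
            if epochs_by_cell and (nb, pool) in epochs_by_cell:
                cfg_kwargs["epochs"] = epochs_by_cell[(nb, pool)]
            cfg = AEConfig(**cfg_kwargs)
            model = build(cfg, seed=seed)
            encoder, hist = train(train_masks, cfg, seed=seed, model=model)
            val_ssim, val_dice = _eval_model(model, val_masks)
            rows.append({"n_blocks": nb, "use_pooling": pool,
                         "val_ssim": val_ssim, "val_dice": val_dice,
                         "final_loss": hist[-1],
                         "n_parameters": model.n_parameters()})
            logger.info("grid cell blocks=%d pooling=%s: SSIM %.4f Dice %.4f",
                        nb, pool, val_ssim, val_dice)
    report = pd.DataFrame(rows)
    order = report.sort_values(["val_ssim", "n_parameters"],
                               ascending=[False, True], kind="mergesort")
    best = order.iloc[0]
    best_cfg = AEConfig(**{**asdict(base), "n_blocks": int(best.n_blocks),
                           "use_pooling": bool(best.use_pooling)})
    return best_cfg, report


# ------------------------------------------------------------- serialization

def save_checkpoint(encoder: ShapeEncoder, path) -> None:
    """Single-file checkpoint: parameters + config."""
    model = encoder.model
    state = model.net.state_dict()
    np.savez(path, __config__=json.dumps(asdict(model.config)), **state)


def load_checkpoint(path) -> ShapeEncoder:
    data = np.load(path, allow_pickle=False)
    config = AEConfig(**json.loads(str(data["__config__"])))
    model = build(config, seed=0)
    state = {k: data[k] for k in data.files if k != "__config__"}
    model.net.load_state_dict(state)
    return ShapeEncoder(model)
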