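"""Episodic prototypical meta-learning with a two-branch embedding.

Each coupled sample is embedded by concatenating an image-branch vector
(a CNN backbone applied to the background-removed RGB) with a
mask-branch vector (the frozen shape encoder applied to the binary
mask). Class prototypes are support-embedding means; classification is
nearest prototype under squared Euclidean distance, trained episodically
with cross-entropy over softmax(-d^2) on the query set. Inference is
non-episodic against a fixed, cached support set.

Backbones: `small_cnn` (4 conv blocks, the default for CPU use) and
ResNet-18/50-style residual networks, all built on the NumPy toolkit.
Pretrained weights are not bundled; requesting them raises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .augmentation import FLIP_TAGS, FoldAssignment, apply_transform
from .preprocessing import CoupledSample

__all__ = [
    "EpisodeSpec", "Episode", "TrainConfig", "PrototypeSet", "Prediction",
    "EpisodeError", "build_backbone", "ProtoShapeModel", "group_by_class",
    "sample_episode", "prototypes", "classify", "softmax_scores",
    "episode_loss", "meta_train", "FixedSupportClassifier",
]

logger = logging.getLogger(__name__)


class EpisodeError(ValueError):
    """Raised when an episode cannot be sampled without origin reuse."""


@dataclass(frozen=True)
class EpisodeSpec:
    """K-way H-shot episode with J queries per class (N=K*H, M=K*J)."""

    K: int
    H: int
    J: int = 1

    def __post_init__(self):
        if min(self.K, self.H, self.J) < 1 or self.K < 2:
            raise ValueError("need K >= 2, H >= 1, J >= 1")

    @property
    def N(self) -> int:
        return self.K * self.H

    @property
    def M(self) -> int:
        return self.K * self.J


@dataclass
class Episode:
    support: list[CoupledSample]
    query: list[CoupledSample]

    def check_origin_disjoint(self) -> None:
        s = {x.origin_id for x in self.support}
        q = {x.origin_id for x in self.query}
        if s & q:
            raise EpisodeError(f"support/query share origins: {s & q}")


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "small_cnn"
    pretrained: bool = False
    lr: float = 1e-3
    weight_decay: float = 1e-5
    momentum: float = 0.9
    epochs: int = 50
    lr_decay: float = 0.1
    lr_decay_epoch: int = 30
    episodes_per_epoch: int = 50
    val_episodes: int = 50


@dataclass
class PrototypeSet:
    """Per-class mean embeddings plus the raw support embeddings."""

    classes: np.ndarray            # (K,) sorted class labels
    prototypes: np.ndarray         # (K, D)
    support: dict[int, np.ndarray]  # class -> (H, D)


@dataclass
class Prediction:
    distances: np.ndarray          # squared Euclidean, aligned with classes
    classes: np.ndarray
    label: int
    second: int
    scores: np.ndarray             # softmax(-squared distances)
    reliability: float | None = None
    ts_inverse: float | None = None
    rs_diagnostics: dict = field(default_factory=dict)


# ------------------------------------------------------------------- backbones

def _small_cnn(rng, in_ch=3, channels=(8, 16, 32, 64)):
    layers = []
    for ch in channels:
        layers += [nn.Conv2d(in_ch, ch, 3, stride=1, pad=1, rng=rng),
                   nn.ReLU(), nn.MaxPool2d()]
        in_ch = ch
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers), channels[-1]


def _res_block(rng, in_ch, out_ch, stride):
    body = nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, stride=stride, pad=1, rng=rng), nn.ReLU(),
        nn.Conv2d(out_ch, out_ch, 3, stride=1, pad=1, rng=rng))
    short = None
    if stride != 1 or in_ch != out_ch:
        short = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                        pad=0, rng=rng))
    return nn.Residual(body, short)


def _bottleneck_block(rng, in_ch, mid_ch, stride):
    out_ch = 4 * mid_ch
    body = nn.Sequential(
        nn.Conv2d(in_ch, mid_ch, 1, stride=1, pad=0, rng=rng), nn.ReLU(),
        nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, pad=1, rng=rng), nn.ReLU(),
        nn.Conv2d(mid_ch, out_ch, 1, stride=1, pad=0, rng=rng))
    short = None
    if stride != 1 or in_ch != out_ch:
        short = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                        pad=0, rng=rng))
    return nn.Residual(body, short)


def _resnet(rng, depth: int):
    stem = [nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng), nn.ReLU(),
            nn.MaxPool2d()]
    if depth == 18:
        plan, block, expansion = [(64, 2), (128, 2), (256, 2), (512, 2)], _res_block, 1
    elif depth == 50:
        plan, block, expansion = [(64, 3), (128, 4), (256, 6), (512, 3)], _bottleneck_block, 4
    else:
        raise ValueError("depth must be 18 or 50")
    layers = list(stem)
    in_ch = 64
    for stage, (ch, reps) in enumerate(plan):
        for r in range(reps):
            stride = 2 if (stage > 0 and r == 0) else 1
            layers.append(block(rng, in_ch, ch, stride))
            in_ch = ch * expansion
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers), in_ch


def build_backbone(name: str, seed: int = 0, pretrained: bool = False):
    """Build a named image backbone; returns (net, out_dim)."""
    if pretrained:
        raise ValueError("pretrained backbone weights are not bundled; "
                         "use pretrained=False")
    rng = np.random.default_rng(seed)
    if name == "small_cnn":
        return _small_cnn(rng)
    if name == "resnet18":
        return _resnet(rng, 18)
    if name == "resnet50":
        return _resnet(rng, 50)
    raise ValueError(f"unknown backbone {name!r}")


# ----------------------------------------------------------------------- model

class ProtoShapeModel:
    """Two-branch embedder: CNN on masked RGB ⊕ frozen encoder on the mask.

    `shape_encoder=None` ablates the mask branch (pure ProtoNet on the
    image embedding). Per-channel input normalization statistics are
    estimated from the training fold and stored with the model.
    """

    def __init__(self, backbone: str = "small_cnn", shape_encoder=None,
                 seed: int = 0, pretrained: bool = False, dtype=np.float32):
        self.backbone_name = backbone
        self.net, self.d_img = build_backbone(backbone, seed, pretrained)
        self.net.astype(dtype)
        self.dtype = dtype
        self.shape_encoder = shape_encoder
        self.d_mask = shape_encoder.latent_dim if shape_encoder else 0
        self.norm_mean = np.zeros(3, dtype=dtype)
        self.norm_std = np.ones(3, dtype=dtype)

    @property
    def embedding_dim(self) -> int:
        return self.d_img + self.d_mask

    def fit_normalization(self, samples) -> None:
        px = np.stack([s.rgb for s in samples])  # (n, S, S, 3)
        self.norm_mean = px.mean(axis=(0, 1, 2)).astype(self.dtype)
        self.norm_std = (px.std(axis=(0, 1, 2)) + 1e-8).astype(self.dtype)

    def _image_batch(self, samples) -> np.ndarray:
        x = np.stack([s.rgb for s in samples]).astype(self.dtype)
        x = (x - self.norm_mean) / self.norm_std
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def embed(self, samples, train: bool = False) -> np.ndarray:
        """Concatenated embeddings (n, d_img + d_mask); mask branch frozen."""
        img = self.net.forward(self._image_batch(samples), train=train)
        if self.shape_encoder is None:
            return img.astype(np.float64)
        masks = np.stack([s.mask for s in samples])
        shp = self.shape_encoder.embed(masks)
        return np.concatenate([img, shp], axis=1).astype(np.float64)

    def backward_images(self, grad_embeddings: np.ndarray) -> None:
        """Backprop embedding gradients through the image branch only."""
        g = grad_embeddings[:, :self.d_img].astype(self.dtype)
        self.net.backward(g)


# -------------------------------------------------------------------- episodes

def group_by_class(samples) -> dict[int, list[CoupledSample]]:
    groups: dict[int, list[CoupledSample]] = {}
    for s in samples:
        groups.setdefault(s.class_label, []).append(s)
    return groups


def sample_episode(groups: dict[int, list[CoupledSample]], spec: EpisodeSpec,
                   rng: np.random.Generator, augmented: bool = True) -> Episode:
    """Draw one episode; support and query never share an origin photo.

    `groups` maps class -> coupled originals. When `augmented` is true,
    each drawn origin contributes one random flip x rotation derivative.
    """
    eligible = [c for c, lst in groups.items()
                if len({s.origin_id for s in lst}) >= spec.H + spec.J]
    if len(eligible) < spec.K:
        raise EpisodeError(
            f"only {len(eligible)} classes have >= {spec.H + spec.J} origins; "
            f"need K={spec.K}")
    classes = rng.choice(sorted(eligible), size=spec.K, replace=False)

    def variant(sample):
        if not augmented:
            return sample
        flip = FLIP_TAGS[int(rng.integers(4))]
        rot = int(rng.integers(20))
        return apply_transform(sample, flip, rot)

    support, query = [], []
    for c in classes:
        pool = groups[c]
        origins = sorted({s.origin_id for s in pool})
        chosen = rng.choice(origins, size=spec.H + spec.J, replace=False)
        by_origin = {o: [s for s in pool if s.origin_id == o] for o in chosen}
        for o in chosen[:spec.H]:
            support.append(variant(by_origin[o][int(rng.integers(len(by_origin[o])))]))
        for o in chosen[spec.H:]:
            query.append(variant(by_origin[o][int(rng.integers(len(by_origin[o])))]))
    ep = Episode(support, query)
    ep.check_origin_disjoint()
    return ep


# ------------------------------------------------------------- prototype head

def prototypes(embeddings: np.ndarray, labels) -> PrototypeSet:
    """Arithmetic-mean class prototypes plus raw support embeddings."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    protos = np.stack([embeddings[labels == c].mean(axis=0) for c in classes])
    support = {int(c): embeddings[labels == c] for c in classes}
    return PrototypeSet(classes, protos, support)


def classify(query_emb: np.ndarray, protos: PrototypeSet):
    """Squared Euclidean distances, predicted and second-best labels."""
    diff = protos.prototypes - query_emb[None, :]
    d2 = np.einsum("kd,kd->k", diff, diff)
    order = np.argsort(d2, kind="stable")
    if len(order) > 1 and d2[order[0]] == d2[order[1]]:
        logger.info("classification tie at distance %.3g; kept lowest class "
                    "index", float(d2[order[0]]))
    pred = int(protos.classes[order[0]])
    second = int(protos.classes[order[1]]) if len(order) > 1 else pred
    return d2, pred, second


def softmax_scores(d2: np.ndarray) -> np.ndarray:
    """Class scores = softmax over negative squared distances."""
    z = -d2 - (-d2).max()
    e = np.exp(z)
    return e / e.sum()


def _episode_forward(model: ProtoShapeModel, episode: Episode, train: bool):
    """Loss, accuracy and (if train) gradients wrt all embeddings."""
    ns = len(episode.support)
    emb = model.embed(episode.support + episode.query, train=train)
    s_emb, q_emb = emb[:ns], emb[ns:]
    s_lab = [s.class_label for s in episode.support]
    q_lab = np.asarray([q.class_label for q in episode.query])
    protos = prototypes(s_emb, s_lab)

    diff = q_emb[:, None, :] - protos.prototypes[None, :, :]  # (M, K, D)
    d2 = np.einsum("mkd,mkd->mk", diff, diff)
    z = -d2
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    y = (q_lab[:, None] == protos.classes[None, :]).astype(float)
    loss = float(-(y * np.log(np.clip(p, 1e-12, None))).sum() / len(q_lab))
    acc = float((protos.classes[d2.argmin(axis=1)] == q_lab).mean())
    if not train:
        return loss, acc, None

    # dL/dd2 = (y - p)/M ; d2 -> query and prototype gradients
    gd = (y - p) / len(q_lab)                      # (M, K)
    gq = 2.0 * np.einsum("mk,mkd->md", gd, diff)
    gproto = -2.0 * np.einsum("mk,mkd->kd", gd, diff)
    counts = np.array([(np.asarray(s_lab) == c).sum() for c in protos.classes])
    gs_class = gproto / counts[:, None]
    class_index = {int(c): i for i, c in enumerate(protos.classes)}
    gs = np.stack([gs_class[class_index[l]] for l in s_lab])
    grad = np.concatenate([gs, gq], axis=0)
    return loss, acc, grad


def episode_loss(episode: Episode, model: ProtoShapeModel) -> float:
    """Mean query cross-entropy of softmax(-d^2) for one episode."""
    loss, _, _ = _episode_forward(model, episode, train=False)
    return loss


# ---------------------------------------------------------------- meta-training

def meta_train(originals, fold_assignment: FoldAssignment, config: TrainConfig,
               spec: EpisodeSpec, seed: int = 0, shape_encoder=None,
               folds=None, augmented: bool = True):
    """Episodic training with fold-held-out meta-validation.

    `originals` are coupled originals; augmentation variants are drawn
    on the fly inside episodes. Returns (models per fold, history frame
    with per-epoch mean/STD meta-validation accuracy).
    """
    folds = list(range(fold_assignment.n_folds)) if folds is None else list(folds)
    history, models = [], {}
    for fold in folds:
        train_set = [s for s in originals
                     if fold_assignment.fold_of[s.origin_id] != fold]
        val_set = [s for s in originals
                   if fold_assignment.fold_of[s.origin_id] == fold]
        g_train = group_by_class(train_set)
        g_val = group_by_class(val_set)
        model = ProtoShapeModel(config.backbone, shape_encoder,
                                seed=seed + fold, pretrained=config.pretrained)
        model.fit_normalization(train_set)
        opt = nn.SGD(model.net, lr=config.lr, weight_decay=config.weight_decay,
                     momentum=config.momentum)
        rng = np.random.default_rng(seed * 1000 + fold)
        for epoch in range(config.epochs):
            if epoch == config.lr_decay_epoch:
                opt.lr *= config.lr_decay
            losses = []
            for _ in range(config.episodes_per_epoch):
                ep = sample_episode(g_train, spec, rng, augmented=augmented)
                loss, _, grad = _episode_forward(model, ep, train=True)
                model.backward_images(grad)
                opt.step()
                opt.zero_grad()
                losses.append(loss)
            accs = []
            for _ in range(config.val_episodes):
                ep = sample_episode(g_val, spec, rng, augmented=augmented)
                _, acc, _ = _episode_forward(model, ep, train=False)
                accs.append(acc)
            history.append({"fold": fold, "epoch": epoch,
                            "train_loss": float(np.mean(losses)),
                            "mean_acc": 100.0 * float(np.mean(accs)),
                            "std_acc": 100.0 * float(np.std(accs))})
            logger.info("fold %d epoch %d: loss %.3f val acc %.1f%%",
                        fold, epoch, history[-1]["train_loss"],
                        history[-1]["mean_acc"])
        models[fold] = model
    return models, pd.DataFrame(history)


def save_model(model: ProtoShapeModel, path) -> None:
    """Single-file checkpoint of the image branch + normalization stats.

    The frozen shape encoder is checkpointed separately by the
    autoencoder module and re-attached at load time.
    """
    np.savez(path, __backbone__=model.backbone_name,
             __norm_mean__=model.norm_mean, __norm_std__=model.norm_std,
             **model.net.state_dict())


def load_model(path, shape_encoder=None) -> ProtoShapeModel:
    data = np.load(path, allow_pickle=False)
    model = ProtoShapeModel(str(data["__backbone__"]), shape_encoder, seed=0)
    model.net.load_state_dict(
        {k: data[k] for k in data.files if not k.startswith("__")})
    model.norm_mean = data["__norm_mean__"]
    model.norm_std = data["__norm_std__"]
    return model


# -------------------------------------------------------------------- inference

class FixedSupportClassifier:
    """Non-episodic inference against a fixed, cached support set."""

    def __init__(self, model: ProtoShapeModel, support: list[CoupledSample]):
        self.model = model
        emb = model.embed(support, train=False)
        self.protos = prototypes(emb, [s.class_label for s in support])

    def predict(self, sample: CoupledSample, with_reliability: bool = False,
                rs_tol: float = 0.005, rs_max_samples: int = 8192,
                seed: int = 0) -> Prediction:
        q = self.model.embed([sample], train=False)[0]
        d2, pred, second = classify(q, self.protos)
        out = Prediction(d2, self.protos.classes.copy(), pred, second,
                         softmax_scores(d2))
        if with_reliability:
            from . import reliability as rel
            out.ts_inverse = rel.ts_inverse(q, self.protos)
            proj = rel.project(self.protos, q)
            res = rel.reliability_score(proj, pred, second, tol=rs_tol,
                                        max_samples=rs_max_samples, seed=seed)
            out.reliability = res.rs
            out.rs_diagnostics = {"n_samples": res.n_samples_used,
                                  "halted_by": res.halted_by,
                                  "standard_error": res.standard_error}
        return out
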