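"""Classification backbone with the L2-constrained softmax head.

The penultimate-layer activation (the feature descriptor) is rescaled to
a fixed L2 norm ``alpha`` before the final C-way classifier, so that
minimizing the softmax cross-entropy separates classes by direction on a
hypersphere rather than by magnitude:

    minimize  -(1/M) sum_i log softmax(W^T f(x_i) + b)[y_i]
    subject to ||f(x_i)||_2 = alpha  for all i.

Two backbones are provided: ``tiny_cnn``, a three-block convolutional
network small enough to train on a CPU in seconds, and
``vgg16_transfer``, the standard 13-conv/2-fc VGG16 topology with the
first 10 weight-bearing layers frozen, optionally initialized from a
local ``.npz`` weights file.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .augment import AugmentConfig, SoftLabeledImage, augment_epoch, one_hot
from .engine import (Adam, Conv2D, Dense, Flatten, GlobalAvgPool, L2Constraint,
                     MaxPool2D, ReLU, Sequential, softmax, softmax_cross_entropy)
from .imaging import PseudoColorImage

__all__ = [
    "FeatureDescriptor",
    "L2HeadConfig",
    "TrainingConfig",
    "TrainedModel",
    "DCNNModel",
    "l2_constrain",
    "l2_softmax_loss",
    "build_model",
    "train",
    "extract_features",
    "predict_softmax",
    "binary_score",
]

_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Penultimate-layer activation for one image."""

    x: np.ndarray
    case_id: str
    label: int


@dataclass(frozen=True)
class L2HeadConfig:
    """Final-classifier settings. ``alpha`` is the fixed descriptor norm;
    ``constrained=False`` yields a plain softmax head (the conventional
    baseline)."""

    alpha: float = 80.0
    n_classes: int = 3
    constrained: bool = True
    norm_eps: float = 0.0  # >0 guards the L2 denominator during training

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; the defaults are the reference protocol
    (Adam at 1e-5, batch size 1, up to 500 epochs, 10 frozen layers for
    the transfer backbone)."""

    learning_rate: float = 1e-5
    batch_size: int = 1
    max_epochs: int = 500
    early_stop_patience: int = 20
    frozen_layers: int | None = None  # None -> backbone default (vgg16: 10, tiny: 0)
    backbone: str = "tiny_cnn"
    input_size: int = 100
    feature_dim: int = 64  # penultimate width of tiny_cnn
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")
        if self.backbone not in ("tiny_cnn", "vgg16_transfer"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


def l2_constrain(x: np.ndarray, alpha: float = 80.0) -> np.ndarray:
    """Rescale vector(s) to L2 norm ``alpha``: x -> alpha * x / ||x||.

    Accepts a single vector or a batch (norms taken along the last axis).
    A zero vector raises :class:`engine.DegenerateFeatureError`.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=np.float64)
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norms == 0.0):
        raise engine.DegenerateFeatureError("cannot rescale a zero vector")
    return alpha * x / norms


def l2_softmax_loss(features: np.ndarray, labels: np.ndarray,
                    W: np.ndarray, b: np.ndarray) -> float:
    """Softmax cross-entropy on (already constrained) descriptors.

    ``labels`` may be integer class indices or rows on the probability
    simplex (the mixup case); the soft form reduces exactly to the hard
    form for one-hot rows.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n_classes = W.shape[1]
    labels = np.asarray(labels)
    if labels.ndim <= 1 and labels.dtype.kind in "iu" or (labels.ndim == 0):
        idx = np.atleast_1d(labels).astype(int)
        if np.any((idx < 0) | (idx >= n_classes)):
            raise ValueError("label outside the class range")
        targets = np.zeros((len(idx), n_classes))
        targets[np.arange(len(idx)), idx] = 1.0
    else:
        targets = np.atleast_2d(np.asarray(labels, dtype=np.float64))
        if np.any(targets < -1e-12) or np.any(np.abs(targets.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("soft labels must lie on the probability simplex")
    logits = features @ W + b
    loss, _ = softmax_cross_entropy(logits, targets)
    return loss


class DCNNModel:
    """Backbone + head with feature extraction at the penultimate layer."""

    def __init__(self, net: Sequential, head: L2HeadConfig,
                 config: TrainingConfig, feature_dim: int):
        self.net = net
        self.head = head
        self.config = config
        self.feature_dim = feature_dim

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[engine.Parameter]:
        return self.net.params()

    def weight_layers(self) -> list[engine.Layer]:
        return [ly for ly in self.net.layers if ly.params()]

    def set_frozen(self, n_layers: int) -> None:
        """Freeze the first ``n_layers`` weight-bearing layers from the
        input side (pooling/activation layers carry no parameters and are
        not counted)."""
        for i, layer in enumerate(self.weight_layers()):
            for p in layer.params():
                p.trainable = i >= n_layers

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v

    # -- forward passes -----------------------------------------------------
    def _as_batch(self, images) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        return arr

    def logits(self, images) -> np.ndarray:
        return self.net.forward(self._as_batch(images))

    def predict_proba(self, images) -> np.ndarray:
        return softmax(self.logits(images))

    def features(self, images) -> np.ndarray:
        return self.net.forward_features(self._as_batch(images))

    def loss_on(self, images: np.ndarray, targets: np.ndarray) -> float:
        loss, _ = softmax_cross_entropy(self.logits(images), targets)
        return loss


def _build_tiny(head: L2HeadConfig, cfg: TrainingConfig,
                rng: np.random.Generator) -> tuple[Sequential, int]:
    d = cfg.feature_dim
    layers: list[engine.Layer] = [
        Conv2D(3, 16, 3, stride=2, pad=1, rng=rng, name="conv1"), ReLU(), MaxPool2D(2),
        Conv2D(16, 32, 3, stride=1, pad=1, rng=rng, name="conv2"), ReLU(), MaxPool2D(2),
        Conv2D(32, 64, 3, stride=1, pad=1, rng=rng, name="conv3"), ReLU(), GlobalAvgPool(),
        Dense(64, d, rng=rng, name="fc_feat"),
    ]
    if head.constrained:
        layers.append(L2Constraint(head.alpha, eps=head.norm_eps))
    feature_index = len(layers) - 1
    layers.append(Dense(d, head.n_classes, rng=rng, name="fc_out"))
    return Sequential(layers, feature_index=feature_index), d


def _build_vgg16(head: L2HeadConfig, cfg: TrainingConfig, rng: np.random.Generator,
                 weights_path: str | None) -> tuple[Sequential, int]:
    layers: list[engine.Layer] = []
    in_ch, k = 3, 1
    for item in _VGG16_CFG:
        if item == "M":
            layers.append(MaxPool2D(2))
        else:
            layers.append(Conv2D(in_ch, item, 3, 1, 1, rng=rng,
                                 dtype=np.float32, name=f"block_conv{k}"))
            layers.append(ReLU())
            in_ch, k = item, k + 1
    spatial = cfg.input_size
    for item in _VGG16_CFG:
        if item == "M":
            spatial //= 2
    flat = spatial * spatial * 512
    layers += [Flatten(),
               Dense(flat, 4096, rng=rng, dtype=np.float32, name="fc1"), ReLU(),
               Dense(4096, 4096, rng=rng, dtype=np.float32, name="fc2"), ReLU()]
    if head.constrained:
        layers.append(L2Constraint(head.alpha, eps=head.norm_eps))
    feature_index = len(layers) - 1
    layers.append(Dense(4096, head.n_classes, rng=rng, dtype=np.float32, name="fc_out"))
    net = Sequential(layers, feature_index=feature_index)
    if weights_path is not None:
        data = np.load(weights_path)
        for p in net.params():
            if p.name in data:
                if data[p.name].shape != p.value.shape:
                    raise ValueError(f"weights for {p.name} have shape "
                                     f"{data[p.name].shape}, expected {p.value.shape}")
                p.value[...] = data[p.name]
    return net, 4096


def build_model(config: TrainingConfig, head: L2HeadConfig,
                weights_path: str | None = None) -> DCNNModel:
    """Construct an untrained model; freezing is applied per
    ``config.frozen_layers`` (default 10 for the transfer backbone, 0 for
    the small test backbone)."""
    rng = np.random.default_rng(config.seed)
    if config.backbone == "tiny_cnn":
        net, dim = _build_tiny(head, config, rng)
        frozen = 0 if config.frozen_layers is None else config.frozen_layers
    else:
        net, dim = _build_vgg16(head, config, rng, weights_path)
        frozen = 10 if config.frozen_layers is None else config.frozen_layers
    model = DCNNModel(net, head, config, dim)
    model.set_frozen(frozen)
    return model


@dataclass
class TrainedModel:
    model: DCNNModel
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    config: TrainingConfig
    n_texture_images_used: int = 0

    def save_history(self, path: str) -> None:
        self.history.to_csv(path, index=False)


def _stack_images(items: list[PseudoColorImage]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([it.pixels for it in items]).astype(np.float64)
    labels = np.array([it.label for it in items], dtype=int)
    return imgs, labels


def train(model: DCNNModel,
          train_cases: list[PseudoColorImage],
          val_cases: list[PseudoColorImage],
          textures: list[PseudoColorImage] | None = None,
          augment_config: AugmentConfig | None = None,
          config: TrainingConfig | None = None) -> TrainedModel:
    """Train with Adam and early stopping on validation loss.

    Each epoch iterates over every training image plus every auxiliary
    texture image (class 2), freshly augmented.  The model with the best
    validation loss is restored at the end.  Deterministic for a fixed
    seed.
    """
    if not train_cases:
        raise ValueError("empty training set")
    if not val_cases:
        raise ValueError("empty validation set")
    cfg = config or model.config
    n_classes = model.head.n_classes
    textures = textures or []
    if textures and n_classes < 3:
        raise ValueError("texture class requires a 3-class head")

    base_items = [SoftLabeledImage(c.pixels, one_hot(c.label, n_classes))
                  for c in list(train_cases) + list(textures)]
    val_imgs, val_labels = _stack_images(val_cases)
    val_targets = np.zeros((len(val_cases), n_classes))
    val_targets[np.arange(len(val_cases)), val_labels] = 1.0

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    best_loss, best_state, best_epoch = np.inf, model.state(), 0
    rows, patience_left = [], cfg.early_stop_patience

    for epoch in range(1, cfg.max_epochs + 1):
        if augment_config is not None:
            epoch_seed = int(rng.integers(0, 2 ** 31 - 1))
            items = augment_epoch(base_items, augment_config, epoch_seed)
        else:
            items = base_items
        order = rng.permutation(len(items))
        total = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = np.stack([items[i].pixels for i in idx])
            targets = np.stack([items[i].label_weights for i in idx])
            logits = model.net.forward(batch)
            loss, dlogits = softmax_cross_entropy(logits, targets)
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            total += loss * len(idx)
        train_loss = total / len(order)
        val_loss = model.loss_on(val_imgs, val_targets)
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_loss - 1e-12:
            best_loss, best_state, best_epoch = val_loss, model.state(), epoch
            patience_left = cfg.early_stop_patience
        else:
            if patience_left <= 0:
                break
            patience_left -= 1

    model.load_state(best_state)
    return TrainedModel(model, pd.DataFrame(rows), best_epoch, cfg,
                        n_texture_images_used=len(textures))


def extract_features(model: DCNNModel | TrainedModel,
                     images: list[PseudoColorImage],
                     batch_size: int = 32) -> list[FeatureDescriptor]:
    """Constrained penultimate-layer descriptors for a list of images."""
    net_model = model.model if isinstance(model, TrainedModel) else model
    out: list[FeatureDescriptor] = []
    for start in range(0, len(images), batch_size):
        chunk = images[start:start + batch_size]
        feats = net_model.features(np.stack([c.pixels for c in chunk]))
        for case, x in zip(chunk, feats):
            out.append(FeatureDescriptor(np.asarray(x, dtype=np.float64),
                                         case.case_id, case.label))
    return out


def predict_softmax(model: DCNNModel | TrainedModel,
                    images: list[PseudoColorImage],
                    batch_size: int = 32) -> np.ndarray:
    """Class-probability vectors, one simplex row per image."""
    net_model = model.model if isinstance(model, TrainedModel) else model
    probs = []
    for start in range(0, len(images), batch_size):
        chunk = images[start:start + batch_size]
        probs.append(net_model.predict_proba(np.stack([c.pixels for c in chunk])))
    return np.concatenate(probs, axis=0)


def binary_score(probs: np.ndarray) -> np.ndarray:
    """Malignancy score from class probabilities: p1 renormalized over the
    two cohort classes, p1 / (p0 + p1)."""
    probs = np.atleast_2d(probs)
    denom = probs[:, 0] + probs[:, 1]
    return probs[:, 1] / denom
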