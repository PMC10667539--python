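"""Dataset splitting and the keratoconus classifier protocols.

Two classifier families are provided, both binary (score 1 = keratoconus):

- a compact from-scratch CNN for 50x50x3 color crops (three stride-2 conv
  layers with 64/32/16 3x3 filters, two fully connected layers with a 0.25
  dropout in between, single sigmoid output), trained with fivefold
  cross-validation and an RMSprop optimizer;
- a transfer-learning recipe over a pluggable backbone: augmentation
  (horizontal flip + 20% random rotation) -> [0,255] to [-1,1] rescale ->
  frozen backbone -> global average pooling -> dense 512 -> dropout 0.2 ->
  sigmoid head, trained in a frozen feature-extraction phase followed by a
  fine-tuning phase that unfreezes the top backbone layers.

Splits are stratified 80/20 with the test partition drawn exclusively from
original (non-generated) images, and 10% of the training set held out for
validation — the protocol that keeps augmented training sets comparable on
an untouched, real-data test set.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.model_selection import KFold

from . import nn
from .vae_core import LabeledImage

__all__ = [
    "SplitSpec", "Split", "CustomCnnConfig", "TransferConfig", "TrainRecord",
    "StubBackbone", "TransferModel", "InsufficientOriginalImages",
    "split_dataset", "build_custom_cnn", "train_custom_cnn_cv",
    "build_transfer_model", "train_transfer", "fit_binary", "predict_scores",
    "POSITIVE_LABEL",
]

POSITIVE_LABEL = "kcn"


class InsufficientOriginalImages(ValueError):
    """A class lacks enough original images to fill its test share."""


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.8
    test_frac: float = 0.2
    val_frac_of_train: float = 0.1
    stratified: bool = True
    test_originals_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("train_frac + test_frac must equal 1")


@dataclasses.dataclass
class Split:
    train: list[LabeledImage]
    val: list[LabeledImage]
    test: list[LabeledImage]


def split_dataset(dataset: Sequence[LabeledImage], spec: SplitSpec | None = None) -> Split:
    """Stratified train/val/test partition with an originals-only test set.

    Per class: the test share (``test_frac`` of the class) is drawn from
    original images only; 10% of the remaining training pool (rounded) goes
    to validation.  Partitions are disjoint and exhaustive; deterministic
    given ``spec.seed``.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    labels = sorted({r.label for r in dataset})
    train: list[LabeledImage] = []
    val: list[LabeledImage] = []
    test: list[LabeledImage] = []
    for lab in labels:
        members = [i for i, r in enumerate(dataset) if r.label == lab]
        n_test = int(round(spec.test_frac * len(members)))
        if spec.test_originals_only:
            pool = [i for i in members if dataset[i].origin == "original"]
            if len(pool) < n_test:
                raise InsufficientOriginalImages(
                    f"class {lab!r}: {len(pool)} originals < test share {n_test}")
        else:
            pool = members
        test_idx = set(rng.choice(pool, size=n_test, replace=False).tolist())
        rest = [i for i in members if i not in test_idx]
        n_val = int(round(spec.val_frac_of_train * len(rest)))
        val_idx = set(rng.choice(rest, size=n_val, replace=False).tolist())
        test.extend(dataset[i] for i in sorted(test_idx))
        val.extend(dataset[i] for i in sorted(val_idx))
        train.extend(dataset[i] for i in rest if i not in val_idx)
    return Split(train=train, val=val, test=test)


@dataclasses.dataclass(frozen=True)
class CustomCnnConfig:
    input_shape: tuple[int, int, int] = (50, 50, 3)
    conv_filters: tuple[int, int, int] = (64, 32, 16)
    kernel: int = 3
    stride: int = 2
    fc_widths: tuple[int, int] = (128, 64)
    dropout: float = 0.25
    folds: int = 5
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "rmsprop"


def build_custom_cnn(config: CustomCnnConfig | None = None, seed: int = 0) -> nn.Sequential:
    """conv64s2 -> conv32s2 -> conv16s2 -> flatten -> fc1 -> dropout -> fc2 -> sigmoid(1)."""
    config = config or CustomCnnConfig()
    rng = np.random.default_rng(seed)
    h, w, c = config.input_shape
    layers: list[nn.Layer] = []
    prev = c
    for i, f in enumerate(config.conv_filters):
        layers += [nn.Conv2D(prev, f, k=config.kernel, stride=config.stride,
                             rng=rng, name=f"conv{i + 1}"), nn.ReLU()]
        prev = f
        h, w = -(-h // config.stride), -(-w // config.stride)
    layers.append(nn.Flatten())
    flat = h * w * prev
    fc1, fc2 = config.fc_widths
    layers += [
        nn.Dense(flat, fc1, rng=rng, name="fc1"), nn.ReLU(),
        nn.Dropout(config.dropout, name="dropout"),
        nn.Dense(fc1, fc2, rng=rng, name="fc2"), nn.ReLU(),
        nn.Dense(fc2, 1, rng=rng, name="output"), nn.Sigmoid(),
    ]
    return nn.Sequential(layers, input_shape=config.input_shape)


@dataclasses.dataclass
class TrainRecord:
    fold_or_phase: str
    epoch_losses: list[float]
    val_losses: list[float]
    predictions: list[tuple[float, int]]  # (score in [0,1], true label)


def _stack(records: Sequence[LabeledImage]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(r.image, dtype=np.float32) for r in records])
    y = np.array([1.0 if r.label == POSITIVE_LABEL else 0.0 for r in records],
                 dtype=np.float32)[:, None]
    return x, y


def predict_scores(model: nn.Sequential, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
    out = [model.forward(x[s:s + batch_size])
           for s in range(0, x.shape[0], batch_size)]
    return np.concatenate(out)[:, 0]


def _augment_images(x: np.ndarray, rotation_frac: float, flip: bool,
                    rng: np.random.Generator) -> np.ndarray:
    out = x.copy()
    for i in range(out.shape[0]):
        if flip and rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        if rotation_frac > 0:
            deg = rng.uniform(-1, 1) * rotation_frac * 360.0
            for c in range(out.shape[3]):
                out[i, ..., c] = ndimage.rotate(out[i, ..., c], deg, reshape=False,
                                                order=1, mode="nearest")
    return out


def fit_binary(model: nn.Sequential, x: np.ndarray, y: np.ndarray, *,
               epochs: int, learning_rate: float, optimizer: str,
               batch_size: int, seed: int,
               x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
               params=None, augment_rotation: float = 0.0,
               augment_flip: bool = False) -> tuple[list[float], list[float]]:
    """SGD loop minimizing binary cross-entropy; returns (train, val) loss curves.

    ``params`` restricts the optimizer to a subset of (param, grad) pairs
    (used to keep a transfer backbone frozen); gradients are still
    propagated through frozen layers.
    """
    rng = np.random.default_rng(seed)
    opt = nn.make_optimizer(optimizer, model.params() if params is None else params,
                            learning_rate)
    hist, vhist = [], []
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        tot, nb = 0.0, 0
        for s in range(0, n, batch_size):
            xb = x[order[s:s + batch_size]]
            yb = y[order[s:s + batch_size]]
            if augment_flip or augment_rotation > 0:
                xb = _augment_images(xb, augment_rotation, augment_flip, rng)
            p = model.forward(xb, training=True, rng=rng)
            tot += nn.bce(p, yb)
            nb += 1
            model.backward(nn.bce_grad(p, yb).astype(np.float32))
            opt.step()
        hist.append(tot / nb)
        if x_val is not None and x_val.shape[0]:
            vhist.append(nn.bce(model.forward(x_val), y_val))
    return hist, vhist


def train_custom_cnn_cv(pool: Sequence[LabeledImage],
                        config: CustomCnnConfig | None = None,
                        seed: int = 0) -> list[TrainRecord]:
    """Fivefold cross-validation with random shuffling.

    Each fold trains a fresh model on 4/5 of the pool for ``config.epochs``
    epochs and predicts on the held-out 1/5; every sample is held out exactly
    once across folds.
    """
    config = config or CustomCnnConfig()
    if len(pool) < config.folds:
        raise ValueError(f"pool of {len(pool)} smaller than {config.folds} folds")
    x, y = _stack(pool)
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=seed)
    records: list[TrainRecord] = []
    for k, (tr, ho) in enumerate(kf.split(x)):
        model = build_custom_cnn(config, seed=seed + 1000 * (k + 1))
        hist, _ = fit_binary(model, x[tr], y[tr], epochs=config.epochs,
                             learning_rate=config.learning_rate,
                             optimizer=config.optimizer,
                             batch_size=config.batch_size, seed=seed + k)
        scores = predict_scores(model, x[ho])
        records.append(TrainRecord(
            fold_or_phase=f"fold{k + 1}", epoch_losses=hist, val_losses=[],
            predictions=[(float(s), int(y[i, 0])) for s, i in zip(scores, ho)]))
    return records


# --- transfer learning ----------------------------------------------------

class StubBackbone:
    """A small deterministic conv feature extractor standing in for a
    pretrained backbone (the pluggable-backbone interface carries no
    external weights).  Declares its input side and emits a spatial feature
    map suitable for global average pooling."""

    def __init__(self, input_side: int = 160, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_side = input_side
        self.layers: list[nn.Layer] = [
            nn.Conv2D(3, 16, stride=4, rng=rng, name="bb_conv1"), nn.ReLU(),
            nn.Conv2D(16, 8, stride=4, rng=rng, name="bb_conv2"), nn.ReLU(),
        ]
        self.out_channels = 8


@dataclasses.dataclass(frozen=True)
class TransferConfig:
    head_dense: int = 512
    head_dropout: float = 0.2
    aug_flip: bool = True
    aug_rotation_frac: float = 0.20
    frozen_epochs: int = 15
    finetune_epochs: int = 10
    finetune_unfrozen_layers: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 32
    optimizer_frozen: str = "adam"
    optimizer_finetune: str = "adam"


@dataclasses.dataclass
class TransferModel:
    net: nn.Sequential  # rescale -> backbone -> GAP -> head
    backbone_layers: list[nn.Layer]
    head_layers: list[nn.Layer]
    input_side: int

    def backbone_checksums(self) -> dict[str, int]:
        import zlib

        out = {}
        for i, layer in enumerate(self.backbone_layers):
            if layer.params():
                blob = b"".join(np.ascontiguousarray(p).tobytes() for p, _ in layer.params())
                out[f"{i}_{layer.name}"] = zlib.crc32(blob)
        return out


def build_transfer_model(config: TransferConfig, backbone, seed: int = 0) -> TransferModel:
    """Assemble rescale ([0,255] -> [-1,1]) -> frozen backbone -> GAP ->
    dense head.  Augmentation is applied at the data level during training
    only, so inference is deterministic."""
    if not hasattr(backbone, "input_side"):
        raise ValueError("backbone must declare its input side")
    rng = np.random.default_rng(seed)
    side = int(backbone.input_side)
    probe = np.zeros((1, side, side, 3), dtype=np.float32)
    feat = probe
    for layer in backbone.layers:
        feat = layer.forward(feat)
    c = feat.shape[-1]
    head: list[nn.Layer] = [
        nn.GlobalAvgPool(),
        nn.Dense(c, config.head_dense, rng=rng, name="head_dense"), nn.ReLU(),
        nn.Dropout(config.head_dropout, name="head_dropout"),
        nn.Dense(config.head_dense, 1, rng=rng, name="head_out"), nn.Sigmoid(),
    ]
    net = nn.Sequential([nn.Rescale(1.0 / 127.5, -1.0, name="rescale")]
                        + list(backbone.layers) + head,
                        input_shape=(side, side, 3))
    return TransferModel(net=net, backbone_layers=list(backbone.layers),
                         head_layers=head, input_side=side)


def train_transfer(model: TransferModel, split: Split, config: TransferConfig,
                   seed: int = 0) -> tuple[TrainRecord, TrainRecord]:
    """Frozen feature extraction (head only), then fine-tuning of the top
    ``finetune_unfrozen_layers`` parameterized backbone layers."""
    x_tr, y_tr = _stack(split.train)
    x_val, y_val = (_stack(split.val) if split.val else (None, None))
    x_te, y_te = _stack(split.test) if split.test else (np.empty((0,)), np.empty((0, 1)))

    head_params = [pg for layer in model.head_layers for pg in layer.params()]
    hist1, vhist1 = fit_binary(
        model.net, x_tr, y_tr, epochs=config.frozen_epochs,
        learning_rate=config.learning_rate, optimizer=config.optimizer_frozen,
        batch_size=config.batch_size, seed=seed, x_val=x_val, y_val=y_val,
        params=head_params, augment_rotation=config.aug_rotation_frac,
        augment_flip=config.aug_flip)
    scores = predict_scores(model.net, x_te) if x_te.size else np.empty(0)
    rec1 = TrainRecord("frozen", hist1, vhist1,
                       [(float(s), int(t)) for s, t in zip(scores, y_te[:, 0])])

    param_layers = [l for l in model.backbone_layers if l.params()]
    unfrozen = param_layers[-config.finetune_unfrozen_layers:] if config.finetune_unfrozen_layers else []
    ft_params = head_params + [pg for layer in unfrozen for pg in layer.params()]
    hist2, vhist2 = fit_binary(
        model.net, x_tr, y_tr, epochs=config.finetune_epochs,
        learning_rate=config.learning_rate, optimizer=config.optimizer_finetune,
        batch_size=config.batch_size, seed=seed + 1, x_val=x_val, y_val=y_val,
        params=ft_params, augment_rotation=config.aug_rotation_frac,
        augment_flip=config.aug_flip)
    scores = predict_scores(model.net, x_te) if x_te.size else np.empty(0)
    rec2 = TrainRecord("finetune", hist2, vhist2,
                       [(float(s), int(t)) for s, t in zip(scores, y_te[:, 0])])
    return rec1, rec2
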