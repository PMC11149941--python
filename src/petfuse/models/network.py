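"""The three dementia classifiers and their training loop.

- ``feature_only``: z-score layer → small fully connected stack → softmax(2);
  the radiomics-feature network.
- ``cnn``: image → conv(16 filters, 5x5x5) → batch norm → ReLU →
  [optional 2x max pool] → fully connected(50) → flatten → fully
  connected(2) → softmax.
- ``combined``: the cnn image branch, with the selected radiomics features
  concatenated onto the width-50 vector before the final fully connected
  layer, so the penultimate vector has width ``50 + n_features``.

Labels: control = 0 (negative), demented = 1 (positive). The softmax output
is the posterior probability of each class. The feature normalizer (per
feature mean/SD) is fitted on the training rows only — never on validation
rows — and is stored with the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import (
    Adam,
    BatchNorm,
    Conv3D,
    Dense,
    Flatten,
    Layer,
    MaxPool3D,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "TrainedModel",
    "PredictionRecord",
    "CohortData",
    "Network",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]

LABELS = ("control", "demented")


@dataclass
class ModelConfig:
    """Architecture parameters; defaults follow the published model scheme."""

    kind: str = "combined"  # feature_only | cnn | combined
    image_shape: tuple[int, int, int] = (79, 95, 69)
    n_features: int = 4
    conv_filters: int = 16
    conv_kernel: int = 5
    fc_image_width: int = 50
    fc_feature_width: int = 16  # hidden width of the feature-only stack
    n_classes: int = 2
    feature_normalization: str = "zscore"
    pooling: bool = False  # optional pooling block for the pure-CNN variant

    def __post_init__(self) -> None:
        if self.kind not in ("feature_only", "cnn", "combined"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_classes != 2:
            raise ValueError("binary classification only: n_classes must be 2")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        if self.kind == "cnn":
            self.n_features = 0
        if self.kind == "combined" and self.n_features < 1:
            raise ValueError("combined model requires n_features >= 1")
        if self.kind == "feature_only" and self.n_features < 1:
            raise ValueError("feature_only model requires n_features >= 1")
        for name in ("conv_filters", "conv_kernel", "fc_image_width", "fc_feature_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingConfig:
    """90/10 stratified split and the (pinned) optimization defaults."""

    train_fraction: float = 0.90
    val_fraction: float = 0.10
    seed: int = 0
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.val_fraction - 1.0) > 1e-9:
            raise ValueError("train_fraction + val_fraction must equal 1")


@dataclass
class CohortData:
    """In-memory training cohort: ids, labels, optional images and features."""

    ids: list[str]
    labels: np.ndarray  # int, 0 = control, 1 = demented
    images: np.ndarray | None = None  # (N, D, H, W)
    features: np.ndarray | None = None  # (N, F)

    @classmethod
    def from_labels(cls, ids, labels, images=None, features=None) -> "CohortData":
        lab = np.asarray(
            [LABELS.index(l) if isinstance(l, str) else int(l) for l in labels], dtype=np.int64
        )
        return cls(list(ids), lab, images, features)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class PredictionRecord:
    subject_id: str
    score_control: float
    score_demented: float
    predicted_label: str

    @property
    def scores(self) -> tuple[float, float]:
        return self.score_control, self.score_demented


class Network:
    """Layer graph for one of the three classifier kinds."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.image_layers: list[Layer] = []
        self.feature_layers: list[Layer] = []
        if config.kind in ("cnn", "combined"):
            conv = Conv3D(1, config.conv_filters, config.conv_kernel, rng)
            out_sp = conv.out_shape(config.image_shape)
            layers: list[Layer] = [conv, BatchNorm(config.conv_filters), ReLU()]
            if config.pooling:
                layers.append(MaxPool3D())
                out_sp = tuple(s // 2 for s in out_sp)
                if any(s < 1 for s in out_sp):
                    raise ValueError("image too small for the pooling block")
            flat_width = int(np.prod(out_sp)) * config.conv_filters
            layers += [Flatten(), Dense(flat_width, config.fc_image_width, rng)]
            self.image_layers = layers
            head_in = config.fc_image_width + config.n_features
        else:
            self.feature_layers = [
                Dense(config.n_features, config.fc_feature_width, rng),
                ReLU(),
            ]
            head_in = config.fc_feature_width
        self.head = Dense(head_in, config.n_classes, rng)
        self.concat_width = head_in

    # -- introspection ------------------------------------------------------
    def all_layers(self) -> list[Layer]:
        return [*self.image_layers, *self.feature_layers, self.head]

    def describe(self) -> list[tuple[str, int]]:
        """Deterministic layer inventory: (layer class name, parameter count)."""
        return [(type(l).__name__, l.n_params) for l in self.all_layers()]

    @property
    def n_params(self) -> int:
        return sum(n for _, n in self.describe())

    # -- forward / backward -------------------------------------------------
    def _forward_logits(self, images, features, train: bool) -> np.ndarray:
        if self.config.kind == "feature_only":
            h = features
            for layer in self.feature_layers:
                h = layer.forward(h, train)
            return self.head.forward(h, train)
        h = images[..., None]  # add the single input channel
        for layer in self.image_layers:
            h = layer.forward(h, train)
        if self.config.kind == "combined":
            self._img_width = h.shape[1]
            h = np.concatenate([h, features], axis=1)
        return self.head.forward(h, train)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        if self.config.kind == "feature_only":
            for layer in reversed(self.feature_layers):
                d = layer.backward(d)
            return
        if self.config.kind == "combined":
            d = d[:, : self._img_width]
        for layer in reversed(self.image_layers):
            d = layer.backward(d)

    def predict_proba(self, images, features) -> np.ndarray:
        return softmax(self._forward_logits(images, features, train=False))


def build_model(config: ModelConfig, seed: int = 0) -> Network:
    """Instantiate the layer graph for ``config`` with seeded weights."""
    return Network(config, seed)


@dataclass
class TrainedModel:
    config: ModelConfig
    network: Network
    feature_normalizer: tuple[np.ndarray, np.ndarray] | None  # (mean, sd) per feature
    training_log: list[dict]
    val_accuracy: float  # percent
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)

    def normalize(self, features: np.ndarray | None) -> np.ndarray | None:
        if features is None or self.feature_normalizer is None:
            return features
        mean, sd = self.feature_normalizer
        return (features - mean) / sd


def _stratified_split(labels: np.ndarray, val_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _check_split(labels: np.ndarray, train_idx: np.ndarray, val_idx: np.ndarray) -> None:
    for name, idx, minimum in (("training", train_idx, 2), ("validation", val_idx, 1)):
        counts = np.bincount(labels[idx], minlength=2)
        if (counts < minimum).any():
            raise ValueError(
                f"a class has fewer than {minimum} subjects in the {name} split; "
                "use a larger cohort"
            )


def _accuracy(net: Network, images, features, labels) -> float:
    probs = net.predict_proba(images, features)
    return float((probs.argmax(axis=1) == labels).mean())


def train(network: Network, cohort: CohortData, tcfg: TrainingConfig | None = None) -> TrainedModel:
    """Stratified 90/10 split, cross-entropy minimization with Adam.

    Fully reproducible given ``tcfg.seed``. Returns the trained model with
    its per-epoch training log and final validation accuracy (percent).
    """
    tcfg = tcfg or TrainingConfig()
    cfg = network.config
    needs_images = cfg.kind in ("cnn", "combined")
    needs_features = cfg.kind in ("feature_only", "combined")
    if needs_images and cohort.images is None:
        raise ValueError(f"model kind {cfg.kind!r} needs images")
    if needs_features and cohort.features is None:
        raise ValueError(f"model kind {cfg.kind!r} needs features")
    if needs_features and cohort.features.shape[1] != cfg.n_features:
        raise ValueError(
            f"feature width mismatch: expected {cfg.n_features}, got {cohort.features.shape[1]}"
        )
    if needs_images and tuple(cohort.images.shape[1:]) != cfg.image_shape:
        raise ValueError(
            f"image shape mismatch: expected {cfg.image_shape}, got {tuple(cohort.images.shape[1:])}"
        )

    rng = np.random.default_rng(tcfg.seed)
    labels = cohort.labels
    train_idx, val_idx = _stratified_split(labels, tcfg.val_fraction, rng)
    _check_split(labels, train_idx, val_idx)

    normalizer = None
    feats = None
    if needs_features:
        raw = np.asarray(cohort.features, dtype=np.float64)
        mean = raw[train_idx].mean(axis=0)
        sd = raw[train_idx].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        normalizer = (mean, sd)
        feats = (raw - mean) / sd
    imgs = np.asarray(cohort.images, dtype=np.float64) if needs_images else None

    def batch(idx):
        bi = imgs[idx] if imgs is not None else None
        bf = feats[idx] if feats is not None else None
        return bi, bf

    opt = Adam(network.all_layers(), lr=tcfg.learning_rate)
    log: list[dict] = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, order.size, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            bi, bf = batch(idx)
            logits = network._forward_logits(bi, bf, train=True)
            loss, dlogits = softmax_cross_entropy(logits, labels[idx])
            network._backward(dlogits)
            opt.step()
            losses.append(loss)
        ti, tf = batch(train_idx)
        vi, vf = batch(val_idx)
        log.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(losses)),
                "train_accuracy": _accuracy(network, ti, tf, labels[train_idx]),
                "val_accuracy": _accuracy(network, vi, vf, labels[val_idx]),
            }
        )
    vi, vf = batch(val_idx)
    val_acc = 100.0 * _accuracy(network, vi, vf, labels[val_idx])
    return TrainedModel(
        config=cfg,
        network=network,
        feature_normalizer=normalizer,
        training_log=log,
        val_accuracy=val_acc,
        train_ids=[cohort.ids[i] for i in train_idx],
        val_ids=[cohort.ids[i] for i in val_idx],
    )


def predict(
    model: TrainedModel,
    image: np.ndarray | None = None,
    features: np.ndarray | None = None,
    subject_id: str = "subject",
) -> PredictionRecord:
    """Softmax posterior scores for one subject.

    Features are z-scored with the stored training normalizer.
    """
    cfg = model.config
    imgs = None
    if cfg.kind in ("cnn", "combined"):
        if image is None:
            raise ValueError(f"model kind {cfg.kind!r} needs an image")
        image = np.asarray(image, dtype=np.float64)
        if tuple(image.shape) != cfg.image_shape:
            raise ValueError(f"image shape mismatch: expected {cfg.image_shape}, got {image.shape}")
        imgs = image[None]
    feats = None
    if cfg.kind in ("feature_only", "combined"):
        if features is None:
            raise ValueError(f"model kind {cfg.kind!r} needs features")
        features = np.asarray(features, dtype=np.float64).reshape(1, -1)
        if features.shape[1] != cfg.n_features:
            raise ValueError(
                f"feature width mismatch: expected {cfg.n_features}, got {features.shape[1]}"
            )
        feats = model.normalize(features)
    probs = model.network.predict_proba(imgs, feats)[0]
    return PredictionRecord(
        subject_id=subject_id,
        score_control=float(probs[0]),
        score_demented=float(probs[1]),
        predicted_label=LABELS[int(probs.argmax())],
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Weights to a single .npz with a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for li, layer in enumerate(model.network.all_layers()):
        for name, p in layer.params():
            arrays[f"{li}:{name}"] = p
        if isinstance(layer, BatchNorm):
            arrays[f"{li}:running_mean"] = layer.running_mean
            arrays[f"{li}:running_var"] = layer.running_var
    if model.feature_normalizer is not None:
        arrays["norm_mean"], arrays["norm_sd"] = model.feature_normalizer
    np.savez(path, **arrays)
    sidecar = {
        "config": asdict(model.config),
        "val_accuracy": model.val_accuracy,
        "training_log": model.training_log,
        "train_ids": model.train_ids,
        "val_ids": model.val_ids,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = sidecar["config"]
    cfg_d["image_shape"] = tuple(cfg_d["image_shape"])
    cfg = ModelConfig(**cfg_d)
    net = Network(cfg, seed=0)
    data = np.load(path)
    for li, layer in enumerate(net.all_layers()):
        for name, p in layer.params():
            p[...] = data[f"{li}:{name}"]
        if isinstance(layer, BatchNorm):
            layer.running_mean = data[f"{li}:running_mean"]
            layer.running_var = data[f"{li}:running_var"]
    norm = None
    if "norm_mean" in data:
        norm = (data["norm_mean"], data["norm_sd"])
    return TrainedModel(
        config=cfg,
        network=net,
        feature_normalizer=norm,
        training_log=sidecar["training_log"],
        val_accuracy=sidecar["val_accuracy"],
        train_ids=sidecar["train_ids"],
        val_ids=sidecar["val_ids"],
    )
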