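"""Compact depthwise-separable CNN for two-class screening, plus cost accounting.

The classifier takes the fused color+texture feature vector of an image
(CIF_min + CIF_max histograms concatenated with the 2^s-bin LBP
histogram), reshapes it to a square single-channel map, and runs it
through one standard 3x3 convolution followed by depthwise-separable
blocks (DWConv 3x3 -> BN -> ReLU -> PWConv 1x1 -> BN -> ReLU), global
average pooling and a dense softmax over {normal, abnormal}.

Cost model.  For a layer with k input channels, l output channels, kernel
H_ip x H_ip and output spatial size H_o/p x H_o/p, a standard convolution
costs ``H_o/p^2 * k * l * H_ip^2`` multiply-accumulates, while the
depthwise-separable factorization costs
``H_o/p^2 * k * H_ip^2 + k * l * H_ip^2``, so the ratio is exactly
``1/l + 1/H_o/p^2`` — the headline efficiency gain of this family of
networks.  :func:`cost_report` verifies the identity in exact rational
arithmetic.

The model object follows the statsmodels convention: :class:`MondNet` is
built from data, ``fit()`` returns a :class:`MondNetResults` carrying the
fitted network, per-epoch history and a ``summary()`` table.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .synthetic import ABNORMAL, NORMAL

CLASS_NAMES = (NORMAL, ABNORMAL)  # index 0, 1; "abnormal" is the positive class


class ConfigurationError(ValueError):
    """Raised for invalid classifier configuration."""


# ---------------------------------------------------------------------------
# computational-cost accounting


@dataclass(frozen=True)
class ConvSpec:
    """Shape of one convolutional layer for cost accounting.

    in_channels k, out_channels l, kernel size H_ip, output spatial size H_o/p.
    """

    in_channels: int
    out_channels: int
    kernel_size: int
    out_spatial: int

    def __post_init__(self) -> None:
        if min(self.in_channels, self.out_channels, self.kernel_size, self.out_spatial) < 1:
            raise ConfigurationError("all ConvSpec dimensions must be >= 1")


@dataclass(frozen=True)
class CostReport:
    """Multiply-accumulate counts and their exact ratio."""

    standard_cost: int
    separable_cost: int
    ratio: Fraction


def standard_conv_cost(spec: ConvSpec) -> int:
    """MACs of a standard convolution: H_o/p^2 * k * l * H_ip^2."""
    return (
        spec.out_spatial**2
        * spec.in_channels
        * spec.out_channels
        * spec.kernel_size**2
    )


def separable_conv_cost(spec: ConvSpec) -> int:
    """MACs of the depthwise-separable factorization.

    Depthwise term ``H_o/p^2 * k * H_ip^2`` plus pointwise term
    ``k * l * H_ip^2``; the ratio to the standard cost is then exactly
    ``1/l + 1/H_o/p^2``.
    """
    depthwise = spec.out_spatial**2 * spec.in_channels * spec.kernel_size**2
    pointwise = spec.in_channels * spec.out_channels * spec.kernel_size**2
    return depthwise + pointwise


def cost_report(spec: ConvSpec) -> CostReport:
    """Exact costs and the reduction ratio 1/l + 1/H_o/p^2."""
    std = standard_conv_cost(spec)
    sep = separable_conv_cost(spec)
    ratio = Fraction(sep, std)
    assert ratio == Fraction(1, spec.out_channels) + Fraction(1, spec.out_spatial**2)
    return CostReport(standard_cost=std, separable_cost=sep, ratio=ratio)


# ---------------------------------------------------------------------------
# architecture


@dataclass(frozen=True)
class ArchConfig:
    """Network architecture: one standard conv then depthwise-separable blocks.

    ``base_stride=0`` means automatic: the stem convolution uses stride 2
    on inputs of 32 pixels or larger (the usual choice in this network
    family) and stride 1 on small feature-map inputs.
    """

    base_filters: int = 16
    block_channels: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    in_channels: int = 1
    base_stride: int = 0

    def __post_init__(self) -> None:
        if self.base_filters < 1 or any(c < 1 for c in self.block_channels):
            raise ConfigurationError("channel counts must be >= 1")
        if self.base_stride not in (0, 1, 2):
            raise ConfigurationError("base_stride must be 0 (auto), 1 or 2")

    def stem_stride(self, spatial: int) -> int:
        if self.base_stride:
            return self.base_stride
        return 2 if spatial >= 32 else 1


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults follow the package's reference run."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 1e-4
    val_split: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not 0.0 < self.val_split < 1.0:
            raise ConfigurationError("val_split must lie in (0, 1)")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigurationError("invalid batch_size or learning_rate")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be >= 0")


def features_to_maps(features: np.ndarray) -> np.ndarray:
    """Reshape (n, d) feature rows to (n, side, side, 1) zero-padded square maps."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n, d = features.shape
    side = int(np.ceil(np.sqrt(d)))
    padded = np.zeros((n, side * side))
    padded[:, :d] = features
    return padded.reshape(n, side, side, 1)


def fuse_inputs(
    features: np.ndarray, images: np.ndarray | list[np.ndarray] | None
) -> np.ndarray:
    """Assemble the network input tensor.

    Without images, the fused histogram vector alone becomes a square
    single-channel map.  With images, the histogram map is zero-padded to
    the image size and stacked as an extra channel on the (0-1 scaled)
    preprocessed image tensor.
    """
    maps = features_to_maps(features)
    if images is None:
        return maps
    imgs = np.stack([np.asarray(im, dtype=np.float64) for im in images]) / 255.0
    if imgs.ndim == 3:
        imgs = imgs[..., None]
    n, h, w, _ = imgs.shape
    side = maps.shape[1]
    if side > min(h, w):
        raise ConfigurationError(
            f"feature map side {side} exceeds image size {h}x{w}"
        )
    chan = np.zeros((n, h, w, 1))
    chan[:, :side, :side, :] = maps
    return np.concatenate([imgs, chan], axis=3)


def _dw_separable_block(
    channels_in: int, channels_out: int, stride: int, rng: np.random.Generator
) -> list[nn.Layer]:
    return [
        nn.DepthwiseConv2D(channels_in, 3, stride, rng),
        nn.BatchNorm(channels_in),
        nn.ReLU(),
        nn.Conv2D(channels_in, channels_out, 1, 1, rng),  # pointwise
        nn.BatchNorm(channels_out),
        nn.ReLU(),
    ]


def build_network(
    arch: ArchConfig,
    rng: np.random.Generator,
    standard_only: bool = False,
    input_spatial: int = 17,
) -> nn.Sequential:
    """Assemble the network; ``standard_only`` swaps each separable block
    for a standard 3x3 convolution with identical channel shapes (the
    cost/parameter baseline)."""
    layers: list[nn.Layer] = [
        nn.Conv2D(
            arch.in_channels,
            arch.base_filters,
            arch.kernel_size,
            arch.stem_stride(input_spatial),
            rng,
        ),
        nn.BatchNorm(arch.base_filters),
        nn.ReLU(),
    ]
    c_in = arch.base_filters
    for c_out in arch.block_channels:
        if standard_only:
            layers += [
                nn.Conv2D(c_in, c_out, 3, 2, rng),
                nn.BatchNorm(c_out),
                nn.ReLU(),
            ]
        else:
            layers += _dw_separable_block(c_in, c_out, 2, rng)
        c_in = c_out
    layers += [nn.GlobalAvgPool(), nn.Dense(c_in, 2, rng)]
    return nn.Sequential(layers)


def build_model(
    feature_length: int,
    arch: ArchConfig | None = None,
    seed: int = 0,
    standard_only: bool = False,
    image_shape: tuple[int, int, int] | None = None,
) -> "MondNetModel":
    """Functional constructor for an untrained model.

    ``image_shape`` (H, W, C), when given, switches the model to fused
    image+histogram input; ``arch.in_channels`` must then equal C + 1.
    """
    arch = arch or ArchConfig()
    spatial = image_shape[0] if image_shape else int(np.ceil(np.sqrt(feature_length)))
    net = build_network(
        arch, np.random.default_rng(seed), standard_only=standard_only,
        input_spatial=spatial,
    )
    return MondNetModel(
        net=net, arch=arch, feature_length=feature_length, image_shape=image_shape
    )


@dataclass
class MondNetModel:
    """An (un)trained network plus the metadata needed to use it."""

    net: nn.Sequential
    arch: ArchConfig
    feature_length: int
    image_shape: tuple[int, int, int] | None = None

    def n_params(self) -> int:
        return self.net.n_params()

    def _inputs(self, features: np.ndarray, images) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[1] != self.feature_length:
            raise ConfigurationError(
                f"feature length {features.shape[1]} != expected {self.feature_length}"
            )
        if (images is None) != (self.image_shape is None):
            raise ConfigurationError(
                "model was built "
                + ("with" if self.image_shape else "without")
                + " image input; pass images accordingly"
            )
        return fuse_inputs(features, images)

    def predict_proba(self, features: np.ndarray, images=None) -> np.ndarray:
        return self.net.predict_proba(self._inputs(features, images))

    def predict(
        self, features: np.ndarray, images=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Class labels and probabilities; ties go to "abnormal" (screening posture)."""
        proba = self.predict_proba(features, images)
        idx = (proba[:, 1] >= proba[:, 0]).astype(int)
        labels = np.array([CLASS_NAMES[i] for i in idx])
        return labels, proba

    # ---- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "arch": asdict(self.arch),
            "feature_length": self.feature_length,
            "image_shape": list(self.image_shape) if self.image_shape else None,
        }
        arrays = self.net.state_arrays()
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MondNetModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arch_d = meta["arch"]
            arch_d["block_channels"] = tuple(arch_d["block_channels"])
            arch = ArchConfig(**arch_d)
            shape = tuple(meta["image_shape"]) if meta.get("image_shape") else None
            model = build_model(meta["feature_length"], arch=arch, image_shape=shape)
            model.net.load_state({k: data[k] for k in data.files if k != "__meta__"})
        return model


# ---------------------------------------------------------------------------
# statsmodels-style Model / Results


def _encode_labels(labels) -> np.ndarray:
    try:
        return np.array([CLASS_NAMES.index(lab) for lab in labels])
    except ValueError as exc:
        raise ConfigurationError(f"labels must be in {CLASS_NAMES}") from exc


class MondNet:
    """Two-class screening model over fused color+texture features.

    Parameters
    ----------
    features : (n, d) array
        Fused feature rows (CIF histograms + LBP histogram).
    labels : sequence of {"normal", "abnormal"}
    arch : ArchConfig, optional

    ``fit(config)`` trains with SGD-momentum under cosine learning-rate
    decay and returns a :class:`MondNetResults`.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels,
        images: np.ndarray | list[np.ndarray] | None = None,
        arch: ArchConfig | None = None,
    ):
        self.features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        self.y = _encode_labels(labels)
        if len(self.features) != len(self.y):
            raise ConfigurationError("features and labels must be equal length")
        if len(np.unique(self.y)) < 2:
            raise ConfigurationError("training data must contain both classes")
        if np.bincount(self.y, minlength=2).min() < 2:
            raise ConfigurationError("need at least 2 examples per class")
        self.images = images
        if images is not None:
            img0 = np.asarray(images[0])
            if img0.ndim == 2:
                img0 = img0[..., None]
            self.image_shape: tuple[int, int, int] | None = img0.shape
            in_ch = img0.shape[2] + 1
        else:
            self.image_shape = None
            in_ch = 1
        self.arch = arch or ArchConfig(in_channels=in_ch)
        if self.arch.in_channels != in_ch:
            raise ConfigurationError(
                f"arch.in_channels={self.arch.in_channels} but input has {in_ch} channels"
            )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_column: str = "label",
        images: np.ndarray | list[np.ndarray] | None = None,
        arch: ArchConfig | None = None,
    ) -> "MondNet":
        feature_cols = [c for c in frame.columns if c not in (label_column, "path", "provenance")]
        return cls(
            frame[feature_cols].to_numpy(float), frame[label_column].tolist(),
            images=images, arch=arch,
        )

    def fit(self, config: TrainConfig | None = None) -> "MondNetResults":
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        x_maps = fuse_inputs(self.features, self.images)
        model = MondNetModel(
            net=build_network(self.arch, rng, input_spatial=x_maps.shape[1]),
            arch=self.arch,
            feature_length=self.features.shape[1],
            image_shape=self.image_shape,
        )
        y = self.y
        n = len(y)
        steps_per_epoch = max(1, -(-n // config.batch_size))
        opt = nn.SGDMomentum(
            model.net,
            lr=config.learning_rate,
            momentum=config.momentum,
            total_steps=config.epochs * steps_per_epoch,
            weight_decay=config.weight_decay,
        )
        history = {"epoch": [], "loss": [], "accuracy": []}
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                logits = model.net.forward(x_maps[idx], train=True)
                loss, dlogits = nn.cross_entropy_grad(logits, y[idx])
                model.net.backward(dlogits)
                opt.step()
                epoch_loss += loss * len(idx)
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
            history["epoch"].append(epoch)
            history["loss"].append(epoch_loss / n)
            history["accuracy"].append(correct / n)
        return MondNetResults(
            model=model,
            history=pd.DataFrame(history),
            train_config=config,
            n_train=n,
        )


@dataclass
class MondNetResults:
    """Fitted classifier: network, training history and summary."""

    model: MondNetModel
    history: pd.DataFrame
    train_config: TrainConfig
    n_train: int

    def predict(self, features: np.ndarray, images=None) -> tuple[np.ndarray, np.ndarray]:
        return self.model.predict(features, images)

    def predict_proba(self, features: np.ndarray, images=None) -> np.ndarray:
        return self.model.predict_proba(features, images)

    @property
    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1])

    @property
    def final_accuracy(self) -> float:
        return float(self.history["accuracy"].iloc[-1])

    def summary(self) -> str:
        buf = io.StringIO()
        arch = self.model.arch
        rows = [
            ("Model:", "MondNet (depthwise-separable CNN)"),
            ("Classes:", " / ".join(CLASS_NAMES)),
            ("Feature length:", str(self.model.feature_length)),
            ("Input:", "image + histogram channel" if self.model.image_shape
                       else "histogram map"),
            ("Architecture:", f"conv{arch.kernel_size}x{arch.kernel_size}({arch.base_filters}) + "
                              f"dw-sep blocks {list(arch.block_channels)}"),
            ("Parameters:", str(self.model.n_params())),
            ("Training examples:", str(self.n_train)),
            ("Epochs:", str(self.train_config.epochs)),
            ("Batch size:", str(self.train_config.batch_size)),
            ("Final train loss:", f"{self.final_loss:.4f}"),
            ("Final train accuracy:", f"{self.final_accuracy:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        buf.write("MondNet fit results\n")
        buf.write("=" * 48 + "\n")
        for key, val in rows:
            buf.write(f"{key:<{width}}  {val}\n")
        return buf.getvalue()

    def save(self, model_path: str | Path, history_path: str | Path | None = None) -> None:
        self.model.save(model_path)
        if history_path is not None:
            self.history.to_csv(history_path, index=False)


# functional wrappers matching the operation surface ------------------------


def train(
    features: np.ndarray,
    labels,
    config: TrainConfig | None = None,
    arch: ArchConfig | None = None,
    images: np.ndarray | list[np.ndarray] | None = None,
) -> MondNetResults:
    """Train a fresh model on fused features; see :class:`MondNet`."""
    return MondNet(features, labels, images=images, arch=arch).fit(config)


def predict(
    model: MondNetModel, features: np.ndarray, images=None
) -> tuple[np.ndarray, np.ndarray]:
    """Predict class labels and probabilities with a fitted model."""
    return model.predict(features, images)
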