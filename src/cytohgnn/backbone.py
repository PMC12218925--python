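"""Compound-scaling CNN feature extractor.

A 17-layer network — one stem convolution, fifteen mobile inverted
bottleneck (MBConv) blocks and a 1x1 head convolution — followed by global
average pooling (GAP), which turns an RGB cell image into a
2304-dimensional feature vector.  Each MBConv block applies, in order:
channel expansion by a 1x1 convolution when its expansion factor exceeds 1,
a depthwise convolution, squeeze-and-excitation channel recalibration with
sigmoid gating, and a 1x1 projection; batch normalisation and the swish
activation follow each convolution except the projection, which keeps batch
normalisation only.  A residual shortcut is used when a block keeps both
stride 1 and its channel count.

The layer table below is the network at the default compound coefficient
(phi = 1); the compound-scaling rule governs the input resolution (224 *
1.15 rounded to a multiple of 32, i.e. 256 pixels by default).

Parameters are randomly initialised from a seed.  Supervised fitting trains
a temporary linear softmax head on the GAP features; the convolutional
trunk acts as a seeded random-projection feature extractor and the head is
discarded when features are exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DegenerateInputError, InvalidConfigError, ShapeError
from .feature_table import FeatureTable
from .nn_ops import (
    BatchNorm,
    conv2d,
    depthwise_conv2d,
    global_avg_pool,
    relu,
    sigmoid,
    softmax,
    swish,
)
from .scaling import ScalingConfig, compound_scale, conv_output_size, se_channels

__all__ = [
    "LayerSpec",
    "BackboneSpec",
    "default_layer_table",
    "build_backbone",
    "CompoundScalingBackbone",
    "BackboneFitResult",
]

FEATURE_DIM = 2304
N_LAYERS = 17


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the backbone table.

    ``kind`` is one of ``stem_conv``, ``mbconv``, ``head_conv``.
    ``expansion_factor`` and ``se_ratio`` apply to MBConv layers only.
    """

    kind: str
    kernel_size: int
    stride: int
    out_channels: int
    expansion_factor: float = 1.0
    se_ratio: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("stem_conv", "mbconv", "head_conv"):
            raise InvalidConfigError(f"unknown layer kind {self.kind!r}")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise InvalidConfigError(f"kernel size must be odd positive, got {self.kernel_size}")
        if self.stride not in (1, 2):
            raise InvalidConfigError(f"stride must be 1 or 2, got {self.stride}")
        if self.out_channels < 1:
            raise InvalidConfigError(f"out_channels must be positive, got {self.out_channels}")
        if self.expansion_factor <= 0 or self.se_ratio < 1:
            raise InvalidConfigError("expansion_factor must be > 0 and se_ratio >= 1")


@dataclass(frozen=True)
class BackboneSpec:
    """The resolved architecture: 17 layers, input resolution, feature size."""

    layers: tuple
    input_resolution: int
    feature_dim: int

    def __post_init__(self) -> None:
        if len(self.layers) != N_LAYERS:
            raise InvalidConfigError(
                f"backbone must have exactly {N_LAYERS} layers, got {len(self.layers)}"
            )
        last = self.layers[-1]
        if last.kind != "head_conv" or last.out_channels != self.feature_dim:
            raise InvalidConfigError(
                "last layer must be the head convolution producing feature_dim channels"
            )


def default_layer_table() -> tuple:
    """The normative 17-layer table (stem + 15 MBConv + 1x1 head).

    Stage layout: stem 3x3/s2 -> 32ch; MBConv stages
    (repeat, kernel, stage stride, channels, expansion) =
    (1,3,1,16,1), (2,3,2,24,6), (2,5,2,40,6), (3,3,2,80,6),
    (3,5,1,112,6), (4,5,2,192,6); head 1x1 -> 2304ch.  Within a stage only
    the first block carries the stage stride.
    """
    layers = [LayerSpec("stem_conv", 3, 2, 32)]
    stages = [
        (1, 3, 1, 16, 1.0),
        (2, 3, 2, 24, 6.0),
        (2, 5, 2, 40, 6.0),
        (3, 3, 2, 80, 6.0),
        (3, 5, 1, 112, 6.0),
        (4, 5, 2, 192, 6.0),
    ]
    for repeat, kernel, stage_stride, channels, expansion in stages:
        for j in range(repeat):
            layers.append(
                LayerSpec(
                    "mbconv",
                    kernel,
                    stage_stride if j == 0 else 1,
                    channels,
                    expansion_factor=expansion,
                    se_ratio=4,
                )
            )
    layers.append(LayerSpec("head_conv", 1, 1, FEATURE_DIM))
    return tuple(layers)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _ConvBNAct:
    """Convolution + batch norm + optional swish (stem and head layers)."""

    def __init__(self, rng, in_ch, spec: LayerSpec):
        f = spec.kernel_size
        self.spec = spec
        self.weight = _he_init(rng, (spec.out_channels, in_ch, f, f), in_ch * f * f)
        self.bn = BatchNorm(spec.out_channels)

    def forward(self, x, training=False):
        x = conv2d(x, self.weight, stride=self.spec.stride)
        return swish(self.bn(x, training=training))


class _MBConv:
    """Mobile inverted bottleneck block with squeeze-excitation."""

    def __init__(self, rng, in_ch, spec: LayerSpec):
        self.spec = spec
        self.in_ch = in_ch
        mid = int(round(in_ch * spec.expansion_factor))
        self.mid_ch = mid
        self.expand_weight = None
        if mid != in_ch:
            self.expand_weight = _he_init(rng, (mid, in_ch, 1, 1), in_ch)
            self.expand_bn = BatchNorm(mid)
        f = spec.kernel_size
        self.dw_weight = _he_init(rng, (mid, f, f), f * f)
        self.dw_bn = BatchNorm(mid)
        # squeeze-excitation bottleneck sized from the block input channels
        se_mid = se_channels(in_ch, spec.se_ratio)
        self.se_reduce_w = _he_init(rng, (se_mid, mid), mid)
        self.se_reduce_b = np.zeros(se_mid, dtype=np.float32)
        self.se_expand_w = _he_init(rng, (mid, se_mid), se_mid)
        self.se_expand_b = np.zeros(mid, dtype=np.float32)
        self.project_weight = _he_init(rng, (spec.out_channels, mid, 1, 1), mid)
        self.project_bn = BatchNorm(spec.out_channels)
        self.use_skip = spec.stride == 1 and in_ch == spec.out_channels

    def forward(self, x, training=False):
        inputs = x
        if self.expand_weight is not None:
            x = swish(self.expand_bn(conv2d(x, self.expand_weight), training=training))
        x = depthwise_conv2d(x, self.dw_weight, stride=self.spec.stride)
        x = swish(self.dw_bn(x, training=training))
        # squeeze: GAP over space; excite: reduce -> swish -> expand -> sigmoid
        s = global_avg_pool(x)
        s = swish(s @ self.se_reduce_w.T + self.se_reduce_b)
        gate = sigmoid(s @ self.se_expand_w.T + self.se_expand_b)
        x = x * gate[:, :, None, None]
        x = self.project_bn(conv2d(x, self.project_weight), training=training)
        if self.use_skip:
            x = x + inputs
        return x


@dataclass
class BackboneFitResult:
    """Outcome of supervised head training on GAP features."""

    history: pd.DataFrame
    final_accuracy: float
    initial_loss: float
    final_loss: float


class CompoundScalingBackbone:
    """17-layer compound-scaled CNN with GAP feature output.

    Parameters
    ----------
    config : ScalingConfig
        Compound-scaling parameters; the default gives a 256-pixel input.
    seed : int
        Seed for parameter initialisation (deterministic network).
    """

    def __init__(self, config: Optional[ScalingConfig] = None, seed: int = 0):
        self.config = config if config is not None else ScalingConfig()
        self.seed = int(seed)
        multipliers = compound_scale(self.config)
        layers = default_layer_table()
        self.spec = BackboneSpec(
            layers=layers,
            input_resolution=multipliers.input_resolution,
            feature_dim=FEATURE_DIM,
        )
        if self.spec.feature_dim != FEATURE_DIM:
            raise InvalidConfigError(
                f"configuration must yield a {FEATURE_DIM}-dimensional feature vector"
            )
        rng = np.random.default_rng(self.seed)
        self.blocks = []
        in_ch = 3
        for spec in layers:
            if spec.kind == "mbconv":
                self.blocks.append(_MBConv(rng, in_ch, spec))
            else:
                self.blocks.append(_ConvBNAct(rng, in_ch, spec))
            in_ch = spec.out_channels
        self.head_: Optional[tuple] = None  # temporary linear classifier (W, b)

    # ------------------------------------------------------------------ #

    @property
    def feature_dim(self) -> int:
        return self.spec.feature_dim

    @property
    def input_resolution(self) -> int:
        return self.spec.input_resolution

    def spatial_sizes(self) -> list:
        """Spatial side length entering each layer plus the final size."""
        sizes = [self.spec.input_resolution]
        for spec in self.spec.layers:
            sizes.append(conv_output_size(sizes[-1], spec.stride))
        return sizes

    # ------------------------------------------------------------------ #

    def _prepare(self, images) -> np.ndarray:
        """Validate, rescale to [0,1], resize bilinearly, convert to NCHW."""
        if isinstance(images, np.ndarray) and images.ndim == 3:
            images = images[None]
        arrays = []
        res = self.spec.input_resolution
        for img in images:
            arr = np.asarray(img)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise ShapeError(
                    f"expected RGB images with 3 channels, got shape {arr.shape}"
                )
            if arr.dtype == np.uint8:
                arr = arr.astype(np.float32) / 255.0
            else:
                arr = arr.astype(np.float32)
            if arr.shape[0] != res or arr.shape[1] != res:
                im = Image.fromarray(
                    np.clip(arr * 255.0, 0, 255).astype(np.uint8), mode="RGB"
                )
                im = im.resize((res, res), Image.BILINEAR)
                arr = np.asarray(im, dtype=np.float32) / 255.0
            arrays.append(arr)
        if not arrays:
            raise DegenerateInputError("empty image batch")
        batch = np.stack(arrays)
        return np.ascontiguousarray(batch.transpose(0, 3, 1, 2))

    def forward_features(self, images, batch_size: int = 8) -> np.ndarray:
        """Run the trunk and GAP: images -> (N, 2304) feature matrix.

        Deterministic for fixed parameters and inputs; batch norm uses its
        stored running statistics so rows do not depend on batch
        composition.
        """
        x = self._prepare(images)
        chunks = []
        for start in range(0, x.shape[0], batch_size):
            h = x[start : start + batch_size]
            for block in self.blocks:
                h = block.forward(h, training=False)
            chunks.append(global_avg_pool(h))
        return np.concatenate(chunks).astype(np.float64)

    def extract_feature_table(
        self,
        images,
        labels,
        sample_ids: Optional[Sequence[str]] = None,
        class_names: Optional[Sequence[str]] = None,
        batch_size: int = 8,
    ) -> FeatureTable:
        """Convenience wrapper bundling GAP features into a FeatureTable."""
        features = self.forward_features(images, batch_size=batch_size)
        labels = np.asarray(labels, dtype=int)
        if sample_ids is None:
            sample_ids = [f"sample_{i:05d}" for i in range(features.shape[0])]
        if class_names is None:
            class_names = [f"class_{c}" for c in range(int(labels.max()) + 1)]
        return FeatureTable(
            features=features,
            labels=labels,
            sample_ids=list(sample_ids),
            class_names=list(class_names),
        )

    # ------------------------------------------------------------------ #

    def fit(
        self,
        images,
        labels,
        epochs: int = 30,
        learning_rate: float = 0.01,
        seed: int = 0,
        batch_size: int = 8,
    ) -> BackboneFitResult:
        """Supervised fitting via a temporary linear softmax head.

        GAP features are extracted once and a multinomial logistic head is
        trained on them with Adam; the head is kept on ``self.head_`` for
        inspection but is not part of exported features.
        """
        labels = np.asarray(labels, dtype=int)
        classes = np.unique(labels)
        if classes.size < 2:
            raise DegenerateInputError("supervised fitting needs at least 2 classes")
        feats = self.forward_features(images, batch_size=batch_size)
        # standardise for optimisation conditioning
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        F = (feats - mu) / sd
        n, d = F.shape
        n_classes = int(classes.max()) + 1
        onehot = np.eye(n_classes)[labels]

        rng = np.random.default_rng(seed)
        W = rng.normal(0.0, 0.01, size=(d, n_classes))
        b = np.zeros(n_classes)
        mW = np.zeros_like(W); vW = np.zeros_like(W)
        mb = np.zeros_like(b); vb = np.zeros_like(b)
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        records = []
        for epoch in range(1, epochs + 1):
            probs = softmax(F @ W + b)
            loss = -np.mean(np.log(np.clip(probs[np.arange(n), labels], 1e-12, 1.0)))
            grad_logits = (probs - onehot) / n
            gW = F.T @ grad_logits
            gb = grad_logits.sum(axis=0)
            t = epoch
            for g, m, v, p in ((gW, mW, vW, W), (gb, mb, vb, b)):
                m *= beta1; m += (1 - beta1) * g
                v *= beta2; v += (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            acc = float(np.mean(np.argmax(probs, axis=1) == labels))
            records.append({"epoch": epoch, "train_loss": loss, "train_accuracy": acc})

        self.head_ = (W, b, mu, sd)
        final_probs = softmax(F @ W + b)
        final_acc = float(np.mean(np.argmax(final_probs, axis=1) == labels))
        history = pd.DataFrame.from_records(records)
        return BackboneFitResult(
            history=history,
            final_accuracy=final_acc,
            initial_loss=float(history["train_loss"].iloc[0]),
            final_loss=float(history["train_loss"].iloc[-1]),
        )


def build_backbone(config: Optional[ScalingConfig] = None, seed: int = 0) -> CompoundScalingBackbone:
    """Construct the 17-layer network for a scaling configuration."""
    return CompoundScalingBackbone(config=config, seed=seed)
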