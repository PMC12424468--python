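"""Modality encoders: a clinical MLP and a weighted-residual image network.

The image encoder is a residual CNN in which every skip connection is scaled
by a learnable scalar ``alpha`` (one per block, initialized to 1 so training
starts from a plain residual block):

    y = F(x) + alpha * skip(x),   F = [conv -> batch-norm -> LeakyReLU] x 2

When the block changes resolution or channel count, ``skip`` is a learned
1x1 strided projection, also scaled by ``alpha`` so the weighting stays
meaningful across shape changes.  Channels grow 64 -> 128 -> 256 -> 512
across four stages (scaled proportionally for smaller ``base_width``);
dropout regularizes the last two stages.

The clinical MLP maps the encoded metadata row to a 128-d latent via a ReLU
layer and expands it to a 256-d embedding.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor
from .nn import (BatchNorm2d, Conv2d, Dropout, LeakyReLU, Linear,
                 MaxPool2d, Module, Sequential)

__all__ = ["ClinicalMLP", "WeightedResidualBlock", "WeightedResNet"]


class ShapeError(ValueError):
    pass


class ClinicalMLP(Module):
    """affine(d_c -> hidden) -> ReLU -> affine(hidden -> out_dim)."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 hidden: int = 128, out_dim: int = 256):
        super().__init__()
        self.in_features = in_features
        self.out_dim = out_dim
        self.fc1 = Linear(in_features, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ShapeError(
                f"clinical encoder expects {self.in_features} features, "
                f"got {x.shape[-1]}")
        return self.fc2(self.fc1(x).relu())


class WeightedResidualBlock(Module):
    """Residual unit with a learnable scalar weight on the skip path."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, stride: int = 1,
                 dropout_p: float = 0.0, leaky_slope: float = 0.01,
                 alpha_init: float = 1.0):
        super().__init__()
        self.in_channels = in_channels
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng, stride=stride,
                            padding=1, bias=False)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng, stride=1,
                            padding=1, bias=False)
        self.bn2 = BatchNorm2d(out_channels)
        self.act = LeakyReLU(leaky_slope)
        self.dropout = Dropout(dropout_p, rng) if dropout_p > 0 else None
        self.alpha = Tensor(np.array(alpha_init, dtype=np.float32),
                            requires_grad=True)
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv2d(in_channels, out_channels, 1, rng,
                               stride=stride, padding=0, bias=False)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ShapeError(
                f"block expects {self.in_channels} channels, got {x.shape[1]}")
        h = self.act(self.bn1(self.conv1(x)))
        if self.dropout is not None:
            h = self.dropout(h)
        h = self.act(self.bn2(self.conv2(h)))
        skip = x if self.proj is None else self.proj(x)
        # y = F(x) + alpha * skip(x); no activation after the addition
        return h + skip * self.alpha


class WeightedResNet(Module):
    """Weighted-residual CNN image encoder.

    Stem: 7x7 stride-2 conv, batch-norm, LeakyReLU, 3x3 stride-2 max-pool.
    Four stages of [stride-2 block, stride-1 block] doubling the channel
    count each stage; dropout active in stages 3 and 4.  Head: global
    average pool, then a two-layer fully connected network to a
    ``feature_dim``-d embedding (512 at default width).  ``classify`` adds a
    linear class head for the image-only ablation.
    """

    def __init__(self, rng: np.random.Generator, base_width: int = 64,
                 feature_dim: int | None = None, n_classes: int = 7,
                 dropout_p: float = 0.3, leaky_slope: float = 0.01,
                 image_size: int | None = None,
                 literal_softmax_head: bool = False):
        super().__init__()
        w = base_width
        self.feature_dim = feature_dim if feature_dim is not None else 8 * w
        self.image_size = image_size
        self.literal_softmax_head = literal_softmax_head
        self.stem = Sequential(
            Conv2d(3, w, 7, rng, stride=2, padding=3, bias=False),
            BatchNorm2d(w), LeakyReLU(leaky_slope),
            MaxPool2d(3, 2, 1))
        widths = [w, 2 * w, 4 * w, 8 * w]
        self.stages = []
        in_ch = w
        for i, out_ch in enumerate(widths):
            p = dropout_p if i >= 2 else 0.0   # dropout in res3/res4 only
            self.stages.append(Sequential(
                WeightedResidualBlock(in_ch, out_ch, rng, stride=2,
                                      dropout_p=p, leaky_slope=leaky_slope),
                WeightedResidualBlock(out_ch, out_ch, rng, stride=1,
                                      dropout_p=p, leaky_slope=leaky_slope)))
            in_ch = out_ch
        self.head1 = Linear(8 * w, self.feature_dim, rng)
        self.head_act = LeakyReLU(leaky_slope)
        self.head2 = Linear(self.feature_dim, self.feature_dim, rng)
        self.class_head = Linear(self.feature_dim, n_classes, rng)

    # ------------------------------------------------------------------
    def _backbone(self, x: Tensor, capture: dict | None = None) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(
                f"expected B x 3 x S x S input, got shape {x.shape}")
        if self.image_size is not None and x.shape[2] != self.image_size:
            raise ShapeError(
                f"expected spatial size {self.image_size}, got {x.shape[2]}")
        h = self.stem(x)
        for i, stage in enumerate(self.stages):
            h = stage(h)
            if capture is not None:
                capture[f"stage{i + 1}"] = h
        pooled = h.mean(axis=(2, 3))            # adaptive average pool to 1x1
        feat = self.head2(self.head_act(self.head1(pooled)))
        if self.literal_softmax_head:
            feat = feat.softmax(axis=-1)
        return feat

    def features(self, x: Tensor, capture: dict | None = None) -> Tensor:
        """B x feature_dim embedding batch."""
        return self._backbone(x, capture)

    def classify(self, x: Tensor, capture: dict | None = None) -> Tensor:
        """B x n_classes scores (shares the backbone with ``features``)."""
        return self.class_head(self._backbone(x, capture))

    def forward(self, x: Tensor, mode: str = "features",
                capture: dict | None = None) -> Tensor:
        if mode == "features":
            return self.features(x, capture)
        if mode == "classify":
            return self.classify(x, capture)
        raise ValueError(f"unknown mode {mode!r}")

    def alphas(self) -> list[Tensor]:
        """The learnable skip weights, one per residual block."""
        out = []
        for stage in self.stages:
            for block in stage.layers:
                out.append(block.alpha)
        return out
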