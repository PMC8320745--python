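"""Convolutional feature extractors for 32x32 grayscale patches.

Two backbones are provided:

``tiny``
    A four-block plain conv net (~100K parameters) sized so that the full
    training pipeline runs in minutes on one CPU core.  This is the default
    and the configuration exercised by the test suite.

``resnet``
    A small residual network in the same spirit as the deep residual
    architectures used for material recognition: a stem convolution followed
    by residual blocks (two 3x3 convolutions with an identity skip) per
    stage.  Provided for experiments on larger category sets where the extra
    depth pays off.

Both expose, in addition to the final feature vector, one globally pooled
response per stage plus the stem's pooled response — the attachment points
for the auxiliary attribute classifiers.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import Conv2d, Module, avg_pool2, global_avg_pool

__all__ = ["TinyBackbone", "ResidualBackbone", "build_backbone", "BACKBONES"]


class TinyBackbone(Module):
    """Stem + 4 plain conv blocks; 32x32x1 input -> 64-dim feature vector."""

    feature_dim = 64
    # pooled-response widths: stem + one per block
    stage_dims = (8, 16, 32, 64, 64)

    def __init__(self, rng: np.random.Generator):
        self.stem = Conv2d(1, 8, rng)
        self.block1 = Conv2d(8, 16, rng)
        self.block2 = Conv2d(16, 32, rng)
        self.block3 = Conv2d(32, 64, rng)
        self.block4 = Conv2d(64, 64, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        stages: list[Tensor] = []
        h = avg_pool2(self.stem(x).relu())          # 8 x 16 x 16
        stages.append(global_avg_pool(h))
        h = avg_pool2(self.block1(h).relu())        # 16 x 8 x 8
        stages.append(global_avg_pool(h))
        h = avg_pool2(self.block2(h).relu())        # 32 x 4 x 4
        stages.append(global_avg_pool(h))
        h = avg_pool2(self.block3(h).relu())        # 64 x 2 x 2
        stages.append(global_avg_pool(h))
        h = self.block4(h).relu()                   # 64 x 2 x 2
        feat = global_avg_pool(h)
        stages.append(feat)
        return feat, stages


class _ResBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, rng)
        self.conv2 = Conv2d(channels, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return (self.conv2(self.conv1(x).relu()) + x).relu()


class ResidualBackbone(Module):
    """Stem + 3 residual stages with channel doubling between stages."""

    feature_dim = 64
    stage_dims = (16, 16, 32, 64)

    def __init__(self, rng: np.random.Generator):
        self.stem = Conv2d(1, 16, rng)
        self.res1 = _ResBlock(16, rng)
        self.widen1 = Conv2d(16, 32, rng, ksize=1)
        self.res2 = _ResBlock(32, rng)
        self.widen2 = Conv2d(32, 64, rng, ksize=1)
        self.res3 = _ResBlock(64, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        stages: list[Tensor] = []
        h = avg_pool2(self.stem(x).relu())          # 16 x 16 x 16
        stages.append(global_avg_pool(h))
        h = avg_pool2(self.res1(h))                 # 16 x 8 x 8
        stages.append(global_avg_pool(h))
        h = avg_pool2(self.widen1(h).relu())
        h = self.res2(h)                            # 32 x 4 x 4
        stages.append(global_avg_pool(h))
        h = self.widen2(h).relu()
        h = self.res3(h)                            # 64 x 4 x 4
        feat = global_avg_pool(h)
        stages.append(feat)
        return feat, stages


BACKBONES = {"tiny": TinyBackbone, "resnet": ResidualBackbone}


def build_backbone(name: str, rng: np.random.Generator) -> Module:
    try:
        cls = BACKBONES[name]
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}") from None
    return cls(rng)
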