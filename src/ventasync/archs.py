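"""Feature-extractor architectures.

Each builder returns the convolutional trunk only (no pooling head): a
``Sequential`` for the chain-structured nets, or a composite forward-only
graph for the inception-residual net.  The classification models wrap
these with global average pooling and a dense softmax head.

Four extractors are provided:

* ``tiny_cnn`` — a three-block, 64-feature net small enough to train on a
  CPU in seconds; its layer table is documented in ``docs/methods.md``.
* ``mobilenet_v1`` — depthwise-separable MobileNet at width 1.0
  (3,228,864 trunk parameters, 1024 features).
* ``vgg16_bn`` — the 13-convolution VGG16 trunk with one batch-norm layer
  inserted between the last convolution of each of the five blocks and
  the following max-pool (14,720,576 trunk parameters, 512 features).
* ``inception_resnet_v2`` — the standard Inception-ResNet-v2 trunk
  (54,336,736 parameters, 1536 features; batch-norm without gamma, as
  published).
"""

from __future__ import annotations

import numpy as np

from .nn.layers import (AvgPool2D, BatchNorm, Conv2D, DepthwiseConv2D,
                        Dense, MaxPool2D, ReLU)
from .nn.network import Branch, Residual, Sequential

FEATURE_DIMS = {
    "tiny_cnn": 64,
    "mobilenet_v1": 1024,
    "vgg16_bn": 512,
    "inception_resnet_v2": 1536,
}

ARCH_NAMES = tuple(FEATURE_DIMS)


def build_extractor(name: str, rng=None):
    """Build the named trunk with freshly initialized weights."""
    rng = rng or np.random.default_rng(0)
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown extractor {name!r}; "
                         f"choose from {ARCH_NAMES}") from None
    return builder(rng)


def tiny_cnn(rng) -> Sequential:
    """56->28->14 spatial pyramid via strided convolutions; 64 features."""
    return Sequential([
        Conv2D(3, 16, 5, stride=4, padding="same", rng=rng, name="block1_conv"),
        BatchNorm(16, name="block1_bn"), ReLU(),
        Conv2D(16, 32, 3, stride=2, padding="same", rng=rng, name="block2_conv"),
        BatchNorm(32, name="block2_bn"), ReLU(),
        Conv2D(32, 64, 3, stride=2, padding="same", rng=rng, name="block3_conv"),
        BatchNorm(64, name="block3_bn"), ReLU(),
    ], name="tiny_cnn")


def mobilenet_v1(rng) -> Sequential:
    layers = [Conv2D(3, 32, 3, stride=2, rng=rng, name="conv1"),
              BatchNorm(32), ReLU()]
    cfg = [(32, 64, 1), (64, 128, 2), (128, 128, 1), (128, 256, 2),
           (256, 256, 1), (256, 512, 2)] + [(512, 512, 1)] * 5 + \
          [(512, 1024, 2), (1024, 1024, 1)]
    for i, (cin, cout, s) in enumerate(cfg, start=1):
        layers += [DepthwiseConv2D(cin, 3, stride=s, rng=rng, name=f"dw{i}"),
                   BatchNorm(cin), ReLU(),
                   Conv2D(cin, cout, 1, rng=rng, name=f"pw{i}"),
                   BatchNorm(cout), ReLU()]
    return Sequential(layers, name="mobilenet_v1")


def vgg16_bn(rng) -> Sequential:
    layers = []
    cin = 3
    for b, (cout, reps) in enumerate([(64, 2), (128, 2), (256, 3),
                                      (512, 3), (512, 3)], start=1):
        for r in range(reps):
            layers += [Conv2D(cin, cout, 3, use_bias=True, rng=rng,
                              name=f"block{b}_conv{r + 1}"), ReLU()]
            cin = cout
        # batch norm between the block's last convolution and its max-pool
        layers += [BatchNorm(cout, name=f"block{b}_bn"), MaxPool2D(2)]
    return Sequential(layers, name="vgg16_bn")


def _conv_bn(cin, cout, kernel, rng, stride=1, padding="same", act=True):
    layers = [Conv2D(cin, cout, kernel, stride=stride, padding=padding, rng=rng),
              BatchNorm(cout, scale=False)]
    if act:
        layers.append(ReLU())
    return layers


def _block35(rng):
    branch = Branch([
        _conv_bn(320, 32, 1, rng),
        _conv_bn(320, 32, 1, rng) + _conv_bn(32, 32, 3, rng),
        _conv_bn(320, 32, 1, rng) + _conv_bn(32, 48, 3, rng)
        + _conv_bn(48, 64, 3, rng),
    ])
    up = Conv2D(128, 320, 1, use_bias=True, rng=rng)
    return Residual(Sequential([branch, up]), scale=0.17)


def _block17(rng):
    branch = Branch([
        _conv_bn(1088, 192, 1, rng),
        _conv_bn(1088, 128, 1, rng) + _conv_bn(128, 160, (1, 7), rng)
        + _conv_bn(160, 192, (7, 1), rng),
    ])
    up = Conv2D(384, 1088, 1, use_bias=True, rng=rng)
    return Residual(Sequential([branch, up]), scale=0.1)


def _block8(rng, scale=0.2, activate=True):
    branch = Branch([
        _conv_bn(2080, 192, 1, rng),
        _conv_bn(2080, 192, 1, rng) + _conv_bn(192, 224, (1, 3), rng)
        + _conv_bn(224, 256, (3, 1), rng),
    ])
    up = Conv2D(448, 2080, 1, use_bias=True, rng=rng)
    return Residual(Sequential([branch, up]), scale=scale, activate=activate)


def inception_resnet_v2(rng) -> Sequential:
    stem = (
        _conv_bn(3, 32, 3, rng, stride=2, padding="valid")
        + _conv_bn(32, 32, 3, rng, padding="valid")
        + _conv_bn(32, 64, 3, rng)
        + [MaxPool2D(3, 2, padding="valid")]
        + _conv_bn(64, 80, 1, rng, padding="valid")
        + _conv_bn(80, 192, 3, rng, padding="valid")
        + [MaxPool2D(3, 2, padding="valid")]
    )
    mixed_5b = Branch([
        _conv_bn(192, 96, 1, rng),
        _conv_bn(192, 48, 1, rng) + _conv_bn(48, 64, 5, rng),
        _conv_bn(192, 64, 1, rng) + _conv_bn(64, 96, 3, rng)
        + _conv_bn(96, 96, 3, rng),
        [AvgPool2D(3, 1, padding="same")] + _conv_bn(192, 64, 1, rng),
    ])
    mixed_6a = Branch([
        _conv_bn(320, 384, 3, rng, stride=2, padding="valid"),
        _conv_bn(320, 256, 1, rng) + _conv_bn(256, 256, 3, rng)
        + _conv_bn(256, 384, 3, rng, stride=2, padding="valid"),
        [MaxPool2D(3, 2, padding="valid")],
    ])
    mixed_7a = Branch([
        _conv_bn(1088, 256, 1, rng) + _conv_bn(256, 384, 3, rng, stride=2,
                                               padding="valid"),
        _conv_bn(1088, 256, 1, rng) + _conv_bn(256, 288, 3, rng, stride=2,
                                               padding="valid"),
        _conv_bn(1088, 256, 1, rng) + _conv_bn(256, 288, 3, rng)
        + _conv_bn(288, 320, 3, rng, stride=2, padding="valid"),
        [MaxPool2D(3, 2, padding="valid")],
    ])
    layers = (stem + [mixed_5b]
              + [_block35(rng) for _ in range(10)]
              + [mixed_6a]
              + [_block17(rng) for _ in range(20)]
              + [mixed_7a]
              + [_block8(rng) for _ in range(9)]
              + [_block8(rng, scale=1.0, activate=False)]
              + _conv_bn(2080, 1536, 1, rng))
    return Sequential(layers, name="inception_resnet_v2")


_BUILDERS = {
    "tiny_cnn": tiny_cnn,
    "mobilenet_v1": mobilenet_v1,
    "vgg16_bn": vgg16_bn,
    "inception_resnet_v2": inception_resnet_v2,
}
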