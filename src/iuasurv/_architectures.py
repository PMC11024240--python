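"""Declarative shape programs for the ImageNet backbone architectures.

The transfer-learning backbones (InceptionV3, ResNet50, InceptionResNetV2,
VGG19) are represented here as layer tapes: each builder walks the
architecture graph in its Keras dialect (headless, ``include_top=False``),
tracking channel and spatial dimensions, and records every parameterized
layer.  Parameter counts (trainable plus batch-norm moving statistics) and
forward-pass FLOPs are then exact arithmetic over the tape -- no weights are
ever instantiated, which is all the complexity accounting needs.

Batch-norm conventions follow each architecture's reference implementation:
ResNet50 uses scaled BN (gamma, beta, moving mean, moving variance = 4 per
channel); the Inception family uses scale-free BN (3 per channel).  FLOPs
use the multiply-accumulate = 2 FLOPs convention, recorded in the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Tuple

__all__ = ["architecture_tape", "KNOWN_ARCHITECTURES"]


@dataclass
class LayerRecord:
    name: str
    kind: str
    n_params: int
    flops: int


@dataclass
class Tape:
    h: int
    w: int
    c: int
    records: List[LayerRecord] = field(default_factory=list)

    # -- helpers -----------------------------------------------------------
    def _out_size(self, size, k, stride, pad):
        if pad == "same":
            return math.ceil(size / stride)
        return (size - k) // stride + 1

    def clone(self) -> "Tape":
        return Tape(self.h, self.w, self.c, [])

    # -- layers ------------------------------------------------------------
    def conv(
        self,
        out_ch: int,
        kh: int,
        kw: int = None,
        stride: int = 1,
        pad: str = "same",
        bias: bool = True,
        bn: str = None,
        name: str = "conv",
    ) -> "Tape":
        """2D convolution; ``bn`` is None, 'scale' (4/ch) or 'noscale' (3/ch)."""
        kw = kh if kw is None else kw
        oh = self._out_size(self.h, kh, stride, pad)
        ow = self._out_size(self.w, kw, stride, pad)
        n_params = kh * kw * self.c * out_ch + (out_ch if bias else 0)
        flops = 2 * kh * kw * self.c * oh * ow * out_ch
        if bias:
            flops += oh * ow * out_ch
        self.records.append(LayerRecord(name, "conv", n_params, flops))
        if bn is not None:
            per_ch = 4 if bn == "scale" else 3
            self.records.append(
                LayerRecord(name + "_bn", "bn", per_ch * out_ch, 2 * oh * ow * out_ch)
            )
        self.h, self.w, self.c = oh, ow, out_ch
        return self

    def pool(self, k: int, stride: int, pad: str = "valid", kind: str = "max") -> "Tape":
        oh = self._out_size(self.h, k, stride, pad)
        ow = self._out_size(self.w, k, stride, pad)
        self.records.append(
            LayerRecord(f"{kind}pool", "pool", 0, k * k * oh * ow * self.c)
        )
        self.h, self.w = oh, ow
        return self

    def zeropad(self, p: int) -> "Tape":
        self.h += 2 * p
        self.w += 2 * p
        return self

    def branch(self, *paths: Callable[["Tape"], "Tape"]) -> "Tape":
        """Run parallel paths from the current shape; concatenate channels."""
        outs = []
        for path in paths:
            sub = self.clone()
            path(sub)
            outs.append(sub)
        h0, w0 = outs[0].h, outs[0].w
        assert all(o.h == h0 and o.w == w0 for o in outs), "branch shape mismatch"
        for o in outs:
            self.records.extend(o.records)
        self.h, self.w = h0, w0
        self.c = sum(o.c for o in outs)
        return self

    def set_channels(self, c: int) -> "Tape":
        """Channel override after a residual merge (sum keeps input width)."""
        self.c = c
        return self

    # -- accounting --------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(r.n_params for r in self.records)

    @property
    def flops(self) -> int:
        return sum(r.flops for r in self.records)


# ---------------------------------------------------------------------------
# VGG19
# ---------------------------------------------------------------------------


def _vgg19(size: int) -> Tape:
    t = Tape(size, size, 3)
    for block, (n_convs, ch) in enumerate(
        [(2, 64), (2, 128), (4, 256), (4, 512), (4, 512)], start=1
    ):
        for i in range(n_convs):
            t.conv(ch, 3, name=f"block{block}_conv{i + 1}")
        t.pool(2, 2)
    return t


# ---------------------------------------------------------------------------
# ResNet50 (v1, scaled BN, biased convolutions)
# ---------------------------------------------------------------------------


def _resnet_block(t: Tape, filters: int, stride: int, conv_shortcut: bool, name: str):
    c_in = t.c

    def shortcut(s: Tape):
        if conv_shortcut:
            s.conv(4 * filters, 1, stride=stride, bn="scale", name=name + "_0")
        return s

    def main(s: Tape):
        s.conv(filters, 1, stride=stride, bn="scale", name=name + "_1")
        s.conv(filters, 3, bn="scale", name=name + "_2")
        s.conv(4 * filters, 1, bn="scale", name=name + "_3")
        return s

    t.branch(shortcut, main)
    t.set_channels(4 * filters)  # residual add, not concat
    return t


def _resnet50(size: int) -> Tape:
    t = Tape(size, size, 3)
    t.zeropad(3)
    t.conv(64, 7, stride=2, pad="valid", bn="scale", name="conv1")
    t.zeropad(1)
    t.pool(3, 2)
    for stack, (filters, blocks, stride) in enumerate(
        [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)], start=2
    ):
        for b in range(blocks):
            _resnet_block(
                t,
                filters,
                stride if b == 0 else 1,
                conv_shortcut=(b == 0),
                name=f"conv{stack}_block{b + 1}",
            )
    return t


# ---------------------------------------------------------------------------
# InceptionV3 (scale-free BN, no conv bias)
# ---------------------------------------------------------------------------


def _cb(t: Tape, ch, kh, kw=None, stride=1, pad="same", name="cb"):
    return t.conv(ch, kh, kw, stride=stride, pad=pad, bias=False, bn="noscale", name=name)


def _inception_v3(size: int) -> Tape:
    t = Tape(size, size, 3)
    _cb(t, 32, 3, stride=2, pad="valid")
    _cb(t, 32, 3, pad="valid")
    _cb(t, 64, 3)
    t.pool(3, 2)
    _cb(t, 80, 1, pad="valid")
    _cb(t, 192, 3, pad="valid")
    t.pool(3, 2)

    def mixed_a(t: Tape, pool_ch: int):
        t.branch(
            lambda s: _cb(s, 64, 1),
            lambda s: _cb(_cb(s, 48, 1), 64, 5),
            lambda s: _cb(_cb(_cb(s, 64, 1), 96, 3), 96, 3),
            lambda s: _cb(s.pool(3, 1, pad="same", kind="avg"), pool_ch, 1),
        )

    mixed_a(t, 32)  # mixed0
    mixed_a(t, 64)  # mixed1
    mixed_a(t, 64)  # mixed2

    # mixed3: grid reduction
    t.branch(
        lambda s: _cb(s, 384, 3, stride=2, pad="valid"),
        lambda s: _cb(_cb(_cb(s, 64, 1), 96, 3), 96, 3, stride=2, pad="valid"),
        lambda s: s.pool(3, 2),
    )

    def mixed_b(t: Tape, mid: int):
        t.branch(
            lambda s: _cb(s, 192, 1),
            lambda s: _cb(_cb(_cb(s, mid, 1), mid, 1, 7), 192, 7, 1),
            lambda s: _cb(
                _cb(_cb(_cb(_cb(s, mid, 1), mid, 7, 1), mid, 1, 7), mid, 7, 1), 192, 1, 7
            ),
            lambda s: _cb(s.pool(3, 1, pad="same", kind="avg"), 192, 1),
        )

    mixed_b(t, 128)  # mixed4
    mixed_b(t, 160)  # mixed5
    mixed_b(t, 160)  # mixed6
    mixed_b(t, 192)  # mixed7

    # mixed8: grid reduction
    t.branch(
        lambda s: _cb(_cb(s, 192, 1), 320, 3, stride=2, pad="valid"),
        lambda s: _cb(
            _cb(_cb(_cb(s, 192, 1), 192, 1, 7), 192, 7, 1), 192, 3, stride=2, pad="valid"
        ),
        lambda s: s.pool(3, 2),
    )

    def mixed_c(t: Tape):
        t.branch(
            lambda s: _cb(s, 320, 1),
            lambda s: _cb(s, 384, 1).branch(
                lambda u: _cb(u, 384, 1, 3), lambda u: _cb(u, 384, 3, 1)
            ),
            lambda s: _cb(_cb(s, 448, 1), 384, 3).branch(
                lambda u: _cb(u, 384, 1, 3), lambda u: _cb(u, 384, 3, 1)
            ),
            lambda s: _cb(s.pool(3, 1, pad="same", kind="avg"), 192, 1),
        )

    mixed_c(t)  # mixed9
    mixed_c(t)  # mixed10
    return t


# ---------------------------------------------------------------------------
# InceptionResNetV2 (scale-free BN; residual 'up' projections carry a bias
# and no BN)
# ---------------------------------------------------------------------------


def _inception_resnet_v2(size: int) -> Tape:
    t = Tape(size, size, 3)
    _cb(t, 32, 3, stride=2, pad="valid")
    _cb(t, 32, 3, pad="valid")
    _cb(t, 64, 3)
    t.pool(3, 2)
    _cb(t, 80, 1, pad="valid")
    _cb(t, 192, 3, pad="valid")
    t.pool(3, 2)

    # mixed_5b
    t.branch(
        lambda s: _cb(s, 96, 1),
        lambda s: _cb(_cb(s, 48, 1), 64, 5),
        lambda s: _cb(_cb(_cb(s, 64, 1), 96, 3), 96, 3),
        lambda s: _cb(s.pool(3, 1, pad="same", kind="avg"), 64, 1),
    )

    def residual_block(t: Tape, paths, name: str):
        c_in = t.c
        sub = t.clone()
        sub.branch(*paths)
        # linear projection back to the trunk width: 1x1 conv, bias, no BN
        sub.conv(c_in, 1, bias=True, bn=None, name=name + "_up")
        t.records.extend(sub.records)
        # residual sum: shape unchanged

    for i in range(10):  # block35
        residual_block(
            t,
            [
                lambda s: _cb(s, 32, 1),
                lambda s: _cb(_cb(s, 32, 1), 32, 3),
                lambda s: _cb(_cb(_cb(s, 32, 1), 48, 3), 64, 3),
            ],
            f"block35_{i + 1}",
        )

    # mixed_6a
    t.branch(
        lambda s: _cb(s, 384, 3, stride=2, pad="valid"),
        lambda s: _cb(_cb(_cb(s, 256, 1), 256, 3), 384, 3, stride=2, pad="valid"),
        lambda s: s.pool(3, 2),
    )

    for i in range(20):  # block17
        residual_block(
            t,
            [
                lambda s: _cb(s, 192, 1),
                lambda s: _cb(_cb(_cb(s, 128, 1), 160, 1, 7), 192, 7, 1),
            ],
            f"block17_{i + 1}",
        )

    # mixed_7a
    t.branch(
        lambda s: _cb(_cb(s, 256, 1), 384, 3, stride=2, pad="valid"),
        lambda s: _cb(_cb(s, 256, 1), 288, 3, stride=2, pad="valid"),
        lambda s: _cb(_cb(_cb(s, 256, 1), 288, 3), 320, 3, stride=2, pad="valid"),
        lambda s: s.pool(3, 2),
    )

    for i in range(10):  # block8 (9 scaled + 1 final unactivated)
        residual_block(
            t,
            [
                lambda s: _cb(s, 192, 1),
                lambda s: _cb(_cb(_cb(s, 192, 1), 224, 1, 3), 256, 3, 1),
            ],
            f"block8_{i + 1}",
        )

    _cb(t, 1536, 1, name="conv_7b")
    return t


KNOWN_ARCHITECTURES: Dict[str, Callable[[int], Tape]] = {
    "vgg19": _vgg19,
    "resnet50": _resnet50,
    "inception_v3": _inception_v3,
    "inception_resnet_v2": _inception_resnet_v2,
}


def architecture_tape(name: str, input_size: int = 336) -> Tape:
    """Build the layer tape for a named backbone at the given input size."""
    if name not in KNOWN_ARCHITECTURES:
        raise ValueError(
            f"unknown backbone {name!r}; known: {sorted(KNOWN_ARCHITECTURES)}"
        )
    return KNOWN_ARCHITECTURES[name](input_size)
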