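"""Convolutional / transformer feature extractors.

``mobilenet_v3_small`` follows the published architecture table exactly
(inverted residual blocks, squeeze-excitation with channel counts rounded
to multiples of 8, hardswish activations), with the final 1000-way
classification linear removed and the penultimate 576->1024 linear
retained — yielding the canonical 1,517,856 trainable parameters
(1.52 M).  ``tiny_cnn`` is a three-block CNN used for fast experiments on
small synthetic images.  ``resnet50``, ``efficientnet_b0`` and ``vit_b16``
are canonical reference classifiers used as single-backbone baselines on
RGB input; their internals follow the standard published designs.

Every builder returns a :class:`Backbone` whose forward maps an NHWC
image batch to an (N, out_dim) embedding; ``backbone.last_conv`` marks the
module whose output feeds saliency mapping.
"""

from __future__ import annotations

import numpy as np

from .attention import MultiHeadSelfAttention
from .layers import (
    F32,
    BatchNorm,
    Conv2d,
    Dropout,
    Flatten,
    GlobalAvgPool,
    Hardswish,
    Identity,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    ReLU,
    SEUnit,
    Sequential,
    SiLU,
    gelu,
)


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class Backbone(Module):
    """A feature extractor with a declared embedding width."""

    def __init__(self, body: Module, out_dim: int, last_conv: Module | None = None):
        self.body = body
        self.out_dim = out_dim
        self.last_conv = last_conv

    def forward(self, x, training=False):
        return self.body(x, training=training)

    def backward(self, dy):
        return self.body._backprop(dy)


class InvertedResidual(Module):
    """MobileNetV3 bottleneck: expand (1x1) -> depthwise -> [SE] -> project,
    with a residual connection when stride is 1 and widths match."""

    def __init__(self, c_in, kernel, c_exp, c_out, use_se, act, stride, name):
        Act = Hardswish if act == "HS" else ReLU
        layers: list[Module] = []
        if c_exp != c_in:
            layers += [
                Conv2d(c_in, c_exp, 1, name=f"{name}.expand"),
                BatchNorm(c_exp, eps=1e-3, momentum=0.01, name=f"{name}.expand_bn"),
                Act(),
            ]
        layers += [
            Conv2d(c_exp, c_exp, kernel, stride=stride, groups=c_exp,
                   name=f"{name}.dw"),
            BatchNorm(c_exp, eps=1e-3, momentum=0.01, name=f"{name}.dw_bn"),
            Act(),
        ]
        if use_se:
            layers.append(
                SEUnit(c_exp, _make_divisible(c_exp // 4), name=f"{name}.se")
            )
        layers += [
            Conv2d(c_exp, c_out, 1, name=f"{name}.project"),
            BatchNorm(c_out, eps=1e-3, momentum=0.01, name=f"{name}.project_bn"),
        ]
        self.block = Sequential(*layers)
        self.use_res = stride == 1 and c_in == c_out

    def forward(self, x, training=False):
        y = self.block(x, training=training)
        return (x + y).astype(F32) if self.use_res else y

    def backward(self, dy):
        dx = self.block._backprop(dy)
        return (dx + dy).astype(F32) if self.use_res else dx


# (c_in, kernel, c_exp, c_out, use_se, activation, stride)
_MNV3_SMALL = [
    (16, 3, 16, 16, True, "RE", 2),
    (16, 3, 72, 24, False, "RE", 2),
    (24, 3, 88, 24, False, "RE", 1),
    (24, 5, 96, 40, True, "HS", 2),
    (40, 5, 240, 40, True, "HS", 1),
    (40, 5, 240, 40, True, "HS", 1),
    (40, 5, 120, 48, True, "HS", 1),
    (48, 5, 144, 48, True, "HS", 1),
    (48, 5, 288, 96, True, "HS", 2),
    (96, 5, 576, 96, True, "HS", 1),
    (96, 5, 576, 96, True, "HS", 1),
]


def mobilenet_v3_small(out_dim: int = 1024, dropout: float = 0.2) -> Backbone:
    """MobileNetV3-Small encoder ending at the ``out_dim`` embedding."""
    layers: list[Module] = [
        Conv2d(3, 16, 3, stride=2, name="stem"),
        BatchNorm(16, eps=1e-3, momentum=0.01, name="stem_bn"),
        Hardswish(),
    ]
    for i, cfg in enumerate(_MNV3_SMALL):
        layers.append(InvertedResidual(*cfg, name=f"block{i}"))
    last_conv = Sequential(
        Conv2d(96, 576, 1, name="last_conv"),
        BatchNorm(576, eps=1e-3, momentum=0.01, name="last_conv_bn"),
        Hardswish(),
    )
    layers.append(last_conv)
    head = Sequential(
        GlobalAvgPool(),
        Linear(576, out_dim, name="embed"),
        Hardswish(),
        Dropout(dropout),
    )
    return Backbone(Sequential(*layers, head), out_dim, last_conv=last_conv)


def tiny_cnn(out_dim: int = 64, width: int = 16) -> Backbone:
    """Four-block CNN for fast desk-scale experiments (64x64 inputs).

    The final 3x3 block sits on the stride-8 grid, so its units cover a
    receptive field of roughly half a 64 px image — wide enough to
    respond to lesion-scale regions rather than just their edges, which
    keeps class-activation maps meaningful at this scale.
    """
    w = width
    last_conv = Sequential(
        Conv2d(4 * w, 8 * w, 3, name="t.conv4"),
        BatchNorm(8 * w, name="t.bn4"),
        ReLU(),
    )
    body = Sequential(
        Conv2d(3, w, 3, stride=2, name="t.conv1"),
        BatchNorm(w, name="t.bn1"),
        ReLU(),
        Conv2d(w, 2 * w, 3, stride=2, name="t.conv2"),
        BatchNorm(2 * w, name="t.bn2"),
        ReLU(),
        Conv2d(2 * w, 4 * w, 3, stride=2, name="t.conv3"),
        BatchNorm(4 * w, name="t.bn3"),
        ReLU(),
        last_conv,
        GlobalAvgPool(),
        Linear(8 * w, out_dim, name="t.embed"),
        ReLU(),
    )
    return Backbone(body, out_dim, last_conv=last_conv)


# ---------------------------------------------------------------------------
# reference baselines (single-backbone RGB classifiers)
# ---------------------------------------------------------------------------

class _Bottleneck(Module):
    def __init__(self, c_in, width, c_out, stride, name):
        self.conv = Sequential(
            Conv2d(c_in, width, 1, name=f"{name}.c1"),
            BatchNorm(width, name=f"{name}.bn1"),
            ReLU(),
            Conv2d(width, width, 3, stride=stride, name=f"{name}.c2"),
            BatchNorm(width, name=f"{name}.bn2"),
            ReLU(),
            Conv2d(width, c_out, 1, name=f"{name}.c3"),
            BatchNorm(c_out, name=f"{name}.bn3"),
        )
        if stride != 1 or c_in != c_out:
            self.down: Module | None = Sequential(
                Conv2d(c_in, c_out, 1, stride=stride, name=f"{name}.down"),
                BatchNorm(c_out, name=f"{name}.down_bn"),
            )
        else:
            self.down = None
        self.relu = ReLU()

    def forward(self, x, training=False):
        y = self.conv(x, training=training)
        sc = self.down(x, training=training) if self.down is not None else x
        return self.relu(y + sc, training=training)

    def backward(self, dy):
        d = self.relu._backprop(dy)
        dx = self.conv._backprop(d)
        dx = dx + (self.down._backprop(d) if self.down is not None else d)
        return dx.astype(F32)


class _MaxPool3x3s2(Module):
    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
        ho, wo = (h + 1) // 2, (w + 1) // 2
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        win = win[:, ::2, ::2][:, :ho, :wo]
        flat = win.reshape(n, ho, wo, c, 9)
        self._arg = flat.argmax(axis=-1)
        self._xshape = x.shape
        return flat.max(axis=-1).astype(F32)

    def backward(self, dy):
        n, h, w, c = self._xshape
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=F32)
        ho, wo = dy.shape[1], dy.shape[2]
        ii, jj = np.divmod(self._arg, 3)
        bi = np.arange(n)[:, None, None, None]
        hi = (np.arange(ho) * 2)[None, :, None, None] + ii
        wi = (np.arange(wo) * 2)[None, None, :, None] + jj
        ci = np.arange(c)[None, None, None, :]
        np.add.at(dxp, (bi, hi, wi, ci), dy)
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


def resnet50(num_classes: int = 6) -> Backbone:
    """Canonical ResNet-50 classifier head on RGB."""
    stages = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
    layers: list[Module] = [
        Conv2d(3, 64, 7, stride=2, padding=3, name="r.stem"),
        BatchNorm(64, name="r.stem_bn"),
        ReLU(),
        _MaxPool3x3s2(),
    ]
    c_in = 64
    last_block: Module | None = None
    for si, (width, c_out, blocks, stride) in enumerate(stages):
        for b in range(blocks):
            blk = _Bottleneck(c_in, width, c_out, stride if b == 0 else 1,
                              name=f"r.s{si}b{b}")
            layers.append(blk)
            c_in = c_out
            last_block = blk
    layers += [GlobalAvgPool(), Linear(2048, num_classes, name="r.fc")]
    return Backbone(Sequential(*layers), num_classes, last_conv=last_block)


class _MBConv(Module):
    """EfficientNet MBConv (SiLU activations, sigmoid-gated SE sized from
    the block *input* channels)."""

    def __init__(self, c_in, c_out, kernel, stride, expand, name):
        c_exp = c_in * expand
        layers: list[Module] = []
        if expand != 1:
            layers += [
                Conv2d(c_in, c_exp, 1, name=f"{name}.expand"),
                BatchNorm(c_exp, eps=1e-3, momentum=0.01, name=f"{name}.expand_bn"),
                SiLU(),
            ]
        layers += [
            Conv2d(c_exp, c_exp, kernel, stride=stride, groups=c_exp, name=f"{name}.dw"),
            BatchNorm(c_exp, eps=1e-3, momentum=0.01, name=f"{name}.dw_bn"),
            SiLU(),
            SEUnit(c_exp, max(1, c_in // 4), gate="sigmoid", act="silu",
                   name=f"{name}.se"),
            Conv2d(c_exp, c_out, 1, name=f"{name}.project"),
            BatchNorm(c_out, eps=1e-3, momentum=0.01, name=f"{name}.project_bn"),
        ]
        self.block = Sequential(*layers)
        self.use_res = stride == 1 and c_in == c_out

    def forward(self, x, training=False):
        y = self.block(x, training=training)
        return (x + y).astype(F32) if self.use_res else y

    def backward(self, dy):
        dx = self.block._backprop(dy)
        return (dx + dy).astype(F32) if self.use_res else dx


# (expand, c_out, repeats, stride, kernel)
_EFFNET_B0 = [
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
]


def efficientnet_b0(num_classes: int = 6, dropout: float = 0.2) -> Backbone:
    layers: list[Module] = [
        Conv2d(3, 32, 3, stride=2, name="e.stem"),
        BatchNorm(32, eps=1e-3, momentum=0.01, name="e.stem_bn"),
        SiLU(),
    ]
    c_in = 32
    for si, (expand, c_out, repeats, stride, kernel) in enumerate(_EFFNET_B0):
        for b in range(repeats):
            layers.append(
                _MBConv(c_in, c_out, kernel, stride if b == 0 else 1, expand,
                        name=f"e.s{si}b{b}")
            )
            c_in = c_out
    last_conv = Sequential(
        Conv2d(c_in, 1280, 1, name="e.head_conv"),
        BatchNorm(1280, eps=1e-3, momentum=0.01, name="e.head_bn"),
        SiLU(),
    )
    layers += [last_conv, GlobalAvgPool(), Dropout(dropout),
               Linear(1280, num_classes, name="e.fc")]
    return Backbone(Sequential(*layers), num_classes, last_conv=last_conv)


class _PatchEmbed(Module):
    def __init__(self, dim: int, patch: int, name: str = "v.patch"):
        self.patch = patch
        self.proj = Linear(patch * patch * 3, dim, name=name)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        p = self.patch
        if h % p or w % p:
            raise ValueError(f"image size must be a multiple of patch size {p}")
        self._hw = (h // p, w // p)
        t = x.reshape(n, h // p, p, w // p, p, c).transpose(0, 1, 3, 2, 4, 5)
        t = t.reshape(n, (h // p) * (w // p), p * p * c)
        return self.proj(t, training=training)

    def backward(self, dy):
        dt = self.proj.backward(dy)
        n = dt.shape[0]
        gh, gw = self._hw
        p = self.patch
        dt = dt.reshape(n, gh, gw, p, p, 3).transpose(0, 1, 3, 2, 4, 5)
        return dt.reshape(n, gh * p, gw * p, 3)


class _ViTBlock(Module):
    def __init__(self, dim, heads, mlp_dim, name):
        self.ln1 = LayerNorm(dim, name=f"{name}.ln1")
        self.attn = MultiHeadSelfAttention(dim, heads, name=f"{name}.attn")
        self.ln2 = LayerNorm(dim, name=f"{name}.ln2")
        self.mlp = Sequential(
            Linear(dim, mlp_dim, name=f"{name}.fc1", init="xavier"),
            gelu(),
            Linear(mlp_dim, dim, name=f"{name}.fc2", init="xavier"),
        )

    def forward(self, x, training=False):
        x = x + self.attn(self.ln1(x, training), training)
        return (x + self.mlp(self.ln2(x, training), training)).astype(F32)

    def backward(self, dy):
        d = dy + self.ln2.backward(self.mlp._backprop(dy))
        return (d + self.ln1.backward(self.attn.backward(d))).astype(F32)


class _ViT(Module):
    def __init__(self, image_size, patch, dim, depth, heads, mlp_dim, num_classes):
        self.embed = _PatchEmbed(dim, patch)
        tokens = (image_size // patch) ** 2 + 1
        self.cls = Parameter("v.cls", np.zeros((1, 1, dim)))
        self.pos = Parameter("v.pos", np.random.default_rng(0).normal(0, 0.02, (1, tokens, dim)))
        self.blocks = Sequential(
            *[_ViTBlock(dim, heads, mlp_dim, name=f"v.b{i}") for i in range(depth)]
        )
        self.ln = LayerNorm(dim, name="v.ln")
        self.head = Linear(dim, num_classes, name="v.head", init="xavier")

    def forward(self, x, training=False):
        z = self.embed(x, training=training)
        n = z.shape[0]
        z = np.concatenate([np.broadcast_to(self.cls.data, (n, 1, z.shape[-1])), z], axis=1)
        if z.shape[1] != self.pos.data.shape[1]:
            raise ValueError(
                f"image size incompatible with positional embedding "
                f"({z.shape[1]} vs {self.pos.data.shape[1]} tokens)"
            )
        z = (z + self.pos.data).astype(F32)
        z = self.blocks(z, training=training)
        self._ln_in_shape = z.shape
        z = self.ln(z, training=training)
        return self.head(z[:, 0, :], training=training)

    def backward(self, dy):
        dz0 = self.head.backward(dy)
        dz = np.zeros(self._ln_in_shape, dtype=F32)
        dz[:, 0, :] = dz0
        dz = self.blocks._backprop(self.ln.backward(dz))
        self.pos.grad += dz.sum(axis=0, keepdims=True)
        self.cls.grad += dz[:, :1, :].sum(axis=0, keepdims=True)
        return self.embed.backward(dz[:, 1:, :])


def vit_b16(num_classes: int = 6, image_size: int = 224) -> Backbone:
    """ViT-B/16 encoder classifier (12 blocks, width 768, 12 heads)."""
    vit = _ViT(image_size, 16, 768, 12, 12, 3072, num_classes)
    return Backbone(vit, num_classes, last_conv=None)


BACKBONES = {
    "mobilenetv3-small": mobilenet_v3_small,
    "tiny": tiny_cnn,
}
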