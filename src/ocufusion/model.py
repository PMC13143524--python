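"""The color-space fusion classifier and its ablation variants.

Architecture (default ``csfnet`` variant):

* three independent branch encoders — one MobileNetV3-Small per color
  space — each mapping an image plane to a d = 1,024 feature embedding
  (no weight sharing);
* concatenation to F = [F_RGB; F_HSV; F_YCbCr] in R^3072;
* single-head global self-attention over the fused vector with
  3072 x 3072 linear projections (weights + biases, 28,320,768
  parameters) and d_k = 3072 (single-token mode; an optional three-token
  mode treats each color space embedding as a token with 1024 x 1024
  projections);
* a classification head 3072 -> 1024 -> 512 -> 6 with batch
  normalization, ReLU and dropout after each hidden layer.

Training mode emits raw logits (the loss applies softmax internally);
inference applies softmax explicitly.

The variant registry covers the ablations: RGB-only, fusion without
attention, channel-recalibration fusions (SE / CBAM-channel / ECA / NAM
applied to the 3,072-d fused vector), and single-backbone reference
baselines on RGB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .colorspace import NormalizationStats
from .data import CLASS_NAMES
from .nn.attention import TokenSelfAttention, softmax
from .nn.backbones import (
    Backbone,
    efficientnet_b0,
    mobilenet_v3_small,
    resnet50,
    tiny_cnn,
    vit_b16,
)
from .nn.layers import (
    F32,
    BatchNorm,
    Dropout,
    Identity,
    Linear,
    Module,
    Parameter,
    ReLU,
    Sequential,
    Sigmoid,
    set_init_rng,
)

VARIANTS = (
    "csfnet",
    "rgb-only",
    "fusion-no-attention",
    "fusion-se",
    "fusion-cbam-channel",
    "fusion-eca",
    "fusion-nam",
    "baseline-resnet50",
    "baseline-efficientnet",
    "baseline-vit",
)


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``pretrained`` enables the transfer-learning scheme for the RGB branch
    (HSV/YCbCr branches always start from random initialization); it
    requires a local weights file, so the default is random initialization
    everywhere.
    """

    variant: str = "csfnet"
    backbone: str = "mobilenetv3-small"
    feature_dim: int = 1024
    attention_mode: str = "single-token"  # or "three-token"
    dropout: float = 0.3
    pretrained: bool = False
    pretrained_weights: str | None = None
    image_size: int = 224
    num_classes: int = 6
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.attention_mode not in ("single-token", "three-token"):
            raise ValueError("attention_mode must be 'single-token' or 'three-token'")


def _build_backbone(config: ModelConfig) -> Backbone:
    if config.backbone == "mobilenetv3-small":
        return mobilenet_v3_small(out_dim=config.feature_dim)
    if config.backbone == "tiny":
        return tiny_cnn(out_dim=config.feature_dim)
    raise ValueError(f"unknown branch backbone {config.backbone!r}")


class BranchEncoder(Module):
    """One color-space branch: backbone -> d-dimensional embedding."""

    def __init__(self, config: ModelConfig, space: str):
        self.space = space
        self.backbone = _build_backbone(config)
        self.out_dim = self.backbone.out_dim
        if space == "rgb" and config.pretrained:
            if not config.pretrained_weights:
                raise ValueError(
                    "pretrained initialization requires a local weights file "
                    "(set pretrained_weights); no download is attempted"
                )
            state = dict(np.load(config.pretrained_weights))
            self.backbone.load_state_dict(state)

    def forward(self, x, training=False):
        return self.backbone(x, training=training)

    def backward(self, dy):
        return self.backbone.backward(dy)


class AttentionFusion(Module):
    """Self-attention over the fused representation.

    Single-token mode: one 3d-wide token per sample, 3d x 3d linear
    projections, d_k = 3d; the softmax over the 1x1 score matrix is
    identically 1, so the output equals the value projection
    F W_v + b_v (and W_q / W_k receive no gradient — an inherent
    property of this mode).
    Three-token mode: one d-wide token per color space, d x d projections,
    d_k = d; outputs are re-concatenated to 3d.
    """

    def __init__(self, branch_dim: int, mode: str = "single-token"):
        self.branch_dim = branch_dim
        self.mode = mode
        width = 3 * branch_dim if mode == "single-token" else branch_dim
        self.attn = TokenSelfAttention(width, name="fusion")
        self.out_dim = 3 * branch_dim

    def forward(self, f: np.ndarray, training: bool = False) -> np.ndarray:
        if self.mode == "single-token":
            return self.attn(f, training=training)
        n = f.shape[0]
        tokens = f.reshape(n, 3, self.branch_dim)
        return self.attn(tokens, training=training).reshape(n, 3 * self.branch_dim)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.mode == "single-token":
            return self.attn.backward(dy)
        n = dy.shape[0]
        dt = self.attn.backward(dy.reshape(n, 3, self.branch_dim))
        return dt.reshape(n, 3 * self.branch_dim)


class ClassificationHead(Module):
    """in_dim -> 1024 -> 512 -> C with BN + ReLU + dropout on hidden layers."""

    def __init__(self, in_dim: int, num_classes: int = 6, dropout: float = 0.3,
                 hidden: tuple[int, int] = (1024, 512)):
        h1, h2 = hidden
        self.net = Sequential(
            Linear(in_dim, h1, name="head.fc1"),
            BatchNorm(h1, name="head.bn1"),
            ReLU(),
            Dropout(dropout),
            Linear(h1, h2, name="head.fc2"),
            BatchNorm(h2, name="head.bn2"),
            ReLU(),
            Dropout(dropout),
            Linear(h2, num_classes, name="head.fc3"),
        )

    def forward(self, x, training=False):
        return self.net(x, training=training)

    def backward(self, dy):
        return self.net._backprop(dy)


# ---------------------------------------------------------------------------
# channel-recalibration fusion blocks (ablation variants), on (N, D) vectors
# ---------------------------------------------------------------------------

class SEVector(Module):
    """Squeeze-and-excitation on a feature vector: x * sigmoid(W2 relu(W1 x))."""

    def __init__(self, dim: int, reduction: int = 16):
        self.fc1 = Linear(dim, dim // reduction, name="se.fc1")
        self.relu = ReLU()
        self.fc2 = Linear(dim // reduction, dim, name="se.fc2")
        self.sig = Sigmoid()

    def forward(self, x, training=False):
        g = self.sig(self.fc2(self.relu(self.fc1(x, training), training), training), training)
        self._cache = (x, g)
        return (x * g).astype(F32)

    def backward(self, dy):
        x, g = self._cache
        dg = dy * x
        dx = dy * g
        dx += self.fc1.backward(self.relu.backward(self.fc2.backward(self.sig.backward(dg))))
        return dx.astype(F32)


class CBAMChannelVector(Module):
    """CBAM channel gate on a vector: sigmoid(MLP(avg) + MLP(max)) * x.

    On a 1x1 "map" the average- and max-pooled descriptors coincide with
    the vector itself, so the gate degenerates to sigmoid(2 * MLP(x)).
    """

    def __init__(self, dim: int, reduction: int = 16):
        self.fc1 = Linear(dim, dim // reduction, name="cbam.fc1")
        self.relu = ReLU()
        self.fc2 = Linear(dim // reduction, dim, name="cbam.fc2")
        self.sig = Sigmoid()

    def forward(self, x, training=False):
        m = self.fc2(self.relu(self.fc1(x, training), training), training)
        g = self.sig(2.0 * m, training)
        self._cache = (x, g)
        return (x * g).astype(F32)

    def backward(self, dy):
        x, g = self._cache
        dm = 2.0 * self.sig.backward(dy * x)
        dx = dy * g + self.fc1.backward(self.relu.backward(self.fc2.backward(dm)))
        return dx.astype(F32)


class ECAVector(Module):
    """Efficient channel attention: a small 1-D convolution across the
    channel axis produces the gate; kernel size follows the adaptive rule
    k = nearest odd to (log2(C) + 1) / 2."""

    def __init__(self, dim: int, kernel: int | None = None):
        if kernel is None:
            t = int((np.log2(dim) + 1.0) / 2.0)
            kernel = t if t % 2 else t + 1
        self.kernel = kernel
        self.weight = Parameter("eca.weight", np.full(kernel, 1.0 / kernel))
        self.sig = Sigmoid()

    def _conv(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p)))
        out = np.zeros_like(x)
        for i in range(self.kernel):
            out += self.weight.data[i] * xp[:, i : i + x.shape[1]]
        return out

    def forward(self, x, training=False):
        u = self._conv(x)
        g = self.sig(u, training)
        self._cache = (x, g)
        return (x * g).astype(F32)

    def backward(self, dy):
        x, g = self._cache
        du = self.sig.backward(dy * x)
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p)))
        dxp = np.zeros_like(xp)
        for i in range(self.kernel):
            self.weight.grad[i] += float((du * xp[:, i : i + x.shape[1]]).sum())
            dxp[:, i : i + x.shape[1]] += self.weight.data[i] * du
        dx = dy * g + dxp[:, p : p + x.shape[1]]
        return dx.astype(F32)


class NAMVector(Module):
    """Normalization-based channel attention: gate channels by their
    batch-norm scale factors, x * sigmoid(BN(x) * |gamma| / sum|gamma|)."""

    def __init__(self, dim: int):
        self.bn = BatchNorm(dim, name="nam.bn")

    def forward(self, x, training=False):
        u = self.bn(x, training=training)
        gamma = self.bn.gamma.data
        s = np.abs(gamma).sum()
        w = np.abs(gamma) / s
        g = 1.0 / (1.0 + np.exp(-(u * w)))
        self._cache = (x, u, w, g, gamma, s)
        return (x * g).astype(F32)

    def backward(self, dy):
        x, u, w, g, gamma, s = self._cache
        ds = dy * x * g * (1.0 - g)  # d loss / d (u * w)
        du = ds * w
        dw = (ds * u).sum(axis=0)
        # w = |gamma| / s  with  s = sum |gamma|
        dgamma = np.sign(gamma) * (dw - (dw * w).sum()) / s
        self.bn.gamma.grad += dgamma.astype(F32)
        dx = dy * g + self.bn.backward(du.astype(F32))
        return dx.astype(F32)


_CHANNEL_BLOCKS = {
    "fusion-se": lambda dim: SEVector(dim, reduction=16),
    "fusion-cbam-channel": lambda dim: CBAMChannelVector(dim, reduction=16),
    "fusion-eca": lambda dim: ECAVector(dim),
    "fusion-nam": lambda dim: NAMVector(dim),
}


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class CSFNetModel(Module):
    """Three branch encoders + fusion + classification head.

    ``forward`` takes a dict of NHWC batches keyed ``rgb``/``hsv``/
    ``ycbcr`` (a plain array is accepted for single-branch variants) and
    returns raw logits; use :meth:`predict_proba` for probabilities.
    """

    SPACES = ("rgb", "hsv", "ycbcr")

    def __init__(self, config: ModelConfig):
        self.config = config
        self.class_names = list(CLASS_NAMES)[: config.num_classes]
        variant = config.variant

        if variant.startswith("baseline-"):
            builder = {
                "baseline-resnet50": lambda: resnet50(config.num_classes),
                "baseline-efficientnet": lambda: efficientnet_b0(config.num_classes),
                "baseline-vit": lambda: vit_b16(config.num_classes, config.image_size),
            }[variant]
            self.branches: dict[str, Module] = {"rgb": builder()}
            self.fusion: Module | None = None
            self.head: Module | None = None
            return

        spaces = ("rgb",) if variant == "rgb-only" else self.SPACES
        self.branches = {s: BranchEncoder(config, s) for s in spaces}
        d = config.feature_dim
        fused_dim = d * len(spaces)
        if variant == "csfnet":
            self.fusion = AttentionFusion(d, mode=config.attention_mode)
        elif variant in _CHANNEL_BLOCKS:
            self.fusion = _CHANNEL_BLOCKS[variant](fused_dim)
        else:  # rgb-only, fusion-no-attention
            self.fusion = None
        self.head = ClassificationHead(
            fused_dim, num_classes=config.num_classes, dropout=config.dropout
        )

    # -- plumbing ----------------------------------------------------------
    @property
    def spaces(self) -> tuple[str, ...]:
        return tuple(self.branches.keys())

    def modules(self):
        yield self
        for br in self.branches.values():
            yield from br.modules()
        if self.fusion is not None:
            yield from self.fusion.modules()
        if self.head is not None:
            yield from self.head.modules()

    @staticmethod
    def _as_batch(x) -> dict[str, np.ndarray]:
        if isinstance(x, dict):
            return x
        return {"rgb": np.asarray(x)}

    # -- forward / backward -------------------------------------------------
    def encode_branches(self, batch) -> dict[str, np.ndarray]:
        batch = self._as_batch(batch)
        training = getattr(self, "_training", False)
        feats = {}
        for s, branch in self.branches.items():
            if s not in batch:
                raise KeyError(f"batch is missing the {s!r} plane")
            feats[s] = branch(batch[s], training=training)
        return feats

    def forward(self, batch, training: bool = False) -> np.ndarray:
        self._training = training
        feats = self.encode_branches(batch)
        if self.head is None:  # baseline classifier: backbone emits logits
            return feats["rgb"]
        f = np.concatenate([feats[s] for s in self.spaces], axis=1)
        if self.fusion is not None:
            f = self.fusion(f, training=training)
        return self.head(f, training=training)

    def backward(self, dlogits: np.ndarray) -> None:
        if self.head is None:
            self.branches["rgb"]._backprop(dlogits)
            return
        df = self.head._backprop(dlogits)
        if self.fusion is not None:
            df = self.fusion._backprop(df)
        d = self.config.feature_dim
        for i, s in enumerate(self.spaces):
            self.branches[s]._backprop(df[:, i * d : (i + 1) * d])

    def predict_proba(self, batch) -> np.ndarray:
        return softmax(self.forward(batch, training=False), axis=1)


def build_variant(tag: str, config: ModelConfig | None = None) -> CSFNetModel:
    """Construct a model variant with deterministic initialization."""
    if config is None:
        config = ModelConfig(variant=tag)
    elif config.variant != tag:
        config = ModelConfig(**{**asdict(config), "variant": tag})
    set_init_rng(np.random.default_rng(np.random.SeedSequence((config.init_seed, 17))))
    return CSFNetModel(config)


def count_parameters(model: Module) -> int:
    """Number of trainable scalars (batch-norm buffers excluded)."""
    return model.num_parameters()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    model: CSFNetModel,
    path: str | Path,
    norm_stats: NormalizationStats | None = None,
    extra: dict | None = None,
) -> None:
    """Serialize weights + config + class order (+ norm stats) to one file."""
    header = {
        "config": asdict(model.config),
        "class_names": model.class_names,
        "extra": extra or {},
    }
    if norm_stats is not None:
        header["norm_stats"] = {
            "computed_from": norm_stats.computed_from,
            "mean": {k: v.tolist() for k, v in norm_stats.mean.items()},
            "std": {k: v.tolist() for k, v in norm_stats.std.items()},
        }
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[CSFNetModel, NormalizationStats | None, dict]:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        state = {k[len("state/") :]: z[k] for k in z.files if k.startswith("state/")}
    config = ModelConfig(**header["config"])
    model = build_variant(config.variant, config)
    model.load_state_dict(state)
    stats = None
    if "norm_stats" in header:
        ns = header["norm_stats"]
        stats = NormalizationStats(
            mean={k: np.asarray(v) for k, v in ns["mean"].items()},
            std={k: np.asarray(v) for k, v in ns["std"].items()},
            computed_from=ns.get("computed_from", ""),
        )
    return model, stats, header.get("extra", {})
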