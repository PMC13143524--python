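"""Color-space decomposition, augmentation, and normalization.

Every sample is represented simultaneously in three 8-bit full-range color
spaces: RGB (raw intensities), HSV (hue/saturation/value, chroma decoupled
from brightness) and YCbCr (luma plus two chroma-difference channels).  All
three planes are encoded on the same 0-255 scale so that one set of
channel-wise normalization statistics, computed from the training split
only, can standardize them.

Dialects are pinned for bit-exactness:

* HSV: standard hexcone conversion, hue 0-360 deg mapped linearly onto
  0-255; achromatic pixels get H = 0.
* YCbCr: ITU-R BT.601 *full-range* matrix (no studio swing), achromatic
  pixels at Cb = Cr = 128.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

COLOR_SPACES = ("rgb", "hsv", "ycbcr")

# BT.601 full-range RGB -> YCbCr matrix (rows: Y, Cb, Cr).
_BT601 = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ],
    dtype=np.float64,
)
_BT601_OFFSET = np.array([0.0, 128.0, 128.0], dtype=np.float64)
_BT601_INV = np.linalg.inv(_BT601)


def _check_range(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float64)
    if a.shape[-1] != 3:
        raise ValueError(f"{name} must have 3 channels in the last axis, got {a.shape}")
    if a.min() < 0 or a.max() > 255:
        raise ValueError(f"{name} values must lie in [0, 255]")
    return a


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit full-range RGB to 8-bit full-range HSV.

    Hexcone model: V = max(R,G,B); S = 255 * (max-min)/max (0 where max is
    0); H in degrees mapped as H * 255/360.  Returns float32 in [0, 255].
    """
    a = _check_range(rgb, "rgb")
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    mx = a.max(axis=-1)
    mn = a.min(axis=-1)
    delta = mx - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(mx > 0, delta / np.where(mx > 0, mx, 1.0), 0.0)
        dsafe = np.where(delta > 0, delta, 1.0)
        h = np.zeros_like(mx)
        # hue sector depends on which channel attains the max
        rmax = (mx == r) & (delta > 0)
        gmax = (mx == g) & (delta > 0) & ~rmax
        bmax = (delta > 0) & ~rmax & ~gmax
        h = np.where(rmax, ((g - b) / dsafe) % 6.0, h)
        h = np.where(gmax, (b - r) / dsafe + 2.0, h)
        h = np.where(bmax, (r - g) / dsafe + 4.0, h)
    h_deg = h * 60.0
    out = np.stack([h_deg * (255.0 / 360.0), s * 255.0, mx], axis=-1)
    return out.astype(np.float32)


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit full-range RGB to BT.601 full-range YCbCr (float32)."""
    a = _check_range(rgb, "rgb")
    out = a @ _BT601.T + _BT601_OFFSET
    return np.clip(out, 0.0, 255.0).astype(np.float32)


def ycbcr_to_rgb(ycbcr: np.ndarray) -> np.ndarray:
    """Inverse BT.601 full-range transform, clipped to [0, 255] (float32)."""
    a = np.asarray(ycbcr, dtype=np.float64)
    out = (a - _BT601_OFFSET) @ _BT601_INV.T
    return np.clip(out, 0.0, 255.0).astype(np.float32)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _luma(rgb: np.ndarray) -> np.ndarray:
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def augment(rgb: np.ndarray, rng) -> np.ndarray:
    """Stochastic training augmentation applied to the RGB image *before*
    color-space decomposition so the three planes stay geometrically aligned.

    Fixed draw order (one value each): flip indicator, rotation angle,
    brightness, contrast and saturation factors.

    * horizontal flip with probability 0.5 (applied when the uniform draw
      exceeds 0.5),
    * rotation by an angle uniform in [-15, +15] degrees, bilinear, black
      fill,
    * brightness/contrast/saturation each scaled by a factor uniform in
      [0.8, 1.2].

    ``rng`` needs ``random()`` and ``uniform(lo, hi)``; a seeded
    ``numpy.random.Generator`` fits.  Returns float32 in [0, 255].
    """
    x = _check_range(rgb, "rgb").astype(np.float32)

    if rng.random() > 0.5:
        x = x[:, ::-1, :].copy()

    angle = float(rng.uniform(-15.0, 15.0))
    if angle != 0.0:
        x = ndimage.rotate(
            x, angle, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
        )
        x = np.clip(x, 0.0, 255.0)

    b = float(rng.uniform(0.8, 1.2))
    c = float(rng.uniform(0.8, 1.2))
    s = float(rng.uniform(0.8, 1.2))
    if b != 1.0:
        x = x * b
    if c != 1.0:
        m = float(_luma(x).mean())
        x = m + c * (x - m)
    if s != 1.0:
        gray = _luma(x)[..., None]
        x = gray + s * (x - gray)
    return np.clip(x, 0.0, 255.0).astype(np.float32)


# ---------------------------------------------------------------------------
# normalization statistics
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-color-space, per-channel mean/std in 0-255 units.

    Computed from the *training* images of one fold only, and applied to
    both splits — the leakage rule the training protocol prescribes.
    """

    mean: dict[str, np.ndarray]  # space -> (3,) float64
    std: dict[str, np.ndarray]
    computed_from: str = ""

    def __post_init__(self) -> None:
        for space in COLOR_SPACES:
            if space not in self.mean or space not in self.std:
                raise KeyError(f"missing stats for color space {space!r}")
            self.mean[space] = np.asarray(self.mean[space], dtype=np.float64)
            self.std[space] = np.asarray(self.std[space], dtype=np.float64)
            if np.any(self.std[space] <= 0):
                raise ValueError(f"non-positive std in {space!r} channel statistics")

    @classmethod
    def identity(cls) -> "NormalizationStats":
        """mean 0 / std 1 — normalization becomes the identity map."""
        return cls(
            mean={s: np.zeros(3) for s in COLOR_SPACES},
            std={s: np.ones(3) for s in COLOR_SPACES},
            computed_from="identity",
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "computed_from": self.computed_from,
            "mean": {k: v.tolist() for k, v in self.mean.items()},
            "std": {k: v.tolist() for k, v in self.std.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean={k: np.asarray(v) for k, v in payload["mean"].items()},
            std={k: np.asarray(v) for k, v in payload["std"].items()},
            computed_from=payload.get("computed_from", ""),
        )


def load_rgb(path: str | Path) -> np.ndarray:
    """Read an image file as an H x W x 3 uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def resize_rgb(rgb: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize to ``size x size`` (float32, [0, 255]).

    Resizing happens on the RGB plane before conversion, so all three
    decomposed planes stay aligned.
    """
    x = np.asarray(rgb, dtype=np.float32)
    if x.shape[0] == size and x.shape[1] == size:
        return x
    chans = [
        np.asarray(
            Image.fromarray(x[..., c], mode="F").resize((size, size), Image.BILINEAR)
        )
        for c in range(3)
    ]
    return np.clip(np.stack(chans, axis=-1), 0.0, 255.0).astype(np.float32)


def compute_norm_stats(
    images: Iterable[np.ndarray | str | Path],
    computed_from: str = "",
    size: int | None = None,
) -> NormalizationStats:
    """Pool per-channel mean/std over all pixels of all images, per space.

    ``images`` may be arrays or paths.  With ``size`` set, images are
    resized first (matching what the model will actually consume).
    Raises on an empty input or a zero-variance channel.
    """
    n = 0
    tot = {s: np.zeros(3) for s in COLOR_SPACES}
    tot2 = {s: np.zeros(3) for s in COLOR_SPACES}
    count = 0
    for item in images:
        rgb = load_rgb(item) if isinstance(item, (str, Path)) else np.asarray(item)
        rgb = rgb.astype(np.float64)
        if size is not None:
            rgb = resize_rgb(rgb, size).astype(np.float64)
        planes = {
            "rgb": rgb,
            "hsv": rgb_to_hsv(rgb).astype(np.float64),
            "ycbcr": rgb_to_ycbcr(rgb).astype(np.float64),
        }
        for space, plane in planes.items():
            flat = plane.reshape(-1, 3)
            tot[space] += flat.sum(axis=0)
            tot2[space] += (flat**2).sum(axis=0)
        count += rgb.shape[0] * rgb.shape[1]
        n += 1
    if n == 0:
        raise ValueError("cannot compute normalization statistics from an empty subset")
    mean = {s: tot[s] / count for s in COLOR_SPACES}
    var = {s: np.maximum(tot2[s] / count - mean[s] ** 2, 0.0) for s in COLOR_SPACES}
    std = {s: np.sqrt(var[s]) for s in COLOR_SPACES}
    for s in COLOR_SPACES:
        if np.any(std[s] <= 0):
            raise ValueError(
                f"degenerate (zero-variance) channel in {s!r}; refusing to normalize"
            )
    return NormalizationStats(mean=mean, std=std, computed_from=computed_from)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass
class MultiColorImage:
    """One sample decomposed into three aligned, normalized 3-channel planes."""

    rgb: np.ndarray
    hsv: np.ndarray
    ycbcr: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        if not (self.rgb.shape == self.hsv.shape == self.ycbcr.shape):
            raise ValueError("the three color planes must share identical shape")

    def planes(self) -> dict[str, np.ndarray]:
        return {"rgb": self.rgb, "hsv": self.hsv, "ycbcr": self.ycbcr}


def decompose_and_normalize(
    rgb: np.ndarray,
    stats: NormalizationStats,
    size: int | None = None,
    label: int | None = None,
) -> MultiColorImage:
    """Resize -> convert to HSV/YCbCr -> standardize each channel.

    Each channel is mapped to (x - mean) / std with statistics from
    ``stats`` (0-255 units).  Output planes are float32.
    """
    x = np.asarray(rgb, dtype=np.float32)
    if size is not None:
        x = resize_rgb(x, size)
    planes = {"rgb": x, "hsv": rgb_to_hsv(x), "ycbcr": rgb_to_ycbcr(x)}
    out = {}
    for space, plane in planes.items():
        m = stats.mean[space].astype(np.float32)
        s = stats.std[space].astype(np.float32)
        out[space] = ((plane - m) / s).astype(np.float32)
    return MultiColorImage(rgb=out["rgb"], hsv=out["hsv"], ycbcr=out["ycbcr"], label=label)
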