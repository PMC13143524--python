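"""Grad-CAM saliency for the multi-branch fusion model.

For each color-space branch the last convolutional block's feature map A
is captured during a forward pass; the gradient of the target-class score
(the pre-softmax logit) with respect to A is captured during backward.
Channel weights are the spatially averaged gradients, the map is the
rectified weighted channel sum, normalized to [0, 1] by its maximum
(an all-zero map stays zero and is flagged degenerate), and bilinearly
upsampled to the input size.  The combined map is the unweighted
pixel-wise mean of the three branch maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .colorspace import MultiColorImage
from .model import CSFNetModel


@dataclass
class SaliencyResult:
    """Branch heat-maps (values in [0,1], input-sized) and their mean."""

    branch_maps: dict[str, np.ndarray]
    combined: np.ndarray
    target_class: int
    probabilities: np.ndarray
    degenerate_branches: list[str] = field(default_factory=list)


def _upsample(m: np.ndarray, size: int) -> np.ndarray:
    """Bilinear upsampling aligned to the convolutional grid.

    With the stride-2, pad-1 convolutions used here, feature cell (i, j)
    is centred on input pixel (s*i, s*j) for total stride s; sampling at
    ``x_in = x_out / s`` preserves that alignment (a plain image resize
    would shift every map by s/2 pixels, half a lesion radius at these
    scales).
    """
    if m.shape == (size, size):
        return m.astype(np.float32)
    from scipy import ndimage

    scale = size / m.shape[0]
    coords = np.arange(size, dtype=np.float64) / scale
    cy, cx = np.meshgrid(coords, coords, indexing="ij")
    return ndimage.map_coordinates(
        m.astype(np.float64), [cy, cx], order=1, mode="nearest"
    ).astype(np.float32)


def gradcam(
    model: CSFNetModel,
    sample: MultiColorImage,
    target_class: int | None = None,
) -> SaliencyResult:
    """Compute per-branch and combined saliency for one sample.

    ``target_class`` defaults to the predicted class.  The model is run in
    evaluation mode; saliency hooks capture the last convolutional block
    of each branch backbone.
    """
    planes = sample.planes()
    batch = {s: p[None].astype(np.float32) for s, p in planes.items()}
    size = sample.rgb.shape[0]

    targets = {}
    for s, branch in model.branches.items():
        conv = getattr(getattr(branch, "backbone", branch), "last_conv", None)
        if conv is None:
            raise ValueError(f"branch {s!r} has no convolutional feature map to hook")
        conv.capture = True
        targets[s] = conv

    try:
        logits = model.forward(batch, training=False)
        c = logits.shape[1]
        probs = np.exp(logits[0] - logits[0].max())
        probs = probs / probs.sum()
        cls = int(np.argmax(probs)) if target_class is None else int(target_class)
        if not 0 <= cls < c:
            raise ValueError(f"target class {cls} out of range [0, {c})")
        dlogits = np.zeros_like(logits)
        dlogits[0, cls] = 1.0
        model.zero_grad()
        model.backward(dlogits)
    finally:
        for conv in targets.values():
            conv.capture = False

    branch_maps: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for s, conv in targets.items():
        act = conv.captured_output[0]  # (h, w, ch)
        grad = conv.captured_grad[0]
        weights = grad.mean(axis=(0, 1))  # spatially averaged gradients
        cam = np.maximum((act * weights).sum(axis=-1), 0.0)
        peak = cam.max()
        if peak > 0:
            cam = cam / peak
        else:
            degenerate.append(s)
        branch_maps[s] = np.clip(_upsample(cam, size), 0.0, 1.0)

    combined = np.mean(list(branch_maps.values()), axis=0).astype(np.float32)
    return SaliencyResult(
        branch_maps=branch_maps,
        combined=combined,
        target_class=cls,
        probabilities=probs,
        degenerate_branches=degenerate,
    )


def overlay(
    rgb: np.ndarray,
    saliency: np.ndarray,
    path: str | Path | None = None,
    alpha: float = 0.4,
) -> np.ndarray:
    """Blend a color-mapped heat-map over the RGB image at fixed alpha.

    ``out = (1 - alpha) * image + alpha * colormap(saliency)``; returns
    the uint8 result and writes a PNG when ``path`` is given.
    """
    from matplotlib import colormaps

    rgb = np.asarray(rgb)
    if rgb.shape[:2] != saliency.shape:
        raise ValueError(
            f"size mismatch: image {rgb.shape[:2]} vs saliency {saliency.shape}"
        )
    heat = (colormaps["jet"](np.clip(saliency, 0, 1))[:, :, :3] * 255.0).astype(np.float64)
    out = (1.0 - alpha) * rgb.astype(np.float64) + alpha * heat
    out8 = np.clip(out, 0, 255).astype(np.uint8)
    if path is not None:
        Image.fromarray(out8).save(path)
    return out8


def export_map(saliency: np.ndarray, png_path: str | Path,
               grid_path: str | Path | None = None) -> None:
    """Write a saliency map as an 8-bit grayscale PNG (+ optional text grid)."""
    Image.fromarray((np.clip(saliency, 0, 1) * 255).astype(np.uint8)).save(png_path)
    if grid_path is not None:
        np.savetxt(grid_path, saliency, fmt="%.6f")
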