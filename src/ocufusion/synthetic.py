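"""Reproducible synthetic feline-eye image generator.

Real ophthalmic screening data cannot ship with the package, so every
downstream stage (decomposition, training, evaluation, saliency) is
exercised on procedurally generated eye-like images.  The generator plants
the same *kind* of signal the six clinical categories carry: chromatic
cues (peripheral redness for conjunctivitis-like images, an inflamed rim
for blepharitis-like images) and luminance cues (a dark corneal plaque for
sequestrum-like images, a bright low-contrast blob for ulcer-like images,
global haze for non-ulcerative-keratitis-like images), on a shared base
eye template (sclera background, iris annulus, dark vertical pupil).
Nuisance illumination variation — brightness/contrast jitter and an
optional glare ellipse, magnitude proportional to ``nuisance_strength`` —
is applied to every class so the class signal is never the only source of
variance.

Determinism contract: one pseudo-random stream per image, keyed by
(seed, class index, image index), so regenerating any subset of the
dataset is byte-identical regardless of generation order.

For classes with a localized perturbation the planted pixel mask is stored
as a sidecar PNG (``<image_id>.mask.png``), giving ground truth for
saliency-localization experiments.  "Regular" and the global-haze class
get empty masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .colorspace import rgb_to_ycbcr, ycbcr_to_rgb
from .data import CLASS_NAMES, DatasetManifest, load_manifest

#: Classes whose planted perturbation is localized (non-empty lesion mask).
LOCALIZED_CLASSES = frozenset(
    {"Blepharitis", "Conjunctivitis", "Corneal Sequestrum", "Corneal Ulcer"}
)


@dataclass
class SyntheticSpec:
    """Generation recipe for one dataset.

    ``n_per_class`` is the per-class count under balance; with
    ``class_imbalance`` set, the total ``n_per_class * 6`` is redistributed
    according to the given proportions (largest-remainder rounding, so the
    counts sum exactly to the total).
    """

    n_per_class: int = 50
    image_size: int = 64
    class_names: tuple[str, ...] = CLASS_NAMES
    seed: int = 0
    nuisance_strength: float = 0.0
    class_imbalance: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.nuisance_strength <= 1.0:
            raise ValueError("nuisance_strength must lie in [0, 1]")
        if len(self.class_names) != 6:
            raise ValueError("exactly six class names are required")
        if self.class_imbalance is not None:
            p = np.asarray(self.class_imbalance, dtype=np.float64)
            if p.size != 6 or np.any(p < 0):
                raise ValueError("class_imbalance needs six non-negative proportions")
            if abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"class_imbalance proportions sum to {p.sum():.8f}, not 1 (tol 1e-6)"
                )

    def class_counts(self) -> np.ndarray:
        total = self.n_per_class * 6
        if self.class_imbalance is None:
            return np.full(6, self.n_per_class, dtype=np.int64)
        p = np.asarray(self.class_imbalance, dtype=np.float64)
        raw = p * total
        counts = np.floor(raw).astype(np.int64)
        rem = total - counts.sum()
        order = np.argsort(-(raw - counts))  # largest remainder first
        counts[order[:rem]] += 1
        return counts


def _slug(name: str) -> str:
    return name.lower().replace(" ", "-")


def _image_rng(seed: int, class_idx: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, class_idx, index)))


def _smoothstep(d: np.ndarray, edge: float) -> np.ndarray:
    """1 inside (d <= 0), 0 outside (d >= edge), smooth in between."""
    t = np.clip(1.0 - d / edge, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _render(
    class_name: str, size: int, rng: np.random.Generator, nuisance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render one image; returns (uint8 RGB, boolean lesion mask)."""
    n = size
    ax = np.linspace(-1.0, 1.0, n)
    xx, yy = np.meshgrid(ax, ax)
    r = np.sqrt(xx**2 + yy**2)

    # base colors: a common per-image brightness shift plus a small
    # independent per-channel jitter, so hue stays stable within a class
    common = rng.uniform(-8.0, 8.0)
    jitter = rng.uniform(-2.0, 2.0, size=3)
    sclera = np.array([228.0, 222.0, 208.0]) + common + jitter
    iris = np.array([150.0, 118.0, 60.0]) + common + rng.uniform(-6.0, 6.0, size=3)
    pupil = np.array([22.0, 16.0, 14.0])

    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = sclera

    iris_r = 0.55
    w_iris = _smoothstep(r - iris_r, 0.06)[..., None]
    # mild radial texture on the iris
    tex = 1.0 + 0.08 * np.cos(10.0 * np.arctan2(yy, xx) + rng.uniform(0, 2 * np.pi))
    img = img * (1 - w_iris) + (iris * tex[..., None]) * w_iris

    # vertical slit pupil
    d_pupil = np.sqrt((xx / 0.13) ** 2 + (yy / 0.30) ** 2) - 1.0
    w_pupil = _smoothstep(d_pupil * 0.13, 0.03)[..., None]
    img = img * (1 - w_pupil) + pupil * w_pupil

    mask = np.zeros((n, n), dtype=bool)

    if class_name == "Conjunctivitis":
        # peripheral hue shift toward red on the sclera (chromatic signal)
        region = r > iris_r + 0.03
        shift = np.array([55.0, -25.0, -25.0]) * (1.0 + rng.uniform(-0.15, 0.15))
        img[region] += shift
        mask = region
    elif class_name == "Blepharitis":
        # red, textured rim at the image border
        w = max(2, int(round(0.09 * n)))
        band = np.zeros((n, n), dtype=bool)
        band[:w, :] = band[-w:, :] = band[:, :w] = band[:, -w:] = True
        img[band] += np.array([50.0, -20.0, -20.0])
        img[band] += rng.normal(0.0, 22.0, size=(int(band.sum()), 3))
        mask = band
    elif class_name == "Corneal Sequestrum":
        # dark low-luminance plaque over the iris, placed clear of the
        # (equally dark) pupil slit so the planted signal stays visible
        cx = rng.choice([-1.0, 1.0]) * rng.uniform(0.30, 0.38)
        cy = rng.uniform(-0.12, 0.12)
        pr = 0.15 * (1.0 + rng.uniform(-0.1, 0.1))
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) - pr
        w_pl = _smoothstep(d, 0.04)[..., None]
        # dark *brown* necrotic plaque: low-luminance against the iris but
        # chromatically distinct from the near-black pupil
        plaque = np.array([74.0, 42.0, 18.0])
        img = img * (1 - 0.88 * w_pl) + plaque * 0.88 * w_pl
        mask = d <= 0.04  # full support of the blend, smooth rim included
    elif class_name == "Corneal Ulcer":
        # bright irregular blob with local contrast loss
        cx, cy = rng.uniform(-0.18, 0.18, size=2)
        theta = np.arctan2(yy - cy, xx - cx)
        wobble = sum(
            a * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
            for k, a in ((2, 0.25), (3, 0.18), (5, 0.10))
        )
        br = 0.18 * (1.0 + rng.uniform(-0.15, 0.15)) * (1.0 + wobble)
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) - br
        inside = d <= 0
        w_bl = _smoothstep(d, 0.05)[..., None]
        local_mean = img[inside].mean(axis=0) if inside.any() else img.mean(axis=(0, 1))
        flattened = 0.35 * img + 0.65 * local_mean  # local contrast loss
        bright = 0.55 * flattened + 0.45 * np.array([236.0, 234.0, 222.0])
        img = img * (1 - w_bl) + bright * w_bl
        mask = d <= 0.05  # full support of the blend, smooth rim included
    elif class_name == "Non-Ulcerative Keratitis":
        # global haze: shrink luminance contrast, preserve chroma
        ycc = rgb_to_ycbcr(np.clip(img, 0, 255)).astype(np.float64)
        y = ycc[..., 0]
        ycc[..., 0] = y.mean() + 0.45 * (y - y.mean()) + 18.0
        img = ycbcr_to_rgb(np.clip(ycc, 0, 255)).astype(np.float64)
    elif class_name != "Regular":
        raise ValueError(f"unknown class name {class_name!r}")

    # pixel noise common to all classes
    img += rng.normal(0.0, 3.0, size=img.shape)

    # nuisance illumination: brightness/contrast jitter + optional glare
    if nuisance > 0:
        b = 1.0 + nuisance * rng.uniform(-0.35, 0.35)
        c = 1.0 + nuisance * rng.uniform(-0.35, 0.35)
        img = (img - img.mean()) * c + img.mean()
        img = img * b
        if rng.random() < 0.6:
            gx, gy = rng.uniform(-0.6, 0.6, size=2)
            gr = rng.uniform(0.10, 0.22)
            d = np.sqrt(((xx - gx) / 1.4) ** 2 + (yy - gy) ** 2) - gr
            w_gl = _smoothstep(d, 0.08)[..., None] * (0.55 * nuisance)
            img = img * (1 - w_gl) + 255.0 * w_gl

    return np.clip(img, 0, 255).astype(np.uint8), mask


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> DatasetManifest:
    """Write the dataset (PNGs + sidecar masks + ``manifest.csv``).

    Returns the loaded :class:`DatasetManifest`.  Identical specs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = spec.class_counts()
    rows: list[tuple[str, str]] = []
    for class_idx, (name, n_c) in enumerate(zip(spec.class_names, counts)):
        for i in range(int(n_c)):
            rng = _image_rng(spec.seed, class_idx, i)
            img, mask = _render(name, spec.image_size, rng, spec.nuisance_strength)
            image_id = f"{_slug(name)}_{i:04d}"
            Image.fromarray(img).save(out / f"{image_id}.png")
            Image.fromarray((mask.astype(np.uint8)) * 255).save(
                out / f"{image_id}.mask.png"
            )
            rows.append((f"{image_id}.png", name))
    manifest_path = out / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        fh.write("filepath,label\n")
        for fp, label in rows:
            fh.write(f"{fp},{label}\n")
    return load_manifest(manifest_path, class_names=spec.class_names)


def planted_lesion_mask(dataset_dir: str | Path, image_id: str) -> np.ndarray:
    """Boolean pixel mask of the planted perturbation for one image.

    ``image_id`` is the filename stem (e.g. ``corneal-ulcer_0003``).  Empty
    for "Regular" and global-haze images.
    """
    path = Path(dataset_dir) / f"{image_id}.mask.png"
    if not path.exists():
        raise KeyError(f"unknown image_id {image_id!r} under {dataset_dir}")
    with Image.open(path) as im:
        return np.asarray(im) > 127
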