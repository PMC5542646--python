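"""Seeded synthetic grayscale datasets with category structure and anomalies.

The generator renders small families of parametric "radiograph-like" motifs —
an ellipse with inner structure (skull-like), parallel bright bands
(ribcage-like), a single elongated rod (long-bone-like), branching rods
(hand-like), stacked blocks (spine-like), two rods meeting at a joint
(knee-like), a fan of rods (foot-like) and a ball-on-rod (shoulder-like) —
cycled over categories with per-image parameter jitter.  Each image may carry
a planted anomaly: a bright Gaussian blob (calcification-like) or a dark
transverse gap across a rod (fracture-like), recorded in a binary mask.
Additive Gaussian noise, a linear illumination gradient and a 50% horizontal
flip complete the rendering.

The point is testability, not realism: categories are separable by the
default descriptor, anomalies are conspicuous to the saliency stage, and
every image is reproducible from ``(seed, image index)`` alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import GrayImage

__all__ = [
    "SyntheticSpec",
    "SyntheticImage",
    "generate_dataset",
    "corrupt",
    "salt_pepper",
    "gaussian_noise",
    "write_dataset",
    "read_manifest",
]

MOTIFS = (
    "skull", "ribcage", "long_bone", "hand",
    "spine", "knee", "foot", "shoulder",
)

# rendering calibration: motif structures are kept at moderate contrast while
# calcification blobs saturate, so planted anomalies are conspicuous both to
# the eye and to contrast-driven saliency
MOTIF_GAIN = 0.55
BLOB_CONTRAST = 230.0  # intensity lift of a calcification-like blob (saturating)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one dataset."""

    n_categories: int = 8
    images_per_category: int = 50
    size_range: tuple[int, int] = (120, 512)
    anomaly_prevalence: float = 0.3
    noise_sigma: float = 6.0
    illumination_gradient: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 1 or self.images_per_category < 1:
            raise ValueError("counts must be positive")
        if self.size_range[0] < 32 or self.size_range[1] < self.size_range[0]:
            raise ValueError("size range must satisfy 32 <= min <= max")
        if not (0.0 <= self.anomaly_prevalence <= 1.0):
            raise ValueError("anomaly_prevalence must lie in [0, 1]")
        if self.noise_sigma < 0 or self.illumination_gradient < 0:
            raise ValueError("noise and illumination levels must be >= 0")


@dataclass
class SyntheticImage:
    image: GrayImage
    category: str
    anomaly_type: Literal["none", "blob", "fracture"]
    anomaly_mask: np.ndarray  # bool, same shape as image


def _coords(side: int) -> tuple[np.ndarray, np.ndarray]:
    ax = (np.arange(side) + 0.5) / side
    return np.meshgrid(ax, ax, indexing="ij")  # (y, x) in (0, 1)


def _rod(y, x, p0, p1, half_width):
    """Soft-edged capsule (rod) between normalised points p0 and p1."""
    p0 = np.asarray(p0)
    p1 = np.asarray(p1)
    d = p1 - p0
    L2 = float(d @ d)
    py = y - p0[0]
    px = x - p0[1]
    tproj = np.clip((py * d[0] + px * d[1]) / max(L2, 1e-9), 0.0, 1.0)
    dy = py - tproj * d[0]
    dx = px - tproj * d[1]
    dist = np.hypot(dy, dx)
    return np.clip(1.0 - dist / half_width, 0.0, 1.0), tproj


def _render_motif(motif: str, side: int, rng: np.random.Generator):
    """Render one motif on a (side, side) canvas in [0, 1] units.

    Returns (canvas, rods) where rods is a list of (p0, p1, half_width)
    usable for planting a fracture.
    """
    y, x = _coords(side)
    canvas = np.zeros((side, side))
    rods: list[tuple[tuple, tuple, float]] = []
    j = lambda lo, hi: float(rng.uniform(lo, hi))

    if motif == "skull":
        cy, cx = j(0.42, 0.58), j(0.42, 0.58)
        ry, rx = j(0.26, 0.34), j(0.20, 0.28)
        e = ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
        canvas += 0.85 * np.clip(1.2 - e, 0, 1) ** 0.5 * (e < 1.2)
        canvas -= 0.45 * (e < 0.45)  # darker interior cavity
    elif motif == "ribcage":
        n_bands = int(rng.integers(4, 7))
        width = j(0.035, 0.055)
        for i in range(n_bands):
            cy = 0.18 + 0.62 * i / max(n_bands - 1, 1) + j(-0.02, 0.02)
            band = np.clip(1.0 - np.abs(y - cy) / width, 0, 1)
            lateral = np.clip(1.0 - np.abs(x - 0.5) / j(0.32, 0.4), 0, 1)
            canvas += 0.8 * band * lateral
    elif motif == "long_bone":
        p0 = (j(0.08, 0.2), j(0.35, 0.5))
        p1 = (j(0.8, 0.92), j(0.5, 0.65))
        hw = j(0.05, 0.08)
        prof, _ = _rod(y, x, p0, p1, hw)
        canvas += 0.9 * prof
        rods.append((p0, p1, hw))
    elif motif == "hand":
        base = (j(0.78, 0.88), j(0.45, 0.55))
        for i in range(4):
            tip = (j(0.1, 0.22), 0.2 + 0.2 * i + j(-0.03, 0.03))
            hw = j(0.018, 0.028)
            prof, _ = _rod(y, x, base, tip, hw)
            canvas += 0.85 * prof
            rods.append((base, tip, hw))
    elif motif == "spine":
        n_blocks = int(rng.integers(5, 8))
        bw = j(0.10, 0.14)
        for i in range(n_blocks):
            cy = 0.12 + 0.76 * i / (n_blocks - 1)
            block = (np.abs(y - cy) < 0.045) & (np.abs(x - 0.5) < bw)
            canvas += 0.8 * block.astype(float)
    elif motif == "knee":
        mid = (j(0.45, 0.55), j(0.45, 0.55))
        top = (j(0.05, 0.15), j(0.40, 0.5))
        bot = (j(0.85, 0.95), j(0.5, 0.60))
        for p in (top, bot):
            hw = j(0.045, 0.065)
            prof, _ = _rod(y, x, mid, p, hw)
            canvas += 0.85 * prof
            rods.append((mid, p, hw))
    elif motif == "foot":
        heel = (j(0.8, 0.9), j(0.15, 0.25))
        for i in range(4):
            toe = (j(0.12, 0.2), 0.45 + 0.14 * i + j(-0.02, 0.02))
            hw = j(0.022, 0.032)
            prof, _ = _rod(y, x, heel, toe, hw)
            canvas += 0.8 * prof
            rods.append((heel, toe, hw))
    elif motif == "shoulder":
        cy, cx = j(0.25, 0.35), j(0.3, 0.4)
        r = j(0.09, 0.13)
        ball = np.clip(1.0 - np.hypot(y - cy, x - cx) / r, 0, 1)
        canvas += 0.9 * ball ** 0.7
        p0 = (cy + 0.05, cx + 0.05)
        p1 = (j(0.8, 0.9), j(0.6, 0.75))
        hw = j(0.04, 0.06)
        prof, _ = _rod(y, x, p0, p1, hw)
        canvas += 0.8 * prof
        rods.append((p0, p1, hw))
    else:
        raise ValueError(f"unknown motif {motif!r}")
    return np.clip(canvas, 0, 1.2), rods


def _plant_blob(canvas, rng: np.random.Generator):
    side = canvas.shape[0]
    y, x = _coords(side)
    # calcification-like blobs sit on soft tissue, not on top of bright bone:
    # sample centers until one lands on a locally dark area
    cy, cx = 0.5, 0.5
    for _ in range(60):
        cy, cx = rng.uniform(0.2, 0.8, size=2)
        if canvas[int(cy * side), int(cx * side)] < 0.3:
            break
    r = rng.uniform(0.035, 0.06)
    d2 = ((y - cy) ** 2 + (x - cx) ** 2) / (r * r)
    # plateau profile with a sharp rim (super-Gaussian)
    blob = np.exp(-0.5 * d2 * d2)
    canvas = canvas + (BLOB_CONTRAST / 255.0 * 1.2) * blob
    mask = d2 <= 4.0  # within 2 radii
    return canvas, mask


def _plant_fracture(canvas, rods, rng: np.random.Generator):
    side = canvas.shape[0]
    y, x = _coords(side)
    p0, p1, hw = rods[int(rng.integers(len(rods)))]
    _, tproj = _rod(y, x, p0, p1, hw)
    prof, _ = _rod(y, x, p0, p1, hw * 1.6)
    t_cut = rng.uniform(0.3, 0.7)
    gap_half = rng.uniform(0.02, 0.035)
    gap = (np.abs(tproj - t_cut) < gap_half) & (prof > 0)
    canvas = np.where(gap, canvas * 0.12, canvas)
    return canvas, gap


def _render_image(
    spec: SyntheticSpec, category_idx: int, image_idx: int, global_idx: int
) -> SyntheticImage:
    rng = np.random.default_rng([spec.seed, global_idx])
    side = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
    motif = MOTIFS[category_idx % len(MOTIFS)]
    canvas, rods = _render_motif(motif, side, rng)
    canvas = MOTIF_GAIN * canvas
    canvas = gaussian_filter(canvas, sigma=side / 150.0)  # smooth shading

    anomaly_type = "none"
    mask = np.zeros((side, side), dtype=bool)
    if rng.random() < spec.anomaly_prevalence:
        if rods and rng.random() < 0.5:
            canvas, mask = _plant_fracture(canvas, rods, rng)
            anomaly_type = "fracture"
        else:
            canvas, mask = _plant_blob(canvas, rng)
            anomaly_type = "blob"

    img = 18.0 + 190.0 * np.clip(canvas, 0, 1.2) / 1.2
    # linear illumination gradient along a random direction
    if spec.illumination_gradient > 0:
        slope = rng.uniform(0, spec.illumination_gradient)
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = _coords(side)
        ramp = 1.0 + slope * ((yy - 0.5) * np.cos(theta) + (xx - 0.5) * np.sin(theta))
        img = img * ramp
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    if rng.random() < 0.5:
        img = img[:, ::-1]
        mask = mask[:, ::-1]
    img = np.clip(img, 0, 255)
    return SyntheticImage(
        image=GrayImage(
            img,
            id=f"img{global_idx:05d}",
            label=f"cat{category_idx:02d}",
        ),
        category=f"cat{category_idx:02d}",
        anomaly_type=anomaly_type,
        anomaly_mask=mask,
    )


def generate_dataset(spec: SyntheticSpec) -> list[SyntheticImage]:
    """Render the full dataset; deterministic given the spec.

    Images are generated from independent per-image RNG streams derived from
    ``(spec.seed, global index)``, so the dataset is stable under any
    generation order.
    """
    out = []
    gidx = 0
    for c in range(spec.n_categories):
        for i in range(spec.images_per_category):
            out.append(_render_image(spec, c, i, gidx))
            gidx += 1
    return out


# ---------------------------------------------------------------------------
# query corruption models

def salt_pepper(img: GrayImage, p: float, seed: int = 0) -> GrayImage:
    """Flip each pixel to 0 or 255 with probability p (equal split)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0:
        return GrayImage(img.pixels.copy(), id=img.id, label=img.label)
    rng = np.random.default_rng(seed)
    hit = rng.random(img.pixels.shape) < p
    salt = rng.random(img.pixels.shape) < 0.5
    out = np.where(hit, np.where(salt, 255.0, 0.0), img.pixels)
    return GrayImage(out, id=img.id, label=img.label)


def gaussian_noise(img: GrayImage, variance: float, seed: int = 0) -> GrayImage:
    """Add seeded zero-mean Gaussian noise, clamped to [0, 255]."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0.0:
        return GrayImage(img.pixels.copy(), id=img.id, label=img.label)
    rng = np.random.default_rng(seed)
    out = np.clip(
        img.pixels + rng.normal(0.0, np.sqrt(variance), size=img.pixels.shape),
        0.0, 255.0,
    )
    return GrayImage(out, id=img.id, label=img.label)


def corrupt(
    img: GrayImage,
    model: Literal["saltpepper", "gaussian"],
    level: float,
    seed: int = 0,
) -> GrayImage:
    """Apply a named corruption model: salt-&-pepper probability or Gaussian
    variance."""
    if model == "saltpepper":
        return salt_pepper(img, level, seed)
    if model == "gaussian":
        return gaussian_noise(img, level, seed)
    raise ValueError(f"unknown corruption model {model!r}")


# ---------------------------------------------------------------------------
# on-disk form: PNG images + manifest CSV (+ mask PNGs)

def write_dataset(dataset: list[SyntheticImage], out_dir) -> Path:
    """Write images, masks and a manifest CSV; returns the manifest path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "path", "category", "anomaly_type"])
        for item in dataset:
            rel = f"images/{item.image.id}.png"
            iio.imwrite(out / rel, np.round(item.image.pixels).astype(np.uint8))
            if item.anomaly_type != "none":
                iio.imwrite(
                    out / f"masks/{item.image.id}.png",
                    (item.anomaly_mask * 255).astype(np.uint8),
                )
            writer.writerow([item.image.id, rel, item.category, item.anomaly_type])
    return manifest


def read_manifest(manifest_path) -> list[GrayImage]:
    """Load the images referenced by a manifest CSV as labeled GrayImages."""
    import imageio.v3 as iio

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    images = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            px = np.asarray(iio.imread(root / row["path"]), dtype=np.float64)
            if px.ndim == 3:  # luminance conversion for color inputs
                px = px[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
            images.append(GrayImage(px, id=row["id"], label=row["category"]))
    return images
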