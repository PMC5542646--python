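"""Feature extraction: the pluggable descriptor ("neural code") contract.

Downstream stages only require a deterministic, fixed-length real vector per
preprocessed image.  Any callable with the signature
``(NetInput, ExtractorConfig) -> ndarray`` can be registered under a backbone
id; a learned network's activation vector slots in without touching the rest
of the pipeline.  The built-in backbone is a grid of magnitude-weighted
gradient-orientation histograms (HOG-like): the square input plane is split
into g x g cells, each cell contributes an o-bin histogram of unsigned
gradient orientation weighted by gradient magnitude, L2-normalised per cell,
and the cells are concatenated into a vector of length g * g * o (default
4 * 4 * 8 = 128).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .preprocess import GrayImage, MeanImage, NetInput, preprocess_image
from .saliency import SaliencyMap, extract_salient

CELL_NORM_EPS = 1e-12

__all__ = [
    "ExtractorConfig",
    "extract",
    "builtin_backbone",
    "codes_for_image",
    "register_backbone",
    "get_backbone",
]

_REGISTRY: dict[str, Callable[[NetInput, "ExtractorConfig"], np.ndarray]] = {}


def register_backbone(
    backbone_id: str,
) -> Callable[[Callable[[NetInput, "ExtractorConfig"], np.ndarray]], Callable]:
    """Decorator registering an extractor callable under ``backbone_id``."""

    def _register(fn: Callable[[NetInput, "ExtractorConfig"], np.ndarray]):
        _REGISTRY[backbone_id] = fn
        return fn

    return _register


def get_backbone(backbone_id: str) -> Callable[[NetInput, "ExtractorConfig"], np.ndarray]:
    try:
        return _REGISTRY[backbone_id]
    except KeyError:
        raise KeyError(
            f"unknown backbone {backbone_id!r}; registered: {sorted(_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class ExtractorConfig:
    """Configuration of the feature extractor.

    ``n`` is fixed by the configuration: for the built-in grid-histogram
    backbone it equals ``grid**2 * orientation_bins``.
    """

    backbone: str = "grid-orientation-hist"
    grid: int = 4
    orientation_bins: int = 8
    deterministic: bool = True

    @property
    def n(self) -> int:
        return self.grid * self.grid * self.orientation_bins

    def __post_init__(self) -> None:
        if self.grid < 2:
            raise ValueError("grid must be >= 2")
        if self.orientation_bins < 4:
            raise ValueError("orientation_bins must be >= 4")
        if self.n < 8:
            raise ValueError("descriptor length must be >= 8")


def extract(net_input: NetInput, cfg: ExtractorConfig) -> np.ndarray:
    """Run the configured backbone; returns a finite vector of length cfg.n."""
    code = get_backbone(cfg.backbone)(net_input, cfg)
    code = np.asarray(code, dtype=np.float64)
    if code.shape != (cfg.n,):
        raise ValueError(f"backbone returned shape {code.shape}, expected ({cfg.n},)")
    if not np.all(np.isfinite(code)):
        raise ValueError("backbone returned non-finite values")
    return code


@register_backbone("grid-orientation-hist")
def builtin_backbone(net_input: NetInput, cfg: ExtractorConfig) -> np.ndarray:
    """Grid of magnitude-weighted gradient-orientation histograms.

    Gradients are central differences (one-sided at borders); orientation is
    unsigned (modulo pi) so opposite-contrast edges share a bin.  A constant
    input has no gradients and maps to the all-zero code.
    """
    plane = net_input.planes[0]
    T = plane.shape[0]
    g, o = cfg.grid, cfg.orientation_bins
    if T % g != 0:
        raise ValueError(f"input side {T} not divisible by grid {g}")
    gy, gx = np.gradient(plane)
    mag = np.hypot(gx, gy)
    # unsigned edge/gradient orientation in [0, pi)
    ang = np.mod(np.arctan2(gy, gx), np.pi)
    bins = np.minimum((ang / (np.pi / o)).astype(np.int64), o - 1)
    cell = T // g
    code = np.zeros((g, g, o), dtype=np.float64)
    rows = np.arange(T) // cell
    cols = np.arange(T) // cell
    flat_idx = (
        rows[:, None] * (g * o) + cols[None, :] * o + bins
    ).ravel()
    np.add.at(code.reshape(-1), flat_idx, mag.ravel())
    norms = np.linalg.norm(code.reshape(g * g, o), axis=1)
    scale = np.where(norms > CELL_NORM_EPS, norms, 1.0)
    normed = code.reshape(g * g, o) / scale[:, None]
    normed[norms <= CELL_NORM_EPS] = 0.0
    return normed.ravel()


def codes_for_image(
    img: GrayImage,
    S: SaliencyMap,
    cfg: ExtractorConfig,
    mean: MeanImage,
    crop_to_bbox: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Descriptor pair for an image: whole-frame code and salient-region code.

    The salient patch is the saliency-masked image cropped to the mask's
    bounding box (configurable: ``crop_to_bbox=False`` feeds the full-frame
    masked image), preprocessed exactly like a whole image.
    """
    whole = extract(preprocess_image(img, mean, mean.side), cfg)
    region = extract_salient(img, S)
    if crop_to_bbox:
        r0, c0, r1, c1 = region.bbox
        patch_pixels = region.masked_image[r0:r1, c0:c1]
    else:
        patch_pixels = region.masked_image
    patch = GrayImage(patch_pixels, id=f"{img.id}#salient")
    salient = extract(preprocess_image(patch, mean, mean.side), cfg)
    return whole, salient
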