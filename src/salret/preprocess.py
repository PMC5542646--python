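"""Image preprocessing: adaptive rescaling, zero-padding and mean centering.

A feature extractor expects a fixed-size square input.  Radiographs come in
arbitrary rectangular sizes, so each image is rescaled so that its longer side
equals the target side ``T`` (default 224), zero-padded symmetrically along
the shorter axis, replicated into three identical planes and centered by
subtracting a per-pixel mean image computed over the indexed collection.
Rescaling preserves the aspect ratio exactly; only the padding is synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

DEFAULT_SIDE = 224

__all__ = [
    "DEFAULT_SIDE",
    "GrayImage",
    "NetInput",
    "MeanImage",
    "compute_scale",
    "rescale_and_pad",
    "compute_mean_image",
    "to_net_input",
    "preprocess_image",
]


@dataclass
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 255].

    Parameters
    ----------
    pixels : ndarray, shape (h, w)
        Intensities, stored at floating precision.
    id : str
        Opaque identifier, unique within a collection.
    label : str, optional
        Category identifier used for relevance judgements in evaluation.
    """

    pixels: np.ndarray
    id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have positive dimensions")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie within [0, 255]")

    @property
    def w(self) -> int:
        return self.pixels.shape[1]

    @property
    def h(self) -> int:
        return self.pixels.shape[0]


@dataclass
class NetInput:
    """Fixed-size, mean-centered, 3-plane input for a feature extractor."""

    planes: np.ndarray  # (3, T, T)
    scale_factor: float
    rescaled_width: int
    rescaled_height: int
    pad_offsets: tuple[int, int]  # (row, col) of top-left of image content

    @property
    def side(self) -> int:
        return self.planes.shape[1]


@dataclass
class MeanImage:
    """Per-pixel mean over the indexed (training) squares, side T."""

    planes: np.ndarray  # (T, T)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 2 or self.planes.shape[0] != self.planes.shape[1]:
            raise ValueError("mean image must be square")

    @property
    def side(self) -> int:
        return self.planes.shape[0]

    @classmethod
    def zero(cls, side: int = DEFAULT_SIDE) -> "MeanImage":
        return cls(np.zeros((side, side)))


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (symmetric for x >= 0)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_scale(w: int, h: int, T: int = DEFAULT_SIDE) -> tuple[float, int, int]:
    """Scale factor and rescaled dimensions for an adaptive aspect-preserving resize.

    The longer side is mapped exactly to ``T``:
    ``S_f = T/h`` when ``h > w``, else ``S_f = T/w``; the rescaled width and
    height are ``round(w * S_f)`` and ``round(h * S_f)``.

    Returns
    -------
    (S_f, w_R, h_R)
    """
    if w < 1 or h < 1 or T < 1:
        raise ValueError(f"dimensions must be positive, got w={w}, h={h}, T={T}")
    s_f = T / h if h > w else T / w
    w_r = _round_half_away(w * s_f)
    h_r = _round_half_away(h * s_f)
    return s_f, w_r, h_r


def rescale_and_pad(
    img: GrayImage, T: int = DEFAULT_SIDE
) -> tuple[np.ndarray, tuple[int, int]]:
    """Resample the image to fit a T x T square and zero-pad the shorter axis.

    Bilinear interpolation; the content is centered on the padded axis, with
    an odd leftover pixel going to the trailing (bottom/right) side.

    Returns
    -------
    square : ndarray, (T, T)
    pad_offsets : (row, col) of the top-left corner of the content rectangle.
    """
    _, w_r, h_r = compute_scale(img.w, img.h, T)
    if (h_r, w_r) == img.pixels.shape:
        content = img.pixels.copy()
    else:
        content = resize(
            img.pixels,
            (h_r, w_r),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    square = np.zeros((T, T), dtype=np.float64)
    row0 = (T - h_r) // 2
    col0 = (T - w_r) // 2
    square[row0 : row0 + h_r, col0 : col0 + w_r] = content
    return square, (row0, col0)


def compute_mean_image(squares: Sequence[np.ndarray]) -> MeanImage:
    """Per-pixel arithmetic mean over a collection of equally sized squares."""
    if len(squares) == 0:
        raise ValueError("cannot compute a mean image from an empty collection")
    side = squares[0].shape[0]
    for s in squares:
        if s.shape != (side, side):
            raise ValueError("all squares must share the same side")
    return MeanImage(np.mean(np.stack(squares), axis=0))


def to_net_input(
    square: np.ndarray,
    mean: MeanImage,
    scale_factor: float = 1.0,
    rescaled_width: Optional[int] = None,
    rescaled_height: Optional[int] = None,
    pad_offsets: tuple[int, int] = (0, 0),
) -> NetInput:
    """Center the square with the mean image and replicate to 3 planes."""
    square = np.asarray(square, dtype=np.float64)
    if square.shape != mean.planes.shape:
        raise ValueError(
            f"side mismatch: square {square.shape} vs mean {mean.planes.shape}"
        )
    centered = square - mean.planes
    planes = np.stack([centered, centered, centered])
    side = square.shape[0]
    return NetInput(
        planes=planes,
        scale_factor=scale_factor,
        rescaled_width=side if rescaled_width is None else rescaled_width,
        rescaled_height=side if rescaled_height is None else rescaled_height,
        pad_offsets=pad_offsets,
    )


def preprocess_image(img: GrayImage, mean: MeanImage, T: int = DEFAULT_SIDE) -> NetInput:
    """Full preprocessing chain: rescale, pad, mean-subtract, replicate."""
    s_f, w_r, h_r = compute_scale(img.w, img.h, T)
    square, offsets = rescale_and_pad(img, T)
    return to_net_input(square, mean, s_f, w_r, h_r, offsets)
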