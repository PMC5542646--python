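"""Reading grayscale images and writing debug/report artifacts."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .preprocess import GrayImage
from .saliency import SaliencyMap, SalientRegion

__all__ = ["load_image", "save_saliency_png", "save_mask_pgm", "plot_pr_curves"]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def load_image(path, id: str | None = None, label: str | None = None) -> GrayImage:
    """Read a PNG/PGM/TIFF image as 8-bit grayscale promoted to float.

    Color inputs are converted by luminance; an alpha channel is dropped.
    """
    px = np.asarray(iio.imread(path)).astype(np.float64)
    if px.ndim == 3:
        px = px[..., :3] @ _LUMA
    if px.max() > 255:  # 16-bit inputs: rescale into the 8-bit intensity domain
        px = px * (255.0 / px.max())
    return GrayImage(np.clip(px, 0, 255), id=id or Path(path).stem, label=label)


def save_saliency_png(S: SaliencyMap, path) -> None:
    """Write the saliency map as an 8-bit grayscale heat image."""
    iio.imwrite(path, np.round(S.values * 255).astype(np.uint8))


def save_mask_pgm(region: SalientRegion, path) -> None:
    """Write the salient-region mask as a binary PGM."""
    iio.imwrite(path, (region.mask.astype(np.uint8) * 255), extension=".pgm")


def plot_pr_curves(curves: dict[str, list], path) -> None:
    """Plot one or more labeled PR curves to a PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.plot(
            [pt.recall for pt in curve],
            [pt.precision for pt in curve],
            marker="o", label=name,
        )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
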