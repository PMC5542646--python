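"""Graph-based visual saliency and salient-region extraction.

Saliency is computed bottom-up on a small working grid (default 32 x 32).
Each feature channel (intensity plus four gradient-orientation energies) is
turned into a fully connected directed graph whose edge weight from node
(i, j) to (p, q) is

    w1 = |log(M(i,j) / M(p,q))| * exp(-((i-p)^2 + (j-q)^2) / (2 sigma^2)),

the product of a logarithmic dissimilarity and a Gaussian proximity kernel.
Treating the graph as a Markov chain (row-normalised transition matrix) and
solving for its equilibrium distribution concentrates probability mass on
locations that are locally unusual — an activation map.  A second chain,
whose edge weight into a node is proportional to that node's activation times
proximity, concentrates the mass further.  Channel maps are averaged,
upsampled to image resolution, and rescaled to [0, 1].

The salient region is the set of pixels whose saliency meets the dynamic
threshold tau = mean(S); the masked image (original intensities inside the
region, zero outside) cropped to the mask's bounding box is what downstream
feature extraction sees.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from skimage.transform import resize

from .preprocess import GrayImage

EPS_CLAMP = 1e-6
MAX_GRAPH_NODES = 2304  # 48 x 48 working grid
POWER_TOL = 1e-9
POWER_MAXITER = 10_000
DEFAULT_WORKING_SIDE = 32

__all__ = [
    "FeatureMap",
    "ActivationGraph",
    "SaliencyMap",
    "SalientRegion",
    "ConvergenceError",
    "build_feature_maps",
    "dissimilarity",
    "proximity",
    "proximity_matrix",
    "build_activation_graph",
    "equilibrium",
    "concentrate_mass",
    "combine_maps",
    "threshold_tau",
    "extract_salient",
    "compute_saliency",
]


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance within the iteration cap."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"stationary distribution did not converge in {iterations} "
            f"iterations (L1 residual {residual:.3e})"
        )


@dataclass
class FeatureMap:
    """A working-resolution channel response, clamped to be strictly positive."""

    values: np.ndarray  # (r, r), all >= EPS_CLAMP
    channel: str  # "intensity" | "orientation-<deg>"
    scale: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature map must be 2-D")


@dataclass
class ActivationGraph:
    """Dense weight matrix of the fully connected saliency graph.

    ``weights[a, b]`` is the weight of the directed edge from flattened grid
    node ``a`` to node ``b`` (row-major flattening of the r x r grid).
    """

    weights: np.ndarray  # (r*r, r*r)
    side: int
    sigma: float


@dataclass
class SaliencyMap:
    """Per-pixel salience at image resolution, rescaled to [0, 1]."""

    values: np.ndarray  # (h, w) in [0, 1]
    working_map: np.ndarray  # (r, r) mean equilibrium distribution, sums to 1


@dataclass
class SalientRegion:
    """The thresholded salient region of an image."""

    mask: np.ndarray  # (h, w) bool
    tau: float
    masked_image: np.ndarray  # (h, w): original pixels on mask, 0 elsewhere
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


def build_feature_maps(
    img: GrayImage, r: int = DEFAULT_WORKING_SIDE
) -> list[FeatureMap]:
    """Intensity plus 4 orientation-energy channels at working resolution r x r.

    The image is resampled to r x r; orientation energy for edge orientation
    theta is the squared directional derivative across that orientation, so a
    vertical edge (theta = 90 deg) responds in the horizontal-gradient channel.
    """
    work = resize(
        img.pixels, (r, r), order=1, mode="edge", anti_aliasing=True,
        preserve_range=True,
    )
    maps = [FeatureMap(np.maximum(work, EPS_CLAMP), "intensity")]
    gy, gx = np.gradient(work)
    for theta_deg in (0, 45, 90, 135):
        # unit vector across the edge orientation (gradient direction)
        phi = np.deg2rad(theta_deg - 90.0)
        energy = (gx * np.cos(phi) + gy * np.sin(phi)) ** 2
        maps.append(
            FeatureMap(np.maximum(energy, EPS_CLAMP), f"orientation-{theta_deg}")
        )
    return maps


def dissimilarity(M: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Logarithmic dissimilarity |log(M(i,j) / M(p,q))| between two locations."""
    M = np.maximum(np.asarray(M, dtype=np.float64), EPS_CLAMP)
    return abs(float(np.log(M[a]) - np.log(M[b])))


def proximity(a: float, b: float, sigma: float) -> float:
    """Gaussian proximity kernel F(a, b) = exp(-(a^2 + b^2) / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-(a * a + b * b) / (2.0 * sigma * sigma)))


@lru_cache(maxsize=8)
def _proximity_matrix_cached(side: int, sigma: float) -> np.ndarray:
    idx = np.arange(side)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    rows = ii.ravel()
    cols = jj.ravel()
    d2 = (rows[:, None] - rows[None, :]) ** 2 + (cols[:, None] - cols[None, :]) ** 2
    F = np.exp(-d2 / (2.0 * sigma * sigma))
    F.setflags(write=False)
    return F


def proximity_matrix(side: int, sigma: float) -> np.ndarray:
    """Pairwise proximity F(i-p, j-q) over all node pairs of a side x side grid.

    Cached per (side, sigma): the matrix depends only on the grid geometry.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _proximity_matrix_cached(int(side), float(sigma))


def build_activation_graph(M: FeatureMap, sigma: float) -> ActivationGraph:
    """Fully connected directed graph with weights dissimilarity x proximity."""
    side = M.values.shape[0]
    n = side * side
    if n > MAX_GRAPH_NODES:
        raise ValueError(
            f"{side}x{side} map gives {n} nodes > cap {MAX_GRAPH_NODES}; "
            "downsample the feature map first"
        )
    logm = np.log(np.maximum(M.values, EPS_CLAMP)).ravel()
    d = np.abs(logm[:, None] - logm[None, :])
    weights = d * proximity_matrix(side, sigma)
    return ActivationGraph(weights=weights, side=side, sigma=sigma)


def _stationary(weights: np.ndarray) -> np.ndarray:
    """Equilibrium distribution of the Markov chain with the given edge weights.

    Rows with no outgoing mass only occur for degenerate (constant) maps, in
    which case the uniform distribution is the defined answer.
    """
    n = weights.shape[0]
    row_sums = weights.sum(axis=1)
    if np.all(row_sums <= 0):
        return np.full(n, 1.0 / n)
    if np.any(row_sums <= 0):
        # isolated rows: park their mass in place via a self-loop
        weights = weights.copy()
        dead = row_sums <= 0
        weights[dead, :] = 0.0
        weights[np.ix_(dead, dead)] = np.eye(int(dead.sum()))
        row_sums = weights.sum(axis=1)
    P = weights / row_sums[:, None]
    v = np.full(n, 1.0 / n)
    iters_used = 0
    if n >= 256:
        # warm-start phase in single precision: same iteration, coarse
        # tolerance; the final convergence test below always runs in double
        P32 = P.astype(np.float32)
        v32 = v.astype(np.float32)
        for _ in range(POWER_MAXITER // 2):
            v_next = v32 @ P32
            v_next /= v_next.sum()
            residual = float(np.abs(v_next - v32).sum())
            v32 = v_next
            iters_used += 1
            if residual < 1e-6:
                break
        v = v32.astype(np.float64)
        v /= v.sum()
    residual = np.inf
    for it in range(iters_used + 1, POWER_MAXITER + 1):
        v_next = v @ P
        s = v_next.sum()
        if s > 0:
            v_next = v_next / s
        residual = float(np.abs(v_next - v).sum())
        v = v_next
        if residual < POWER_TOL:
            return v
    raise ConvergenceError(POWER_MAXITER, residual)


def equilibrium(graph: ActivationGraph) -> np.ndarray:
    """Stationary distribution over grid nodes, reshaped to (side, side)."""
    return _stationary(graph.weights).reshape(graph.side, graph.side)


def concentrate_mass(A: np.ndarray, sigma: float) -> np.ndarray:
    """Mass-concentration pass: a second chain attracted to high activations.

    The edge weight into node (p, q) is A(p, q) * F(i-p, j-q); mass flows
    toward strongly activated locations.  Returns the equilibrium
    distribution, shaped like ``A``.

    Note the chain is not translation invariant near the grid border, so a
    uniform activation map concentrates slightly toward the grid center; this
    mild center bias is inherent to the graph construction.
    """
    A = np.asarray(A, dtype=np.float64)
    if np.any(A < 0):
        raise ValueError("activation map must be non-negative")
    side = A.shape[0]
    F = proximity_matrix(side, sigma)
    weights = F * A.ravel()[None, :]
    return _stationary(weights).reshape(A.shape)


def combine_maps(
    maps: list[np.ndarray], image_shape: tuple[int, int]
) -> SaliencyMap:
    """Average channel maps, upsample to image resolution, rescale to [0, 1]."""
    if len(maps) == 0:
        raise ValueError("need at least one working map")
    mean_map = np.mean(np.stack([np.asarray(m, dtype=np.float64) for m in maps]), axis=0)
    up = resize(
        mean_map, image_shape, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    lo, hi = float(up.min()), float(up.max())
    if hi - lo < 1e-15:
        values = np.full(image_shape, 0.5)
    else:
        values = (up - lo) / (hi - lo)
    return SaliencyMap(values=values, working_map=mean_map)


def threshold_tau(S: SaliencyMap) -> float:
    """Dynamic threshold: the mean value of the saliency map."""
    return float(S.values.mean())


def extract_salient(
    img: GrayImage, S: SaliencyMap, min_pixels: int = 16
) -> SalientRegion:
    """Mask the image to its salient region (S >= tau) and record the bbox.

    An empty or tiny mask (< ``min_pixels``) falls back to the whole frame so
    downstream feature extraction always has content to work with.
    """
    if S.values.shape != img.pixels.shape:
        raise ValueError("saliency map must be at image resolution")
    tau = threshold_tau(S)
    mask = S.values >= tau
    if mask.sum() < min_pixels:
        mask = np.ones_like(mask, dtype=bool)
    masked = np.where(mask, img.pixels, 0.0)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    return SalientRegion(mask=mask, tau=tau, masked_image=masked, bbox=bbox)


def compute_saliency(
    img: GrayImage,
    r: int = DEFAULT_WORKING_SIDE,
    sigma: Optional[float] = None,
) -> SaliencyMap:
    """Full saliency pipeline for one image.

    Parameters
    ----------
    r : int
        Working grid side (graph has r^2 nodes; capped at 48).
    sigma : float, optional
        Proximity bandwidth in working-grid pixels.  Defaults to r / 10; the
        useful range extends to r / 5.
    """
    if sigma is None:
        sigma = r / 10.0
    maps = build_feature_maps(img, r)
    concentrated = []
    for fm in maps:
        graph = build_activation_graph(fm, sigma)
        activation = equilibrium(graph)
        concentrated.append(concentrate_mass(activation, sigma))
    return combine_maps(concentrated, img.pixels.shape)
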