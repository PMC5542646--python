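"""Kernelized locality-sensitive hashing over normalised descriptors.

A b-bit binary key is assigned to every descriptor so that similar
descriptors collide with high probability.  The construction follows the
kernelised LSH recipe: sample rho anchor descriptors, form their RBF kernel
matrix K (bandwidth gamma from the median heuristic unless given), double
center it, and compute K^{-1/2} by symmetric eigendecomposition.  Each of the
b hash functions draws t distinct anchor indices to form an indicator vector
e_s and uses the weight row w = K^{-1/2} e_s; a descriptor x hashes to bit 1
when sum_i w(i) * kappa(x, anchor_i) >= 0 (sign of zero is taken as 1).

Eigenvalues of the centered kernel below ``eig_floor`` are treated as zero
and excluded from the inverse square root (a truncated pseudo-inverse).  The
centered kernel always annihilates the all-ones direction; inverting that
null space would let a spurious constant component of e_s dominate every
hash function and produce constant bits, destroying locality sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist

DEFAULT_BITS = 128
DEFAULT_RHO = 300
DEFAULT_T = 30
EIG_FLOOR = 1e-12

__all__ = [
    "DEFAULT_BITS",
    "DEFAULT_RHO",
    "DEFAULT_T",
    "KLSHModel",
    "HashKey",
    "rbf_kernel",
    "median_gamma",
    "fit_klsh",
    "hash_descriptor",
    "hash_many",
    "hamming",
]


@dataclass
class KLSHModel:
    """Fitted hashing parameters; fully determined by (data, rho, t, b, gamma, seed)."""

    anchors: np.ndarray  # (rho, n)
    gamma: float
    W: np.ndarray  # (b, rho)
    rho: int
    t: int
    b: int
    seed: int
    eig_floor: float = EIG_FLOOR


@dataclass(frozen=True)
class HashKey:
    """A b-bit binary code, stored packed (``np.packbits`` order)."""

    packed: bytes
    b: int

    @classmethod
    def from_bits(cls, bits: np.ndarray) -> "HashKey":
        bits = np.asarray(bits, dtype=np.uint8)
        return cls(packed=np.packbits(bits).tobytes(), b=bits.size)

    @property
    def bits(self) -> np.ndarray:
        return np.unpackbits(
            np.frombuffer(self.packed, dtype=np.uint8), count=self.b
        )


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """kappa(x, y) = exp(-gamma * ||x - y||^2), in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def median_gamma(X: np.ndarray) -> float:
    """Median heuristic: gamma = 1 / median(||x - y||^2) over distinct pairs."""
    sq = pdist(np.asarray(X, dtype=np.float64), metric="sqeuclidean")
    med = float(np.median(sq[sq > 0])) if np.any(sq > 0) else 0.0
    if med <= 0:
        raise ValueError("degenerate anchor set: all pairwise distances zero")
    return 1.0 / med


def _center_kernel(K: np.ndarray) -> np.ndarray:
    """Symmetric double centering: subtract row and column means, add grand mean."""
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def _inv_sqrt(K: np.ndarray, eig_floor: float) -> np.ndarray:
    """Truncated inverse square root of a symmetric PSD matrix."""
    vals, vecs = np.linalg.eigh(K)
    inv = np.where(vals > eig_floor, 1.0 / np.sqrt(np.maximum(vals, eig_floor)), 0.0)
    return (vecs * inv[None, :]) @ vecs.T


def fit_klsh(
    descriptors: np.ndarray,
    rho: int = DEFAULT_RHO,
    t: int = DEFAULT_T,
    b: int = DEFAULT_BITS,
    seed: int = 0,
    gamma: Optional[float] = None,
    eig_floor: float = EIG_FLOOR,
) -> KLSHModel:
    """Fit the hashing model on a collection of normalised descriptors.

    Parameters
    ----------
    descriptors : ndarray, shape (N, n)
        The indexed descriptor collection; ``N >= rho >= t``.
    rho, t, b : int
        Anchor count, indices per hash function, bits per key.
    seed : int
        Seeds both anchor sampling and per-bit index draws.
    gamma : float, optional
        RBF bandwidth; median heuristic over anchor pairs when omitted.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("descriptors must be a 2-D array")
    N = X.shape[0]
    if not (N >= rho >= t >= 1):
        raise ValueError(f"need N >= rho >= t >= 1, got N={N}, rho={rho}, t={t}")
    if b < 1:
        raise ValueError("b must be >= 1")
    rng = np.random.default_rng(seed)
    anchors = X[rng.choice(N, size=rho, replace=False)]
    if gamma is None:
        gamma = median_gamma(anchors)
    K = np.exp(-gamma * cdist(anchors, anchors, metric="sqeuclidean"))
    Kc = _center_kernel(K)
    K_inv_sqrt = _inv_sqrt(Kc, eig_floor)
    W = np.zeros((b, rho), dtype=np.float64)
    for j in range(b):
        idx = rng.choice(rho, size=t, replace=False)
        e_s = np.zeros(rho)
        e_s[idx] = 1.0
        W[j] = K_inv_sqrt @ e_s
    if not np.all(np.isfinite(W)):
        raise ValueError("degenerate kernel: non-finite hash weights")
    return KLSHModel(
        anchors=anchors, gamma=gamma, W=W, rho=rho, t=t, b=b,
        seed=seed, eig_floor=eig_floor,
    )


def _kernel_vector(model: KLSHModel, x: np.ndarray) -> np.ndarray:
    diffs = model.anchors - x[None, :]
    return np.exp(-model.gamma * np.sum(diffs * diffs, axis=1))


def hash_descriptor(model: KLSHModel, x: np.ndarray) -> HashKey:
    """Hash one normalised descriptor to its b-bit key (sign(0) -> bit 1)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.anchors.shape[1],):
        raise ValueError(
            f"descriptor length {x.shape} does not match model "
            f"({model.anchors.shape[1]},)"
        )
    scores = model.W @ _kernel_vector(model, x)
    return HashKey.from_bits((scores >= 0).astype(np.uint8))


def hash_many(model: KLSHModel, X: np.ndarray) -> np.ndarray:
    """Vectorised hashing; returns a (N, b) uint8 bit matrix."""
    X = np.asarray(X, dtype=np.float64)
    Kq = np.exp(-model.gamma * cdist(X, model.anchors, metric="sqeuclidean"))
    return (Kq @ model.W.T >= 0).astype(np.uint8)


def hamming(k1: HashKey, k2: HashKey) -> int:
    """Number of differing bits between two equal-length keys."""
    if k1.b != k2.b:
        raise ValueError(f"key length mismatch: {k1.b} vs {k2.b}")
    return int(np.count_nonzero(k1.bits != k2.bits))
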