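"""Descriptor fusion and min-max normalization.

The fused descriptor is the convex combination ``alpha * whole + beta *
salient`` of the whole-image and salient-region codes (alpha + beta = 1,
defaults 0.4 / 0.6), so saliency information is injected into the whole-image
representation with a tunable strength.  Before hashing, descriptors are
min-max normalised with a single global (scalar) minimum and maximum fitted
over the indexed collection; query-time values outside the fitted range are
clamped into [0, 1].  A per-dimension variant is available behind the
``mode`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

DEFAULT_ALPHA = 0.4
DEFAULT_BETA = 0.6
WEIGHT_TOL = 1e-12

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
    "FusedDescriptor",
    "Normalizer",
    "fuse",
    "fit_normalizer",
    "normalize",
]


@dataclass
class FusedDescriptor:
    """Weighted fusion of whole-image and salient-region codes."""

    values: np.ndarray
    alpha: float
    beta: float


@dataclass
class Normalizer:
    """Fitted min-max range.  ``m_n``/``m_x`` are scalars in ``global`` mode,
    per-dimension vectors in ``per_dimension`` mode."""

    m_n: np.ndarray
    m_x: np.ndarray
    mode: Literal["global", "per_dimension"] = "global"


def fuse(
    nc_whole: np.ndarray,
    nc_salient: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> FusedDescriptor:
    """Elementwise weighted sum ``alpha * whole + beta * salient``.

    Setting (alpha, beta) = (1, 0) reduces to the whole-image code; (0, 1)
    to the salient-region code.
    """
    nc_whole = np.asarray(nc_whole, dtype=np.float64)
    nc_salient = np.asarray(nc_salient, dtype=np.float64)
    if nc_whole.shape != nc_salient.shape:
        raise ValueError(
            f"length mismatch: {nc_whole.shape} vs {nc_salient.shape}"
        )
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > WEIGHT_TOL:
        raise ValueError(
            f"weights must be non-negative and sum to 1, got {alpha} + {beta}"
        )
    return FusedDescriptor(alpha * nc_whole + beta * nc_salient, alpha, beta)


def _stack(descriptors: Iterable) -> np.ndarray:
    arrs = [
        d.values if isinstance(d, FusedDescriptor) else np.asarray(d, dtype=np.float64)
        for d in descriptors
    ]
    if not arrs:
        raise ValueError("empty descriptor collection")
    return np.stack(arrs)


def fit_normalizer(
    descriptors: Iterable,
    mode: Literal["global", "per_dimension"] = "global",
) -> Normalizer:
    """Fit the min-max range over a descriptor collection.

    ``global`` mode takes a single scalar minimum and maximum over every
    entry of every descriptor; ``per_dimension`` fits one range per feature.
    """
    X = _stack(descriptors)
    if mode == "global":
        m_n = np.asarray(X.min())
        m_x = np.asarray(X.max())
        if m_x <= m_n:
            raise ValueError("degenerate collection: all activations identical")
    elif mode == "per_dimension":
        m_n = X.min(axis=0)
        m_x = X.max(axis=0)
        if np.all(m_x <= m_n):
            raise ValueError("degenerate collection: all activations identical")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Normalizer(m_n=m_n, m_x=m_x, mode=mode)


def normalize(desc, norm: Normalizer) -> np.ndarray:
    """Map a descriptor into [0, 1]^n with the fitted range, clamping
    out-of-range (query-time) values."""
    v = desc.values if isinstance(desc, FusedDescriptor) else np.asarray(desc, float)
    span = np.asarray(norm.m_x, dtype=np.float64) - np.asarray(norm.m_n, dtype=np.float64)
    span = np.where(span > 0, span, 1.0)
    return np.clip((v - norm.m_n) / span, 0.0, 1.0)
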