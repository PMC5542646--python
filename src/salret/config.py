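"""Pipeline configuration: one declarative object covering every stage.

Defaults follow the method's stated operating point where one exists
(input side 224, fusion weights 0.4/0.6, 128-bit keys); everything else is a
documented package choice.  Configurations serialise to YAML and carry a
stable fingerprint (SHA-256 of the canonical JSON form) that is stored with
every index so that a query can verify it was produced under the same
settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal, Optional

import yaml

from .descriptor import DEFAULT_ALPHA, DEFAULT_BETA
from .features import ExtractorConfig
from .hashing import DEFAULT_BITS, DEFAULT_RHO, DEFAULT_T
from .preprocess import DEFAULT_SIDE
from .saliency import DEFAULT_WORKING_SIDE

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the retrieval pipeline.

    Attributes
    ----------
    input_side : int
        Side T of the square extractor input (pixels).
    working_side : int
        Saliency working-grid side r; the saliency graph has r^2 nodes.
    sigma_fraction : float
        Proximity bandwidth as a fraction of the working side (1/10 default,
        up to 1/5 is sensible).
    alpha, beta : float
        Fusion weights for whole-image / salient-region codes; alpha+beta=1.
    crop_salient_to_bbox : bool
        Feed the bbox crop of the masked image (True) or the full-frame
        masked image (False) to the extractor.
    normalization : str
        "global" scalar min-max (default) or "per_dimension".
    rho, t, bits : int
        KLSH anchors, indices per hash function, key length.
    gamma : float or None
        RBF bandwidth; None selects the median heuristic over anchor pairs.
    max_radius : int
        Hamming-radius cap for bucket candidate expansion.
    seed : int
        Master seed for every stochastic stage (anchor and index draws).
    """

    input_side: int = DEFAULT_SIDE
    working_side: int = DEFAULT_WORKING_SIDE
    sigma_fraction: float = 0.1
    clamp_eps: float = 1e-6
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    crop_salient_to_bbox: bool = True
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    normalization: Literal["global", "per_dimension"] = "global"
    rho: int = DEFAULT_RHO
    t: int = DEFAULT_T
    bits: int = DEFAULT_BITS
    gamma: Optional[float] = None
    max_radius: int = 16
    recall_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        if not (0 < self.sigma_fraction <= 0.5):
            raise ValueError("sigma_fraction must be in (0, 0.5]")
        if self.max_radius < 0:
            raise ValueError("max_radius must be >= 0")

    @property
    def sigma(self) -> float:
        return self.working_side * self.sigma_fraction

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recall_grid"] = list(self.recall_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "extractor" in d and isinstance(d["extractor"], dict):
            d["extractor"] = ExtractorConfig(**d["extractor"])
        if "recall_grid" in d:
            d["recall_grid"] = tuple(d["recall_grid"])
        return cls(**d)

    def fingerprint(self) -> str:
        """SHA-256 of the canonical JSON serialisation."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def with_weights(self, alpha: float) -> "PipelineConfig":
        """A copy with fusion weights (alpha, 1 - alpha)."""
        return replace(self, alpha=alpha, beta=round(1.0 - alpha, 12))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
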