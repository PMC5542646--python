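"""Building, persisting and querying the image index.

``build_index`` runs the whole representation chain over a collection —
preprocess, saliency, whole/salient codes, fusion, min-max normalisation,
KLSH fitting, hashing — and stores every per-image record together with the
fitted components (mean image, normaliser, hashing model) so queries are
processed under exactly the indexed settings.  Queries run either as a
linear similarity scan over all records or as a hash-bucket candidate search
(multi-probe by increasing Hamming radius) followed by similarity reranking.

Similarity between normalised (hence non-negative) descriptors is cosine,
which lands in [0, 1]; identical descriptors score exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import h5py
import numpy as np

from .config import PipelineConfig
from .descriptor import FusedDescriptor, Normalizer, fit_normalizer, fuse, normalize
from .features import codes_for_image, extract
from .hashing import HashKey, KLSHModel, fit_klsh, hamming, hash_many
from .preprocess import (
    GrayImage,
    MeanImage,
    compute_mean_image,
    preprocess_image,
    rescale_and_pad,
)
from .saliency import compute_saliency

__all__ = [
    "ImageIndex",
    "QueryResult",
    "similarity",
    "pipeline_codes",
    "build_index",
    "prepare_query",
    "query_linear",
    "query_hashed",
    "save_index",
    "load_index",
]


@dataclass
class QueryResult:
    """Ranked retrieval result for one query."""

    ranked: list[tuple[str, float]]  # (record id, similarity), non-increasing
    k: int
    mode: Literal["linear", "hashed"]
    candidates_examined: int
    candidate_ids: Optional[list[str]] = None  # hashed mode: the probed pool

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.ranked]


@dataclass
class ImageIndex:
    """Persisted collection of descriptors, keys, labels and hash buckets."""

    ids: list[str]
    labels: list[Optional[str]]
    descriptors: np.ndarray  # (N, n) normalised
    keys: np.ndarray  # (N, b) uint8 bits
    normalizer: Normalizer
    klsh: KLSHModel
    mean_image: MeanImage
    config: PipelineConfig
    fingerprint: str
    buckets: dict[bytes, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("record ids must be unique")
        if not self.buckets:
            self.buckets = _build_buckets(self.keys)

    @property
    def size(self) -> int:
        return len(self.ids)

    def key_of(self, i: int) -> HashKey:
        return HashKey.from_bits(self.keys[i])


def _build_buckets(keys: np.ndarray) -> dict[bytes, list[int]]:
    buckets: dict[bytes, list[int]] = {}
    for i, bits in enumerate(keys):
        buckets.setdefault(np.packbits(bits).tobytes(), []).append(i)
    return buckets


def similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of two non-negative normalised descriptors, in [0, 1].

    Identical nonzero vectors score exactly 1; a zero vector scores 0 against
    anything.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if np.array_equal(x, y):
        return 0.0 if not np.any(x) else 1.0
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(np.dot(x, y) / (nx * ny), 0.0, 1.0))


def _scores_against(D: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vectorised cosine of q against the rows of D (with the exact-match fix)."""
    norms = np.linalg.norm(D, axis=1)
    nq = float(np.linalg.norm(q))
    if nq == 0.0:
        return np.zeros(D.shape[0])
    denom = np.where(norms > 0, norms * nq, 1.0)
    scores = np.clip((D @ q) / denom, 0.0, 1.0)
    scores[norms == 0] = 0.0
    near = np.flatnonzero(scores > 1.0 - 1e-9)
    for i in near:
        if np.array_equal(D[i], q):
            scores[i] = 1.0
    return scores


def pipeline_codes(
    images: Sequence[GrayImage], config: PipelineConfig
) -> tuple[MeanImage, list[tuple[np.ndarray, np.ndarray]]]:
    """Mean image plus (whole, salient) code pairs for a collection.

    This is the expensive half of indexing (saliency + feature extraction
    per image); the result can be fed back to :func:`build_index` or the
    evaluation sweeps to avoid recomputation when only fusion weights or
    hashing settings change.
    """
    squares = [rescale_and_pad(img, config.input_side)[0] for img in images]
    mean = compute_mean_image(squares)
    pairs = []
    for img in images:
        S = compute_saliency(img, r=config.working_side, sigma=config.sigma)
        pairs.append(
            codes_for_image(
                img, S, config.extractor, mean,
                crop_to_bbox=config.crop_salient_to_bbox,
            )
        )
    return mean, pairs


def build_index(
    images: Sequence[GrayImage],
    config: Optional[PipelineConfig] = None,
    precomputed: Optional[
        tuple[MeanImage, list[tuple[np.ndarray, np.ndarray]]]
    ] = None,
) -> ImageIndex:
    """Run the full representation chain and assemble the index.

    The KLSH anchor count is clamped to the collection size (and ``t`` to the
    anchor count) so small collections index without manual retuning.
    ``precomputed`` accepts the output of :func:`pipeline_codes` for the same
    image sequence to skip the saliency/feature pass.
    """
    if len(images) == 0:
        raise ValueError("cannot build an index from an empty collection")
    config = config or PipelineConfig()
    errors = []
    for img in images:
        if not img.id:
            errors.append("image with empty id")
    if errors:
        raise ValueError("invalid collection: " + "; ".join(errors))

    mean, pairs = precomputed if precomputed is not None else pipeline_codes(
        images, config
    )
    fused = [
        fuse(nc_i, nc_s, config.alpha, config.beta) for nc_i, nc_s in pairs
    ]
    normalizer = fit_normalizer(fused, mode=config.normalization)
    D = np.stack([normalize(f, normalizer) for f in fused])
    rho = min(config.rho, len(images))
    t = min(config.t, rho)
    klsh = fit_klsh(
        D, rho=rho, t=t, b=config.bits, seed=config.seed, gamma=config.gamma
    )
    keys = hash_many(klsh, D)
    return ImageIndex(
        ids=[img.id for img in images],
        labels=[img.label for img in images],
        descriptors=D,
        keys=keys,
        normalizer=normalizer,
        klsh=klsh,
        mean_image=mean,
        config=config,
        fingerprint=config.fingerprint(),
    )


def prepare_query(index: ImageIndex, img: GrayImage) -> tuple[np.ndarray, HashKey]:
    """Normalised descriptor and hash key for a query image, computed with the
    index's fitted components."""
    cfg = index.config
    S = compute_saliency(img, r=cfg.working_side, sigma=cfg.sigma)
    nc_i, nc_s = codes_for_image(
        img, S, cfg.extractor, index.mean_image,
        crop_to_bbox=cfg.crop_salient_to_bbox,
    )
    fused = fuse(nc_i, nc_s, cfg.alpha, cfg.beta)
    q = normalize(fused, index.normalizer)
    bits = hash_many(index.klsh, q[None, :])[0]
    return q, HashKey.from_bits(bits)


def _rank(
    index: ImageIndex, candidate_idx: np.ndarray, scores: np.ndarray, k: int
) -> list[tuple[str, float]]:
    order = sorted(
        range(len(candidate_idx)),
        key=lambda j: (-scores[j], index.ids[candidate_idx[j]]),
    )
    top = order[: min(k, len(order))]
    return [(index.ids[candidate_idx[j]], float(scores[j])) for j in top]


QueryInput = Union[GrayImage, np.ndarray]


def _query_descriptor(index: ImageIndex, query: QueryInput) -> np.ndarray:
    if isinstance(query, GrayImage):
        return prepare_query(index, query)[0]
    return np.asarray(query, dtype=np.float64)


def query_linear(index: ImageIndex, query: QueryInput, k: int = 10) -> QueryResult:
    """Score every record by similarity; top-k, ties broken by ascending id.

    ``query`` may be a raw image (run through the fitted pipeline) or an
    already-normalised descriptor.
    """
    if index.size == 0:
        raise ValueError("empty index")
    if k < 1:
        raise ValueError("k must be >= 1")
    q = _query_descriptor(index, query)
    scores = _scores_against(index.descriptors, q)
    all_idx = np.arange(index.size)
    return QueryResult(
        ranked=_rank(index, all_idx, scores, k),
        k=k,
        mode="linear",
        candidates_examined=index.size,
    )


def query_hashed(
    index: ImageIndex,
    query: QueryInput,
    k: int = 10,
    max_radius: Optional[int] = None,
) -> QueryResult:
    """Bucket candidate search: probe buckets in increasing Hamming radius
    from the query key until at least ``3k`` candidates are gathered or the
    radius cap is exceeded, then rerank candidates by similarity.

    A radius cap of ``b`` (the key length) or more means exhaustive
    expansion: every record becomes a candidate and the ranking coincides
    with the linear scan."""
    if index.size == 0:
        raise ValueError("empty index")
    if k < 1:
        raise ValueError("k must be >= 1")
    if max_radius is None:
        max_radius = index.config.max_radius
    if isinstance(query, GrayImage):
        q, qkey = prepare_query(index, query)
    else:
        q = np.asarray(query, dtype=np.float64)
        bits = hash_many(index.klsh, q[None, :])[0]
        qkey = HashKey.from_bits(bits)

    distinct = list(index.buckets.items())
    key_bits = np.stack(
        [np.unpackbits(np.frombuffer(p, dtype=np.uint8), count=index.klsh.b)
         for p, _ in distinct]
    )
    dists = np.count_nonzero(key_bits != qkey.bits[None, :], axis=1)

    need = max(k, 3 * k)
    exhaustive = max_radius >= index.klsh.b
    candidates: list[int] = []
    for radius in range(0, min(max_radius, index.klsh.b) + 1):
        at_r = np.flatnonzero(dists == radius)
        for j in at_r:
            candidates.extend(distinct[j][1])
        if not exhaustive and len(candidates) >= need:
            break
    cand_idx = np.array(sorted(candidates), dtype=np.int64)
    if cand_idx.size == 0:
        return QueryResult(
            ranked=[], k=k, mode="hashed", candidates_examined=0,
            candidate_ids=[],
        )
    scores = _scores_against(index.descriptors[cand_idx], q)
    return QueryResult(
        ranked=_rank(index, cand_idx, scores, k),
        k=k,
        mode="hashed",
        candidates_examined=int(cand_idx.size),
        candidate_ids=[index.ids[i] for i in cand_idx],
    )


# ---------------------------------------------------------------------------
# persistence (single HDF5 container)

def save_index(index: ImageIndex, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("descriptors", data=index.descriptors)
        f.create_dataset("keys", data=np.packbits(index.keys, axis=1))
        f.create_dataset("mean_image", data=index.mean_image.planes)
        f.create_dataset("anchors", data=index.klsh.anchors)
        f.create_dataset("W", data=index.klsh.W)
        str_dt = h5py.string_dtype()
        f.create_dataset("ids", data=np.array(index.ids, dtype=object), dtype=str_dt)
        f.create_dataset(
            "labels",
            data=np.array([l if l is not None else "" for l in index.labels],
                          dtype=object),
            dtype=str_dt,
        )
        f.attrs["gamma"] = index.klsh.gamma
        f.attrs["rho"] = index.klsh.rho
        f.attrs["t"] = index.klsh.t
        f.attrs["b"] = index.klsh.b
        f.attrs["klsh_seed"] = index.klsh.seed
        f.attrs["eig_floor"] = index.klsh.eig_floor
        f.attrs["norm_mode"] = index.normalizer.mode
        f.attrs["norm_m_n"] = np.asarray(index.normalizer.m_n)
        f.attrs["norm_m_x"] = np.asarray(index.normalizer.m_x)
        f.attrs["config"] = json.dumps(index.config.to_dict(), sort_keys=True)
        f.attrs["fingerprint"] = index.fingerprint


def load_index(path) -> ImageIndex:
    with h5py.File(path, "r") as f:
        b = int(f.attrs["b"])
        keys = np.unpackbits(f["keys"][...], axis=1)[:, :b]
        config = PipelineConfig.from_dict(json.loads(f.attrs["config"]))
        klsh = KLSHModel(
            anchors=f["anchors"][...],
            gamma=float(f.attrs["gamma"]),
            W=f["W"][...],
            rho=int(f.attrs["rho"]),
            t=int(f.attrs["t"]),
            b=b,
            seed=int(f.attrs["klsh_seed"]),
            eig_floor=float(f.attrs["eig_floor"]),
        )
        normalizer = Normalizer(
            m_n=np.asarray(f.attrs["norm_m_n"]),
            m_x=np.asarray(f.attrs["norm_m_x"]),
            mode=str(f.attrs["norm_mode"]),
        )
        labels = [l if l else None for l in f["labels"].asstr()[...]]
        return ImageIndex(
            ids=list(f["ids"].asstr()[...]),
            labels=labels,
            descriptors=f["descriptors"][...],
            keys=keys,
            normalizer=normalizer,
            klsh=klsh,
            mean_image=MeanImage(f["mean_image"][...]),
            config=config,
            fingerprint=str(f.attrs["fingerprint"]),
        )
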