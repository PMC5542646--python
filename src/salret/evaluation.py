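"""Retrieval evaluation: precision/recall, PR curves, AUC and experiments.

Relevance is category-label equality.  Precision is N_R / (N_R + N_I) over
the retrieved set; recall is N_R / T_R against the total number of relevant
records in the index.  Per-query PR curves use standard interpolated
precision on the fixed recall grid {0.1, ..., 1.0} (precision at level r is
the maximum precision over all ranking cutoffs achieving recall >= r; levels
never reached score 0) and are macro-averaged across queries.  AUC is the
trapezoidal integral of the mean curve over [0, 1], extending the first grid
value back to recall 0.

The module also runs the two sensitivity experiments end to end on labeled
synthetic data: the fusion-weight sweep (retrieval quality as a function of
the whole-image/salient-region weighting) and the noise-robustness sweep
(salt-&-pepper and Gaussian corruption of queries, with an optional 3x3
median-filter denoising pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .config import PipelineConfig
from .descriptor import fit_normalizer, fuse, normalize
from .hashing import fit_klsh, hash_many
from .index import ImageIndex, QueryResult, build_index, pipeline_codes, query_linear
from .preprocess import GrayImage
from .synthetic import corrupt

DEFAULT_RECALL_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))

__all__ = [
    "PRPoint",
    "EvalReport",
    "precision_recall",
    "precision_at_k",
    "pr_curve",
    "auc",
    "evaluate_queries",
    "fusion_sweep",
    "noise_sweep",
]


@dataclass(frozen=True)
class PRPoint:
    recall: float
    precision: float


@dataclass
class EvalReport:
    """Aggregate retrieval report over a query set."""

    per_query: list[list[PRPoint]]
    mean_curve: list[PRPoint]
    auc: float
    per_category: pd.DataFrame  # category, n_queries, mean precision@10, AUC
    config: dict = field(default_factory=dict)

    def mean_precision_at(self, recall_level: float) -> float:
        for pt in self.mean_curve:
            if abs(pt.recall - recall_level) < 1e-9:
                return pt.precision
        raise KeyError(f"recall level {recall_level} not on the grid")


def precision_recall(
    result: QueryResult, relevant_ids: set[str], total_relevant: int
) -> tuple[float, float]:
    """Precision and recall of one retrieved set.

    ``total_relevant`` (T_R) is the number of relevant records in the index.
    """
    if total_relevant < 1:
        raise ValueError("total_relevant must be >= 1")
    retrieved = result.ids
    if len(retrieved) == 0:
        raise ValueError("empty query result")
    n_rel = sum(1 for rid in retrieved if rid in relevant_ids)
    precision = n_rel / len(retrieved)
    recall = n_rel / total_relevant
    return precision, recall


def precision_at_k(result: QueryResult, relevant_ids: set[str], k: int) -> float:
    """Fraction of the top-k retrieved that are relevant."""
    top = result.ids[:k]
    if not top:
        return 0.0
    return sum(1 for rid in top if rid in relevant_ids) / len(top)


def pr_curve(
    result: QueryResult,
    relevant_ids: set[str],
    total_relevant: int,
    grid: Sequence[float] = DEFAULT_RECALL_GRID,
) -> list[PRPoint]:
    """Interpolated precision at each recall grid level for one ranking."""
    if total_relevant < 1:
        raise ValueError("total_relevant must be >= 1")
    rel_flags = np.array([rid in relevant_ids for rid in result.ids])
    cum_rel = np.cumsum(rel_flags)
    cutoffs = np.arange(1, len(rel_flags) + 1)
    precisions = cum_rel / cutoffs
    recalls = cum_rel / total_relevant
    points = []
    for r in grid:
        achieved = recalls >= r - 1e-12
        p = float(precisions[achieved].max()) if achieved.any() else 0.0
        points.append(PRPoint(recall=float(r), precision=p))
    return points


def _mean_curve(curves: list[list[PRPoint]]) -> list[PRPoint]:
    grid = [pt.recall for pt in curves[0]]
    mat = np.array([[pt.precision for pt in c] for c in curves])
    return [PRPoint(r, float(p)) for r, p in zip(grid, mat.mean(axis=0))]


def auc(curve: Sequence[PRPoint]) -> float:
    """Trapezoidal area under a PR curve on an ascending recall grid,
    extending the first value back to recall 0."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    recalls = np.array([0.0] + [pt.recall for pt in curve])
    precisions = np.array([curve[0].precision] + [pt.precision for pt in curve])
    return float(np.trapezoid(precisions, recalls))


def _relevant(index: ImageIndex, label: Optional[str]) -> set[str]:
    return {rid for rid, lab in zip(index.ids, index.labels) if lab == label}


def evaluate_queries(
    index: ImageIndex,
    queries: Sequence[GrayImage],
    k: Optional[int] = None,
    grid: Sequence[float] = DEFAULT_RECALL_GRID,
) -> EvalReport:
    """Linear-scan retrieval evaluation of a labeled query set.

    Rankings cover the whole index (k defaults to the index size) so every
    recall level is reachable.
    """
    if k is None:
        k = index.size
    curves, rows = [], []
    for q in queries:
        rel = _relevant(index, q.label)
        if not rel:
            raise ValueError(f"no relevant records in index for label {q.label!r}")
        res = query_linear(index, q, k=k)
        curves.append(pr_curve(res, rel, len(rel), grid))
        rows.append(
            {
                "category": q.label,
                "precision_at_10": precision_at_k(res, rel, 10),
                "auc": auc(curves[-1]),
            }
        )
    df = pd.DataFrame(rows)
    per_cat = (
        df.groupby("category")
        .agg(n_queries=("category", "size"),
             precision_at_10=("precision_at_10", "mean"),
             auc=("auc", "mean"))
        .reset_index()
    )
    mean_curve = _mean_curve(curves)
    return EvalReport(
        per_query=curves,
        mean_curve=mean_curve,
        auc=auc(mean_curve),
        per_category=per_cat,
        config={"k": k, "grid": list(grid)},
    )


def fusion_sweep(
    index_images: Sequence[GrayImage],
    queries: Sequence[GrayImage],
    alphas: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    config: Optional[PipelineConfig] = None,
    precomputed: Optional[tuple] = None,
) -> pd.DataFrame:
    """Retrieval quality as a function of the fusion weights.

    The whole/salient code pairs are computed once; for each (alpha,
    1 - alpha) pair the fusion, normalisation and linear retrieval are redone
    and the mean interpolated precision at recall 0.1 plus precision@10 are
    reported.  ``precomputed`` may carry ``(mean_image, index_code_pairs,
    query_code_pairs)`` from an earlier pass over the same images.

    Returns a DataFrame with columns alpha, beta, precision_at_recall_01,
    precision_at_10.
    """
    config = config or PipelineConfig()
    if precomputed is not None:
        mean_img, idx_pairs, q_pairs = precomputed
    else:
        mean_img, idx_pairs = pipeline_codes(index_images, config)
        q_pairs = query_codes(queries, mean_img, config)

    labels = [img.label for img in index_images]
    ids = [img.id for img in index_images]
    rows = []
    for alpha in alphas:
        beta = round(1.0 - alpha, 12)
        fused = [fuse(w, s, alpha, beta) for w, s in idx_pairs]
        norm = fit_normalizer(fused, mode=config.normalization)
        D = np.stack([normalize(f, norm) for f in fused])
        p01, p10 = [], []
        for q, (qw, qs) in zip(queries, q_pairs):
            qd = normalize(fuse(qw, qs, alpha, beta), norm)
            sims = _cosine_rows(D, qd)
            order = sorted(range(len(ids)), key=lambda i: (-sims[i], ids[i]))
            rel = {ids[i] for i in range(len(ids)) if labels[i] == q.label}
            ranked_ids = [ids[i] for i in order]
            rel_flags = np.array([rid in rel for rid in ranked_ids])
            cum = np.cumsum(rel_flags)
            prec = cum / np.arange(1, len(ids) + 1)
            rec = cum / len(rel)
            achieved = rec >= 0.1 - 1e-12
            p01.append(float(prec[achieved].max()) if achieved.any() else 0.0)
            p10.append(float(rel_flags[:10].mean()))
        rows.append(
            {
                "alpha": alpha,
                "beta": beta,
                "precision_at_recall_01": float(np.mean(p01)),
                "precision_at_10": float(np.mean(p10)),
            }
        )
    return pd.DataFrame(rows)


def query_codes(queries, mean_img, config: PipelineConfig) -> list:
    """Whole/salient code pairs for query images under a fitted mean image."""
    from .features import codes_for_image
    from .saliency import compute_saliency

    out = []
    for q in queries:
        S = compute_saliency(q, r=config.working_side, sigma=config.sigma)
        out.append(
            codes_for_image(q, S, config.extractor, mean_img,
                            crop_to_bbox=config.crop_salient_to_bbox)
        )
    return out


def _cosine_rows(D: np.ndarray, q: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(D, axis=1) * np.linalg.norm(q)
    denom = np.where(norms > 0, norms, 1.0)
    out = np.clip((D @ q) / denom, 0.0, 1.0)
    out[norms == 0] = 0.0
    return out


def noise_sweep(
    index: ImageIndex,
    queries: Sequence[GrayImage],
    model: str = "saltpepper",
    levels: Sequence[float] = (0.0, 0.05, 0.1, 0.2),
    denoise: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean precision@10 with queries corrupted at increasing noise levels.

    ``model`` is "saltpepper" (level = flip probability) or "gaussian"
    (level = noise variance).  ``denoise`` applies a 3x3 median filter to the
    corrupted query before retrieval.  Level 0 reproduces the clean baseline
    exactly.  Corruption seeds derive from ``(seed, query index, level
    index)`` and are recorded in the output.
    """
    rows = []
    for li, level in enumerate(levels):
        precisions = []
        for qi, q in enumerate(queries):
            q_seed = int(
                np.random.SeedSequence([seed, qi, li]).generate_state(1)[0]
                % (2**31)
            )
            noisy = corrupt(q, model, level, seed=q_seed)
            if denoise:
                noisy = GrayImage(
                    median_filter(noisy.pixels, size=3), id=noisy.id,
                    label=noisy.label,
                )
            rel = _relevant(index, q.label)
            res = query_linear(index, noisy, k=10)
            precisions.append(precision_at_k(res, rel, 10))
        rows.append(
            {
                "model": model,
                "level": level,
                "denoise": denoise,
                "precision_at_10": float(np.mean(precisions)),
                "n_queries": len(queries),
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
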