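"""Plate re-identification across frames.

Each plate gets a signature: per-channel RGB histograms (256 bins),
estimated radius, and optionally an externally supplied embedding vector
(e.g. from a vision transformer — never computed here). Pairwise
similarities are fused by a weighted sum into a score matrix in [0, 1],
and a maximum-score one-to-one assignment is solved by the Hungarian
algorithm; pairs below a score floor stay unmatched.

Histogram similarity uses the Hellinger form of the Bhattacharyya
distance, d = sqrt(1 − Σ√(p·q)) on normalized histograms, which is
bounded in [0, 1] and so composes cleanly with the other components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import ParameterError, PointCloud


class UndefinedHistogramError(ValueError):
    """Raised for an all-zero histogram (no pixels to compare)."""


@dataclass
class PlateSignature:
    """Appearance + size descriptor of one tracked plate."""

    histograms: np.ndarray  # 3 x 256 per-channel counts
    radius: float  # m
    embedding: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.histograms = np.asarray(self.histograms, dtype=np.float64)
        if self.histograms.shape != (3, 256):
            raise ParameterError("histograms must be 3 x 256")
        if np.any(self.histograms < 0):
            raise ParameterError("histogram bins must be >= 0")
        if self.radius <= 0:
            raise ParameterError("radius must be positive")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=np.float64).ravel()


def signature_from_cloud(
    cloud: PointCloud, radius: float, embedding: Optional[np.ndarray] = None
) -> PlateSignature:
    """Build a signature from a colored plate cloud (histograms over its
    per-point RGB values)."""
    if not cloud.has_colors:
        raise ParameterError("signature requires a colored cloud")
    hists = np.stack(
        [np.bincount(cloud.colors[:, c], minlength=256) for c in range(3)]
    ).astype(np.float64)
    return PlateSignature(hists, radius, embedding)


def histogram_similarity(h1: np.ndarray, h2: np.ndarray) -> float:
    """1 − mean-over-channels Bhattacharyya (Hellinger) distance, in [0, 1]."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ParameterError("histograms must have equal bin counts")
    h1 = np.atleast_2d(h1)
    h2 = np.atleast_2d(h2)
    dists = []
    for a, b in zip(h1, h2):
        sa, sb = a.sum(), b.sum()
        if sa == 0 or sb == 0:
            raise UndefinedHistogramError("cannot compare an all-zero histogram")
        bc = np.sum(np.sqrt((a / sa) * (b / sb)))
        dists.append(np.sqrt(max(0.0, 1.0 - bc)))
    return float(1.0 - np.mean(dists))


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    v1 = np.asarray(v1, dtype=np.float64).ravel()
    v2 = np.asarray(v2, dtype=np.float64).ravel()
    if v1.shape != v2.shape:
        raise ParameterError("vectors must have equal length")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ParameterError("cosine similarity undefined for a zero vector")
    return float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))


def radius_similarity(r1: float, r2: float) -> float:
    """Scale-free size agreement: min/max of the two radii."""
    if r1 <= 0 or r2 <= 0:
        raise ParameterError("radii must be positive")
    return float(min(r1, r2) / max(r1, r2))


@dataclass
class FusionWeights:
    """Relative weights of the similarity components (sum to 1)."""

    embedding: float = 0.5
    histogram: float = 0.3
    radius: float = 0.2

    def normalized(self, with_embedding: bool) -> tuple[float, float, float]:
        e = self.embedding if with_embedding else 0.0
        total = e + self.histogram + self.radius
        if total <= 0:
            raise ParameterError("fusion weights must sum to a positive value")
        return e / total, self.histogram / total, self.radius / total


@dataclass
class ScoreMatrix:
    scores: np.ndarray  # n_prev x n_curr, in [0, 1]
    components: dict = field(default_factory=dict)


def fuse_scores(
    signatures_prev: Sequence[PlateSignature],
    signatures_curr: Sequence[PlateSignature],
    weights: Optional[FusionWeights] = None,
) -> ScoreMatrix:
    """Weighted-sum fusion of the similarity components into one matrix.

    Cosine similarity is rescaled from [−1, 1] to [0, 1]. The embedding
    component is skipped (its weight renormalized over the others) when
    either side lacks embeddings.
    """
    weights = weights or FusionWeights()
    n, m = len(signatures_prev), len(signatures_curr)
    have_emb = all(s.embedding is not None for s in signatures_prev) and all(
        s.embedding is not None for s in signatures_curr
    ) and n > 0 and m > 0
    w_emb, w_hist, w_rad = weights.normalized(have_emb)
    scores = np.zeros((n, m))
    comp_hist = np.zeros((n, m))
    comp_rad = np.zeros((n, m))
    comp_emb = np.zeros((n, m))
    for i, sp in enumerate(signatures_prev):
        for j, sc in enumerate(signatures_curr):
            comp_hist[i, j] = histogram_similarity(sp.histograms, sc.histograms)
            comp_rad[i, j] = radius_similarity(sp.radius, sc.radius)
            if have_emb:
                comp_emb[i, j] = (cosine_similarity(sp.embedding, sc.embedding) + 1) / 2
            scores[i, j] = (
                w_emb * comp_emb[i, j]
                + w_hist * comp_hist[i, j]
                + w_rad * comp_rad[i, j]
            )
    return ScoreMatrix(
        np.clip(scores, 0.0, 1.0),
        components={"histogram": comp_hist, "radius": comp_rad, "embedding": comp_emb},
    )


def hungarian_match(
    scores: ScoreMatrix | np.ndarray, min_score: float = 0.3
) -> list[tuple[int, Optional[int]]]:
    """Maximum-total-score one-to-one assignment.

    Returns one (prev_index, curr_index-or-None) pair per previous item;
    assignments scoring below ``min_score`` and surplus items of a
    rectangular problem are left unmatched (None).
    """
    mat = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    if mat.size == 0:
        return [(i, None) for i in range(mat.shape[0])]
    if not np.all(np.isfinite(mat)):
        raise ParameterError("score matrix must be finite")
    rows, cols = linear_sum_assignment(mat, maximize=True)
    assigned = {int(r): int(c) for r, c in zip(rows, cols) if mat[r, c] >= min_score}
    return [(i, assigned.get(i)) for i in range(mat.shape[0])]
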