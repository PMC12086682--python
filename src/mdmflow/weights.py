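"""Cell-specific modality weights.

Cell differentiation is modelled as movement in the latent feature space
of each modality: an expanding neighborhood signals an active
developmental process. Each modality m is scored per cell c as

    s_c^m = sum over l != m of median( ECDF^m( d_c^{m,l} ) )

where d_c^{m,l} are distances, measured in modality-m space, from cell c
to its nearest neighbors found in modality l, and ECDF^m rank-normalizes
distances against the global distance distribution of modality m
(estimated from P uniformly sampled cell pairs). Scores are smoothed
over the neighborhood of the highest-scoring modality and passed through
a softmax with temperature ``alpha`` to yield per-cell weights that sum
to 1 across modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "DistanceECDF",
    "ModalityNeighborhood",
    "WeightMatrix",
    "build_neighborhoods",
    "estimate_ecdf",
    "score_modalities",
    "smooth_scores",
    "softmax_weights",
    "compute_weights",
]


class ConfigurationError(ValueError):
    """An argument combination the method does not define."""


class InsufficientDataError(ValueError):
    """Too few cells for the requested operation."""


@dataclass
class ModalityNeighborhood:
    """k nearest neighbors of every cell inside one modality's space.

    ``nn_indices`` is C x k (self excluded), ``nn_distances`` matches, with
    distances nondecreasing along each row.
    """

    nn_indices: np.ndarray
    nn_distances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.nn_indices = np.asarray(self.nn_indices, dtype=int)
        self.nn_distances = np.asarray(self.nn_distances, dtype=float)
        if self.nn_indices.shape != self.nn_distances.shape:
            raise ValueError("index and distance arrays must share a shape")
        C = self.nn_indices.shape[0]
        if self.nn_indices.size:
            if self.nn_indices.min() < 0 or self.nn_indices.max() >= C:
                raise ValueError("neighbor indices out of range")
            own = np.arange(C)[:, None]
            if np.any(self.nn_indices == own):
                raise ValueError("a cell may not be its own neighbor")
            if np.any(self.nn_distances < 0):
                raise ValueError("distances must be nonnegative")
            if np.any(np.diff(self.nn_distances, axis=1) < 0):
                raise ValueError("distances must be nondecreasing per row")


@dataclass
class DistanceECDF:
    """Empirical CDF of pairwise distances within one modality.

    Built from P uniformly sampled distinct cell pairs; evaluation at x
    returns the fraction of sampled distances <= x (a nondecreasing,
    right-continuous step function into [0, 1]).
    """

    sorted_sample: np.ndarray

    def __post_init__(self) -> None:
        self.sorted_sample = np.sort(np.asarray(self.sorted_sample, dtype=float).ravel())

    @property
    def n_pairs(self) -> int:
        return self.sorted_sample.size

    def __call__(self, x) -> np.ndarray:
        pos = np.searchsorted(self.sorted_sample, x, side="right")
        return pos / self.n_pairs


@dataclass
class WeightMatrix:
    """C x M cell-specific modality weights; every row sums to 1."""

    w: np.ndarray
    alpha: float = 10.0
    smoothing_k: Optional[int] = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2:
            raise ValueError("weights must be a C x M matrix")
        if np.any(self.w < -1e-12) or np.any(self.w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        rowsums = self.w.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("weight rows must sum to 1 within 1e-9")

    @property
    def n_cells(self) -> int:
        return self.w.shape[0]

    @property
    def n_modalities(self) -> int:
        return self.w.shape[1]


def _knn_exclude_self(embedding: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact Euclidean kNN excluding each query cell itself.

    Robust to duplicate points: the query's own index is dropped wherever
    it lands in the candidate list, not assumed first.
    """
    C = embedding.shape[0]
    if k >= C:
        raise ConfigurationError(f"k={k} requires at least {k + 1} cells, got {C}")
    nn = NearestNeighbors(n_neighbors=min(k + 1, C), algorithm="auto")
    nn.fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    out_idx = np.empty((C, k), dtype=int)
    out_dist = np.empty((C, k), dtype=float)
    for c in range(C):
        mask = idx[c] != c
        if mask.sum() == idx.shape[1]:  # self not returned (duplicates); drop last
            mask[-1] = False
        out_idx[c] = idx[c][mask][:k]
        out_dist[c] = dist[c][mask][:k]
    return out_idx, out_dist


def build_neighborhoods(
    embeddings: Sequence[np.ndarray], k: int
) -> list[ModalityNeighborhood]:
    """Per-modality exact k-nearest-neighbor search (self excluded)."""
    neighborhoods = []
    for emb in embeddings:
        idx, dist = _knn_exclude_self(np.asarray(emb, dtype=float), k)
        neighborhoods.append(ModalityNeighborhood(idx, dist, k))
    return neighborhoods


def estimate_ecdf(embedding: np.ndarray, P: int = 1000, seed: int = 0) -> DistanceECDF:
    """Estimate the modality's pairwise-distance ECDF from P sampled pairs.

    Pairs are uniform over distinct ordered pairs (no self-pairing), drawn
    with replacement across pairs.
    """
    embedding = np.asarray(embedding, dtype=float)
    C = embedding.shape[0]
    if C < 2:
        raise InsufficientDataError("ECDF estimation needs at least 2 cells")
    if P < 1:
        raise ConfigurationError("P must be >= 1")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, C, size=P)
    j = (i + rng.integers(1, C, size=P)) % C
    dists = np.linalg.norm(embedding[i] - embedding[j], axis=1)
    return DistanceECDF(dists)


def score_modalities(
    embeddings: Sequence[np.ndarray],
    neighborhoods: Sequence[ModalityNeighborhood],
    ecdfs: Sequence[DistanceECDF],
) -> np.ndarray:
    """Raw per-cell modality scores (C x M).

    The score of modality m sums, over every other modality l, the median
    ECDF^m-scaled distance from each cell to its modality-l neighbors
    measured in modality-m space. Cross-modality terms only: l == m never
    enters the sum.
    """
    M = len(embeddings)
    if M < 2:
        raise ConfigurationError("modality scoring needs at least 2 modalities")
    if not (len(neighborhoods) == len(ecdfs) == M):
        raise ValueError("one neighborhood and one ECDF per modality required")
    embeddings = [np.asarray(e, dtype=float) for e in embeddings]
    C = embeddings[0].shape[0]
    scores = np.zeros((C, M))
    for m in range(M):
        emb_m = embeddings[m]
        for l in range(M):
            if l == m:
                continue
            nbr = neighborhoods[l].nn_indices  # C x k, found in modality l
            # distances measured in modality-m space
            diff = emb_m[nbr] - emb_m[:, None, :]
            d = np.linalg.norm(diff, axis=2)
            scores[:, m] += np.median(ecdfs[m](d), axis=1)
    return scores


def smooth_scores(
    scores: np.ndarray,
    neighborhoods: Sequence[ModalityNeighborhood],
    smoothing_k: Optional[int] = None,
) -> np.ndarray:
    """Average each cell's score row over its neighborhood in the
    highest-scoring modality.

    The average runs over the cell itself plus its ``smoothing_k`` nearest
    neighbors from modality argmax_m s_c^m (ties toward the lower modality
    index). Self-inclusion keeps isolated cells stable.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    C, M = scores.shape
    k = neighborhoods[0].k if smoothing_k is None else smoothing_k
    best = np.argmax(scores, axis=1)  # argmax breaks ties toward lower index
    smoothed = np.empty_like(scores)
    for m in range(M):
        cells = np.nonzero(best == m)[0]
        if cells.size == 0:
            continue
        nbr = neighborhoods[m].nn_indices[cells, :k]
        pooled = np.concatenate([cells[:, None], nbr], axis=1)  # self + neighbors
        smoothed[cells] = scores[pooled].mean(axis=1)
    return smoothed


def softmax_weights(scores: np.ndarray, alpha: float = 10.0) -> WeightMatrix:
    """Normalize score rows with a temperature-``alpha`` softmax (Eq. with
    max-subtraction for numerical stability); rows sum to 1."""
    if alpha < 1:
        raise ConfigurationError("alpha must be >= 1")
    scores = np.asarray(scores, dtype=float)
    z = alpha * scores
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    w = e / e.sum(axis=1, keepdims=True)
    return WeightMatrix(w, alpha=alpha)


def compute_weights(
    embeddings: Sequence[np.ndarray],
    k: int = 20,
    P: int = 1000,
    alpha: float = 10.0,
    seed: int = 0,
    smoothing_k: Optional[int] = None,
) -> WeightMatrix:
    """End-to-end multimodal weight pipeline.

    ECDF estimation -> cross-modality scoring -> neighborhood smoothing ->
    softmax normalization. Deterministic for a fixed seed. The same seed
    drives pair sampling in every modality, so byte-identical modalities
    receive identical scores (and hence equal weights).
    """
    embeddings = [np.asarray(e, dtype=float) for e in embeddings]
    neighborhoods = build_neighborhoods(embeddings, k)
    ecdfs = [estimate_ecdf(emb, P=P, seed=seed) for emb in embeddings]
    scores = score_modalities(embeddings, neighborhoods, ecdfs)
    scores = smooth_scores(scores, neighborhoods, smoothing_k=smoothing_k)
    wm = softmax_weights(scores, alpha=alpha)
    wm.smoothing_k = k if smoothing_k is None else smoothing_k
    return wm
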