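"""Embedding-quality and imputation benchmarks.

Scorers are pure functions over an embedding plus externally supplied
inputs (signature activities, velocity directions, transition
probabilities, absorption probabilities); none of those quantities are
computed here.

* cohesiveness — do highly signature-active cells sit in active,
  connected embedding regions? Per connected component G of an
  eps-connectivity graph over the top-activity cells,
  Psi_G = exp(-sum_c psi_c) with psi_c the mean activity over a cell's
  nearest neighbors; the total score is Phi = -log sum_G Psi_G, which
  penalizes fragmented components. Higher is better.
* vector-field alignment — median cosine similarity between each cell's
  projected developmental direction and vectors toward its
  highest-transition-probability targets.
* terminal-state separation — how strongly each terminal state's
  absorption probabilities dominate the embedding neighborhood of its
  own location relative to other terminal states' neighborhoods.
* cell-type correlation score and count downsampling for imputation
  robustness experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .datamodel import DimensionError, TransitionMatrix
from .mdm import MDMEmbedding
from .weights import InsufficientDataError

__all__ = [
    "CohesivenessResult",
    "cohesiveness_score",
    "vector_field_score",
    "terminal_separation_score",
    "mse",
    "celltype_correlation_score",
    "downsample_counts",
    "knn_label_purity",
]


def _coords(embedding) -> np.ndarray:
    return embedding.coords if isinstance(embedding, MDMEmbedding) else np.asarray(embedding, float)


@dataclass
class CohesivenessResult:
    component_scores: list[float]  # Psi_G per connected component
    total: float  # Phi
    n_components: int
    selected_cells: np.ndarray
    eps: float


def _median_pair_distance(X: np.ndarray, n_pairs: int = 1000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    C = X.shape[0]
    i = rng.integers(0, C, size=n_pairs)
    j = (i + rng.integers(1, C, size=n_pairs)) % C
    return float(np.median(np.linalg.norm(X[i] - X[j], axis=1)))


def cohesiveness_score(
    embedding,
    activity: np.ndarray,
    top_fraction: float = 0.05,
    n_psi: int = 3,
    eps: Optional[float] = None,
    seed: int = 0,
) -> CohesivenessResult:
    """Signature-cohesiveness score Phi of an embedding.

    The ``top_fraction`` most signature-active cells are selected; each
    selected cell's psi_c is the mean activity over its ``n_psi`` nearest
    embedding neighbors (searched among all cells). Components come from
    eps-connectivity (DBSCAN with min_samples=1, so every selected cell
    belongs to a component); ``eps`` defaults to the embedding's median
    cell-cell distance estimated from 1000 random pairs.
    """
    X = _coords(embedding)
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] != X.shape[0]:
        raise DimensionError("one activity value per cell required")
    if not np.all(np.isfinite(activity)):
        raise ValueError("activities must be finite")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    C = X.shape[0]
    n_top = max(int(round(top_fraction * C)), 1)
    selected = np.argsort(-activity, kind="stable")[:n_top]
    if selected.size < 2:
        raise InsufficientDataError("need at least 2 selected cells")
    if eps is None:
        eps = _median_pair_distance(X, seed=seed)
    nn = NearestNeighbors(n_neighbors=min(n_psi + 1, C)).fit(X)
    _, idx = nn.kneighbors(X[selected])
    psi = np.empty(selected.size)
    for row, c in enumerate(selected):
        nbr = idx[row][idx[row] != c][:n_psi]
        psi[row] = activity[nbr].mean()
    labels = DBSCAN(eps=eps, min_samples=1).fit_predict(X[selected])
    components = []
    for lab in np.unique(labels):
        components.append(float(np.exp(-psi[labels == lab].sum())))
    phi = -float(np.log(sum(components)))
    return CohesivenessResult(components, phi, len(components), selected, float(eps))


def vector_field_score(
    embedding,
    directions: np.ndarray,
    transitions: TransitionMatrix,
    n_top: int = 3,
) -> tuple[np.ndarray, float]:
    """Alignment between an embedding and a projected velocity vector field.

    Each cell with at least one positive transition is scored as the
    median cosine similarity between its projected direction and the
    vectors toward its ``n_top`` highest-probability transition targets.
    Returns per-cell scores (NaN for unscored cells) and the embedding
    score, the median over scored cells.
    """
    X = _coords(embedding)
    directions = np.asarray(directions, dtype=float)
    if directions.shape != X.shape:
        raise DimensionError("directions must match the embedding shape")
    if transitions.n_cells != X.shape[0]:
        raise DimensionError("transitions not aligned to the embedding")
    P = transitions.probs
    scores = np.full(X.shape[0], np.nan)
    for c in range(X.shape[0]):
        row = P.getrow(c)
        if row.nnz == 0:
            continue
        v = directions[c]
        norm_v = np.linalg.norm(v)
        if norm_v == 0:
            warnings.warn(
                f"cell {c} has a zero direction vector; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        targets = row.indices[np.lexsort((row.indices, -row.data))][:n_top]
        sims = []
        for t in targets:
            u = X[t] - X[c]
            norm_u = np.linalg.norm(u)
            if norm_u == 0:
                continue
            sims.append(float(v @ u / (norm_v * norm_u)))
        if sims:
            scores[c] = float(np.median(sims))
    scored = scores[~np.isnan(scores)]
    overall = float(np.median(scored)) if scored.size else float("nan")
    return scores, overall


def terminal_separation_score(
    embedding,
    absorption: np.ndarray,
    n: Union[int, Sequence[int]],
    location_fraction: float = 0.01,
) -> dict:
    """Net absorption of each terminal state in the embedding.

    A terminal state's location is the mean coordinate of the
    ``location_fraction`` of cells with its highest absorption
    probabilities. ap(n, t1, t2) is the mean absorption probability
    toward t1 over the n embedding-nearest neighbors of t2's location;
    the score of terminal t at neighborhood size n is

        score(n, t) = ap(n, t, t) - sum over t0 != t of ap(n, t, t0).

    ``absorption`` is C x |T|; returns ``{n: {terminal_index: score}}``.
    """
    X = _coords(embedding)
    A = np.asarray(absorption, dtype=float)
    if A.ndim != 2 or A.shape[0] != X.shape[0]:
        raise DimensionError("absorption must be C x n_terminal")
    if A.shape[1] < 2:
        raise ValueError("need at least 2 terminal states")
    if np.any(A < -1e-12) or np.any(A > 1 + 1e-12):
        raise ValueError("absorption probabilities must lie in [0, 1]")
    C, T = A.shape
    ns = [int(n)] if np.isscalar(n) else [int(v) for v in n]
    if max(ns) >= C:
        raise ValueError("neighborhood size must be below the cell count")
    n_loc = max(int(round(location_fraction * C)), 1)
    locations = np.empty((T, X.shape[1]))
    for t in range(T):
        top = np.argsort(-A[:, t], kind="stable")[:n_loc]
        locations[t] = X[top].mean(axis=0)
    if len(np.unique(locations.round(12), axis=0)) < T:
        warnings.warn(
            "identical terminal-state locations; scores still computed",
            RuntimeWarning,
            stacklevel=2,
        )
    nn = NearestNeighbors(n_neighbors=max(ns)).fit(X)
    _, idx = nn.kneighbors(locations)  # T x max(n); neighbors of each location
    result: dict[int, dict[int, float]] = {}
    for size in ns:
        per_terminal = {}
        for t in range(T):
            ap_tt = A[idx[t, :size], t].mean()
            penalty = sum(A[idx[t0, :size], t].mean() for t0 in range(T) if t0 != t)
            per_terminal[t] = float(ap_tt - penalty)
        result[size] = per_terminal
    return result


def mse(x, y) -> float:
    """Mean squared difference between two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DimensionError(f"length mismatch: {x.size} vs {y.size}")
    return float(np.mean((x - y) ** 2))


def celltype_correlation_score(correlations: np.ndarray, labels: Sequence) -> float:
    """Mean same-type minus mean different-type cell-cell correlation.

    Diagonal entries are excluded. Label classes of size 1 contribute no
    same-type pairs and are excluded from the same-type mean with a
    warning.
    """
    R = np.asarray(correlations, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DimensionError("correlation matrix must be square")
    labels = np.asarray(labels)
    if labels.size != R.shape[0]:
        raise DimensionError("one label per cell required")
    singletons = [lab for lab in np.unique(labels) if (labels == lab).sum() == 1]
    if singletons:
        warnings.warn(
            f"label classes with a single cell contribute no same-type pairs: {singletons}",
            RuntimeWarning,
            stacklevel=2,
        )
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(labels.size, dtype=bool)
    return float(R[same & off].mean() - R[~same].mean())


def downsample_counts(counts, p: float, seed: int = 0):
    """Remove exactly round(p * total) individual count units uniformly at
    random (multivariate hypergeometric thinning); entries stay >= 0."""
    if not 0 <= p < 1:
        raise ValueError("p must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sparse = sp.issparse(counts)
    if sparse:
        mat = counts.tocsr(copy=True)
        data = mat.data
    else:
        mat = np.array(counts)
        data = mat.ravel()
    if np.any(data < 0) or np.any(data != np.round(data)):
        raise ValueError("count downsampling requires nonnegative integer counts")
    total = int(data.sum())
    n_remove = int(round(p * total))
    if n_remove:
        removed = rng.multivariate_hypergeometric(
            data.astype(np.int64), n_remove, method="marginals"
        )
        data = data - removed
    if sparse:
        mat.data = data
        mat.eliminate_zeros()
        return mat
    return data.reshape(mat.shape)


def knn_label_purity(coords: np.ndarray, labels: Sequence, k: int = 20) -> float:
    """Fraction of cells whose majority label among their k nearest
    neighbors (self excluded, ties toward the lexicographically smaller
    label) matches their own label."""
    X = _coords(coords)
    labels = np.asarray(labels)
    codes, inv = np.unique(labels, return_inverse=True)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    correct = 0
    for c in range(X.shape[0]):
        nbr = idx[c][idx[c] != c][:k]
        votes = np.bincount(inv[nbr], minlength=codes.size)
        correct += int(np.argmax(votes) == inv[c])
    return correct / X.shape[0]
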