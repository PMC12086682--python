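"""Multimodal diffusion maps (MDM).

Per modality, cell-cell affinities come from a density-adjusted symmetric
Gaussian kernel

    kappa(c1, c2) = exp( -d(c1, c2)^2 / (eps_c1 * eps_c2) )

with eps_c the distance from cell c to its N-th nearest neighbor (local
bandwidth). Affinities are weighted per cell pair by the mean of the two
cells' modality weights, row-normalized per modality, summed into the
multimodal Markov chain K, and symmetrized as

    K_hat = D K + (D K)^T

with D the row-normalizer of K. The embedding is built from the top
eigenpairs of K_hat: coordinate i is the (i+1)-th eigenvector scaled by
its eigenvalue; the first eigenpair (largest eigenvalue) is dropped as
non-informative. E extra eigenpairs are computed and discarded to guard
against eigenvector degradation at small eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .weights import ConfigurationError, WeightMatrix, _knn_exclude_self, compute_weights

__all__ = [
    "KernelParams",
    "MultimodalChain",
    "EigenSystem",
    "MDMEmbedding",
    "gaussian_kernel",
    "build_chain",
    "eigendecompose",
    "embed",
    "run_mdm",
]

# below this size the dense symmetric eigensolver is faster and exact
_DENSE_FALLBACK_CELLS = 500


@dataclass
class KernelParams:
    """Bandwidth and sparsity parameters of the Gaussian affinity kernel.

    ``n_kernel_neighbor`` is the index N of the neighbor whose distance
    sets the local bandwidth eps_c (default 20). ``n_graph_neighbors`` is
    the number of neighbors kept per cell in the sparse affinity graph;
    it defaults to ``n_kernel_neighbor`` and must be at least as large.
    """

    n_kernel_neighbor: int = 20
    n_graph_neighbors: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_graph_neighbors is None:
            self.n_graph_neighbors = self.n_kernel_neighbor
        if self.n_kernel_neighbor < 1 or self.n_graph_neighbors < 1:
            raise ConfigurationError("neighbor counts must be >= 1")
        if self.n_kernel_neighbor > self.n_graph_neighbors:
            raise ConfigurationError(
                "n_kernel_neighbor cannot exceed n_graph_neighbors"
            )


@dataclass
class MultimodalChain:
    """Per-modality affinities K^m, combined chain K, symmetrized K_hat."""

    per_modality_K: list
    combined_K: sp.spmatrix
    symmetric_K: sp.spmatrix

    @property
    def n_cells(self) -> int:
        return self.combined_K.shape[0]


@dataclass
class EigenSystem:
    """Retained eigenpairs of K_hat, sorted by decreasing eigenvalue.

    Eigenvectors are unit-norm columns with a deterministic sign
    convention (the largest-magnitude entry is positive).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_components: int
    n_extra: int

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.eigenvectors.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvector column per eigenvalue required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted in decreasing order")


@dataclass
class MDMEmbedding:
    """C x N eigenvalue-scaled eigenvector embedding (first pair skipped)."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def gaussian_kernel(embedding: np.ndarray, params: KernelParams) -> sp.csr_matrix:
    """Sparse symmetric density-adjusted Gaussian affinity matrix.

    Each cell contributes affinities to its ``n_graph_neighbors`` nearest
    neighbors; the graph is symmetrized by union (an edge present one way
    gets the same kappa both ways). Self-affinities are excluded.
    Duplicate cells can give eps_c = 0; the bandwidth is then floored at a
    machine-epsilon-scaled positive value with a warning.
    """
    embedding = np.asarray(embedding, dtype=float)
    C = embedding.shape[0]
    if C <= params.n_kernel_neighbor:
        raise ConfigurationError(
            f"need more than n_kernel_neighbor={params.n_kernel_neighbor} cells, got {C}"
        )
    k = min(params.n_graph_neighbors, C - 1)
    idx, dist = _knn_exclude_self(embedding, k)
    eps = dist[:, params.n_kernel_neighbor - 1].copy()
    if np.any(eps <= 0):
        warnings.warn(
            "zero kernel bandwidth (duplicate cells); flooring eps",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = max(dist.max(), 1.0)
        eps = np.maximum(eps, np.finfo(float).eps * scale)
    rows = np.repeat(np.arange(C), k)
    cols = idx.ravel()
    kappa = np.exp(-(dist.ravel() ** 2) / (eps[rows] * eps[cols]))
    K = sp.coo_matrix((kappa, (rows, cols)), shape=(C, C)).tocsr()
    # union symmetrization: kappa is symmetric in (c1, c2), so taking the
    # elementwise maximum of K and K^T assigns the same value both ways
    K = K.maximum(K.T)
    K.eliminate_zeros()
    return K


def _row_normalize(K: sp.spmatrix) -> sp.csr_matrix:
    """Left-multiply by the diagonal inverse row-sum matrix; all-zero rows
    stay zero."""
    K = K.tocsr()
    rowsum = np.asarray(K.sum(axis=1)).ravel()
    inv = np.zeros_like(rowsum)
    nz = rowsum > 0
    inv[nz] = 1.0 / rowsum[nz]
    return sp.diags(inv) @ K


def build_chain(
    affinities: Sequence[sp.spmatrix], weights: WeightMatrix
) -> MultimodalChain:
    """Merge per-modality affinity kernels into the multimodal chain.

    K^m(c1, c2) = ((w_c1^m + w_c2^m) / 2) * kappa^m(c1, c2), symmetric by
    construction; K = sum_m D^m K^m with D^m the per-modality row
    normalizer; K_hat = D K + (D K)^T with D the row normalizer of K.
    """
    affinities = [a.tocsr() for a in affinities]
    C = affinities[0].shape[0]
    M = len(affinities)
    if weights.w.shape != (C, M):
        raise ValueError(
            f"weights shape {weights.w.shape} does not match {M} affinity "
            f"matrices of {C} cells"
        )
    per_modality = []
    combined = sp.csr_matrix((C, C))
    for m, kappa in enumerate(affinities):
        if kappa.shape != (C, C):
            raise ValueError("all affinity matrices must be C x C")
        W = sp.diags(weights.w[:, m])
        Km = 0.5 * (W @ kappa + kappa @ W)  # pairwise mean weight times kappa
        per_modality.append(Km.tocsr())
        combined = combined + _row_normalize(Km)
    isolated = np.asarray(combined.sum(axis=1)).ravel() == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated cell(s) with zero affinity in every "
            "modality; their chain rows stay zero",
            RuntimeWarning,
            stacklevel=2,
        )
    DK = _row_normalize(combined)
    K_hat = (DK + DK.T).tocsr()
    return MultimodalChain(per_modality, combined.tocsr(), K_hat)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the largest-|entry| coordinate is positive
    (ties resolved by the lowest index, as argmax does)."""
    vectors = vectors.copy()
    lead = np.abs(vectors).argmax(axis=0)
    flip = vectors[lead, np.arange(vectors.shape[1])] < 0
    vectors[:, flip] *= -1
    return vectors


def eigendecompose(
    chain: MultimodalChain | sp.spmatrix,
    n_components: int = 10,
    n_extra: int = 10,
    method: str = "auto",
) -> EigenSystem:
    """Top (N + E + 1) eigenpairs of the symmetric operator K_hat.

    Eigenvalues are sorted by decreasing algebraic value (negative
    eigenvalues, if any, sort last and are not retained when
    N + E + 1 << C). Dense symmetric decomposition is used for small
    problems; ARPACK (scipy eigsh) otherwise, with a fixed starting
    vector for reproducibility.
    """
    K_hat = chain.symmetric_K if isinstance(chain, MultimodalChain) else chain.tocsr()
    C = K_hat.shape[0]
    n_keep = n_components + n_extra + 1
    if n_keep > C - 1:
        raise ConfigurationError(
            f"n_components + n_extra + 1 = {n_keep} must be <= C - 1 = {C - 1}"
        )
    if method not in ("auto", "dense", "sparse"):
        raise ConfigurationError(f"unknown eigensolver method {method!r}")
    use_dense = method == "dense" or (method == "auto" and C <= _DENSE_FALLBACK_CELLS)
    if use_dense:
        dense = np.asarray(K_hat.todense())
        vals, vecs = scipy.linalg.eigh(dense)
        order = np.argsort(vals)[::-1][:n_keep]
        vals, vecs = vals[order], vecs[:, order]
    else:
        v0 = np.full(C, 1.0 / np.sqrt(C))
        try:
            vals, vecs = scipy.sparse.linalg.eigsh(K_hat, k=n_keep, which="LA", v0=v0)
        except scipy.sparse.linalg.ArpackNoConvergence as exc:
            raise RuntimeError(
                "sparse eigensolver did not converge; retry with a dense "
                "decomposition (scipy.linalg.eigh on chain.symmetric_K.todense())"
            ) from exc
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    vecs = _fix_signs(vecs)
    return EigenSystem(vals, vecs, n_components=n_components, n_extra=n_extra)


def embed(eig: EigenSystem, n_components: Optional[int] = None) -> MDMEmbedding:
    """Eigenvalue-scaled eigenvector embedding, skipping the first pair."""
    N = eig.n_components if n_components is None else n_components
    if eig.eigenvalues.size < N + 1:
        raise ValueError(
            f"need {N + 1} eigenpairs for an {N}-dimensional embedding, "
            f"have {eig.eigenvalues.size}"
        )
    coords = eig.eigenvectors[:, 1 : N + 1] * eig.eigenvalues[1 : N + 1]
    return MDMEmbedding(coords)


def run_mdm(
    embeddings: Sequence[np.ndarray],
    weights: Optional[WeightMatrix] = None,
    n_components: int = 10,
    n_kernel_neighbor: int = 20,
    n_graph_neighbors: Optional[int] = None,
    n_extra: int = 10,
    weight_k: int = 20,
    P: int = 1000,
    alpha: float = 10.0,
    seed: int = 0,
) -> tuple[MDMEmbedding, EigenSystem, MultimodalChain, WeightMatrix]:
    """Full MDM pipeline: weights -> kernels -> chain -> eigenbasis -> embedding.

    If ``weights`` is omitted they are computed from the embeddings
    (unit weights for a single modality, in which case the method reduces
    to classical diffusion maps). Deterministic for a fixed seed.
    """
    embeddings = [np.asarray(e, dtype=float) for e in embeddings]
    C = embeddings[0].shape[0]
    M = len(embeddings)
    if weights is None:
        if M == 1:
            weights = WeightMatrix(np.ones((C, 1)))
        else:
            weights = compute_weights(
                embeddings, k=weight_k, P=P, alpha=alpha, seed=seed
            )
    if n_graph_neighbors is None:
        n_graph_neighbors = max(weight_k, n_kernel_neighbor)
    params = KernelParams(n_kernel_neighbor, n_graph_neighbors)
    affinities = [gaussian_kernel(e, params) for e in embeddings]
    chain = build_chain(affinities, weights)
    eig = eigendecompose(chain, n_components=n_components, n_extra=n_extra)
    return embed(eig), eig, chain, weights
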