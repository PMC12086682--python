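"""Independent brute-force reference implementations used only by tests.

Everything here is dense, loop-based, and deliberately naive so it can
serve as an oracle for the production (sparse, vectorized) code paths.
"""

from __future__ import annotations

import numpy as np


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    C = X.shape[0]
    D = np.zeros((C, C))
    for i in range(C):
        for j in range(C):
            D[i, j] = np.linalg.norm(X[i] - X[j])
    return D


def dense_kernel(X: np.ndarray, n_kernel_neighbor: int, n_graph_neighbors: int) -> np.ndarray:
    """Brute-force density-adjusted Gaussian kernel on a kNN graph with
    union symmetrization."""
    C = X.shape[0]
    D = pairwise_distances(X)
    eps = np.zeros(C)
    adj = np.zeros((C, C), dtype=bool)
    for i in range(C):
        order = [j for j in np.argsort(D[i], kind="stable") if j != i]
        eps[i] = D[i, order[n_kernel_neighbor - 1]]
        for j in order[:n_graph_neighbors]:
            adj[i, j] = True
    adj = adj | adj.T
    K = np.zeros((C, C))
    for i in range(C):
        for j in range(C):
            if adj[i, j]:
                K[i, j] = np.exp(-D[i, j] ** 2 / (eps[i] * eps[j]))
    return K


def row_normalize(K: np.ndarray) -> np.ndarray:
    out = np.zeros_like(K)
    for i in range(K.shape[0]):
        s = K[i].sum()
        if s > 0:
            out[i] = K[i] / s
    return out


def dense_chain(kernels: list[np.ndarray], w: np.ndarray) -> np.ndarray:
    """K^m -> weighted -> row-normalized -> summed -> symmetrized K_hat."""
    C = kernels[0].shape[0]
    K = np.zeros((C, C))
    for m, kappa in enumerate(kernels):
        Km = np.zeros((C, C))
        for i in range(C):
            for j in range(C):
                Km[i, j] = 0.5 * (w[i, m] + w[j, m]) * kappa[i, j]
        K += row_normalize(Km)
    DK = row_normalize(K)
    return DK + DK.T


def fix_signs(vecs: np.ndarray) -> np.ndarray:
    vecs = vecs.copy()
    for i in range(vecs.shape[1]):
        lead = np.abs(vecs[:, i]).argmax()
        if vecs[lead, i] < 0:
            vecs[:, i] *= -1
    return vecs


def dense_mdm(
    embeddings: list[np.ndarray],
    w: np.ndarray,
    n_kernel_neighbor: int,
    n_graph_neighbors: int,
    n_components: int,
    n_extra: int,
):
    """Full dense evaluation of the MDM pipeline: kernel, chain,
    eigendecomposition, eigenvalue-scaled embedding skipping the first pair.

    Returns (eigenvalues, eigenvectors, coords) for the top
    n_components + n_extra + 1 pairs.
    """
    kernels = [dense_kernel(X, n_kernel_neighbor, n_graph_neighbors) for X in embeddings]
    K_hat = dense_chain(kernels, w)
    vals, vecs = np.linalg.eigh(K_hat)
    order = np.argsort(vals)[::-1][: n_components + n_extra + 1]
    vals, vecs = vals[order], fix_signs(vecs[:, order])
    coords = vecs[:, 1 : n_components + 1] * vals[1 : n_components + 1]
    return vals, vecs, coords


def exhaustive_ecdf(X: np.ndarray):
    """ECDF over all distinct pairwise distances (the infinite-sample limit
    of pair sampling)."""
    C = X.shape[0]
    dists = [np.linalg.norm(X[i] - X[j]) for i in range(C) for j in range(C) if i != j]
    dists = np.sort(dists)

    def ecdf(x):
        return np.searchsorted(dists, x, side="right") / len(dists)

    return ecdf


def score_eq1(embeddings, nn_indices, ecdfs) -> np.ndarray:
    """Loop evaluation of the modality score: for each cell and modality m,
    sum over l != m of the median ECDF^m-scaled distance to the
    modality-l neighbors measured in modality-m space."""
    M = len(embeddings)
    C = embeddings[0].shape[0]
    s = np.zeros((C, M))
    for c in range(C):
        for m in range(M):
            for l in range(M):
                if l == m:
                    continue
                d = [np.linalg.norm(embeddings[m][c] - embeddings[m][j]) for j in nn_indices[l][c]]
                s[c, m] += np.median([ecdfs[m](x) for x in d])
    return s
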