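"""Eigenbasis diffusion imputation and indicator-based subtrajectory expansion.

t-step diffusion imputation applies the symmetric multimodal operator
K_hat to a feature matrix G: G_imputed = K_hat^t G. Because K_hat is
symmetric with orthonormal eigenvectors Q and eigenvalues Lambda,

    K_hat^t G = Q Lambda^t Q^T G,

so only the eigenvalue vector is powered and the cost is independent of
t. In practice a truncated basis (the embedding's retained eigenpairs,
including the first) approximates the full operator; truncation can
produce small negative imputed values, which are kept unless clipping is
requested.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .mdm import EigenSystem
from .weights import ConfigurationError

__all__ = ["impute", "diffuse_indicator"]


def impute(
    basis: EigenSystem,
    G,
    t: int,
    clip_nonnegative: bool = False,
) -> np.ndarray:
    """Diffuse a cell-by-feature matrix t steps in the retained eigenbasis.

    Returns ``Q Lambda^t Q^T G``; ``t = 0`` yields the plain projection
    ``Q Q^T G`` onto the basis. Only ``Lambda`` is powered, so runtime
    does not grow with t.
    """
    if t < 0:
        raise ConfigurationError("t must be a nonnegative integer")
    G = np.asarray(G.todense() if sp.issparse(G) else G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    Q = basis.eigenvectors
    if G.shape[0] != Q.shape[0]:
        raise ValueError(
            f"G has {G.shape[0]} rows but the basis spans {Q.shape[0]} cells"
        )
    lam_t = basis.eigenvalues**t
    imputed = Q @ (lam_t[:, None] * (Q.T @ G))
    if clip_nonnegative:
        imputed = np.maximum(imputed, 0.0)
    return imputed


def diffuse_indicator(
    basis: EigenSystem,
    seed_cells: Sequence[int],
    t: int,
    threshold: Optional[float] = None,
) -> np.ndarray:
    """Expand a seed cell set along the multimodal affinity structure.

    A 0/1 indicator over cells is diffused ``t`` steps via :func:`impute`;
    cells whose diffused value exceeds ``threshold`` join the selection,
    and the seed is always retained. With ``threshold=None`` the cutoff is
    the 90th percentile of the non-seed diffused values (strictly
    greater), a conservative default under basis truncation.

    Returns the sorted integer indices of the expanded set.
    """
    seed_cells = np.asarray(list(seed_cells), dtype=int)
    if seed_cells.size == 0:
        raise ConfigurationError("seed cell set must be nonempty")
    C = basis.eigenvectors.shape[0]
    indicator = np.zeros(C)
    indicator[seed_cells] = 1.0
    diffused = impute(basis, indicator, t).ravel()
    # zero out eigenbasis reconstruction noise so a threshold of exactly 0
    # selects only cells genuinely carrying diffused mass
    floor = 1e-10 * np.max(np.abs(diffused))
    diffused[np.abs(diffused) < floor] = 0.0
    non_seed = np.ones(C, dtype=bool)
    non_seed[seed_cells] = False
    if threshold is None:
        threshold = float(np.percentile(diffused[non_seed], 90)) if non_seed.any() else 0.0
    selected = non_seed & (diffused > threshold)
    selected[seed_cells] = True
    return np.nonzero(selected)[0]
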