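"""Core containers shared by every stage of the workflow.

Cell order is the single source of truth: every downstream matrix
(weights, chain, embedding, graphs) indexes cells by their position in
the shared ``cell_ids`` order of a :class:`MultimodalDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class DimensionError(ValueError):
    """Shapes or id lists do not line up."""


class AlignmentError(ValueError):
    """Cell-id alignment across modalities failed."""


def _as_2d(matrix):
    if sp.issparse(matrix):
        return matrix.tocsr()
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


def _check_finite(matrix, name: str) -> None:
    data = matrix.data if sp.issparse(matrix) else matrix
    if np.asarray(data).size and not np.all(np.isfinite(data)):
        raise ValueError(f"{name} contains non-finite entries")


@dataclass
class MultimodalDataset:
    """Ordered collection of cell-by-feature matrices over a shared cell index.

    Parameters
    ----------
    modalities
        One matrix per modality, dense or sparse, each with exactly C rows
        in identical cell order.
    modality_names
        Human-readable modality names, one per matrix.
    cell_ids
        Shared cell identifiers, length C, no duplicates.
    feature_ids
        Per-modality feature identifier lists; lengths must match the
        matrix column counts.
    obs
        Optional per-cell annotations (labels, timestamps, pseudotime)
        indexed by ``cell_ids``.
    is_count
        Per-modality flags marking count matrices; count entries must be
        nonnegative.
    """

    modalities: list
    modality_names: list[str]
    cell_ids: list[str]
    feature_ids: list[list[str]]
    obs: Optional[pd.DataFrame] = None
    is_count: Optional[list[bool]] = None

    def __post_init__(self) -> None:
        if len(self.modalities) < 1:
            raise ValueError("a dataset needs at least one modality")
        self.modalities = [_as_2d(m) for m in self.modalities]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DimensionError("duplicate cell ids")
        C = len(self.cell_ids)
        if len(self.modality_names) != len(self.modalities):
            raise DimensionError("one name per modality required")
        if len(self.feature_ids) != len(self.modalities):
            raise DimensionError("one feature-id list per modality required")
        if self.is_count is None:
            self.is_count = [False] * len(self.modalities)
        for name, mat, fids, count in zip(
            self.modality_names, self.modalities, self.feature_ids, self.is_count
        ):
            if mat.shape[0] != C:
                raise DimensionError(
                    f"modality {name!r} has {mat.shape[0]} rows, expected {C}"
                )
            if mat.shape[1] < 1:
                raise DimensionError(f"modality {name!r} has no features")
            if len(fids) != mat.shape[1]:
                raise DimensionError(
                    f"modality {name!r}: {len(fids)} feature ids for "
                    f"{mat.shape[1]} columns"
                )
            _check_finite(mat, f"modality {name!r}")
            if count:
                data = mat.data if sp.issparse(mat) else mat
                if np.asarray(data).size and np.min(data) < 0:
                    raise ValueError(f"count modality {name!r} has negative entries")
        if self.obs is not None:
            self.obs = self.obs.loc[self.cell_ids]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def dense(self, m: int) -> np.ndarray:
        """Modality ``m`` as a dense float array."""
        mat = self.modalities[m]
        return np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)

    def embeddings(self) -> list[np.ndarray]:
        """All modalities as dense float arrays (the latent embeddings fed
        to the kernel and weighting stages)."""
        return [self.dense(m) for m in range(self.n_modalities)]


@dataclass
class TransitionMatrix:
    """Sparse cell-to-cell developmental transition probabilities.

    Supplied externally — RNA velocity, optimal transport, or lineage
    tracing — and aligned to the dataset's cell order. Rows may be all
    zero for cells without inferred transitions.
    """

    probs: sp.spmatrix
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not sp.issparse(self.probs):
            self.probs = sp.csr_matrix(np.asarray(self.probs, dtype=float))
        self.probs = self.probs.tocsr()
        if self.probs.shape[0] != self.probs.shape[1]:
            raise DimensionError("transition matrix must be square")
        if self.probs.nnz and self.probs.data.min() < 0:
            raise ValueError("transition probabilities must be nonnegative")
        if self.cell_ids and len(self.cell_ids) != self.probs.shape[0]:
            raise DimensionError("cell id count does not match matrix shape")

    @property
    def n_cells(self) -> int:
        return self.probs.shape[0]

    def has_transitions(self) -> np.ndarray:
        """Boolean mask of cells with at least one positive outgoing probability."""
        return np.asarray((self.probs > 0).sum(axis=1)).ravel() > 0
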