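"""Readers and writers for the standard formats the tool touches.

Supported on-disk formats:

* Matrix Market (MTX) coordinate format with companion row/column id
  files (``<stem>.cells.tsv`` and ``<stem>.features.tsv``),
* tab-delimited text (header row = feature ids, first column = cell ids),
* h5ad annotated-matrix containers (cells x features).

The delimited dialect is fixed: tab-separated, UTF-8, header row
required. MTX files are 1-based on disk; matrices are 0-indexed in
memory.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import AlignmentError, DimensionError, MultimodalDataset

_FORMATS = ("mtx", "delimited", "h5ad")


class ParseError(ValueError):
    """A file did not parse under its declared format."""


def _id_file_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if path.endswith(".mtx") else path
    return stem + ".cells.tsv", stem + ".features.tsv"


def _read_id_file(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def read_modality(path: str, format: str):
    """Read one cell-by-feature matrix plus its id lists.

    Returns ``(matrix, cell_ids, feature_ids)``; sparse input stays sparse.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "mtx":
        try:
            matrix = scipy.io.mmread(path).tocsr()
        except Exception as exc:  # noqa: BLE001 - surface the offending file
            raise ParseError(f"malformed MTX file {path}: {exc}") from exc
        cells_path, features_path = _id_file_paths(path)
        cell_ids = _read_id_file(cells_path)
        feature_ids = _read_id_file(features_path)
        if len(cell_ids) != matrix.shape[0]:
            raise DimensionError(
                f"{cells_path}: {len(cell_ids)} ids for {matrix.shape[0]} rows"
            )
        if len(feature_ids) != matrix.shape[1]:
            raise DimensionError(
                f"{features_path}: {len(feature_ids)} ids for {matrix.shape[1]} columns"
            )
        return matrix, cell_ids, feature_ids
    if format == "delimited":
        try:
            df = pd.read_csv(path, sep="\t", header=0, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"malformed delimited file {path}: {exc}") from exc
        cell_ids = [str(c) for c in df.index]
        if len(set(cell_ids)) != len(cell_ids):
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DimensionError(f"duplicate cell ids in {path}: {dupes}")
        return df.to_numpy(), cell_ids, [str(f) for f in df.columns]
    # h5ad
    import anndata as ad

    adata = ad.read_h5ad(path)
    matrix = adata.X
    if sp.issparse(matrix):
        matrix = matrix.tocsr()
    else:
        matrix = np.asarray(matrix)
    return matrix, [str(c) for c in adata.obs_names], [str(f) for f in adata.var_names]


def write_modality(
    matrix,
    cell_ids: Sequence[str],
    feature_ids: Sequence[str],
    path: str,
    format: str,
) -> None:
    """Write one cell-by-feature matrix in the named format (inverse of
    :func:`read_modality`)."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if matrix.shape[0] != len(cell_ids):
        raise DimensionError("cell id count does not match matrix rows")
    if matrix.shape[1] != len(feature_ids):
        raise DimensionError("feature id count does not match matrix columns")
    if format == "mtx":
        scipy.io.mmwrite(path, sp.coo_matrix(matrix))
        cells_path, features_path = _id_file_paths(path)
        for ids, p in ((cell_ids, cells_path), (feature_ids, features_path)):
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("\n".join(str(i) for i in ids) + "\n")
    elif format == "delimited":
        dense = matrix.todense() if sp.issparse(matrix) else matrix
        df = pd.DataFrame(np.asarray(dense), index=list(cell_ids), columns=list(feature_ids))
        df.to_csv(path, sep="\t")
    else:
        import anndata as ad

        adata = ad.AnnData(
            X=matrix.copy() if sp.issparse(matrix) else np.asarray(matrix),
            obs=pd.DataFrame(index=[str(c) for c in cell_ids]),
            var=pd.DataFrame(index=[str(f) for f in feature_ids]),
        )
        adata.write_h5ad(path)


def assemble_dataset(
    matrices: Sequence,
    cell_ids: Sequence[Sequence[str]],
    feature_ids: Optional[Sequence[Sequence[str]]] = None,
    modality_names: Optional[Sequence[str]] = None,
    align: bool = False,
    obs: Optional[pd.DataFrame] = None,
) -> MultimodalDataset:
    """Assemble per-modality matrices into a :class:`MultimodalDataset`.

    With ``align=True`` the modalities are restricted to the intersection
    of their cell ids and reordered to a single shared order (the order
    of the intersection ids as they appear in the first modality).
    Without it, all id lists must already be identical.
    """
    matrices = list(matrices)
    cell_ids = [[str(c) for c in ids] for ids in cell_ids]
    if len(matrices) != len(cell_ids):
        raise DimensionError("one cell-id list per matrix required")
    if modality_names is None:
        modality_names = [f"modality{m}" for m in range(len(matrices))]
    if feature_ids is None:
        feature_ids = [
            [f"feature{j}" for j in range(mat.shape[1])] for mat in matrices
        ]
    if align:
        shared = set(cell_ids[0])
        for ids in cell_ids[1:]:
            shared &= set(ids)
        if not shared:
            raise AlignmentError("no cell ids common to all modalities")
        order = [c for c in cell_ids[0] if c in shared]
        reordered = []
        for mat, ids in zip(matrices, cell_ids):
            pos = {c: i for i, c in enumerate(ids)}
            idx = np.array([pos[c] for c in order])
            reordered.append(mat[idx])
        matrices, shared_ids = reordered, order
    else:
        for ids in cell_ids[1:]:
            if ids != cell_ids[0]:
                raise AlignmentError(
                    "cell id lists differ; pass align=True to intersect"
                )
        shared_ids = cell_ids[0]
    if obs is not None:
        obs = obs.loc[shared_ids]
    return MultimodalDataset(
        modalities=matrices,
        modality_names=list(modality_names),
        cell_ids=shared_ids,
        feature_ids=[list(f) for f in feature_ids],
        obs=obs,
    )


def write_embedding(coords, cell_ids: Sequence[str], path: str) -> None:
    """Write a cell-by-dimension embedding as tab-delimited text.

    First column holds cell ids, then one column per dimension named
    ``dim0, dim1, ...``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise DimensionError("embedding must be 2-D")
    if coords.shape[0] != len(cell_ids):
        raise DimensionError(
            f"{coords.shape[0]} embedding rows for {len(cell_ids)} cell ids"
        )
    df = pd.DataFrame(
        coords,
        index=[str(c) for c in cell_ids],
        columns=[f"dim{i}" for i in range(coords.shape[1])],
    )
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")


def read_embedding(path: str) -> tuple[np.ndarray, list[str]]:
    """Read an embedding written by :func:`write_embedding`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.index]
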