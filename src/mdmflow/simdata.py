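"""Simulated developmental multimodal datasets.

Two benchmark datasets with known lineage structure, type labels,
pseudotime and per-type ground-truth modality assignment:

* **binary tree** — 3 modalities, 6 types A-F, 1000 observations per
  type. Modalities 1, 2 and 3 introduce the developmental lineages A-B,
  C-D and E-F respectively: in its introducing modality a lineage pair is
  laid out as two unit-spaced isotropic 3D Gaussians, while every other
  modality collapses those types onto a common Gaussian blob (no
  separating structure). The lineage topology is a binary tree:
  A -> B, then B branches into C -> D and E -> F.
* **rare transitions** — 2 modalities, 9 types A-I, 500 observations per
  type. Types A-C are sampled uniformly from unit-length 3D segments laid
  head-to-tail in modality 1 (the trunk); modality 2 introduces three
  Gaussian lineage pairs D-E, F-G and H-I branching off A, B and C — the
  rare transitions out of the trunk.

Observations are oversampled per type, then density-downsampled to the
target count: each point is retained with probability proportional to
the cubed distance to its N-th nearest neighbor (N = 25), which keeps
sparse-region points and flattens density. Pseudotime orders cells by
lineage depth plus position along the lineage axis; noise permutes the
pseudotime-sorted order within consecutive blocks of 100 cells.

Gaussian means, covariances (0.25 * I) and segment endpoints are a fixed
documented default geometry reproducing the intended lineage topology;
all of it is overridable via the ``geometry`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .datamodel import DimensionError, MultimodalDataset
from .weights import WeightMatrix

__all__ = [
    "SimulatedDataset",
    "density_downsample",
    "make_binary_tree",
    "make_rare_transitions",
    "target_weights",
    "weight_mse",
]

_SIGMA = 0.5  # isotropic std; covariance 0.25 * I


@dataclass
class _TypeGeometry:
    """One cell type: where it lives in each modality and on the lineage tree."""

    introducing_modality: int
    depth: int  # lineage depth of the type's branch segment
    # per-modality source: ("gauss", mean) or ("segment", start, end)
    sources: list
    axis: np.ndarray  # lineage-progress direction in the introducing modality
    root: np.ndarray  # branch root in the introducing modality


@dataclass
class SimulatedDataset:
    """Generated observations with full ground truth."""

    modalities: list[np.ndarray]
    type_labels: np.ndarray
    pseudotime: np.ndarray  # noisy rank, a permutation of 0..C-1
    clean_pseudotime: np.ndarray  # pre-noise rank
    introducing_modality: dict[str, int]
    seed: int
    name: str

    @property
    def n_cells(self) -> int:
        return self.type_labels.size

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def to_multimodal(self) -> MultimodalDataset:
        cell_ids = [f"cell{i}" for i in range(self.n_cells)]
        obs = pd.DataFrame(
            {
                "type": self.type_labels,
                "pseudotime": self.pseudotime,
                "clean_pseudotime": self.clean_pseudotime,
            },
            index=cell_ids,
        )
        return MultimodalDataset(
            modalities=[m.copy() for m in self.modalities],
            modality_names=[f"modality{m}" for m in range(self.n_modalities)],
            cell_ids=cell_ids,
            feature_ids=[["x", "y", "z"] for _ in self.modalities],
            obs=obs,
        )


def density_downsample(
    points: np.ndarray, target_n: int, nn_index: int = 25, seed: int = 0
) -> np.ndarray:
    """Density-flattening subsample: retain ``target_n`` points without
    replacement with probability proportional to the cubed distance to
    each point's ``nn_index``-th nearest neighbor.

    Sparse-region points (large neighbor distances) are preferentially
    retained. Returns sorted indices into ``points``.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if target_n > n:
        raise DimensionError(f"cannot sample {target_n} from {n} points")
    if nn_index >= n:
        raise DimensionError(f"nn_index={nn_index} requires more than {nn_index} points")
    nn = NearestNeighbors(n_neighbors=nn_index + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    w = dist[:, nn_index] ** 3
    total = w.sum()
    rng = np.random.default_rng(seed)
    if total == 0:
        warnings.warn(
            "all neighbor distances are zero; falling back to uniform sampling",
            RuntimeWarning,
            stacklevel=2,
        )
        chosen = rng.choice(n, size=target_n, replace=False)
    else:
        chosen = rng.choice(n, size=target_n, replace=False, p=w / total)
    return np.sort(chosen)


def _binary_tree_geometry() -> dict[str, _TypeGeometry]:
    blob = ("gauss", np.zeros(3))
    x = np.array([1.0, 0.0, 0.0])
    geom = {}
    pairs = [("A", "B", 0, 0), ("C", "D", 1, 2), ("E", "F", 2, 2)]
    for first, second, mod, base_depth in pairs:
        for label, offset, depth in ((first, 1.0, base_depth), (second, 2.0, base_depth + 1)):
            sources = [blob, blob, blob]
            sources[mod] = ("gauss", offset * x)
            geom[label] = _TypeGeometry(
                introducing_modality=mod,
                depth=depth,
                sources=sources,
                axis=x,
                root=np.zeros(3),
            )
    return geom


def _rare_transitions_geometry() -> dict[str, _TypeGeometry]:
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    trunk_blob = ("gauss", np.zeros(3))  # A-C in modality 2
    branch_blob = ("gauss", np.array([1.5, 1.0, 0.0]))  # D-I in modality 1
    geom = {}
    # trunk: unit segments head-to-tail along x in modality 1
    for i, label in enumerate("ABC"):
        geom[label] = _TypeGeometry(
            introducing_modality=0,
            depth=i,
            sources=[("segment", i * x, (i + 1) * x), trunk_blob],
            axis=x,
            root=np.zeros(3),
        )
    # rare-transition branches in modality 2: D-E off A, F-G off B, H-I off C
    branches = [("D", "E", x, 0), ("F", "G", y, 1), ("H", "I", z, 2)]
    for first, second, axis, parent_depth in branches:
        for label, offset, depth in (
            (first, 1.0, parent_depth + 1),
            (second, 2.0, parent_depth + 2),
        ):
            geom[label] = _TypeGeometry(
                introducing_modality=1,
                depth=depth,
                sources=[branch_blob, ("gauss", offset * axis)],
                axis=axis,
                root=np.zeros(3),
            )
    return geom


def _sample_source(rng: np.random.Generator, source, n: int) -> np.ndarray:
    kind = source[0]
    if kind == "gauss":
        return rng.normal(loc=source[1], scale=_SIGMA, size=(n, 3))
    start, end = source[1], source[2]
    u = rng.uniform(size=(n, 1))
    return start + u * (end - start)


def _generate(
    name: str,
    geometry: dict[str, _TypeGeometry],
    n_per_type: int,
    seed: int,
    oversample: int,
    downsample_nn: int,
    noise_block: int,
) -> SimulatedDataset:
    rng = np.random.default_rng(seed)
    M = len(next(iter(geometry.values())).sources)
    modality_parts: list[list[np.ndarray]] = [[] for _ in range(M)]
    labels: list[str] = []
    progress_parts: list[np.ndarray] = []
    for label in sorted(geometry):
        g = geometry[label]
        n_over = oversample * n_per_type
        coords = [_sample_source(rng, g.sources[m], n_over) for m in range(M)]
        keep = density_downsample(
            coords[g.introducing_modality],
            n_per_type,
            nn_index=downsample_nn,
            seed=int(rng.integers(2**31)),
        )
        coords = [c[keep] for c in coords]
        for m in range(M):
            modality_parts[m].append(coords[m])
        labels.extend([label] * n_per_type)
        # progress along the lineage axis from the branch root, scaled to [0, 1)
        proj = (coords[g.introducing_modality] - g.root) @ g.axis
        span = proj.max() - proj.min()
        u = (proj - proj.min()) / (span if span > 0 else 1.0)
        progress_parts.append(g.depth + u)
    modalities = [np.vstack(parts) for parts in modality_parts]
    labels_arr = np.array(labels)
    progress = np.concatenate(progress_parts)
    C = labels_arr.size
    order = np.argsort(progress, kind="stable")
    clean = np.empty(C, dtype=int)
    clean[order] = np.arange(C)
    noisy_order = order.copy()
    for start in range(0, C, noise_block):
        block = noisy_order[start : start + noise_block]
        rng.shuffle(block)
        noisy_order[start : start + noise_block] = block
    pseudotime = np.empty(C, dtype=int)
    pseudotime[noisy_order] = np.arange(C)
    return SimulatedDataset(
        modalities=modalities,
        type_labels=labels_arr,
        pseudotime=pseudotime,
        clean_pseudotime=clean,
        introducing_modality={t: g.introducing_modality for t, g in geometry.items()},
        seed=seed,
        name=name,
    )


def make_binary_tree(
    seed: int = 0,
    n_per_type: int = 1000,
    oversample: int = 3,
    downsample_nn: int = 25,
    noise_block: int = 100,
    geometry: Optional[dict[str, _TypeGeometry]] = None,
) -> SimulatedDataset:
    """Binary-tree dataset: 3 modalities, 6 types A-F, 1000 per type."""
    return _generate(
        "binary_tree",
        geometry or _binary_tree_geometry(),
        n_per_type,
        seed,
        oversample,
        downsample_nn,
        noise_block,
    )


def make_rare_transitions(
    seed: int = 0,
    n_per_type: int = 500,
    oversample: int = 3,
    downsample_nn: int = 25,
    noise_block: int = 100,
    geometry: Optional[dict[str, _TypeGeometry]] = None,
) -> SimulatedDataset:
    """Rare-transitions dataset: 2 modalities, 9 types A-I, 500 per type."""
    return _generate(
        "rare_transitions",
        geometry or _rare_transitions_geometry(),
        n_per_type,
        seed,
        oversample,
        downsample_nn,
        noise_block,
    )


def target_weights(dataset: SimulatedDataset) -> np.ndarray:
    """Ground-truth modality weights: 1 for the lineage-introducing
    modality of each cell's type, 0 elsewhere (one-hot rows)."""
    C, M = dataset.n_cells, dataset.n_modalities
    targets = np.zeros((C, M))
    for c, label in enumerate(dataset.type_labels):
        if label not in dataset.introducing_modality:
            raise ValueError(f"unknown type label {label!r}")
        targets[c, dataset.introducing_modality[label]] = 1.0
    return targets


def weight_mse(weights, targets) -> float:
    """Mean squared elementwise difference over all C x M entries."""
    w = weights.w if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    t = np.asarray(targets, dtype=float)
    if w.shape != t.shape:
        raise DimensionError(f"shape mismatch: {w.shape} vs {t.shape}")
    return float(np.mean((w - t) ** 2))
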