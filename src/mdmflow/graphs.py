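"""Fixed-out-degree graphs for force-directed layout.

The MDM latent space captures the global structure of the data; layout
graphs add local ordering. Three variants are provided:

* ``nn`` — each cell links to its nearest MDM neighbors;
* ``transitions`` — each cell links, within a pool of MDM nearest
  neighbors, to the targets with the highest externally supplied
  developmental transition probabilities (velocity, optimal transport,
  lineage tracing), falling back to plain nearest neighbors for any
  shortfall and for cells without determined transitions;
* ``transitions_timestamped`` — candidate neighbors are restricted to the
  subsequent timestamp (terminal timestamp: same timestamp).

Every node gets exactly ``out_degree`` outgoing edges. Ties break by
transition probability (descending), then distance (ascending), then
cell index (ascending). The resulting edge lists feed external layout
engines (ForceAtlas2, UMAP graph layout), which are not reimplemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .datamodel import TransitionMatrix
from .mdm import MDMEmbedding
from .weights import ConfigurationError, _knn_exclude_self

__all__ = [
    "LayoutGraph",
    "nn_graph",
    "transitions_graph",
    "timestamped_graph",
    "export_graph",
    "read_graph",
]


@dataclass
class LayoutGraph:
    """Directed edge list with constant out-degree per node."""

    edges: np.ndarray  # E x 2 (source, target), ordered by source then rank
    out_degree: int
    variant: str

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must be an E x 2 array")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        src, counts = np.unique(self.edges[:, 0], return_counts=True)
        if counts.size and not np.all(counts == self.out_degree):
            raise ValueError("every node must have exactly out_degree edges")
        if len({tuple(e) for e in self.edges.tolist()}) != len(self.edges):
            raise ValueError("duplicate edges are not allowed")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def _coords(embedding) -> np.ndarray:
    return embedding.coords if isinstance(embedding, MDMEmbedding) else np.asarray(embedding, float)


def nn_graph(embedding, out_degree: int) -> LayoutGraph:
    """Variant (i): link each cell to its ``out_degree`` nearest MDM neighbors."""
    X = _coords(embedding)
    C = X.shape[0]
    if out_degree >= C:
        raise ConfigurationError(f"out_degree={out_degree} needs more than {C} cells")
    idx, _ = _knn_exclude_self(X, out_degree)
    src = np.repeat(np.arange(C), out_degree)
    return LayoutGraph(np.column_stack([src, idx.ravel()]), out_degree, "nn")


def _rank_candidates(
    cand_idx: np.ndarray, cand_dist: np.ndarray, cand_prob: np.ndarray, out_degree: int
) -> np.ndarray:
    """Order candidates by probability desc, distance asc, index asc."""
    order = np.lexsort((cand_idx, cand_dist, -cand_prob))
    return cand_idx[order[:out_degree]]


def transitions_graph(
    embedding,
    transitions: TransitionMatrix,
    out_degree: int,
    candidate_pool: Optional[int] = None,
) -> LayoutGraph:
    """Variant (ii): inside each cell's MDM neighborhood, prefer targets
    with high developmental transition probability.

    The neighborhood is the cell's ``candidate_pool`` nearest MDM
    neighbors (default 10 x out_degree). Zero-probability slots fill with
    the closest not-yet-linked neighbors; cells whose transition row is
    all zero get pure nearest-neighbor edges.
    """
    X = _coords(embedding)
    C = X.shape[0]
    if transitions.n_cells != C:
        raise ValueError("transition matrix not aligned to the embedding")
    if candidate_pool is None:
        candidate_pool = 10 * out_degree
    pool = min(candidate_pool, C - 1)
    if out_degree > pool:
        raise ConfigurationError("out_degree exceeds the candidate pool")
    idx, dist = _knn_exclude_self(X, pool)
    P = transitions.probs
    edges = np.empty((C, out_degree), dtype=int)
    for c in range(C):
        probs = np.asarray(P[c, idx[c]].todense()).ravel()
        edges[c] = _rank_candidates(idx[c], dist[c], probs, out_degree)
    src = np.repeat(np.arange(C), out_degree)
    return LayoutGraph(np.column_stack([src, edges.ravel()]), out_degree, "transitions")


def timestamped_graph(
    embedding,
    transitions: TransitionMatrix,
    timestamps: Sequence,
    out_degree: int,
    candidate_pool: Optional[int] = None,
) -> LayoutGraph:
    """Variant (iii): candidates restricted to the subsequent timestamp.

    Cells of the terminal timestamp search within their own timestamp.
    Within the restricted set the ranking is the same as in
    :func:`transitions_graph`.
    """
    X = _coords(embedding)
    C = X.shape[0]
    timestamps = np.asarray(timestamps)
    if timestamps.shape[0] != C:
        raise ValueError("one timestamp per cell required")
    if candidate_pool is None:
        candidate_pool = 10 * out_degree
    levels = np.sort(np.unique(timestamps))
    successor = {t: levels[i + 1] if i + 1 < len(levels) else t for i, t in enumerate(levels)}
    P = transitions.probs
    edges = np.empty((C, out_degree), dtype=int)
    for t in levels:
        sources = np.nonzero(timestamps == t)[0]
        targets = np.nonzero(timestamps == successor[t])[0]
        own = successor[t] == t
        limit = len(targets) - 1 if own else len(targets)
        if limit < out_degree:
            raise ConfigurationError(
                f"timestamp {successor[t]!r} has {len(targets)} cells, fewer than "
                f"out_degree={out_degree} required by timestamp {t!r}"
            )
        pool = min(candidate_pool, limit)
        nn = NearestNeighbors(n_neighbors=min(pool + 1, len(targets))).fit(X[targets])
        dist, local = nn.kneighbors(X[sources])
        for row, c in enumerate(sources):
            cand = targets[local[row]]
            d = dist[row]
            keep = cand != c  # same-timestamp search may return the cell itself
            cand, d = cand[keep][:pool], d[keep][:pool]
            probs = np.asarray(P[c, cand].todense()).ravel()
            edges[c] = _rank_candidates(cand, d, probs, out_degree)
    src = np.repeat(np.arange(C), out_degree)
    return LayoutGraph(
        np.column_stack([src, edges.ravel()]), out_degree, "transitions_timestamped"
    )


def export_graph(graph: LayoutGraph, path: str, cell_ids: Optional[Sequence[str]] = None) -> None:
    """Write the edge list as tab-delimited source/target rows (by source,
    then rank) for external layout engines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\n")
        for s, t in graph.edges:
            if cell_ids is not None:
                fh.write(f"{cell_ids[s]}\t{cell_ids[t]}\n")
            else:
                fh.write(f"{s}\t{t}\n")


def read_graph(path: str) -> list[tuple[str, str]]:
    """Read an exported edge list back as (source, target) id pairs."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n").split("\t") != ["source", "target"]:
            raise ValueError(f"{path} is not an exported edge list")
        return [tuple(line.rstrip("\n").split("\t")) for line in fh if line.strip()]
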