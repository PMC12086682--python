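"""Topic-based latent modalities for unimodal data.

A single count modality is split into pseudo-modalities via latent
Dirichlet allocation: each cell is a multinomial mixture of topics, each
topic a distribution over features. Features are grouped by their most
probable topic and, within each group, only the top features by
feature-topic probability are kept. Each nonempty group becomes a latent
modality; the cell-topic proportions, restricted to retained topics and
renormalized per cell, serve as modality weights so the multimodal
workflow applies unchanged to unimodal data.

LDA runs on raw counts (it is a count model); the latent modality
matrices are log-normalized before entering MDM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import LatentDirichletAllocation

from .weights import ConfigurationError, WeightMatrix

__all__ = ["TopicModel", "LatentModalitySet", "fit_topics", "build_latent_modalities", "log_normalize"]


@dataclass
class TopicModel:
    """Fitted LDA factorization of a count modality.

    ``cell_topic`` (C x T) rows and ``topic_feature`` (T x F) rows are
    probability distributions (each sums to 1).
    """

    cell_topic: np.ndarray
    topic_feature: np.ndarray
    n_topics: int
    n_iterations: int
    random_seed: int

    def __post_init__(self) -> None:
        for name, mat in (("cell_topic", self.cell_topic), ("topic_feature", self.topic_feature)):
            mat = np.asarray(mat, dtype=float)
            if np.any(mat < 0):
                raise ValueError(f"{name} entries must be nonnegative")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"{name} rows must sum to 1 within 1e-6")


@dataclass
class LatentModalitySet:
    """Latent modalities built from one topic model.

    ``feature_groups`` maps each retained topic to its ordered feature
    indices (disjoint groups); ``matrices`` holds the corresponding
    cell-by-feature submatrices; ``weights_source`` is the cell-topic
    matrix restricted to retained topics and renormalized per cell.
    """

    feature_groups: dict[int, np.ndarray]
    matrices: list
    weights_source: np.ndarray
    retained_topics: list[int]

    def as_weight_matrix(self) -> WeightMatrix:
        return WeightMatrix(self.weights_source)


def fit_topics(
    counts,
    n_topics: int,
    n_iterations: int = 30,
    seed: int = 0,
) -> TopicModel:
    """Fit LDA on a nonnegative count matrix.

    Deterministic for a fixed seed (batch variational inference). Cells
    with zero total count admit no multinomial and raise an error naming
    them.
    """
    if n_topics < 2:
        raise ConfigurationError("n_topics must be >= 2")
    X = counts.tocsr() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    data = X.data if sp.issparse(X) else X
    if data.size and data.min() < 0:
        raise ValueError("LDA requires nonnegative counts")
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = np.nonzero(totals == 0)[0].tolist()
        raise ValueError(f"cells with zero total count have no valid multinomial: {bad}")
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        max_iter=n_iterations,
        learning_method="batch",
        random_state=seed,
    )
    cell_topic = lda.fit_transform(X)
    cell_topic = cell_topic / cell_topic.sum(axis=1, keepdims=True)
    topic_feature = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(cell_topic, topic_feature, n_topics, n_iterations, seed)


def _top_feature_mask(probs: np.ndarray, rule: Union[str, int, float, None]) -> np.ndarray:
    """Mask of retained features within one topic group, given their
    feature-topic probabilities."""
    if rule is None:
        return np.ones(probs.size, dtype=bool)
    if rule == "above-uniform":
        return probs > 1.0 / probs.size if probs.size else np.zeros(0, dtype=bool)
    if isinstance(rule, int):  # top-k by probability
        order = np.argsort(-probs, kind="stable")
        mask = np.zeros(probs.size, dtype=bool)
        mask[order[:rule]] = True
        return mask
    raise ConfigurationError(f"unknown top-feature rule {rule!r}")


def build_latent_modalities(
    model: TopicModel,
    counts,
    top_rule: Union[str, int, None] = "above-uniform",
) -> LatentModalitySet:
    """Group features by most probable topic and truncate to top features.

    Each feature is assigned to the topic maximizing its feature-topic
    probability (ties toward the lower topic index). Within each group,
    features are ranked by that probability; the default rule keeps
    features whose within-topic probability exceeds the uniform 1/F, and
    an integer rule keeps the top-k. Topics left without features yield
    no latent modality.
    """
    X = counts.tocsr() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    T, F = model.topic_feature.shape
    if X.shape[1] != F:
        raise ValueError("counts and topic model disagree on the feature count")
    # uniform-threshold rule is evaluated against the full feature space
    assignment = np.argmax(model.topic_feature, axis=0)
    groups: dict[int, np.ndarray] = {}
    matrices = []
    retained: list[int] = []
    for t in range(T):
        members = np.nonzero(assignment == t)[0]
        if members.size == 0:
            continue
        probs = model.topic_feature[t, members]
        if top_rule == "above-uniform":
            keep = probs > 1.0 / F
        else:
            keep = _top_feature_mask(probs, top_rule)
        members = members[keep]
        if members.size == 0:
            continue
        order = np.argsort(-probs[keep], kind="stable")
        members = members[order]
        groups[t] = members
        matrices.append(X[:, members])
        retained.append(t)
    if not retained:
        raise ConfigurationError("top-feature rule retained zero features")
    ws = model.cell_topic[:, retained]
    ws = ws / ws.sum(axis=1, keepdims=True)
    return LatentModalitySet(groups, matrices, ws, retained)


def log_normalize(counts, target_sum: float = 1e4) -> np.ndarray:
    """ln(1 + count scaled to a fixed per-cell total), the normalization
    applied to latent modality matrices before MDM."""
    X = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(X / totals * target_sum)
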