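"""Hierarchical clustering and average-silhouette cluster-number selection.

The number of genetic partitions C is chosen by cutting an agglomerative
dendrogram of the band-profile dissimilarity matrix at each candidate C
and scoring the partition with the average silhouette

    s_i = (b_i - a_i) / max(a_i, b_i),

where a_i is individual i's mean dissimilarity to its own cluster and b_i
its mean dissimilarity to the nearest other cluster; points in singleton
clusters score 0.  The optimal C maximizes the average of s_i; C = 1 has
no defined silhouette and scores 0 by convention, so it is reported (with
a warning) only if every candidate partition scores negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "agglomerative_cluster",
    "silhouette_scores",
    "optimal_clusters",
    "SilhouetteProfile",
]

LINKAGES = ("average", "complete", "single", "ward")


def _check_diss(diss: np.ndarray) -> np.ndarray:
    diss = np.asarray(diss, dtype=float)
    n = diss.shape[0]
    if diss.shape != (n, n) or not np.allclose(diss, diss.T):
        raise ValidationError("dissimilarity matrix must be square and symmetric")
    return diss


def agglomerative_cluster(
    diss: np.ndarray, linkage_method: str = "average", n_clusters: int = 2
) -> np.ndarray:
    """Cut an agglomerative dendrogram at ``n_clusters`` clusters.

    Labels are integers 0..C-1, renumbered by first appearance so the
    labeling is deterministic.
    """
    diss = _check_diss(diss)
    n = diss.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValidationError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if linkage_method not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    if n_clusters == n:
        return np.arange(n)
    z = linkage(squareform(diss, checks=False), method=linkage_method)
    raw = fcluster(z, t=n_clusters, criterion="maxclust")
    # renumber by first appearance
    seen: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = seen.setdefault(int(r), len(seen))
    return labels


def silhouette_scores(
    labels: np.ndarray, diss: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-point silhouette scores and their average, from a distance matrix.

    Requires at least two non-empty clusters.  Points in singleton
    clusters are given score 0 (their within-cluster distance is
    undefined).
    """
    diss = _check_diss(diss)
    labels = np.asarray(labels)
    n = diss.shape[0]
    if labels.shape != (n,):
        raise ValidationError("labels length must match the matrix")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")

    scores = np.zeros(n, dtype=float)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            scores[i] = 0.0
            continue
        a = diss[i, own[own != i]].mean()
        b = min(diss[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return scores, float(scores.mean())


@dataclass
class SilhouetteProfile:
    """Average silhouette per candidate cluster count and the argmax."""

    candidates: np.ndarray  # evaluated C values (1..C_max)
    scores: np.ndarray  # average silhouette per candidate (C=1 -> 0)
    optimal_c: int
    labels: np.ndarray  # partition at the optimum
    linkage_method: str


def optimal_clusters(
    diss: np.ndarray, c_max: int, linkage_method: str = "average"
) -> SilhouetteProfile:
    """Scan C = 1..C_max and pick the partition maximizing average silhouette.

    C = 1 is assigned score 0 by convention and wins only if every
    multi-cluster partition scores negative (flagged with a warning).
    Ties break toward smaller C.
    """
    diss = _check_diss(diss)
    n = diss.shape[0]
    if c_max < 2:
        raise ValidationError("c_max must be >= 2")
    c_max = min(c_max, n)
    candidates = np.arange(1, c_max + 1)
    scores = np.zeros(len(candidates), dtype=float)
    labelings = {1: np.zeros(n, dtype=int)}
    for i, c in enumerate(candidates[1:], start=1):
        labels = agglomerative_cluster(diss, linkage_method, int(c))
        labelings[int(c)] = labels
        if len(np.unique(labels)) < 2:  # merge ties can yield fewer clusters
            scores[i] = -np.inf
            continue
        _, scores[i] = silhouette_scores(labels, diss)
    best_i = int(np.argmax(scores))  # argmax takes the first (smallest C) on ties
    optimal_c = int(candidates[best_i])
    if optimal_c == 1:
        logger.warning(
            "all multi-cluster partitions have negative average silhouette; "
            "reporting C = 1 (no detectable structure)"
        )
    return SilhouetteProfile(
        candidates=candidates,
        scores=np.where(np.isfinite(scores), scores, np.nan),
        optimal_c=optimal_c,
        labels=labelings[optimal_c],
        linkage_method=linkage_method,
    )
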