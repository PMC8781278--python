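"""Global PCA of autoscaled responses and correlation-distance variable clustering.

The clustering operates on *variables*, not runs: the dissimilarity between
responses j and l is d(j, l) = 1 - |r_jl| with r the Pearson correlation,
so strongly positively and strongly negatively associated responses are
both "near" — a block like {fermentation length, maximum fermentation
rate}, which move in opposite directions, must land in one module.  The
signed variant 1 - r is available for comparison.  The dendrogram is built
with average linkage (UPGMA) by default and cut to exactly k clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .preprocess import ResponseMatrix, correlation_matrix

__all__ = ["PCAModel", "ClusterAssignment", "pca", "ahc_cluster", "correlation_distance"]

LINKAGES = ("average", "complete", "single")
DISTANCES = ("absolute", "signed")


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Per component, make the largest-|loading| variable load positively.

    Eigenvector signs are arbitrary; pinning them makes scores, loadings
    and everything fitted to them deterministic across backends.
    """
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


@dataclass
class PCAModel:
    """PCA of an autoscaled response matrix (correlation-matrix PCA).

    ``loadings`` columns are the orthonormal eigenvectors of the sample
    correlation matrix, ordered by decreasing eigenvalue; ``scores`` are
    the projections of the runs; ``explained`` is the percentage of total
    variance per component.
    """

    names: list[str]
    loadings: np.ndarray
    scores: np.ndarray
    explained: np.ndarray

    @property
    def cum_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.names, columns=cols)

    def scores_frame(self, run_ids: list[str]) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=run_ids, columns=cols)


def pca(X: ResponseMatrix, n_components: int | None = None) -> PCAModel:
    """PCA on the correlation structure of an autoscaled response matrix.

    Components are eigenvectors of the sample correlation matrix; scores
    are X @ loadings; explained percentages are 100 * eigenvalue / trace.

    Raises
    ------
    ValueError
        If the input has not been autoscaled (correlation-focused analysis
        requires unit-variance columns) or n_components is out of range.
    """
    if not X.is_scaled:
        raise ValueError("pca requires an autoscaled ResponseMatrix")
    n, m = X.values.shape
    max_comp = min(n - 1, m)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")

    corr = np.asarray(correlation_matrix(X))
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    explained = 100.0 * eigvals / eigvals.sum()

    loadings = eigvecs[:, :n_components]
    return PCAModel(
        names=X.names,
        loadings=loadings,
        scores=X.values @ loadings,
        explained=explained[:n_components],
    )


@dataclass
class ClusterAssignment:
    """Partition of response names into modules with its merge history."""

    labels: dict[str, int]
    merge_history: list[tuple[int, int, float]]
    k: int

    def members(self, cluster_id: int) -> list[str]:
        return [name for name, c in self.labels.items() if c == cluster_id]

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.labels.values()))

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"response": list(self.labels), "cluster_id": list(self.labels.values())}
        )

    def merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merge_history, columns=["left", "right", "height"]
        ).rename_axis("step")


def correlation_distance(
    X: ResponseMatrix, variant: str = "absolute"
) -> pd.DataFrame:
    """Pairwise variable dissimilarity: 1 - |r| (default) or 1 - r."""
    if variant not in DISTANCES:
        raise ValueError(f"distance variant must be one of {DISTANCES}")
    r = correlation_matrix(X)
    d = 1.0 - (r.abs() if variant == "absolute" else r)
    np.fill_diagonal(d.values, 0.0)
    return d.clip(lower=0.0)


def ahc_cluster(
    X: ResponseMatrix,
    k: int,
    linkage: str = "average",
    distance: str = "absolute",
) -> ClusterAssignment:
    """Agglomerative hierarchical clustering of the response variables.

    Parameters
    ----------
    X : ResponseMatrix
        Autoscaled responses (only the correlations matter).
    k : int
        Number of clusters to cut the dendrogram into, 1..n_responses.
    linkage : {"average", "complete", "single"}
        Merge criterion; average linkage (UPGMA) by default.
    distance : {"absolute", "signed"}
        1 - |r| (default) or 1 - r.

    Cluster ids are renumbered 1..k by first appearance in response-column
    order, so the labelling is deterministic given (X, k).
    """
    m = len(X.names)
    if not 1 <= k <= m:
        raise ValueError(f"k must be between 1 and {m}, got {k}")
    d = correlation_distance(X, variant=distance)
    condensed = squareform(np.asarray(d), checks=False)
    Z = hierarchy.linkage(condensed, method=_check_linkage(linkage))
    # cut_tree undoes exactly m - k merges, guaranteeing k clusters even
    # when merge heights tie
    flat = hierarchy.cut_tree(Z, n_clusters=k).ravel()

    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for name, c in zip(X.names, flat):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[name] = relabel[c]
    merge_history = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return ClusterAssignment(labels=labels, merge_history=merge_history, k=k)


def _check_linkage(linkage: str) -> str:
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    return linkage
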