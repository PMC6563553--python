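"""Global transcription profiles: group distances, PCoA, between-group PCA.

The route to the between-group PCA deliberately avoids forming a
genes-x-genes covariance matrix: Euclidean distances among individual
samples -> principal coordinates analysis (Gower double-centering) ->
PCA of the unweighted group centroids in principal-coordinate space, with
every individual projected onto the centroid axes. For Euclidean input the
PCoA scores coincide with centered-data PCA scores up to axis sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_pipeline import ExpressionMatrix

__all__ = [
    "PCoAResult",
    "BgPCAResult",
    "group_euclidean_distances",
    "pcoa",
    "between_group_pca",
    "between_group_pca_pipeline",
]


@dataclass
class PCoAResult:
    scores: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)


@dataclass
class BgPCAResult:
    groups: pd.Series  # sample -> group
    centroid_scores: pd.DataFrame  # group x axis
    axes: np.ndarray  # axes x PCoA-dims loadings
    scores: pd.DataFrame  # individual sample x axis
    variance_fractions: np.ndarray  # per-axis fraction of among-individual variance


def _group_means(values: np.ndarray, groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    names = sorted(groups.unique())
    if any((groups == g).sum() == 0 for g in names):
        raise ValueError("every group must be non-empty")
    means = np.stack([values[(groups == g).to_numpy()].mean(axis=0) for g in names])
    return means, names


def group_euclidean_distances(
    expr: ExpressionMatrix, groups: pd.Series
) -> pd.DataFrame:
    """Euclidean distances between unweighted group mean expression vectors."""
    groups = groups.loc[expr.sample_ids]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    means, names = _group_means(expr.values.to_numpy(float), groups)
    d = squareform(pdist(means))
    return pd.DataFrame(d, index=names, columns=names)


def pcoa(dist: np.ndarray | pd.DataFrame) -> PCoAResult:
    """Principal coordinates analysis by Gower double-centering.

    Scores are eigenvectors scaled by the square root of their (positive)
    eigenvalues; negative eigenvalues are reported in ``eigenvalues`` but
    contribute no axis (they are zero for genuinely Euclidean input).
    """
    if isinstance(dist, pd.DataFrame):
        index = list(dist.index)
        d = dist.to_numpy(float)
    else:
        d = np.asarray(dist, float)
        index = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0.0) * 1e-12
    scores = v[:, pos] * np.sqrt(w[pos])
    frame = pd.DataFrame(
        scores, index=index, columns=[f"PCo{i + 1}" for i in range(scores.shape[1])]
    )
    return PCoAResult(frame, w)


def between_group_pca(scores: pd.DataFrame, groups: pd.Series) -> BgPCAResult:
    """PCA of group centroids with individuals projected onto the axes.

    At most ``n_groups - 1`` axes carry variance. Axis variance is reported
    as the fraction of the total among-individual variance in the input
    space captured by the individual projections on that axis. Axis signs
    are fixed by making each axis' largest-magnitude loading positive.
    """
    groups = groups.loc[scores.index]
    values = scores.to_numpy(float)
    means, names = _group_means(values, groups)
    if len(names) < 2:
        raise ValueError("between-group PCA needs at least 2 groups")
    grand = means.mean(axis=0)  # unweighted centroid of centroids
    u, s, vt = np.linalg.svd(means - grand, full_matrices=False)
    keep = s > max(s[0], 0.0) * 1e-12 if s.size else np.array([], bool)
    # axes ordered by centroid variance (the classic between-group PCA
    # order); with balanced groups the among-individual variance fractions
    # decay in the same order
    axes = vt[keep]
    for i in range(axes.shape[0]):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    proj = (values - grand) @ axes.T
    centroid_proj = (means - grand) @ axes.T
    total_var = ((values - values.mean(axis=0)) ** 2).sum()
    axis_var = ((proj - proj.mean(axis=0)) ** 2).sum(axis=0)
    fractions = axis_var / total_var if total_var > 0 else np.zeros_like(axis_var)
    cols = [f"bwgPC{i + 1}" for i in range(axes.shape[0])]
    return BgPCAResult(
        groups=groups,
        centroid_scores=pd.DataFrame(centroid_proj, index=names, columns=cols),
        axes=axes,
        scores=pd.DataFrame(proj, index=scores.index, columns=cols),
        variance_fractions=fractions,
    )


def between_group_pca_pipeline(
    expr: ExpressionMatrix, groups: pd.Series
) -> BgPCAResult:
    """distances among individuals -> PCoA -> between-group PCA."""
    d = squareform(pdist(expr.values.to_numpy(float)))
    coords = pcoa(pd.DataFrame(d, index=expr.sample_ids, columns=expr.sample_ids))
    return between_group_pca(coords.scores, groups.loc[expr.sample_ids])
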