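"""Signed weighted coexpression networks and module detection.

The pipeline: biweight midcorrelation between genes -> signed adjacency
``((1 + c)/2)^beta`` -> topological overlap matrix (TOM) -> average-linkage
hierarchical clustering of TOM dissimilarity -> dynamic cut with a minimum
module size -> iterative reassignment of every gene by module membership
(kME) -> merging of modules whose eigengenes correlate above
``1 - merge_cut_height``.

Module labels are color names assigned by decreasing module size from the
conventional palette ("turquoise" = largest); unassigned genes are "grey".
Module detection is fully deterministic: no randomness enters anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io_pipeline import ExpressionMatrix

logger = logging.getLogger("coexdiv")

__all__ = [
    "NetworkConfig",
    "ModuleSet",
    "EigengeneMatrix",
    "bicor",
    "bicor_matrix",
    "hybrid_bicor",
    "signed_adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "compute_eigengenes",
    "COLOR_PALETTE",
]

GREY = "grey"

# standard module color order, largest module first
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of network construction and module detection."""

    beta: int | None = None
    powers_scanned: tuple[int, ...] = tuple(range(1, 31))
    scale_free_r2_target: float = 0.9
    fallback_beta: int = 20
    max_p_outliers: float = 0.1
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    kme_threshold: float = 0.55
    n_bins: int = 10


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _bicor_weights(x: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, bool]:
    """Weighted deviations for one vector; returns (g, used_pearson_fallback)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return x - x.mean(), True
    u = (x - med) / (9.0 * mad)
    if max_p_outliers < 0.5:
        # rescale each side so at most max_p_outliers of that tail get zero weight
        q_low = np.quantile(u, max_p_outliers)
        q_high = np.quantile(u, 1.0 - max_p_outliers)
        if q_low > -1.0:
            q_low = -1.0
        if q_high < 1.0:
            q_high = 1.0
        u = np.where(u < 0, u / np.abs(q_low), u / q_high)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w, False


def bicor(
    x: np.ndarray, y: np.ndarray, max_p_outliers: float = 0.1
) -> float:
    """Tukey biweight midcorrelation of two vectors, in [-1, 1].

    Falls back to Pearson centering on a vector whose MAD is zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("bicor needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("bicor undefined for constant vectors")
    gx, _ = _bicor_weights(x, max_p_outliers)
    gy, _ = _bicor_weights(y, max_p_outliers)
    denom = np.linalg.norm(gx) * np.linalg.norm(gy)
    if denom == 0.0:
        return 0.0
    return float(np.clip(gx @ gy / denom, -1.0, 1.0))


def _bicor_transform(values: np.ndarray, max_p_outliers: float) -> np.ndarray:
    """Column-wise weighted, centred, unit-norm transform for bicor products."""
    n, p = values.shape
    out = np.empty_like(values, dtype=float)
    for j in range(p):
        g, _ = _bicor_weights(values[:, j], max_p_outliers)
        norm = np.linalg.norm(g)
        out[:, j] = g / norm if norm > 0 else 0.0
    return out


def bicor_matrix(values: np.ndarray, max_p_outliers: float = 0.1) -> np.ndarray:
    """All pairwise biweight midcorrelations of the columns of ``values``."""
    g = _bicor_transform(np.asarray(values, float), max_p_outliers)
    c = np.clip(g.T @ g, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def hybrid_bicor(
    x: np.ndarray, y: np.ndarray, max_p_outliers: float = 0.1
) -> float:
    """Biweight on the x side, plain (Pearson) centering on the y side.

    The form used against binary traits, where robust weighting of the
    0/1 margin is inappropriate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    gx, _ = _bicor_weights(x, max_p_outliers)
    gy = y - y.mean()
    denom = np.linalg.norm(gx) * np.linalg.norm(gy)
    if denom == 0.0:
        raise ValueError("hybrid bicor undefined: a margin is constant")
    return float(np.clip(gx @ gy / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# adjacency / soft threshold / TOM


def signed_adjacency(cor_matrix: np.ndarray, beta: int) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + c_ij)/2)^beta with unit diagonal."""
    c = np.asarray(cor_matrix, float)
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if np.abs(c).max() > 1.0 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + np.clip(c, -1.0, 1.0)) / 2.0) ** beta
    if a.ndim == 2 and a.shape[0] == a.shape[1]:
        np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit R^2 and slope from the connectivity distribution.

    Bins connectivity into ``n_bins`` equal-width bins and regresses
    log10(bin frequency) on log10(mean bin connectivity); the R^2 is signed
    by -sign(slope) so a decaying (scale-free-like) distribution scores
    positively.
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size == 0 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / len(k)))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = np.array(ys) - (slope * np.array(xs) + intercept)
    ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix, config: NetworkConfig = NetworkConfig()
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power by the scale-free topology criterion.

    Returns the smallest scanned power whose signed fit R^2 reaches the
    target, or ``fallback_beta`` with a warning when no power does (the
    recommended fallback when the 0.9 criterion is not reached).
    """
    values = expr.values.to_numpy(float)
    if values.shape[1] < 30:
        raise ValueError("soft-threshold selection needs >= 30 genes")
    if np.ptp(values) == 0:
        raise ValueError("constant expression matrix")
    cor = bicor_matrix(values, config.max_p_outliers)
    rows = []
    chosen = None
    for power in config.powers_scanned:
        adj = signed_adjacency(cor, power)
        k = adj.sum(axis=1) - 1.0
        r2, slope = scale_free_fit(k, config.n_bins)
        rows.append(
            {"power": power, "signed_r2": r2, "slope": slope, "mean_k": float(k.mean())}
        )
        if chosen is None and r2 >= config.scale_free_r2_target:
            chosen = power
    table = pd.DataFrame(rows)
    if chosen is None:
        logger.warning(
            "no scanned power reached signed R^2 >= %.2f; falling back to beta=%d",
            config.scale_free_r2_target,
            config.fallback_beta,
        )
        chosen = config.fallback_beta
    return int(chosen), table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Signed topological overlap: t_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    return t


# ---------------------------------------------------------------------------
# module containers


@dataclass
class ModuleSet:
    """A partition of genes into color-labelled modules plus "grey"."""

    assignments: dict[str, str]
    dendrogram: np.ndarray | None = None
    min_module_size: int = 30
    merge_cut_height: float = 0.25

    @property
    def module_names(self) -> list[str]:
        sizes: dict[str, int] = {}
        for m in self.assignments.values():
            if m != GREY:
                sizes[m] = sizes.get(m, 0) + 1
        return sorted(sizes, key=lambda m: (-sizes[m], m))

    def genes_of(self, module: str) -> list[str]:
        return [g for g, m in self.assignments.items() if m == module]

    @property
    def grey_genes(self) -> list[str]:
        return self.genes_of(GREY)


@dataclass
class EigengeneMatrix:
    """Per-module eigengene scores with explained variance and kME."""

    scores: pd.DataFrame  # samples x modules, unit variance columns
    var_explained: dict[str, float]
    kme: dict[str, float]  # gene -> correlation with its own module eigengene

    @property
    def module_names(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# eigengenes


def _module_eigengene(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of a samples-x-genes block; unit-variance, mean-oriented."""
    std = values.std(axis=0, ddof=0)
    keep = std > 0
    z = (values[:, keep] - values[:, keep].mean(axis=0)) / std[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0]
    sd = scores.std(ddof=1)
    if sd > 0:
        scores = scores / sd
    frac = float(s[0] ** 2 / (s**2).sum())
    # orient along the module's average standardized expression
    avg = z.mean(axis=1)
    if scores @ (avg - avg.mean()) < 0:
        scores = -scores
    return scores, frac


def compute_eigengenes(
    expr: ExpressionMatrix,
    modules: ModuleSet,
    max_p_outliers: float = 0.1,
) -> EigengeneMatrix:
    """Eigengene (first principal component) of every non-grey module.

    Genes that are constant across samples are dropped from the PCA with a
    warning. kME is the biweight midcorrelation of each assigned gene with
    its own module's eigengene.
    """
    values = expr.values
    cols: dict[str, np.ndarray] = {}
    var_explained: dict[str, float] = {}
    kme: dict[str, float] = {}
    for m in modules.module_names:
        genes = modules.genes_of(m)
        if len(genes) < 2:
            raise ValueError(f"module {m!r} has fewer than 2 genes")
        block = values[genes].to_numpy(float)
        n_const = int((block.std(axis=0) == 0).sum())
        if n_const:
            logger.warning("module %s: dropping %d constant gene(s) from PCA", m, n_const)
            if n_const == block.shape[1]:
                raise ValueError(f"module {m!r} is entirely constant")
        scores, frac = _module_eigengene(block)
        cols[m] = scores
        var_explained[m] = frac
        for g in genes:
            x = values[g].to_numpy(float)
            if np.ptp(x) == 0:
                kme[g] = np.nan
            else:
                kme[g] = bicor(x, scores, max_p_outliers)
    scores_frame = pd.DataFrame(cols, index=values.index)
    return EigengeneMatrix(scores_frame, var_explained, kme)


# ---------------------------------------------------------------------------
# module detection


def _initial_cut(linkage: np.ndarray, n: int, min_size: int) -> np.ndarray:
    """Cluster labels from the merge step maximising the count of big clusters.

    Walks the merge sequence with a union-find, counting clusters of size
    >= min_size after each merge; cuts at the earliest step achieving the
    maximal count (the most conservative such cut). Returns -1 for genes not
    in any big cluster at that step.
    """
    parent = np.arange(2 * n - 1)
    size = np.ones(2 * n - 1, dtype=int)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    big_count = int(n >= min_size) * 0  # singletons count only if min_size == 1
    if min_size <= 1:
        big_count = n
    counts_after = []
    merges = []
    for step, (a, b, _h, _c) in enumerate(linkage):
        ra, rb = find(int(a)), find(int(b))
        node = n + step
        was_big = int(size[ra] >= min_size) + int(size[rb] >= min_size)
        parent[ra] = parent[rb] = node
        size[node] = size[ra] + size[rb]
        big_count += int(size[node] >= min_size) - int(was_big)
        counts_after.append(big_count)
        merges.append((ra, rb, node))
    if not counts_after or max(counts_after) == 0:
        return np.full(n, -1, dtype=int)
    best_step = int(np.argmax(counts_after))  # earliest max

    # replay merges up to and including best_step
    parent = np.arange(2 * n - 1)
    size = np.ones(2 * n - 1, dtype=int)
    for step in range(best_step + 1):
        a, b, _h, _c = linkage[step]
        ra, rb = find(int(a)), find(int(b))
        node = n + step
        parent[ra] = parent[rb] = node
        size[node] = size[ra] + size[rb]
    roots = np.array([find(i) for i in range(n)])
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for root in pd.unique(roots):
        members = roots == root
        if members.sum() >= min_size:
            labels[members] = next_label
            next_label += 1
    return labels


def _kme_table(values: np.ndarray, labels: np.ndarray, module_ids: Sequence[int]) -> np.ndarray:
    """Pearson correlation of every gene with every module eigengene."""
    mes = np.column_stack(
        [_module_eigengene(values[:, labels == m])[0] for m in module_ids]
    )
    vc = values - values.mean(axis=0)
    mc = mes - mes.mean(axis=0)
    denom = np.outer(np.linalg.norm(vc, axis=0), np.linalg.norm(mc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = vc.T @ mc / denom
    return np.nan_to_num(k)


def _kme_reassign(
    labels: np.ndarray,
    values: np.ndarray,
    kme_threshold: float,
    min_module_size: int,
    max_iter: int = 3,
) -> np.ndarray:
    """Iteratively reassign every gene by module membership (kME).

    Each pass computes module eigengenes, assigns every gene to the module
    with the largest |kME| when that value reaches ``kme_threshold`` and to
    grey otherwise, then dissolves any module that has shrunk below the
    minimum module size. Converges in a handful of passes; the loop is the
    membership-refinement analogue of the PAM stage of the dynamic hybrid
    cut.
    """
    labels = labels.copy()
    n = values.shape[1]
    for _ in range(max_iter):
        module_ids = [m for m in np.unique(labels) if m >= 0]
        if not module_ids:
            return labels
        kme = _kme_table(values, labels, module_ids)
        best = np.argmax(np.abs(kme), axis=1)
        best_val = np.abs(kme)[np.arange(n), best]
        new = np.where(best_val >= kme_threshold, np.asarray(module_ids)[best], -1)
        for m in np.unique(new[new >= 0]):
            if (new == m).sum() < min_module_size:
                new[new == m] = -1
        if (new == labels).all():
            break
        labels = new
    return labels


def _merge_by_eigengene(
    labels: np.ndarray,
    values: np.ndarray,
    cut_height: float,
) -> np.ndarray:
    """Iteratively merge the closest pair of modules whose eigengene
    correlation dissimilarity (1 - cor) is below ``cut_height``."""
    labels = labels.copy()
    while True:
        module_ids = [m for m in np.unique(labels) if m >= 0]
        if len(module_ids) < 2:
            return labels
        mes = np.column_stack(
            [_module_eigengene(values[:, labels == m])[0] for m in module_ids]
        )
        cor = np.corrcoef(mes.T)
        dis = 1.0 - cor
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= cut_height:
            return labels
        labels[labels == module_ids[j]] = module_ids[i]


def detect_modules(
    expr: ExpressionMatrix, config: NetworkConfig = NetworkConfig()
) -> tuple[ModuleSet, EigengeneMatrix]:
    """Detect coexpression modules and compute their eigengenes.

    When ``config.beta`` is None the soft threshold is picked by the
    scale-free criterion first. Raises no error on sparse structure: if no
    cluster reaches ``min_module_size`` every gene is labelled grey (with a
    warning) and the eigengene matrix is empty.
    """
    genes = expr.gene_ids
    values = expr.values.to_numpy(float)
    if config.beta is None:
        beta, _ = pick_soft_threshold(expr, config)
    else:
        beta = config.beta

    if len(genes) < config.min_module_size:
        logger.warning("fewer genes than min_module_size: all genes grey")
        modules = ModuleSet(
            {g: GREY for g in genes},
            None,
            config.min_module_size,
            config.merge_cut_height,
        )
        return modules, EigengeneMatrix(
            pd.DataFrame(index=expr.values.index), {}, {}
        )

    cor = bicor_matrix(values, config.max_p_outliers)
    adj = signed_adjacency(cor, beta)
    tom = tom_similarity(adj)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    linkage = sch.linkage(squareform(dissim, checks=False), method="average")

    labels = _initial_cut(linkage, len(genes), config.min_module_size)
    labels = _kme_reassign(
        labels, values, config.kme_threshold, config.min_module_size
    )
    labels = _merge_by_eigengene(labels, values, config.merge_cut_height)

    # color labels by decreasing size
    module_ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    order = module_ids[np.argsort(-counts, kind="stable")]
    palette = {
        m: COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module{i + 1}"
        for i, m in enumerate(order)
    }
    assignments = {
        g: palette[l] if l >= 0 else GREY for g, l in zip(genes, labels)
    }
    modules = ModuleSet(
        assignments, linkage, config.min_module_size, config.merge_cut_height
    )
    if not modules.module_names:
        logger.warning("no module reached min_module_size: all genes grey")
        return modules, EigengeneMatrix(pd.DataFrame(index=expr.values.index), {}, {})
    eigengenes = compute_eigengenes(expr, modules, config.max_p_outliers)
    return modules, eigengenes
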