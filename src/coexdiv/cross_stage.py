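"""Cross-stage comparison: module preservation, overlap tables, consensus.

Z_summary composition. The preservation statistic is a composite of density
and connectivity summaries, each permutation-standardised against random
gene sets of the same size drawn from the test data:

* density (test data only): mean within-module signed adjacency, mean
  within-module correlation, eigengene explained-variance fraction;
* connectivity (reference vs test): correlation of intramodular
  connectivity (kIM), of module membership (kME), and of the within-module
  gene-gene correlations.

Z_density and Z_connectivity are the medians of their groups' Z-scores and
Z_summary is their mean. Evidence classes follow the conventional 2/10
thresholds: < 2 no evidence, 2-10 weak-to-moderate, > 10 strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_pipeline import ExpressionMatrix
from .module_trait import bh_adjust
from .network import (
    GREY,
    COLOR_PALETTE,
    EigengeneMatrix,
    ModuleSet,
    NetworkConfig,
    _initial_cut,
    _kme_table,
    _merge_by_eigengene,
    _module_eigengene,
    bicor_matrix,
    compute_eigengenes,
    signed_adjacency,
    tom_similarity,
)

import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "PreservationStats",
    "OverlapTable",
    "module_preservation",
    "module_overlap_table",
    "consensus_modules",
    "evidence_class",
]


def evidence_class(z_summary: float) -> str:
    if z_summary < 2.0:
        return "none"
    if z_summary <= 10.0:
        return "weak-to-moderate"
    return "strong"


@dataclass
class PreservationStats:
    table: pd.DataFrame  # index module; Z_density, Z_connectivity, Z_summary, size, evidence
    n_perm: int


def _corr(values: np.ndarray, method: str, max_p_outliers: float) -> np.ndarray:
    if method == "pearson":
        return np.corrcoef(values.T)
    return bicor_matrix(values, max_p_outliers)


def _module_stats(
    ref_cor: np.ndarray,
    test_values: np.ndarray,
    beta: int,
    method: str,
    max_p_outliers: float,
) -> np.ndarray:
    """Six preservation statistics for one candidate gene set."""
    test_cor = _corr(test_values, method, max_p_outliers)
    ref_adj = signed_adjacency(ref_cor, beta)
    test_adj = signed_adjacency(test_cor, beta)
    p = test_cor.shape[0]
    off = ~np.eye(p, dtype=bool)
    iu = np.triu_indices(p, 1)

    mean_adj = test_adj[off].mean()
    mean_cor = test_cor[off].mean()
    me, frac = _module_eigengene(test_values)

    k_ref = ref_adj.sum(axis=1) - 1.0
    k_test = test_adj.sum(axis=1) - 1.0
    cor_kim = _safe_cor(k_ref, k_test)
    cor_cor = _safe_cor(ref_cor[iu], test_cor[iu])

    ref_me, _ = _module_eigengene_from_cor(ref_cor)
    kme_test = _kme_against(test_values, me)
    kme_ref = ref_me
    cor_kme = _safe_cor(kme_ref, kme_test)
    return np.array([mean_adj, mean_cor, frac, cor_kim, cor_kme, cor_cor])


def _module_eigengene_from_cor(cor: np.ndarray) -> tuple[np.ndarray, float]:
    # leading eigenvector of the correlation matrix doubles as a kME profile
    w, v = np.linalg.eigh(cor)
    lead = v[:, -1]
    if lead.sum() < 0:
        lead = -lead
    return lead * np.sqrt(max(w[-1], 0.0)), float(w[-1] / np.clip(w, 0, None).sum())


def _kme_against(values: np.ndarray, me: np.ndarray) -> np.ndarray:
    vc = values - values.mean(axis=0)
    mc = me - me.mean()
    denom = np.linalg.norm(vc, axis=0) * np.linalg.norm(mc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = vc.T @ mc / denom
    return np.nan_to_num(r)


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def module_preservation(
    ref_expr: ExpressionMatrix,
    ref_modules: ModuleSet,
    test_expr: ExpressionMatrix,
    n_perm: int = 1000,
    beta: int = 20,
    cor_method: str = "pearson",
    max_p_outliers: float = 0.1,
    seed: int | None = None,
    min_common: int = 3,
) -> PreservationStats:
    """Permutation Z_summary of reference modules evaluated in test data.

    Computed on the intersection of the two gene universes. The null draws
    random gene sets of matching size from the test data (a random
    permutation of module labels); each statistic is standardised as
    (observed - null mean) / null sd.
    """
    common = [g for g in ref_expr.gene_ids if g in set(test_expr.gene_ids)]
    if not common:
        raise ValueError("gene universes do not intersect")
    ref_vals = ref_expr.subset_genes(common).values.to_numpy(float)
    test_vals = test_expr.subset_genes(common).values.to_numpy(float)
    index = {g: i for i, g in enumerate(common)}
    rng = np.random.default_rng(seed)

    rows = []
    for m in ref_modules.module_names:
        genes = [g for g in ref_modules.genes_of(m) if g in index]
        if len(genes) < min_common:
            continue
        idx = np.array([index[g] for g in genes])
        ref_cor = _corr(ref_vals[:, idx], cor_method, max_p_outliers)
        obs = _module_stats(ref_cor, test_vals[:, idx], beta, cor_method, max_p_outliers)
        null = np.empty((n_perm, len(obs)))
        for b in range(n_perm):
            ridx = rng.choice(len(common), size=len(idx), replace=False)
            null[b] = _module_stats(
                ref_cor, test_vals[:, ridx], beta, cor_method, max_p_outliers
            )
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (obs - mu) / sd
        z = np.where(sd == 0, 0.0, z)
        z_density = float(np.median(z[:3]))
        z_conn = float(np.median(z[3:]))
        z_summary = (z_density + z_conn) / 2.0
        rows.append(
            {
                "module": m,
                "size": len(genes),
                "Z_density": z_density,
                "Z_connectivity": z_conn,
                "Z_summary": z_summary,
                "evidence": evidence_class(z_summary),
            }
        )
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    return PreservationStats(table, n_perm)


# ---------------------------------------------------------------------------
# cross-tabulation


@dataclass
class OverlapTable:
    counts: pd.DataFrame  # modules_A x modules_B shared gene counts (incl grey)
    p: pd.DataFrame  # Fisher p per non-grey cell (NaN for grey)
    q: pd.DataFrame  # BH across non-grey cells


def module_overlap_table(modules_a: ModuleSet, modules_b: ModuleSet) -> OverlapTable:
    """Cross-tabulate gene assignments of two partitions with Fisher tests.

    Counts cover the full common gene universe (grey included, so the grand
    total equals the number of shared genes); the per-cell Fisher tests and
    the BH correction are restricted to genes non-grey in both partitions.
    """
    universe = [g for g in modules_a.assignments if g in modules_b.assignments]
    if not universe:
        raise ValueError("disjoint gene universes")
    a_lab = {g: modules_a.assignments[g] for g in universe}
    b_lab = {g: modules_b.assignments[g] for g in universe}
    rows = modules_a.module_names + ([GREY] if GREY in set(a_lab.values()) else [])
    cols = modules_b.module_names + ([GREY] if GREY in set(b_lab.values()) else [])
    counts = pd.DataFrame(0, index=rows, columns=cols)
    for g in universe:
        counts.loc[a_lab[g], b_lab[g]] += 1

    test_universe = [g for g in universe if a_lab[g] != GREY and b_lab[g] != GREY]
    n = len(test_universe)
    p = pd.DataFrame(np.nan, index=rows, columns=cols)
    for ma in modules_a.module_names:
        in_a = {g for g in test_universe if a_lab[g] == ma}
        for mb in modules_b.module_names:
            in_b = {g for g in test_universe if b_lab[g] == mb}
            both = len(in_a & in_b)
            table = [
                [both, len(in_a) - both],
                [len(in_b) - both, n - len(in_a) - len(in_b) + both],
            ]
            p.loc[ma, mb] = sps.fisher_exact(table, alternative="two-sided")[1]

    q = p.copy()
    mask = ~p.isna()
    flat = p.to_numpy()[mask.to_numpy()]
    if flat.size:
        q.to_numpy()[mask.to_numpy()] = bh_adjust(flat)
    return OverlapTable(counts, p, q)


# ---------------------------------------------------------------------------
# consensus modules


def consensus_modules(
    expr_list: list[ExpressionMatrix],
    beta: int = 20,
    min_module_size: int = 30,
    merge_cut_height: float = 0.25,
    max_p_outliers: float = 0.1,
    quantile: float = 0.95,
) -> tuple[ModuleSet, list[EigengeneMatrix]]:
    """Modules coexpressed consistently across datasets, from a min-TOM.

    Per-dataset TOMs are brought to a common scale by power-transforming
    each so its ``quantile`` off-diagonal quantile matches the geometric
    mean of the datasets' quantiles (a symmetric variant of quantile
    calibration, so the result does not depend on dataset order); the
    consensus TOM is their elementwise minimum. Detection then follows the
    single-dataset procedure, except that two modules merge only when their
    eigengenes are close in every dataset. Eigengenes are returned per
    dataset.
    """
    if len(expr_list) < 2:
        raise ValueError("consensus needs at least 2 datasets")
    common = set(expr_list[0].gene_ids)
    for e in expr_list[1:]:
        common &= set(e.gene_ids)
    genes = [g for g in expr_list[0].gene_ids if g in common]
    if len(genes) < 30:
        raise ValueError(f"only {len(genes)} shared genes; need >= 30")
    subs = [e.subset_genes(genes) for e in expr_list]

    toms = []
    quantiles = []
    iu = np.triu_indices(len(genes), 1)
    for sub in subs:
        cor = bicor_matrix(sub.values.to_numpy(float), max_p_outliers)
        tom = tom_similarity(signed_adjacency(cor, beta))
        toms.append(tom)
        quantiles.append(np.quantile(tom[iu], quantile))
    target = float(np.exp(np.mean(np.log(np.clip(quantiles, 1e-300, 1.0)))))
    scaled = []
    for tom, qd in zip(toms, quantiles):
        if 0.0 < qd < 1.0 and 0.0 < target < 1.0:
            tom = tom ** (np.log(target) / np.log(qd))
        scaled.append(tom)
    consensus = np.minimum.reduce(scaled)
    np.fill_diagonal(consensus, 1.0)

    dissim = 1.0 - consensus
    np.fill_diagonal(dissim, 0.0)
    linkage = sch.linkage(squareform(dissim, checks=False), method="average")
    labels = _initial_cut(linkage, len(genes), min_module_size)
    labels = _consensus_kme_reassign(
        labels,
        [s.values.to_numpy(float) for s in subs],
        kme_threshold=0.55,
        min_module_size=min_module_size,
    )
    labels = _merge_consensus_eigengene(
        labels, [s.values.to_numpy(float) for s in subs], merge_cut_height
    )

    module_ids, sizes = np.unique(labels[labels >= 0], return_counts=True)
    order = module_ids[np.argsort(-sizes, kind="stable")]
    palette = {
        m: COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module{i + 1}"
        for i, m in enumerate(order)
    }
    assignments = {g: palette[l] if l >= 0 else GREY for g, l in zip(genes, labels)}
    modules = ModuleSet(assignments, linkage, min_module_size, merge_cut_height)
    eigengenes = [
        compute_eigengenes(sub, modules, max_p_outliers) if modules.module_names
        else EigengeneMatrix(pd.DataFrame(index=sub.values.index), {}, {})
        for sub in subs
    ]
    return modules, eigengenes


def _consensus_kme_reassign(
    labels: np.ndarray,
    values_list: list[np.ndarray],
    kme_threshold: float,
    min_module_size: int,
    max_iter: int = 3,
) -> np.ndarray:
    """Reassign genes by consensus module membership.

    A gene's consensus membership for a module is the minimum over datasets
    of |kME|, so a gene joins only when it tracks the module's eigengene in
    every dataset — the membership analogue of the min-TOM rule.
    """
    labels = labels.copy()
    n = values_list[0].shape[1]
    for _ in range(max_iter):
        module_ids = [m for m in np.unique(labels) if m >= 0]
        if not module_ids:
            return labels
        kme = np.minimum.reduce(
            [np.abs(_kme_table(v, labels, module_ids)) for v in values_list]
        )
        best = np.argmax(kme, axis=1)
        best_val = kme[np.arange(n), best]
        new = np.where(best_val >= kme_threshold, np.asarray(module_ids)[best], -1)
        for m in np.unique(new[new >= 0]):
            if (new == m).sum() < min_module_size:
                new[new == m] = -1
        if (new == labels).all():
            break
        labels = new
    return labels


def _merge_consensus_eigengene(
    labels: np.ndarray, values_list: list[np.ndarray], cut_height: float
) -> np.ndarray:
    """Merge module pairs whose eigengene dissimilarity stays below the cut
    in every dataset (consensus dissimilarity = max over datasets)."""
    labels = labels.copy()
    while True:
        module_ids = [m for m in np.unique(labels) if m >= 0]
        if len(module_ids) < 2:
            return labels
        dis = np.zeros((len(module_ids), len(module_ids)))
        for values in values_list:
            mes = np.column_stack(
                [_module_eigengene(values[:, labels == m])[0] for m in module_ids]
            )
            d = 1.0 - np.corrcoef(mes.T)
            dis = np.maximum(dis, d)
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= cut_height:
            return labels
        labels[labels == module_ids[j]] = module_ids[i]
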