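"""Eigengene-trait association, candidate selection and DE enrichment.

The trait is the binary benthic/limnetic state (benthic = 0, limnetic = 1,
so a positive correlation means overexpression in limnetic samples). The
eigengene-trait correlation is a hybrid biweight midcorrelation: robust
weighting on the eigengene margin, plain centering on the binary margin
(robust estimation is inappropriate for a 0/1 predictor). Significance uses
the Student-t transform with n - 2 degrees of freedom, with
Benjamini-Hochberg control across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_pipeline import ExpressionMatrix
from .network import EigengeneMatrix, ModuleSet, hybrid_bicor

__all__ = [
    "ModuleTraitStats",
    "eigengene_trait_association",
    "bh_adjust",
    "select_candidates",
    "fisher_module_enrichment",
]


@dataclass
class ModuleTraitStats:
    """Per-module association statistics plus per-gene GS where available."""

    table: pd.DataFrame  # index module; columns r, p, q, selected
    gene_significance: dict[str, float]  # gene -> bicor(expression, trait)
    kme: dict[str, float]
    fdr_level: float

    @property
    def selected_modules(self) -> list[str]:
        return [m for m in self.table.index if bool(self.table.loc[m, "selected"])]


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided Student-t p-value for a correlation at n - 2 df."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def eigengene_trait_association(
    eigengenes: EigengeneMatrix,
    trait: pd.Series | np.ndarray,
    fdr_level: float = 0.05,
    max_p_outliers: float = 0.1,
    expr: ExpressionMatrix | None = None,
) -> ModuleTraitStats:
    """Correlate every module eigengene with the binary trait, with BH FDR.

    When ``expr`` is supplied, per-gene gene significance (GS, the hybrid
    bicor of each gene's expression with the trait) is computed as well,
    enabling candidate selection.
    """
    scores = eigengenes.scores
    trait_vec = np.asarray(trait, float)
    if len(trait_vec) != len(scores.index):
        raise ValueError("trait length does not match eigengene samples")
    if np.ptp(trait_vec) == 0:
        raise ValueError("trait is constant")
    n = len(trait_vec)
    rows = []
    for m in scores.columns:
        me = scores[m].to_numpy(float)
        if np.ptp(me) == 0:
            raise ValueError(f"constant eigengene for module {m!r}")
        r = hybrid_bicor(me, trait_vec, max_p_outliers)
        rows.append({"module": m, "r": r, "p": correlation_p_value(r, n)})
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
        columns=["r", "p"], index=pd.Index([], name="module")
    )
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["selected"] = table["q"] <= fdr_level if len(table) else []

    gs: dict[str, float] = {}
    if expr is not None:
        values = expr.values
        for g in expr.gene_ids:
            x = values[g].to_numpy(float)
            if np.ptp(x) == 0:
                gs[g] = np.nan
            else:
                gs[g] = hybrid_bicor(x, trait_vec, max_p_outliers)
    return ModuleTraitStats(table, gs, dict(eigengenes.kme), fdr_level)


def select_candidates(
    stats: ModuleTraitStats,
    modules: ModuleSet,
    threshold: float = 0.7,
) -> dict[str, list[str]]:
    """Genes of each selected module with |kME| > threshold AND |GS| > threshold.

    Strict inequalities on both criteria; absolute values, so strongly
    benthic-overexpressed genes qualify as well.
    """
    if not stats.gene_significance:
        raise ValueError("gene significance not computed: pass expr to the association")
    out: dict[str, list[str]] = {}
    for m in stats.selected_modules:
        picked = []
        for g in modules.genes_of(m):
            kme = stats.kme.get(g, np.nan)
            gs = stats.gene_significance.get(g, np.nan)
            if np.isfinite(kme) and np.isfinite(gs) and abs(kme) > threshold and abs(gs) > threshold:
                picked.append(g)
        out[m] = picked
    return out


def fisher_module_enrichment(
    module_genes: list[str],
    de_flags: dict[str, bool],
    background: list[str],
) -> tuple[float, float]:
    """Fisher exact test for DE-gene enrichment of a module.

    The contrast is module members versus genes outside any selected module;
    ``background`` must contain the tested module's genes plus the
    outside-any-selected-module genes, each with a DE flag. Returns
    (sample odds ratio, two-sided p by hypergeometric tail summation);
    the odds ratio is NaN when a margin is empty (in which case p = 1).
    """
    missing = [g for g in background if g not in de_flags]
    if missing:
        raise ValueError(f"genes without DE flag: {missing[:5]}")
    module_set = set(module_genes)
    in_de = sum(1 for g in background if g in module_set and de_flags[g])
    in_not = sum(1 for g in background if g in module_set and not de_flags[g])
    out_de = sum(1 for g in background if g not in module_set and de_flags[g])
    out_not = sum(1 for g in background if g not in module_set and not de_flags[g])
    table = np.array([[in_de, in_not], [out_de, out_not]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
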