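"""Permutation validation of coexpression modules.

Two tests, both reporting p as the proportion of permuted statistics larger
than or equal to the observed one (the plain empirical convention; a
``plus_one`` option gives the (b+1)/(m+1) estimator instead):

* an eigenvalue test in the spirit of parallel analysis — is the variance
  explained by a module's first principal component larger than expected
  when the association between genes is destroyed by permuting each gene's
  values independently across samples?
* a multivariate association test — is the Escoufier RV coefficient between
  a module's expression matrix and the binary benthic/limnetic trait larger
  than under random relabelling of the trait?
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .network import bicor_matrix

logger = logging.getLogger("coexdiv")

__all__ = [
    "PermutationTestResult",
    "eigenvalue_permutation_test",
    "rv_coefficient",
    "rv_permutation_test",
]


@dataclass
class PermutationTestResult:
    observed_stat: float
    null_stats: np.ndarray
    n_perm: int
    p: float
    stat_name: str
    seed: int | None


def _empirical_p(observed: float, null: np.ndarray, plus_one: bool) -> float:
    b = int((null >= observed).sum())
    if plus_one:
        return (b + 1) / (len(null) + 1)
    return b / len(null)


def _explained_variance_first(values: np.ndarray, cor_type: str, max_p_outliers: float) -> float:
    if cor_type == "pearson":
        c = np.corrcoef(values.T)
    elif cor_type == "bicor":
        c = bicor_matrix(values, max_p_outliers)
    else:
        raise ValueError(f"unknown cor_type: {cor_type!r}")
    eig = np.linalg.eigvalsh(c)
    eig = np.clip(eig, 0.0, None)
    return float(eig[-1] / eig.sum())


def eigenvalue_permutation_test(
    module_expr: np.ndarray,
    n_perm: int = 1000,
    cor_type: str = "pearson",
    max_p_outliers: float = 0.1,
    seed: int | None = None,
    per_column: bool = True,
    plus_one: bool = False,
) -> PermutationTestResult:
    """Test the variance explained by a module's first eigenvalue.

    ``module_expr`` is samples x genes. The null permutes each gene's values
    independently across samples, breaking inter-gene association while
    preserving each gene's marginal distribution (``per_column=False``
    applies one joint permutation to whole samples instead, which provably
    leaves the correlation matrix unchanged — kept only as a demonstrator).
    """
    x = np.asarray(module_expr, float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a samples x genes matrix with >= 3 samples, >= 2 genes")
    const = np.ptp(x, axis=0) == 0
    if const.any():
        logger.warning("dropping %d constant gene(s) from eigenvalue test", const.sum())
        x = x[:, ~const]
        if x.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant genes")
    observed = _explained_variance_first(x, cor_type, max_p_outliers)
    rng = np.random.default_rng(seed)
    n, p = x.shape
    null = np.empty(n_perm)
    for b in range(n_perm):
        if per_column:
            perm = np.empty_like(x)
            for j in range(p):
                perm[:, j] = x[rng.permutation(n), j]
        else:
            perm = x[rng.permutation(n)]
        null[b] = _explained_variance_first(perm, cor_type, max_p_outliers)
    return PermutationTestResult(
        observed_stat=observed,
        null_stats=null,
        n_perm=n_perm,
        p=_empirical_p(observed, null, plus_one),
        stat_name=f"lambda1_fraction_{cor_type}",
        seed=seed,
    )


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Escoufier RV coefficient between two matrices of the same observations.

    RV = trace(Sxy Syx) / sqrt(trace(Sxx^2) trace(Syy^2)) on column-centred
    data; for single-column matrices it reduces to the squared Pearson
    correlation.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of observations")
    if X.shape[0] < 3:
        raise ValueError("RV needs at least 3 observations")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.linalg.norm(Xc.T @ Xc)  # Frobenius norm = sqrt(trace(Sxx^2))
    syy = np.linalg.norm(Yc.T @ Yc)
    if sxx == 0 or syy == 0:
        raise ValueError("zero total variance in X or Y")
    sxy = np.linalg.norm(Xc.T @ Yc) ** 2  # trace(Sxy Syx)
    return float(sxy / (sxx * syy))


def rv_permutation_test(
    module_expr: np.ndarray,
    trait: np.ndarray,
    n_perm: int = 100,
    seed: int | None = None,
    plus_one: bool = False,
) -> PermutationTestResult:
    """RV-based multivariate association between module expression and trait.

    The observed statistic is RV(module expression, trait-as-one-column);
    the null permutes the benthic/limnetic labels while the expression
    matrix stays fixed.
    """
    x = np.asarray(module_expr, float)
    t = np.asarray(trait, float).reshape(-1, 1)
    if np.ptp(t) == 0:
        raise ValueError("trait is constant")
    if n_perm < 20:
        logger.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    observed = rv_coefficient(x, t)
    rng = np.random.default_rng(seed)
    # only the cross-product with the trait changes under relabelling
    Xc = x - x.mean(axis=0)
    sxx = np.linalg.norm(Xc.T @ Xc)
    null = np.empty(n_perm)
    for b in range(n_perm):
        tp = t[rng.permutation(len(t))]
        tc = tp - tp.mean()
        syy = np.linalg.norm(tc.T @ tc)
        null[b] = np.linalg.norm(Xc.T @ tc) ** 2 / (sxx * syy)
    return PermutationTestResult(
        observed_stat=observed,
        null_stats=null,
        n_perm=n_perm,
        p=_empirical_p(observed, null, plus_one),
        stat_name="escoufier_rv",
        seed=seed,
    )
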