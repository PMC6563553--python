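"""Count filtering, variance stabilisation and connectivity-based outlier removal.

The variance-stabilising step here is a deliberate, documented approximation:
median-of-ratios size factors (computed over genes with all-positive counts)
followed by ``log2(count / size_factor + 1)``. It shares the intent of a
dispersion-trend VST — abundances comparable across libraries, variance
roughly independent of the mean at high counts — without re-deriving a
negative-binomial dispersion trend. ``vst`` accepts a ``transformed`` hook so
an externally computed matrix can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_pipeline import CountMatrix, ExpressionMatrix

__all__ = [
    "filter_low_counts",
    "vst",
    "size_factors",
    "remove_outlier_samples",
    "FilterResult",
    "OutlierReport",
]


@dataclass
class FilterResult:
    counts: CountMatrix
    n_removed: int


def filter_low_counts(
    counts: CountMatrix,
    stage_labels: pd.Series,
    total_min: int = 100,
    per_stage_min: int = 50,
) -> FilterResult:
    """Drop transcripts below the total and per-stage read thresholds.

    A transcript is retained iff its total count across all samples is
    >= ``total_min`` AND its summed count within *every* stage is
    >= ``per_stage_min`` (the stricter AND reading of the two clauses;
    per-stage counts are sums over that stage's samples).
    """
    missing = set(counts.sample_ids) - set(stage_labels.index)
    if missing:
        raise ValueError(f"samples without a stage label: {sorted(missing)}")
    labels = stage_labels.loc[counts.sample_ids]
    arr = counts.counts.to_numpy()
    keep = arr.sum(axis=1) >= total_min
    for stage in labels.unique():
        cols = (labels == stage).to_numpy()
        keep &= arr[:, cols].sum(axis=1) >= per_stage_min
    kept = counts.counts.loc[keep]
    return FilterResult(
        CountMatrix(kept, counts.metadata), int(len(counts.counts) - len(kept))
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    arr = counts.to_numpy(float)
    if (arr.sum(axis=0) == 0).any():
        bad = counts.columns[arr.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    sub = arr[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def vst(counts: CountMatrix, transformed: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Variance-stabilise counts; returns a samples-x-genes matrix.

    ``transformed`` (genes x samples) bypasses the built-in transform — the
    hook for plugging in an externally computed stabilised matrix.
    """
    if transformed is not None:
        return ExpressionMatrix(transformed.T, counts.metadata)
    sf = size_factors(counts.counts)
    values = np.log2(counts.counts.to_numpy(float) / sf.to_numpy()[None, :] + 1.0)
    frame = pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionMatrix(frame.T, counts.metadata)


@dataclass
class OutlierEntry:
    sample_id: str
    z_k: float
    removed: bool


@dataclass
class OutlierReport:
    threshold: float
    iterations: list[list[OutlierEntry]] = field(default_factory=list)

    @property
    def removed_samples(self) -> list[str]:
        return [e.sample_id for it in self.iterations for e in it if e.removed]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "iterations": [
                [
                    {"sample_id": e.sample_id, "z_k": e.z_k, "removed": e.removed}
                    for e in it
                ]
                for it in self.iterations
            ],
        }


def _standardized_connectivity(values: np.ndarray) -> np.ndarray:
    # sample-sample signed-square adjacency on Pearson correlations
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(values)
    r = np.nan_to_num(r, nan=1.0)  # constant samples correlate as identical
    adj = ((1.0 + r) / 2.0) ** 2
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    sd = k.std(ddof=1)
    if sd == 0:
        return np.zeros_like(k)
    return (k - k.mean()) / sd


def remove_outlier_samples(
    expr: ExpressionMatrix, z_threshold: float = -2.0
) -> tuple[ExpressionMatrix, OutlierReport]:
    """Iteratively drop samples whose standardized connectivity Z.k < threshold.

    Each iteration builds the sample network A_ij = ((1 + cor_ij)/2)^2,
    standardizes total connectivity, removes every sample below the
    threshold, and repeats on the remainder until no sample is removed.
    """
    if len(expr.sample_ids) < 4:
        raise ValueError("outlier removal needs at least 4 samples")
    report = OutlierReport(threshold=float(z_threshold))
    current = expr
    while True:
        zk = _standardized_connectivity(current.values.to_numpy())
        removed_mask = zk < z_threshold
        report.iterations.append(
            [
                OutlierEntry(sid, float(z), bool(rm))
                for sid, z, rm in zip(current.sample_ids, zk, removed_mask)
            ]
        )
        if not removed_mask.any():
            return current, report
        keep = [s for s, rm in zip(current.sample_ids, removed_mask) if not rm]
        if len(keep) < 3:
            raise ValueError(
                f"outlier removal would leave {len(keep)} samples; "
                f"removed so far: {report.removed_samples}"
            )
        current = current.subset_samples(keep)
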