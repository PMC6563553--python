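"""Permutation testing of genomic overlap between gene sets and QTL regions.

The randomisation respects genome structure: each query interval is
re-placed uniformly at random within its own linkage group with its length
preserved, so modules with many genes and large QTL regions are penalised
exactly as they should be. Overlap is counted as the number of query
intervals with at least 1 bp of (half-open) intersection with the subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_pipeline import RegionSet
from .module_trait import bh_adjust

__all__ = [
    "OverlapTestResult",
    "count_overlaps",
    "region_permutation_test",
    "overlap_battery",
]


@dataclass
class OverlapTestResult:
    name: str
    observed: int
    null_stats: np.ndarray
    n_perm: int
    p: float
    z: float
    q: float = float("nan")
    degenerate: bool = False


def _merged_subject(subject: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per linkage group, merged (disjoint, sorted) subject starts/ends."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, block in subject.frame.groupby("chrom", sort=False):
        ivs = block[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        starts.append(cur_s)
        ends.append(cur_e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def _count_against(
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> int:
    total = 0
    for chrom in np.unique(chroms):
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        sel = chroms == chrom
        s, e = starts[sel], ends[sel]
        # last merged interval starting strictly before the query end
        idx = np.searchsorted(ms, e, side="left") - 1
        hit = (idx >= 0) & (me[np.clip(idx, 0, None)] > s)
        total += int(hit.sum())
    return total


def count_overlaps(query: RegionSet, subject: RegionSet) -> int:
    """Number of query intervals intersecting >= 1 subject interval."""
    if len(query) == 0 or len(subject) == 0:
        return 0
    merged = _merged_subject(subject)
    f = query.frame
    return _count_against(
        merged,
        f["chrom"].to_numpy(),
        f["start"].to_numpy(),
        f["end"].to_numpy(),
    )


def region_permutation_test(
    query: RegionSet,
    subject: RegionSet,
    n_perm: int = 1000,
    seed: int | None = None,
    plus_one: bool = False,
    name: str = "overlap",
) -> OverlapTestResult:
    """One-sided enrichment test of query/subject overlap by re-placement.

    Each permutation re-draws every query interval's start uniformly over
    the valid positions of its own linkage group (length preserved) and
    recounts overlaps; p is the proportion of null counts >= observed.
    """
    genome = query.genome or subject.genome
    if genome is None:
        raise ValueError("a genome (linkage-group lengths) is required")
    f = query.frame
    if len(f) == 0:
        return OverlapTestResult(
            name, 0, np.zeros(n_perm, int), n_perm, 1.0, 0.0, degenerate=True
        )
    chroms = f["chrom"].to_numpy()
    lens = (f["end"] - f["start"]).to_numpy()
    chrom_len = np.array([genome[c] for c in chroms])
    max_start = chrom_len - lens
    if (max_start < 0).any():
        bad = f.iloc[int(np.argmax(max_start < 0))]
        raise ValueError(f"interval {bad['name']!r} longer than its linkage group")

    merged = _merged_subject(subject)
    observed = _count_against(merged, chroms, f["start"].to_numpy(), f["end"].to_numpy())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, int)
    for b in range(n_perm):
        starts = (rng.random(len(f)) * (max_start + 1)).astype(np.int64)
        null[b] = _count_against(merged, chroms, starts, starts + lens)
    n_ge = int((null >= observed).sum())
    p = (n_ge + 1) / (n_perm + 1) if plus_one else n_ge / n_perm
    sd = null.std(ddof=1)
    z = (observed - null.mean()) / sd if sd > 0 else 0.0
    return OverlapTestResult(name, observed, null, n_perm, float(p), float(z))


def overlap_battery(
    gene_sets: dict[str, RegionSet],
    qtl_sets: dict[str, RegionSet],
    combined: bool = True,
    n_perm: int = 1000,
    seed: int | None = None,
    plus_one: bool = False,
) -> list[OverlapTestResult]:
    """All (gene set x QTL set) permutation tests, with BH across the battery.

    With ``combined`` the union of all QTL sets is tested as an extra
    subject ("all_qtl"). Empty gene sets yield a degenerate result
    (observed 0, p = 1) that still enters the BH correction.
    """
    if not gene_sets or not qtl_sets:
        raise ValueError("need at least one gene set and one QTL set")
    subjects = dict(qtl_sets)
    if combined and len(qtl_sets) > 1:
        frames = [q.frame for q in qtl_sets.values()]
        import pandas as pd

        genome = next(iter(qtl_sets.values())).genome
        subjects["all_qtl"] = RegionSet(pd.concat(frames, ignore_index=True), genome)
    results = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(gene_sets) * len(subjects)) % (2**31)
    i = 0
    for gname, gset in gene_sets.items():
        for qname, qset in subjects.items():
            results.append(
                region_permutation_test(
                    gset,
                    qset,
                    n_perm=n_perm,
                    seed=int(seeds[i]),
                    plus_one=plus_one,
                    name=f"{gname}|{qname}",
                )
            )
            i += 1
    qs = bh_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
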