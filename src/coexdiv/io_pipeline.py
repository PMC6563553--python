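"""On-disk formats, run configuration and the stage-by-stage orchestrator.

Conventions: counts live on disk as genes-x-samples TSV (the RNA-seq
convention); all in-memory network math uses samples-x-genes matrices.
The transpose happens exactly once, inside :meth:`CountMatrix.to_expression`
(via :func:`coexdiv.preprocess.vst`). Genomic intervals are 0-based
half-open (BED). All file writes are atomic (write to a temp file in the
target directory, then rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("coexdiv")

__all__ = [
    "SampleMetadata",
    "CountMatrix",
    "ExpressionMatrix",
    "RegionSet",
    "PipelineConfig",
    "RunInputs",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_regions",
    "write_regions",
    "atomic_write_text",
    "run_pipeline",
]


class FormatError(ValueError):
    """A file does not satisfy its format contract."""


# ---------------------------------------------------------------------------
# containers


class SampleMetadata:
    """Per-sample annotations: stage, morph (benthic/limnetic), species, lake."""

    REQUIRED = ("sample_id", "stage", "morph")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id: {dup!r}")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def column(self, name: str) -> pd.Series:
        return self.frame.set_index("sample_id")[name]

    def trait_vector(self, coding: dict[str, int] | None = None) -> pd.Series:
        """Binary morph coding, benthic = 0 / limnetic = 1 by default."""
        coding = coding or {"benthic": 0, "limnetic": 1}
        morph = self.column("morph")
        if morph.isna().any():
            raise ValueError("morph is missing for some samples")
        unknown = set(morph) - set(coding)
        if unknown:
            raise ValueError(f"unknown morph values: {sorted(unknown)}")
        trait = morph.map(coding).astype(float)
        if trait.nunique() < 2:
            raise ValueError("trait is constant: both morphs must be present")
        return trait

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        keep = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleMetadata(keep)


class CountMatrix:
    """Raw non-negative integer read counts, genes x samples, plus metadata."""

    def __init__(self, counts: pd.DataFrame, metadata: SampleMetadata):
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        if list(counts.columns) != metadata.sample_ids:
            meta_set = set(metadata.sample_ids)
            if set(counts.columns) != meta_set:
                raise FormatError("counts columns do not match metadata sample_ids")
            metadata = SampleMetadata(
                metadata.frame.set_index("sample_id").loc[list(counts.columns)].reset_index()
            )
        self.counts = counts
        self.metadata = metadata

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.metadata)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)], self.metadata.subset(sample_ids)
        )

    def concat_samples(self, other: "CountMatrix") -> "CountMatrix":
        if list(self.counts.index) != list(other.counts.index):
            common = self.counts.index.intersection(other.counts.index)
            a, b = self.counts.loc[common], other.counts.loc[common]
        else:
            a, b = self.counts, other.counts
        meta = SampleMetadata(
            pd.concat([self.metadata.frame, other.metadata.frame], ignore_index=True)
        )
        return CountMatrix(pd.concat([a, b], axis=1), meta)


class ExpressionMatrix:
    """Variance-stabilised abundances, samples x genes — the network unit."""

    def __init__(self, values: pd.DataFrame, metadata: SampleMetadata):
        if list(values.index) != metadata.sample_ids:
            metadata = metadata.subset(values.index)
            metadata = SampleMetadata(
                metadata.frame.set_index("sample_id").loc[list(values.index)].reset_index()
            )
        self.values = values
        self.metadata = metadata

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(genes)], self.metadata)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(sample_ids)], self.metadata.subset(sample_ids)
        )


class RegionSet:
    """Genomic intervals (0-based half-open) on named linkage groups."""

    COLUMNS = ("chrom", "start", "end", "name")

    def __init__(self, frame: pd.DataFrame, genome: dict[str, int] | None = None):
        frame = frame.reset_index(drop=True)
        if (frame["start"] >= frame["end"]).any():
            bad = frame[frame["start"] >= frame["end"]].iloc[0]
            raise FormatError(
                f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if (frame["start"] < 0).any():
            raise FormatError("negative interval start")
        if genome is not None:
            unknown = set(frame["chrom"]) - set(genome)
            if unknown:
                raise FormatError(f"intervals on unknown linkage groups: {sorted(unknown)}")
            for lg, length in genome.items():
                sel = frame["chrom"] == lg
                if (frame.loc[sel, "end"] > length).any():
                    raise FormatError(f"interval beyond the end of {lg}")
        self.frame = frame[list(self.COLUMNS)]
        self.genome = dict(genome) if genome is not None else None

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int, str]],
        genome: dict[str, int] | None = None,
    ) -> "RegionSet":
        frame = pd.DataFrame(records, columns=list(cls.COLUMNS))
        return cls(frame, genome)

    def __len__(self) -> int:
        return len(self.frame)

    def subset_names(self, names: Sequence[str]) -> "RegionSet":
        keep = self.frame[self.frame["name"].isin(set(names))]
        return RegionSet(keep, self.genome)

    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All stage parameters, with the study's published values as defaults."""

    # preprocess
    total_min: int = 100
    per_stage_min: int = 50
    zk_threshold: float = -2.0
    # network
    powers_scanned: tuple[int, ...] = tuple(range(1, 31))
    scale_free_r2_target: float = 0.9
    fallback_beta: int = 20
    beta: int | None = None  # None = pick by scale-free fit
    max_p_outliers: float = 0.1
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    # module-trait
    fdr_level: float = 0.05
    candidate_threshold: float = 0.7
    # permutation tests
    eig_permutations: int = 1000
    rv_permutations: int = 100
    preservation_permutations: int = 1000
    region_permutations: int = 1000
    consensus_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_min < 0 or self.per_stage_min < 0:
            raise ValueError("count filters must be non-negative")
        if not (0 < self.max_p_outliers <= 0.5):
            raise ValueError("max_p_outliers must be in (0, 0.5]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 <= self.merge_cut_height <= 1):
            raise ValueError("merge_cut_height must be in [0, 1]")
        if not (0 < self.fdr_level < 1):
            raise ValueError("fdr_level must be in (0, 1)")
        if not (0 <= self.candidate_threshold <= 1):
            raise ValueError("candidate_threshold must be in [0, 1]")
        for name in (
            "eig_permutations",
            "rv_permutations",
            "preservation_permutations",
            "region_permutations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.consensus_quantile < 1):
            raise ValueError("consensus_quantile must be in (0, 1)")
        if not all(p >= 1 for p in self.powers_scanned):
            raise ValueError("powers must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "powers_scanned" in data:
            data["powers_scanned"] = tuple(data["powers_scanned"])
        return cls(**data)


# ---------------------------------------------------------------------------
# readers / writers


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_to_csv(frame: pd.DataFrame, path: str | Path, **kwargs) -> None:
    atomic_write_text(path, frame.to_csv(sep="\t", lineterminator="\n", **kwargs))


def read_counts(path: str | Path, metadata: SampleMetadata | None = None) -> CountMatrix:
    """Read a genes-x-samples integer TSV; first column holds gene ids."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty counts file: {path}") from exc
    if frame.empty and frame.columns.empty:
        raise FormatError(f"empty counts file: {path}")
    for col in frame.columns:
        vals = frame[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals[~vals.apply(lambda v: float(v).is_integer())]
            where = f"sample {col!r}" + (f", gene {bad.index[0]!r}" if len(bad) else "")
            raise FormatError(f"non-integer count at {where}")
    frame = frame.astype(np.int64)
    if metadata is None:
        metadata = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": list(frame.columns),
                    "stage": "unknown",
                    "morph": pd.NA,
                    "species": pd.NA,
                    "lake": pd.NA,
                }
            )
        )
    return CountMatrix(frame, metadata)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    _atomic_to_csv(cm.counts, path, index_label="gene_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    _atomic_to_csv(meta.frame, path, index=False)


def read_regions(path: str | Path, genome: dict[str, int] | None = None) -> RegionSet:
    """Read BED3+ (chrom, start, end[, name]); 0-based half-open."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{i + 1}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"region{len(rows) + 1}"
            rows.append((chrom, start, end, name))
    if not rows:
        raise FormatError(f"empty BED file: {path}")
    return RegionSet.from_records(rows, genome)


def write_regions(rs: RegionSet, path: str | Path) -> None:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}"
        for r in rs.frame.itertuples(index=False)
    ]
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_genome(genome: dict[str, int], path: str | Path) -> None:
    atomic_write_text(
        path, "\n".join(f"{lg}\t{ln}" for lg, ln in genome.items()) + "\n"
    )


def read_genome(path: str | Path) -> dict[str, int]:
    genome: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                lg, ln = line.split("\t")
                genome[lg] = int(ln)
    return genome


# ---------------------------------------------------------------------------
# orchestrator


@dataclass
class RunInputs:
    """Inputs to a full run: stage-1 counts are required, the rest optional."""

    counts_stage1: CountMatrix
    counts_stage2: CountMatrix | None = None
    transcripts: RegionSet | None = None
    qtl: RegionSet | None = None
    de_flags: dict[str, bool] | None = None


def _stage_seed(base_seed: int, label: str) -> int:
    # deterministic stage-local substream, independent of call order
    ss = np.random.SeedSequence([base_seed, abs(hash(label)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def _analyse_stage(
    cm: CountMatrix, config: PipelineConfig, label: str, outdir: Path
) -> dict:
    from . import module_trait, network, preprocess, resample_tests

    report: dict = {"stage": label}
    stage_labels = cm.metadata.column("stage")
    filtered = preprocess.filter_low_counts(
        cm, stage_labels, config.total_min, config.per_stage_min
    )
    report["n_genes_after_filter"] = len(filtered.counts.gene_ids)
    expr = preprocess.vst(filtered.counts)
    expr, outliers = preprocess.remove_outlier_samples(expr, config.zk_threshold)
    report["outliers_removed"] = [
        e.sample_id for it in outliers.iterations for e in it if e.removed
    ]

    if config.beta is not None:
        beta, fit_table = config.beta, None
    else:
        beta, fit_table = network.pick_soft_threshold(
            expr,
            network.NetworkConfig(
                powers_scanned=config.powers_scanned,
                scale_free_r2_target=config.scale_free_r2_target,
                fallback_beta=config.fallback_beta,
                max_p_outliers=config.max_p_outliers,
            ),
        )
        _atomic_to_csv(fit_table, outdir / f"{label}_soft_threshold.tsv", index=False)
    report["beta"] = int(beta)

    net_config = network.NetworkConfig(
        beta=beta,
        max_p_outliers=config.max_p_outliers,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
    )
    modules, eigengenes = network.detect_modules(expr, net_config)
    report["n_modules"] = len(modules.module_names)
    report["module_sizes"] = {m: len(modules.genes_of(m)) for m in modules.module_names}

    trait = expr.metadata.trait_vector()
    stats = module_trait.eigengene_trait_association(
        eigengenes, trait, fdr_level=config.fdr_level, expr=expr
    )
    selected = list(stats.selected_modules)
    report["module_trait"] = {
        m: {"r": float(stats.table.loc[m, "r"]), "p": float(stats.table.loc[m, "p"]),
            "q": float(stats.table.loc[m, "q"])}
        for m in stats.table.index
    }
    report["selected_modules"] = selected

    candidates = module_trait.select_candidates(
        stats, modules, threshold=config.candidate_threshold
    )
    report["n_candidates"] = {m: len(g) for m, g in candidates.items()}

    perm_results = {}
    seed = _stage_seed(config.seed, f"permtests:{label}")
    for i, m in enumerate(selected):
        sub = expr.subset_genes(modules.genes_of(m)).values.to_numpy()
        eig = resample_tests.eigenvalue_permutation_test(
            sub, n_perm=config.eig_permutations, seed=seed + 2 * i
        )
        rv = resample_tests.rv_permutation_test(
            sub, trait.to_numpy(), n_perm=config.rv_permutations, seed=seed + 2 * i + 1
        )
        perm_results[m] = {
            "eigenvalue_p": eig.p,
            "eigenvalue_observed": eig.observed_stat,
            "rv_p": rv.p,
            "rv_observed": rv.observed_stat,
        }
    report["permutation_tests"] = perm_results

    assign = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "module": [modules.assignments[g] for g in expr.gene_ids],
            "kME": [eigengenes.kme.get(g, np.nan) for g in expr.gene_ids],
        }
    )
    _atomic_to_csv(assign, outdir / f"{label}_modules.tsv", index=False)
    _atomic_to_csv(eigengenes.scores, outdir / f"{label}_eigengenes.tsv", index_label="sample_id")
    _atomic_to_csv(stats.table, outdir / f"{label}_module_trait.tsv", index_label="module")

    return {
        "report": report,
        "expr": expr,
        "modules": modules,
        "eigengenes": eigengenes,
        "stats": stats,
        "candidates": candidates,
        "trait": trait,
    }


def run_pipeline(config: PipelineConfig, inputs: RunInputs, outdir: str | Path) -> dict:
    """Run every applicable stage and write artifacts plus ``report.json``.

    Always runs preprocess -> network -> module-trait -> permutation tests on
    stage 1; adds cross-stage preservation/overlap/consensus and the
    trajectory analysis when stage-2 counts are supplied, and the genomic
    overlap battery when transcript and QTL regions are supplied.
    """
    from . import cross_stage, module_trait, preprocess, region_overlap, trajectory

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": asdict(config)}
    logger.info("run_pipeline: parameters %s", report["parameters"])

    s1 = _analyse_stage(inputs.counts_stage1, config, "stage1", outdir)
    report["stage1"] = s1["report"]
    stages = {"stage1": s1}

    if inputs.counts_stage2 is not None:
        s2 = _analyse_stage(inputs.counts_stage2, config, "stage2", outdir)
        report["stage2"] = s2["report"]
        stages["stage2"] = s2

        pres = cross_stage.module_preservation(
            ref_expr=s2["expr"],
            ref_modules=s2["modules"],
            test_expr=s1["expr"],
            n_perm=config.preservation_permutations,
            beta=report["stage2"]["beta"],
            seed=_stage_seed(config.seed, "preservation"),
        )
        _atomic_to_csv(pres.table, outdir / "preservation.tsv", index_label="module")
        report["preservation"] = {
            m: {
                "Z_summary": float(pres.table.loc[m, "Z_summary"]),
                "evidence": str(pres.table.loc[m, "evidence"]),
            }
            for m in pres.table.index
        }

        overlap = cross_stage.module_overlap_table(s1["modules"], s2["modules"])
        _atomic_to_csv(overlap.counts, outdir / "module_overlap_counts.tsv")
        report["module_overlap"] = {
            "n_significant_cells": int((overlap.q.to_numpy() <= config.fdr_level).sum())
        }

        cons_modules, cons_eigengenes = cross_stage.consensus_modules(
            [s1["expr"], s2["expr"]],
            beta=max(report["stage1"]["beta"], report["stage2"]["beta"]),
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height,
            max_p_outliers=config.max_p_outliers,
            quantile=config.consensus_quantile,
        )
        report["consensus"] = {
            "n_modules": len(cons_modules.module_names),
            "module_sizes": {
                m: len(cons_modules.genes_of(m)) for m in cons_modules.module_names
            },
        }
        cons_trait = {}
        for idx, (name, st) in enumerate(stages.items()):
            stats = module_trait.eigengene_trait_association(
                cons_eigengenes[idx],
                st["trait"],
                fdr_level=config.fdr_level,
            )
            cons_trait[name] = {
                m: float(stats.table.loc[m, "q"]) for m in stats.table.index
            }
        report["consensus"]["trait_q"] = cons_trait

        # trajectory runs on the pooled raw counts with a common transform
        pooled = inputs.counts_stage1.concat_samples(inputs.counts_stage2)
        pooled_expr = preprocess.vst(pooled)
        groups = (
            pooled_expr.metadata.column("stage").astype(str)
            + "/"
            + pooled_expr.metadata.column("morph").astype(str)
        )
        dist = trajectory.group_euclidean_distances(pooled_expr, groups)
        _atomic_to_csv(dist, outdir / "group_distances.tsv", index_label="group")
        bg = trajectory.between_group_pca_pipeline(pooled_expr, groups)
        _atomic_to_csv(bg.scores, outdir / "bgpca_scores.tsv", index_label="sample_id")
        report["trajectory"] = {
            "group_distances": {
                f"{a}|{b}": float(dist.loc[a, b])
                for a in dist.index
                for b in dist.columns
                if a < b
            },
            "axis_variance_fractions": [float(v) for v in bg.variance_fractions],
        }

    if inputs.transcripts is not None and inputs.qtl is not None:
        gene_sets = {}
        for name, st in stages.items():
            for m in st["stats"].selected_modules:
                genes = st["modules"].genes_of(m)
                gene_sets[f"{name}:{m}"] = inputs.transcripts.subset_names(genes)
        if inputs.de_flags:
            de_genes = [g for g, f in inputs.de_flags.items() if f]
            gene_sets["DE"] = inputs.transcripts.subset_names(de_genes)
        if gene_sets:
            battery = region_overlap.overlap_battery(
                gene_sets,
                {"qtl": inputs.qtl},
                combined=False,
                n_perm=config.region_permutations,
                seed=_stage_seed(config.seed, "region_overlap"),
            )
            report["region_overlap"] = {
                r.name: {"observed": r.observed, "p": r.p, "q": r.q} for r in battery
            }

    atomic_write_text(outdir / "report.json", json.dumps(report, sort_keys=True, indent=1))
    return report
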