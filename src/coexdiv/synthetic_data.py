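"""Synthetic two-stage RNA-seq count data with planted coexpression structure.

The generator emulates the study design the rest of the package analyses:
two developmental stages sampled from benthic and limnetic morphs, with

* planted coexpression modules driven by per-sample latent scores,
* trait-associated modules (a shift ``delta`` added to the latent score of
  limnetic samples),
* partial preservation of module structure between stages, and
* a toy genome (linkage groups, transcript loci, QTL intervals) with
  optional planted overlap enrichment.

Counts are negative binomial around a log-normal structured mean so that
variance-stabilised values carry the planted correlation structure at
realistic noise levels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_pipeline import CountMatrix, RegionSet, SampleMetadata

__all__ = [
    "SimulationConfig",
    "QtlConfig",
    "SimulationTruth",
    "simulate_two_stage_counts",
    "simulate_genome",
]

UNASSIGNED = "none"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-stage planted-structure simulation.

    Defaults mirror the small-n design of the study the package targets:
    6 benthic + 6 limnetic samples per stage, six modules of 50 genes with
    loadings (gene-latent correlations) in (0.6, 0.9), the first two modules
    trait-associated, and two thirds of modules preserved in stage 2.
    """

    n_samples_per_group: int = 6
    n_modules: int = 6
    module_sizes: tuple[int, ...] = (50, 50, 50, 50, 50, 50)
    n_background_genes: int = 100
    trait_effect_sizes: tuple[float, ...] = (2.0, 1.0, 0.0, 0.0, 0.0, 0.0)
    trait_effect_sizes_stage2: tuple[float, ...] | None = None  # None = same as stage 1
    loading_range: tuple[float, float] = (0.6, 0.9)
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (100_000, 200_000)
    preserved_fraction: float = 2.0 / 3.0
    lfc_scale: float = 1.0
    de_prob_trait_module: float = 0.8
    de_prob_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be positive")
        if self.n_modules < 1:
            raise ValueError("n_modules must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have length n_modules")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("all module_sizes must be >= 1")
        if len(self.trait_effect_sizes) != self.n_modules:
            raise ValueError("trait_effect_sizes must have length n_modules")
        if (
            self.trait_effect_sizes_stage2 is not None
            and len(self.trait_effect_sizes_stage2) != self.n_modules
        ):
            raise ValueError("trait_effect_sizes_stage2 must have length n_modules")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("loading_range must be an interval within (0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be non-negative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be a positive interval")
        if not (0.0 <= self.preserved_fraction <= 1.0):
            raise ValueError("preserved_fraction must be in [0, 1]")

    @property
    def n_genes(self) -> int:
        return int(sum(self.module_sizes)) + self.n_background_genes

    @property
    def n_samples_per_stage(self) -> int:
        return 2 * self.n_samples_per_group


@dataclass(frozen=True)
class QtlConfig:
    """Layout of QTL intervals on the toy genome."""

    n_qtl: int = 4
    qtl_length: int = 100_000
    enriched_module: str | None = None
    enrichment_prob: float = 0.0
    transcript_length: int = 1_000


@dataclass
class SimulationTruth:
    """Everything the generator planted, for downstream recovery checks."""

    gene_module: dict[str, str]
    gene_module_stage2: dict[str, str]
    module_trait_delta: dict[str, float]
    module_preserved: dict[str, bool]
    gene_de: dict[str, bool]
    config: SimulationConfig
    overlap_enriched_module: str | None = None

    @property
    def module_names(self) -> list[str]:
        return sorted(self.module_trait_delta)

    def genes_of_module(self, module: str, stage: int = 1) -> list[str]:
        mapping = self.gene_module if stage == 1 else self.gene_module_stage2
        return [g for g, m in mapping.items() if m == module]

    def to_json(self) -> str:
        payload = {
            "gene_module": self.gene_module,
            "gene_module_stage2": self.gene_module_stage2,
            "module_trait_delta": self.module_trait_delta,
            "module_preserved": self.module_preserved,
            "gene_de": self.gene_de,
            "overlap_enriched_module": self.overlap_enriched_module,
            "config": dataclasses.asdict(self.config),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _sample_metadata(config: SimulationConfig, stage: str) -> pd.DataFrame:
    n = config.n_samples_per_group
    ids = [f"{stage}_{morph}{i + 1}" for morph in ("B", "L") for i in range(n)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "stage": stage,
            "morph": ["benthic"] * n + ["limnetic"] * n,
            "species": ["sp1"] * n + ["sp2"] * n,
            "lake": "toy_lake",
        }
    ).set_index("sample_id")


def _stage_counts(
    config: SimulationConfig,
    stage: str,
    gene_module: Mapping[str, str],
    genes: Sequence[str],
    loadings: np.ndarray,
    baseline: np.ndarray,
    module_names: Sequence[str],
    delta: Mapping[str, float],
    rng: np.random.Generator,
) -> CountMatrix:
    meta = _sample_metadata(config, stage)
    n_samples = len(meta)
    limnetic = (meta["morph"] == "limnetic").to_numpy(float)

    scores = {
        m: rng.standard_normal(n_samples) + delta[m] * limnetic for m in module_names
    }
    n_genes = len(genes)
    z = rng.standard_normal((n_genes, n_samples))
    for gi, g in enumerate(genes):
        m = gene_module[g]
        if m != UNASSIGNED:
            a = loadings[gi]
            z[gi] = a * scores[m] + np.sqrt(1.0 - a * a) * z[gi]

    # mean-model: relative abundance * log-normal structure, then each column
    # is scaled so its expected sum equals the drawn library size (sequencing
    # depth is a property of the library, not of the biology)
    lib = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, n_samples
    )
    s = config.lfc_scale
    rel = baseline / baseline.sum()
    mu = rel[:, None] * np.exp(s * z - 0.5 * s * s)
    mu = mu * (lib / mu.sum(axis=0))[None, :]

    d = config.nb_dispersion
    # NB via gamma-Poisson: Var = mu + d * mu^2
    shape = 1.0 / d
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    frame = pd.DataFrame(counts, index=list(genes), columns=meta.index)
    return CountMatrix(frame, SampleMetadata(meta.reset_index()))


def simulate_two_stage_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, SimulationTruth]:
    """Draw stage-1 and stage-2 count matrices plus the planted truth.

    Stage 2 keeps the gene-to-module map of preserved modules and shuffles
    the genes of non-preserved modules into fresh modules driven by new,
    independent latent scores; all latent scores are redrawn per stage.
    """
    if config.n_genes < max(config.module_sizes):
        raise ValueError("module larger than gene budget")
    rng = np.random.default_rng(config.seed)

    module_names = [f"M{i + 1}" for i in range(config.n_modules)]
    genes: list[str] = []
    gene_module: dict[str, str] = {}
    for m, size in zip(module_names, config.module_sizes):
        for j in range(size):
            g = f"{m}_g{j + 1}"
            genes.append(g)
            gene_module[g] = m
    for j in range(config.n_background_genes):
        g = f"bg_g{j + 1}"
        genes.append(g)
        gene_module[g] = UNASSIGNED

    lo, hi = config.loading_range
    loadings = rng.uniform(lo, hi, len(genes))
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))

    delta = {m: float(d) for m, d in zip(module_names, config.trait_effect_sizes)}
    delta2 = (
        delta
        if config.trait_effect_sizes_stage2 is None
        else {m: float(d) for m, d in zip(module_names, config.trait_effect_sizes_stage2)}
    )
    n_preserved = int(round(config.preserved_fraction * config.n_modules))
    preserved = {m: i < n_preserved for i, m in enumerate(module_names)}

    # stage-2 membership: preserved modules keep their genes, the rest are
    # shuffled among the non-preserved module slots
    gene_module_2 = dict(gene_module)
    loose = [g for g in genes if not preserved.get(gene_module[g], True) and gene_module[g] != UNASSIGNED]
    if loose:
        slots = [gene_module[g] for g in loose]
        perm = rng.permutation(len(loose))
        for g, k in zip(loose, perm):
            gene_module_2[g] = slots[k]

    de_flags: dict[str, bool] = {}
    for g in genes:
        m = gene_module[g]
        p = config.de_prob_trait_module if (m != UNASSIGNED and delta[m] != 0) else config.de_prob_background
        de_flags[g] = bool(rng.random() < p)

    counts1 = _stage_counts(
        config, "1dph", gene_module, genes, loadings, baseline, module_names, delta, rng
    )
    counts2 = _stage_counts(
        config, "1mph", gene_module_2, genes, loadings, baseline, module_names, delta2, rng
    )

    truth = SimulationTruth(
        gene_module=gene_module,
        gene_module_stage2=gene_module_2,
        module_trait_delta=delta,
        module_preserved=preserved,
        gene_de=de_flags,
        config=config,
    )
    return counts1, counts2, truth


def simulate_genome(
    truth: SimulationTruth,
    n_linkage_groups: int = 5,
    genome_length: int = 5_000_000,
    qtl_config: QtlConfig | None = None,
    seed: int | None = None,
) -> tuple[RegionSet, RegionSet]:
    """Place transcripts and QTL intervals on a toy linkage map.

    Transcripts are placed uniformly at random on the linkage groups except
    when ``qtl_config.enriched_module`` requests that a module's transcripts
    fall inside QTL intervals with probability ``enrichment_prob``.
    """
    if n_linkage_groups < 1:
        raise ValueError("n_linkage_groups must be >= 1")
    qtl_config = qtl_config or QtlConfig()
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)

    lg_len = genome_length // n_linkage_groups
    genome = {f"LG{i + 1}": lg_len for i in range(n_linkage_groups)}
    lgs = list(genome)

    if qtl_config.qtl_length > lg_len:
        raise ValueError("QTL longer than its linkage group")
    if qtl_config.transcript_length > lg_len:
        raise ValueError("transcript longer than linkage group")

    qtl_rows = []
    for i in range(qtl_config.n_qtl):
        lg = lgs[int(rng.integers(len(lgs)))]
        start = int(rng.integers(0, genome[lg] - qtl_config.qtl_length + 1))
        qtl_rows.append((lg, start, start + qtl_config.qtl_length, f"qtl{i + 1}"))
    qtl = RegionSet.from_records(qtl_rows, genome)

    tlen = qtl_config.transcript_length
    enriched = qtl_config.enriched_module
    tx_rows = []
    for g in truth.gene_module:
        inside = (
            enriched is not None
            and truth.gene_module[g] == enriched
            and rng.random() < qtl_config.enrichment_prob
            and qtl_rows
        )
        if inside:
            lg, qs, qe, _ = qtl_rows[int(rng.integers(len(qtl_rows)))]
            span = max(qe - qs - tlen, 1)
            start = qs + int(rng.integers(0, span))
            start = min(start, genome[lg] - tlen)
        else:
            lg = lgs[int(rng.integers(len(lgs)))]
            start = int(rng.integers(0, genome[lg] - tlen + 1))
        tx_rows.append((lg, start, start + tlen, g))
    transcripts = RegionSet.from_records(tx_rows, genome)

    truth.overlap_enriched_module = enriched
    return transcripts, qtl
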