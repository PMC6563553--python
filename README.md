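# coexdiv

Coexpression-network analysis of benthic–limnetic divergence across
developmental stages.

Ecologically divergent fish morphs — deep-bodied *benthic*
bottom-dwellers versus elongated *limnetic* open-water swimmers — can
differ not only in which genes they express but in how genes covary.
`coexdiv` implements the full analysis chain for asking that question from
bulk RNA-seq counts sampled at two developmental stages:

- **Preprocessing** — count filtering (≥ 100 reads total and ≥ 50 per
  stage), a median-of-ratios variance-stabilising transform, and iterative
  removal of outlier samples by standardized connectivity (Z.k < −2).
- **Signed weighted networks** — biweight midcorrelation, soft-threshold
  selection by the scale-free topology criterion (powers 1–30, fallback
  β = 20), signed topological overlap, deterministic module detection
  (minimum module size 30, eigengene merge height 0.25), and module
  eigengenes (first principal components) with membership (kME).
- **Module–trait association** — hybrid biweight correlation of eigengenes
  with the benthic(0)/limnetic(1) state, Student-t p-values,
  Benjamini–Hochberg FDR, candidate genes by |kME| > 0.7 and |GS| > 0.7,
  and Fisher enrichment of differential-expression flags.
- **Permutation validation** — a parallel-analysis-style test of the
  variance explained by the first eigenvalue (per-gene permutations) and a
  multivariate trait-association test based on the Escoufier RV
  coefficient (label permutations).
- **Cross-stage comparison** — module preservation (Z_summary with the
  2/10 evidence thresholds), module cross-tabulation with Fisher tests,
  and consensus modules from a calibrated minimum-TOM.
- **Trajectory analysis** — Euclidean distances between stage×morph
  centroids and a between-group PCA computed through a PCoA of sample
  distances.
- **Genomic overlap** — permutation tests of module/QTL interval overlap
  that respect genome size and linkage-group structure.
- **Synthetic data** — a two-stage count generator with planted modules,
  trait effects, partial cross-stage preservation and a toy genome, so
  every stage of the pipeline is testable end-to-end with known truth.

## Worked example

```python
import coexdiv as cx
from coexdiv import preprocess, network, module_trait, resample_tests

# a synthetic two-stage experiment: 6 modules, the first two associated
# with the benthic/limnetic state (delta = 2 and 1)
cfg = cx.SimulationConfig(seed=1, n_samples_per_group=12)
counts1, counts2, truth = cx.simulate_two_stage_counts(cfg)

filtered = preprocess.filter_low_counts(counts1, counts1.metadata.column("stage"))
expr = preprocess.vst(filtered.counts)
expr, outliers = preprocess.remove_outlier_samples(expr)

modules, eigengenes = network.detect_modules(expr, network.NetworkConfig(beta=20))
print({m: len(modules.genes_of(m)) for m in modules.module_names})

trait = expr.metadata.trait_vector()          # benthic=0, limnetic=1
stats = module_trait.eigengene_trait_association(eigengenes, trait, expr=expr)
print(stats.table.round(4))

for m in stats.selected_modules:
    sub = expr.subset_genes(modules.genes_of(m)).values.to_numpy()
    rv = resample_tests.rv_permutation_test(sub, trait.to_numpy(), seed=1)
    print(m, "RV =", round(rv.observed_stat, 3), "p =", rv.p)
```

Output:

```
{'blue': 50, 'turquoise': 50, 'brown': 48, 'yellow': 45, 'green': 44, 'red': 44}
                r       p       q  selected
module
blue       0.4565  0.0249  0.0748     False
turquoise  0.6560  0.0005  0.0030      True
brown     -0.4213  0.0404  0.0807     False
yellow    -0.1625  0.4480  0.5376     False
green      0.1263  0.5565  0.5565     False
red       -0.2264  0.2875  0.4312     False
turquoise RV = 0.404 p = 0.0
```

The turquoise module (r = 0.66, q = 0.003) recovers the strongest planted
trait module (Δ = 2): a positive correlation means its genes are
overexpressed in limnetic samples. It also passes the multivariate RV
label-permutation test (p = 0 at 100 permutations, i.e. no permuted RV
reached the observed value). The weaker planted module (Δ = 1, here
"blue", r = 0.46) narrowly misses the FDR cut at this sample size —
exactly the regime the permutation tests are there to police.

A command-line interface mirrors the library
(`coexdiv simulate`, `coexdiv preprocess`, `coexdiv run-all ...`);
`run-all` writes every intermediate table plus a machine-readable
`report.json` and is bit-identical across runs with the same seed.

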