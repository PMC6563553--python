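import numpy as np
import pandas as pd
import pytest

from coexdiv import cross_stage as cs
from coexdiv.network import ModuleSet, NetworkConfig, detect_modules

from conftest import make_expression, make_metadata, planted_expression


def planted_module_expr(rng, n=24, module_size=50, n_noise=150, loading=0.8, tag="s"):
    s = rng.standard_normal(n)
    a = np.full(module_size, loading)
    block = a * s[:, None] + np.sqrt(1 - a**2) * rng.standard_normal((n, module_size))
    values = np.hstack([block, rng.standard_normal((n, n_noise))])
    genes = [f"m{i}" for i in range(module_size)] + [f"b{i}" for i in range(n_noise)]
    meta = make_metadata(n, prefix=tag)
    expr = make_expression(values, metadata=meta, genes=genes)
    modules = ModuleSet({g: ("turquoise" if g.startswith("m") else "grey") for g in genes})
    return expr, modules


class TestModulePreservation:
    def test_self_copy_shows_strong_evidence(self, rng):
        expr, modules = planted_module_expr(rng)
        stats = cs.module_preservation(expr, modules, expr, n_perm=200, beta=6, seed=0)
        assert stats.table.loc["turquoise", "Z_summary"] > 10
        assert stats.table.loc["turquoise", "evidence"] == "strong"

    def test_noise_test_data_shows_no_evidence(self, rng):
        expr, modules = planted_module_expr(rng)
        noise = make_expression(
            rng.standard_normal((24, 200)),
            metadata=make_metadata(24, prefix="t"),
            genes=expr.gene_ids,
        )
        stats = cs.module_preservation(expr, modules, noise, n_perm=200, beta=6, seed=1)
        assert abs(stats.table.loc["turquoise", "Z_summary"]) < 2

    def test_self_beats_noise_ordering(self, rng):
        expr, modules = planted_module_expr(rng, module_size=40, n_noise=80)
        noise = make_expression(
            rng.standard_normal((24, 120)),
            metadata=make_metadata(24, prefix="t"),
            genes=expr.gene_ids,
        )
        z_self = cs.module_preservation(expr, modules, expr, n_perm=100, beta=6, seed=2)
        z_noise = cs.module_preservation(expr, modules, noise, n_perm=100, beta=6, seed=2)
        assert (
            z_self.table.loc["turquoise", "Z_summary"]
            > z_noise.table.loc["turquoise", "Z_summary"]
        )

    def test_tiny_module_skipped(self, rng):
        expr, _ = planted_module_expr(rng, module_size=5, n_noise=50)
        modules = ModuleSet(
            {g: ("turquoise" if g in expr.gene_ids[:2] else "grey") for g in expr.gene_ids}
        )
        stats = cs.module_preservation(expr, modules, expr, n_perm=20, beta=6, seed=0)
        assert len(stats.table) == 0


class TestModuleOverlapTable:
    def test_identical_partitions_are_diagonal_with_minimal_p(self, rng):
        genes = [f"g{i}" for i in range(90)]
        labels = ["blue"] * 40 + ["brown"] * 30 + ["grey"] * 20
        a = ModuleSet(dict(zip(genes, labels)))
        b = ModuleSet(dict(zip(genes, labels)))
        table = cs.module_overlap_table(a, b)
        assert table.counts.loc["blue", "blue"] == 40
        assert table.counts.loc["brown", "brown"] == 30
        assert table.counts.to_numpy().sum() == 90
        # diagonal p minimal for the margins: compare to hypergeometric extreme
        from scipy.stats import hypergeom

        p_extreme = hypergeom.pmf(40, 70, 40, 40)
        assert table.p.loc["blue", "blue"] <= p_extreme * 1.000001

    def test_all_in_one_module_degenerate(self):
        genes = [f"g{i}" for i in range(60)]
        a = ModuleSet({g: "blue" for g in genes})
        b = ModuleSet(dict(zip(genes, ["red"] * 30 + ["green"] * 30)))
        table = cs.module_overlap_table(a, b)
        assert list(table.counts.loc["blue"]) == [30, 30]
        assert (table.p.loc["blue"] == 1.0).all()

    def test_grand_total_conserved_under_relabeling(self, rng):
        genes = [f"g{i}" for i in range(80)]
        lab_a = rng.choice(["blue", "brown", "grey"], 80)
        lab_b = rng.choice(["red", "green"], 80)
        a = ModuleSet(dict(zip(genes, lab_a)))
        b = ModuleSet(dict(zip(genes, lab_b)))
        t1 = cs.module_overlap_table(a, b)
        swapped = {g: {"red": "green", "green": "red"}[l] for g, l in zip(genes, lab_b)}
        t2 = cs.module_overlap_table(a, ModuleSet(swapped))
        assert t1.counts.to_numpy().sum() == t2.counts.to_numpy().sum() == 80

    def test_disjoint_universes_rejected(self):
        a = ModuleSet({"g1": "blue"})
        b = ModuleSet({"h1": "red"})
        with pytest.raises(ValueError, match="disjoint"):
            cs.module_overlap_table(a, b)

    def test_random_partitions_fisher_calibrated(self, rng):
        hits = total = 0
        for rep in range(100):
            genes = [f"g{i}" for i in range(120)]
            a = ModuleSet(dict(zip(genes, rng.choice(["blue", "brown"], 120))))
            b = ModuleSet(dict(zip(genes, rng.choice(["red", "green"], 120))))
            table = cs.module_overlap_table(a, b)
            ps = table.p.loc[["blue", "brown"], ["red", "green"]].to_numpy().ravel()
            hits += (ps <= 0.05).sum()
            total += ps.size
        # Fisher is conservative on discrete tables: at or below nominal level
        assert hits / total < 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / total)


class TestConsensusModules:
    def test_identical_datasets_reproduce_single_dataset_partition(self, rng):
        values, _ = planted_expression(rng, 24, [50, 40], 60, loading=(0.7, 0.95))
        e1 = make_expression(values, metadata=make_metadata(24, prefix="a"))
        e2 = make_expression(values, metadata=make_metadata(24, prefix="b"))
        single, _ = detect_modules(e1, NetworkConfig(beta=6))
        cons, eigs = cs.consensus_modules([e1, e2], beta=6)
        assert cons.assignments == single.assignments
        assert len(eigs) == 2

    def test_dataset_order_invariance(self, rng):
        v1, _ = planted_expression(rng, 20, [40], 40)
        v2, _ = planted_expression(rng, 20, [40], 40)
        e1 = make_expression(v1, metadata=make_metadata(20, prefix="a"))
        e2 = make_expression(v2, metadata=make_metadata(20, prefix="b"))
        c12, _ = cs.consensus_modules([e1, e2], beta=6)
        c21, _ = cs.consensus_modules([e2, e1], beta=6)
        assert c12.assignments == c21.assignments

    def test_module_planted_in_one_dataset_absent_from_consensus(self, rng):
        n = 24
        s = rng.standard_normal(n)
        a = rng.uniform(0.7, 0.9, 50)
        v1 = np.hstack(
            [a * s[:, None] + np.sqrt(1 - a**2) * rng.standard_normal((n, 50)),
             rng.standard_normal((n, 100))]
        )
        v2 = rng.standard_normal((n, 150))
        e1 = make_expression(v1, metadata=make_metadata(n, prefix="a"))
        e2 = make_expression(v2, metadata=make_metadata(n, prefix="b"))
        cons, _ = cs.consensus_modules([e1, e2], beta=6)
        assert all(cons.assignments[f"g{j}"] == "grey" for j in range(50))

    def test_too_few_shared_genes_rejected(self, rng):
        e1 = make_expression(rng.standard_normal((10, 10)), metadata=make_metadata(10, prefix="a"))
        e2 = make_expression(rng.standard_normal((10, 10)), metadata=make_metadata(10, prefix="b"))
        with pytest.raises(ValueError, match="shared genes"):
            cs.consensus_modules([e1, e2], beta=6)


class TestEvidenceClass:
    @pytest.mark.parametrize(
        "z, cls",
        [(-1.0, "none"), (1.99, "none"), (2.0, "weak-to-moderate"),
         (10.0, "weak-to-moderate"), (10.01, "strong")],
    )
    def test_thresholds(self, z, cls):
        assert cs.evidence_class(z) == cls
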