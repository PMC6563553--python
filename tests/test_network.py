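import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coexdiv import network as nw

from conftest import make_expression, planted_expression


# --- independent straight-line oracles -------------------------------------


def bicor_oracle(x, y, max_p_outliers=0.1):
    """Direct transcription of the published biweight midcorrelation."""

    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - np.mean(v)
        u = (v - med) / (9 * mad)
        lo, hi = np.quantile(u, max_p_outliers), np.quantile(u, 1 - max_p_outliers)
        lo, hi = min(lo, -1.0), max(hi, 1.0)
        u = np.array([ui / abs(lo) if ui < 0 else ui / hi for ui in u])
        w = np.array([(1 - ui**2) ** 2 if abs(ui) < 1 else 0.0 for ui in u])
        return (v - med) * w

    gx, gy = weighted(np.asarray(x, float)), weighted(np.asarray(y, float))
    return float(
        sum(a * b for a, b in zip(gx, gy))
        / np.sqrt(sum(a * a for a in gx) * sum(b * b for b in gy))
    )


def tom_oracle(adj):
    """Triple-loop evaluation of signed topological overlap."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


# --- bicor ------------------------------------------------------------------


class TestBicor:
    def test_self_and_anticorrelation(self, rng):
        x = rng.standard_normal(20)
        assert nw.bicor(x, x) == pytest.approx(1.0)
        assert nw.bicor(x, -x) == pytest.approx(-1.0)

    def test_outlier_pair_matches_oracle_and_beats_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expected = bicor_oracle(x, y)
        assert nw.bicor(x, y) == pytest.approx(expected, abs=1e-10)
        assert nw.bicor(x, y) > np.corrcoef(x, y)[0, 1]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_on_random_vectors(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(15), r.standard_normal(15)
        assert nw.bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-10)

    def test_matrix_agrees_with_pairwise(self, rng):
        values = rng.standard_normal((12, 6))
        c = nw.bicor_matrix(values)
        for i in range(6):
            for j in range(i + 1, 6):
                assert c[i, j] == pytest.approx(
                    nw.bicor(values[:, i], values[:, j]), abs=1e-10
                )

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 9.0])  # MAD = 0
        y = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 7.0])  # MAD = 0
        # both margins fall back to plain centering -> exact Pearson
        assert nw.bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


# --- adjacency / soft threshold --------------------------------------------


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "c, beta, expected",
        [(1.0, 7, 1.0), (-1.0, 7, 0.0), (0.0, 20, 0.5**20)],
    )
    def test_endpoint_values(self, c, beta, expected):
        a = nw.signed_adjacency(np.array([[1.0, c], [c, 1.0]]), beta)
        assert a[0, 1] == pytest.approx(expected, rel=1e-12)

    @given(
        st.floats(-1.0, 0.999),
        st.floats(-1.0, 0.999),
        st.integers(1, 29),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_c_and_beta(self, c1, c2, beta):
        lo, hi = sorted([c1, c2])
        m = np.array([[1.0, lo], [lo, 1.0]]), np.array([[1.0, hi], [hi, 1.0]])
        assert nw.signed_adjacency(m[0], beta)[0, 1] <= nw.signed_adjacency(m[1], beta)[0, 1]
        a_lo = nw.signed_adjacency(m[0], beta)[0, 1]
        a_hi = nw.signed_adjacency(m[0], beta + 1)[0, 1]
        assert a_hi <= a_lo


class TestPickSoftThreshold:
    def test_modular_data_reaches_target_with_smallest_power(self, rng):
        # a continuum of loadings gives a decaying connectivity distribution
        a = rng.uniform(0, 1, 600) ** 2
        values = a * rng.standard_normal(40)[:, None] + np.sqrt(
            1 - a**2
        ) * rng.standard_normal((40, 600))
        expr = make_expression(values)
        beta, table = nw.pick_soft_threshold(expr)
        reached = table[table["signed_r2"] >= 0.9]
        assert len(reached) > 0
        assert beta == int(reached["power"].iloc[0])
        # independent re-computation of the fit at the chosen power
        cor = nw.bicor_matrix(expr.values.to_numpy())
        k = nw.signed_adjacency(cor, beta).sum(axis=1) - 1
        r2, slope = nw.scale_free_fit(k)
        row = table[table["power"] == beta].iloc[0]
        assert r2 == pytest.approx(row["signed_r2"], abs=1e-12)

    def test_pure_noise_returns_fallback_twenty(self, rng):
        expr = make_expression(rng.standard_normal((12, 50)))
        beta, _ = nw.pick_soft_threshold(expr)
        assert beta == 20

    def test_chosen_power_never_exceeds_scan_range(self, rng):
        values, _ = planted_expression(rng, 20, [40], 20)
        beta, _ = nw.pick_soft_threshold(make_expression(values))
        assert beta <= 30


# --- TOM --------------------------------------------------------------------


class TestTom:
    def test_two_gene_full_adjacency(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        t = nw.tom_similarity(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_identity_adjacency_gives_zero_overlap(self):
        t = nw.tom_similarity(np.eye(4))
        assert np.all(t[~np.eye(4, dtype=bool)] == 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        c = np.clip(rng.uniform(-1, 1, (5, 5)), -1, 1)
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        a = nw.signed_adjacency(c, 3)
        np.testing.assert_allclose(nw.tom_similarity(a), tom_oracle(a), atol=1e-12)

    def test_symmetric_bounded(self, rng):
        values = rng.standard_normal((15, 12))
        a = nw.signed_adjacency(nw.bicor_matrix(values), 6)
        t = nw.tom_similarity(a)
        np.testing.assert_allclose(t, t.T, atol=1e-12)
        assert t.min() >= 0.0 and t.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            nw.tom_similarity(a)


# --- eigengenes -------------------------------------------------------------


class TestEigengenes:
    def test_identical_gene_module_is_rank_one(self, rng):
        profile = rng.standard_normal(10)
        expr = make_expression(np.column_stack([profile] * 5))
        modules = nw.ModuleSet({g: "turquoise" for g in expr.gene_ids})
        eig = nw.compute_eigengenes(expr, modules)
        assert eig.var_explained["turquoise"] == pytest.approx(1.0)
        std = (profile - profile.mean()) / profile.std()
        me = eig.scores["turquoise"].to_numpy()
        assert abs(np.corrcoef(me, std)[0, 1]) == pytest.approx(1.0)

    def test_matches_full_eigendecomposition_oracle(self, rng):
        values = rng.standard_normal((12, 7))
        expr = make_expression(values)
        modules = nw.ModuleSet({g: "blue" for g in expr.gene_ids})
        eig = nw.compute_eigengenes(expr, modules)
        z = (values - values.mean(0)) / values.std(0)
        w, v = np.linalg.eigh(z.T @ z)
        assert eig.var_explained["blue"] == pytest.approx(w[-1] / w.sum(), abs=1e-10)
        oracle_scores = z @ v[:, -1]
        me = eig.scores["blue"].to_numpy()
        r = np.corrcoef(me, oracle_scores)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_symmetry(self, rng):
        values = rng.standard_normal((10, 6)) + 2 * rng.standard_normal((10, 1))
        modules = nw.ModuleSet({f"g{j}": "red" for j in range(6)})
        e1 = nw.compute_eigengenes(make_expression(values), modules)
        e2 = nw.compute_eigengenes(make_expression(-values), modules)
        np.testing.assert_allclose(
            e1.scores["red"].to_numpy(), -e2.scores["red"].to_numpy(), atol=1e-10
        )
        for g in modules.assignments:
            assert abs(e1.kme[g]) == pytest.approx(abs(e2.kme[g]), abs=1e-10)


# --- module detection -------------------------------------------------------


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self, rng):
        n = 30
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        values = np.column_stack([s1] * 40 + [s2] * 40 + list(rng.standard_normal((20, n))))
        genes = [f"a{i}" for i in range(40)] + [f"b{i}" for i in range(40)] + [
            f"n{i}" for i in range(20)
        ]
        expr = make_expression(values, genes=genes)
        modules, _ = nw.detect_modules(expr, nw.NetworkConfig(beta=6))
        assert len(modules.module_names) == 2
        a_mods = {modules.assignments[f"a{i}"] for i in range(40)}
        b_mods = {modules.assignments[f"b{i}"] for i in range(40)}
        assert len(a_mods) == 1 and len(b_mods) == 1 and a_mods != b_mods
        assert all(modules.assignments[f"n{i}"] == "grey" for i in range(20))

    def test_block_below_min_size_stays_grey(self, rng):
        n = 30
        s = rng.standard_normal(n)
        values = np.column_stack([s] * 20 + list(rng.standard_normal((40, n))))
        expr = make_expression(values)
        modules, _ = nw.detect_modules(expr, nw.NetworkConfig(beta=6))
        assert modules.module_names == []
        assert set(modules.assignments.values()) == {"grey"}

    def test_same_latent_blocks_merge(self, rng):
        n = 30
        s = rng.standard_normal(n)
        noise = 0.1 * rng.standard_normal((n, 80))
        values = np.column_stack([s] * 80) + noise
        expr = make_expression(values)
        modules, _ = nw.detect_modules(expr, nw.NetworkConfig(beta=6))
        assert len(modules.module_names) == 1

    def test_deterministic(self, rng):
        values, _ = planted_expression(rng, 20, [35, 35], 20)
        expr = make_expression(values)
        m1, e1 = nw.detect_modules(expr, nw.NetworkConfig(beta=12))
        m2, e2 = nw.detect_modules(expr, nw.NetworkConfig(beta=12))
        assert m1.assignments == m2.assignments
        assert e1.scores.equals(e2.scores)

    def test_largest_module_is_turquoise(self, rng):
        values, _ = planted_expression(rng, 30, [60, 35], 10, loading=(0.8, 0.95))
        modules, _ = nw.detect_modules(make_expression(values), nw.NetworkConfig(beta=6))
        sizes = {m: len(modules.genes_of(m)) for m in modules.module_names}
        assert max(sizes, key=sizes.get) == "turquoise"
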