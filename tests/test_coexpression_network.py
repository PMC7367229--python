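import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ketonet.coexpression_network import (
    EigengeneMatrix,
    ModulePartition,
    NetworkParams,
    adjacency,
    build_tom,
    call_hub_genes,
    compute_eigengenes,
    detect_modules,
    intramodular_connectivity,
    merge_modules,
    scale_free_fit_r2,
    select_soft_power,
)
from ketonet.expression_preprocess import ExpressionMatrix
from ketonet.io_formats import UNASSIGNED


def _expr(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    return ExpressionMatrix(
        gene_ids or [f"g{i}" for i in range(g)],
        sample_ids or [f"s{j}" for j in range(s)],
        values,
        "vst",
    )


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Brute-force TOM from an adjacency matrix with zero diagonal."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def eigengene_oracle(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC over samples via covariance eigendecomposition of z-scores."""
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    cov = z.T @ z
    w, v = np.linalg.eigh(cov)
    eig = v[:, -1]
    return eig, float(w[-1] / w.sum())


class TestTom:
    def test_perfect_pair_beta1(self):
        x = np.vstack([np.arange(6.0), 2 * np.arange(6.0) + 3])
        tom = build_tom(_expr(x), beta=1)
        np.testing.assert_allclose(tom, 1.0, atol=1e-12)

    def test_hand_matrix_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(5, 10))
        for beta in (1, 3, 6):
            a = adjacency(_expr(x), beta)
            np.testing.assert_allclose(build_tom(_expr(x), beta), tom_oracle(a), atol=1e-12)

    def test_range_and_symmetry_property(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=(rng.integers(3, 12), rng.integers(4, 16)))
            tom = build_tom(_expr(x), beta=int(rng.integers(1, 8)))
            assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
            np.testing.assert_allclose(tom, tom.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_zero_variance_gene_errors(self):
        x = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            build_tom(_expr(x), beta=1)


class TestSoftPower:
    def test_fixed_beta_skips_selection(self):
        x = np.random.default_rng(0).normal(size=(20, 10))
        assert select_soft_power(_expr(x), NetworkParams(soft_power=4)) == 4

    def test_pure_noise_falls_back(self, caplog):
        rng = np.random.default_rng(123)
        x = rng.normal(size=(150, 24))
        with caplog.at_level("WARNING", logger="ketonet"):
            beta = select_soft_power(_expr(x), NetworkParams(scale_free_target_r2=0.95))
        # pure noise should not reach a 0.95 scale-free fit
        assert beta == 6
        assert "falling back" in caplog.text

    def test_modular_matrix_selects_reasonable_beta(self, small_sim):
        from ketonet.expression_preprocess import vst_normalize

        counts, _, _, _ = small_sim
        expr = vst_normalize(counts)
        beta = select_soft_power(expr, NetworkParams())
        assert 1 <= beta <= 12

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError, match="bins"):
            scale_free_fit_r2(np.array([1.0, 1.0, 1.0, 1.0]))


class TestDetectModules:
    def test_block_diagonal_two_blocks(self):
        n = 80
        tom = np.eye(n)
        tom[:40, :40] = 0.9
        tom[40:, 40:] = 0.9
        np.fill_diagonal(tom, 1.0)
        part = detect_modules(tom, NetworkParams(min_module_size=30))
        sizes = part.sizes()
        assert len(part.modules) == 2
        assert sorted(sizes[m] for m in part.modules) == [40, 40]
        assert UNASSIGNED not in sizes.index

    def test_determinism(self, small_sim):
        from ketonet.expression_preprocess import vst_normalize

        counts, _, _, _ = small_sim
        expr = vst_normalize(counts)
        tom = build_tom(expr, 6)
        p1 = detect_modules(tom, NetworkParams(min_module_size=20), expr=expr)
        p2 = detect_modules(tom, NetworkParams(min_module_size=20), expr=expr)
        pd.testing.assert_series_equal(p1.labels, p2.labels)

    def test_too_few_genes_all_unassigned(self, caplog):
        tom = np.eye(5)
        with caplog.at_level("WARNING", logger="ketonet"):
            part = detect_modules(tom, NetworkParams(min_module_size=30))
        assert set(part.labels) == {UNASSIGNED}

    def test_planted_recovery(self, small_sim):
        from ketonet.expression_preprocess import vst_normalize

        counts, _, _, truth = small_sim
        expr = vst_normalize(counts)
        tom = build_tom(expr, 6)
        part = detect_modules(tom, NetworkParams(min_module_size=20), expr=expr)
        ari = adjusted_rand_score(
            truth.module_labels.loc[expr.gene_ids], part.labels.loc[expr.gene_ids]
        )
        assert ari >= 0.8

    def test_gene_order_invariance(self, small_sim):
        from ketonet.expression_preprocess import vst_normalize

        counts, _, _, _ = small_sim
        expr = vst_normalize(counts)
        rng = np.random.default_rng(2)
        perm = rng.permutation(expr.n_genes)
        expr2 = ExpressionMatrix(
            [expr.gene_ids[i] for i in perm], expr.sample_ids, expr.values[perm], "vst"
        )
        p1 = detect_modules(build_tom(expr, 6), NetworkParams(min_module_size=20), expr=expr)
        p2 = detect_modules(build_tom(expr2, 6), NetworkParams(min_module_size=20), expr=expr2)
        # same partition up to label names
        ari = adjusted_rand_score(p1.labels.loc[expr.gene_ids], p2.labels.loc[expr.gene_ids])
        assert ari == pytest.approx(1.0)


class TestEigengenes:
    def test_identical_genes_variance_one(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.3])
        x = np.tile(profile, (4, 1))
        part = ModulePartition(pd.Series(["blue"] * 4, index=[f"g{i}" for i in range(4)]))
        eg = compute_eigengenes(_expr(x), part)
        z = (profile - profile.mean()) / profile.std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(eg.values.loc["blue"], expected, atol=1e-9)
        assert eg.variance_explained["blue"] == pytest.approx(1.0)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 10))
        part = ModulePartition(pd.Series(["m"] * 6, index=[f"g{i}" for i in range(6)]))
        e1 = compute_eigengenes(_expr(x), part).values.loc["m"]
        e2 = compute_eigengenes(_expr(-x), part).values.loc["m"]
        np.testing.assert_allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(15, 12))
        part = ModulePartition(pd.Series(["m"] * 15, index=[f"g{i}" for i in range(15)]))
        eg = compute_eigengenes(_expr(x), part)
        oracle_vec, oracle_ve = eigengene_oracle(x)
        got = eg.values.loc["m"].to_numpy()
        if np.dot(got, oracle_vec) < 0:
            oracle_vec = -oracle_vec
        np.testing.assert_allclose(got, oracle_vec, atol=1e-9)
        assert eg.variance_explained["m"] == pytest.approx(oracle_ve, abs=1e-9)

    def test_maximal_variance_property(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 8))
        part = ModulePartition(pd.Series(["m"] * 10, index=[f"g{i}" for i in range(10)]))
        eg = compute_eigengenes(_expr(x), part).values.loc["m"].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        best = np.sum((z @ eg) ** 2)
        for _ in range(200):
            v = rng.normal(size=8)
            v /= np.linalg.norm(v)
            assert np.sum((z @ v) ** 2) <= best + 1e-9

    def test_single_gene_module_errors(self):
        x = np.random.default_rng(1).normal(size=(2, 6))
        part = ModulePartition(pd.Series(["a", "b"], index=["g0", "g1"]))
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_eigengenes(_expr(x), part)


class TestMergeModules:
    def _two_identical_modules(self):
        rng = np.random.default_rng(6)
        profile = rng.normal(size=12)
        x = profile[None, :] + 0.01 * rng.normal(size=(8, 12))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"g{i}" for i in range(8)])
        return _expr(x), ModulePartition(labels)

    def test_identical_eigengenes_merged(self):
        expr, part = self._two_identical_modules()
        merged = merge_modules(expr, part, 0.9)
        assert len(merged.modules) == 1

    def test_threshold_one_no_merges(self):
        expr, part = self._two_identical_modules()
        merged = merge_modules(expr, part, 1.0)
        assert len(merged.modules) == 2

    def test_three_similar_modules_chain_merge(self):
        rng = np.random.default_rng(9)
        profile = rng.normal(size=16)
        x = profile[None, :] + 0.15 * rng.normal(size=(12, 16))
        labels = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=[f"g{i}" for i in range(12)])
        expr = _expr(x)
        eg = compute_eigengenes(expr, ModulePartition(labels))
        cors = np.corrcoef(eg.values.to_numpy())
        assert np.all(cors[np.triu_indices(3, 1)] > 0.9)  # premise of the trace
        merged = merge_modules(expr, ModulePartition(labels), 0.9)
        assert len(merged.modules) == 1


class TestHubGenes:
    def test_uncorrelated_trait_excluded(self):
        rng = np.random.default_rng(5)
        shared = rng.normal(size=10)
        x = shared[None, :] + 0.05 * rng.normal(size=(40, 10))
        expr = _expr(x)
        part = ModulePartition(pd.Series(["m"] * 40, index=expr.gene_ids))
        # trait orthogonal to the shared profile by construction
        trait = rng.normal(size=10)
        trait -= trait @ shared / (shared @ shared) * shared
        z = (x - x.mean(axis=1, keepdims=True))
        traits = pd.DataFrame({"t": trait}, index=expr.sample_ids)
        hubs = call_hub_genes(expr, part, traits, beta=1, k_threshold=30, gs_threshold=0.95)
        assert hubs.empty

    def test_perfect_module_connectivity(self):
        profile = np.arange(8.0)
        x = np.tile(profile, (61, 1)) * np.linspace(1, 2, 61)[:, None]
        expr = _expr(x)
        part = ModulePartition(pd.Series(["m"] * 61, index=expr.gene_ids))
        kim = intramodular_connectivity(expr, part, beta=1)
        np.testing.assert_allclose(kim.to_numpy(), 60.0, atol=1e-9)
        traits = pd.DataFrame({"t": profile}, index=expr.sample_ids)
        hubs = call_hub_genes(expr, part, traits, beta=1, k_threshold=30, gs_threshold=0.2)
        assert len(hubs) == 61

    def test_matches_brute_force(self, small_sim):
        from ketonet.expression_preprocess import vst_normalize

        counts, info, _, truth = small_sim
        expr = vst_normalize(counts)
        part = ModulePartition(truth.module_labels.loc[expr.gene_ids])
        traits = info.state_indicators()
        hubs = call_hub_genes(expr, part, traits, beta=6, k_threshold=5, gs_threshold=0.3)

        # brute force: per gene, loop over module peers and traits
        a = np.abs(np.corrcoef(expr.values)) ** 6
        np.fill_diagonal(a, 0.0)
        expected = []
        for gi, gene in enumerate(expr.gene_ids):
            mod = part.labels[gene]
            if mod == UNASSIGNED:
                continue
            peers = [i for i, g in enumerate(expr.gene_ids) if part.labels[g] == mod and i != gi]
            kim = sum(a[gi, j] for j in peers)
            gs = max(
                abs(np.corrcoef(expr.values[gi], traits[t].to_numpy())[0, 1])
                for t in traits.columns
            )
            if kim > 5 and gs > 0.3:
                expected.append(gene)
        assert sorted(hubs["gene_id"]) == sorted(expected)
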