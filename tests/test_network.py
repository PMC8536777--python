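"""Co-expression network: bicor, soft threshold, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chronode import (bicor, bicor_matrix, signed_hybrid_adjacency,
                      pick_soft_threshold, tom_similarity, detect_modules,
                      module_eigengene, scale_free_fit)
from chronode.network import DEFAULT_POWERS, CorrelationMatrix


def bicor_oracle(x, y, c=9.0):
    """Independently coded biweight midcorrelation from the weight formula."""
    def tilde(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    xt, yt = tilde(np.asarray(x, float)), tilde(np.asarray(y, float))
    return float(xt @ yt / np.sqrt((xt @ xt) * (yt @ yt)))


def _blocks_expr(sizes, n_samples=40, within=0.9, seed=0):
    """Planted-block expression: genes in a block share a latent profile."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    noise_sd = np.sqrt(1.0 / within - 1.0)
    for b, size in enumerate(sizes):
        latent = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(latent + noise_sd * rng.normal(size=n_samples))
            labels.append(b + 1)
    expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    return expr, np.array(labels)


class TestBicor:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(size=20)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_antisymmetric_vector_gives_minus_one(self):
        x = np.random.default_rng(1).normal(size=20)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_weight_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_matrix_agrees_with_pairwise_and_is_symmetric(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(10, 15)))
        R = bicor_matrix(expr).values
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        for i in range(10):
            for j in range(i):
                assert R[i, j] == pytest.approx(
                    bicor(expr.iloc[i], expr.iloc[j]), abs=1e-10)

    def test_constant_gene_recorded_as_zero_with_flag(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(np.vstack([np.full(12, 3.0), rng.normal(size=(3, 12))]),
                            index=["const", "a", "b", "c"])
        cor = bicor_matrix(expr)
        assert "const" in cor.fallback_genes
        assert np.all(cor.values[0, 1:] == 0.0)


class TestAdjacencyAndTom:
    def test_signed_hybrid_zeroes_negative_correlations(self):
        rng = np.random.default_rng(5)
        R = np.clip(rng.uniform(-1, 1, size=(20, 20)), -1, 1)
        R = 0.5 * (R + R.T)
        np.fill_diagonal(R, 1.0)
        beta = 7
        adj = signed_hybrid_adjacency(R, beta)
        off = ~np.eye(20, dtype=bool)
        expected = np.where(R > 0, R, 0.0) ** beta
        assert np.allclose(adj[off], expected[off])

    def test_tom_disconnected_pair_is_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.0
        A[2, 3] = A[3, 2] = 1.0
        tom = tom_similarity(A)
        assert tom[0, 1] == 0.0

    def test_tom_complete_unit_graph_is_one(self):
        A = np.ones((6, 6))
        tom = tom_similarity(A)
        assert np.allclose(tom, 1.0)

    def test_tom_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0, 1, size=(6, 6))
        A = 0.5 * (A + A.T)
        np.fill_diagonal(A, 0.0)
        tom = tom_similarity(A)
        k = A.sum(axis=0)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                num = sum(A[i, u] * A[u, j] for u in range(6)) + A[i, j]
                den = min(k[i], k[j]) + 1 - A[i, j]
                assert tom[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError):
            tom_similarity(np.array([[0.0, 0.5], [0.1, 0.0]]))


class TestSoftThreshold:
    def test_exact_power_law_connectivities_fit_well(self):
        """Connectivities drawn from an exact power law p(k) ~ k^-2 give a
        near-perfect signed scale-free fit."""
        rng = np.random.default_rng(7)
        k = (1 - rng.uniform(size=5000)) ** (-1.0)  # Pareto alpha=1 -> p(k)~k^-2
        r2, slope = scale_free_fit(k, n_bins=15)
        assert r2 >= 0.98
        assert slope < 0

    def test_default_candidate_grid_includes_fifteen(self):
        assert 15 in DEFAULT_POWERS

    def test_degenerate_two_gene_input_rejected(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError):
            pick_soft_threshold(CorrelationMatrix(values=R, genes=["a", "b"]))

    def test_all_nonpositive_correlations_rejected(self):
        R = -0.5 * np.ones((60, 60))
        np.fill_diagonal(R, 1.0)
        # zero the diagonal influence by construction: only off-diag is used
        cm = CorrelationMatrix(values=np.where(np.eye(60, dtype=bool), 1.0, -0.5),
                               genes=[str(i) for i in range(60)])
        with pytest.raises(ValueError, match="non-positive"):
            pick_soft_threshold(cm)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        expr, truth = _blocks_expr([50, 50], within=0.9, seed=8)
        R = bicor_matrix(expr).values
        tom = tom_similarity(signed_hybrid_adjacency(R, 6))
        labels = detect_modules(1 - tom, min_module_size=30)
        assert labels.max() == 2
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_iid_noise_mostly_unassigned(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(size=(200, 30)))
            R = bicor_matrix(expr).values
            tom = tom_similarity(signed_hybrid_adjacency(R, 6))
            labels = detect_modules(1 - tom, min_module_size=30)
            fracs.append((labels == 0).mean())
        assert np.mean(fracs) >= 0.8

    def test_single_undersized_block_unassigned(self):
        expr, _ = _blocks_expr([20], within=0.9, seed=9)
        R = bicor_matrix(expr).values
        tom = tom_similarity(signed_hybrid_adjacency(R, 6))
        labels = detect_modules(1 - tom, min_module_size=30)
        assert np.all(labels == 0)


class TestEigengene:
    def test_identical_genes_have_kme_one(self):
        x = np.random.default_rng(10).normal(size=25)
        expr = pd.DataFrame([x, x, x], index=["a", "b", "c"])
        ms = module_eigengene(expr, [1, 1, 1])
        assert np.allclose(ms.kme.to_numpy(), 1.0)

    def test_explained_variance_matches_svd_oracle(self):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.normal(size=(12, 30)))
        ms = module_eigengene(expr, [1] * 12)
        X = expr.to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        s = np.linalg.svd(Xs, compute_uv=False)
        assert ms.explained_variance[1] == pytest.approx(
            s[0] ** 2 / (s ** 2).sum(), abs=1e-10)

    def test_sign_orientation_invariant_to_global_flip(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=20)
        expr = pd.DataFrame([base + rng.normal(0, 0.1, 20) for _ in range(8)])
        ms_pos = module_eigengene(expr, [1] * 8)
        ms_neg = module_eigengene(-expr, [1] * 8)
        # eigengene orientation follows the module average, so a global flip
        # flips the eigengene; correlation magnitude with members unchanged
        assert np.allclose(np.abs(ms_pos.eigengenes.to_numpy()),
                           np.abs(ms_neg.eigengenes.to_numpy()), atol=1e-8)

    def test_singleton_module_eigengene_is_standardized_gene(self):
        x = np.random.default_rng(13).normal(size=15)
        expr = pd.DataFrame([x], index=["a"])
        ms = module_eigengene(expr, [1])
        xs = (x - x.mean()) / x.std()
        v = ms.eigengenes.loc[1].to_numpy()
        assert np.allclose(np.abs(v), np.abs(xs / np.linalg.norm(xs)), atol=1e-10)
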