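"""Sparse-filtering correctness and comparison-method adapters."""

import numpy as np
import pytest

import voxsparse as vs
from voxsparse.decomposition import SparseFilter, sft_objective

from conftest import make_expression


@pytest.fixture(scope="module")
def small_fit(tiny_phantom):
    expr, _, _ = tiny_phantom
    return vs.sparse_filter(expr, 3, max_iter=150, seed=0)


class TestSftObjective:
    def test_identity_activations(self):
        # both normalizations leave the 2x2 identity unchanged; l1 sum = 2
        assert sft_objective(np.eye(2)) == pytest.approx(2.0)

    def test_single_feature_positive_constants(self):
        # one feature: every example's normalized vector is the scalar 1
        f = np.full((7, 1), 3.7)
        assert sft_objective(f) == pytest.approx(7.0)

    def test_exact_scale_invariance(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((20, 4))
        base = sft_objective(f)
        for c in (1e-6, 0.5, 3.0, 1e6):
            assert sft_objective(c * f) == pytest.approx(base, rel=1e-12)

    def test_zero_feature_column_raises(self):
        f = np.zeros((5, 2)); f[:, 0] = 1.0
        with pytest.raises(ValueError, match="zero row norm"):
            sft_objective(f)


class TestSparseFilterCore:
    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.standard_normal((6, 4)))
        model = SparseFilter(expr, 3)
        w = rng.standard_normal(12)
        _, grad = model._objective_grad(w)
        h = 1e-6
        num = np.empty_like(w)
        for i in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[i] += h; wm[i] -= h
            num[i] = (model._objective_grad(wp)[0]
                      - model._objective_grad(wm)[0]) / (2 * h)
        rel = np.abs(grad - num) / np.maximum(np.abs(num), 1e-8)
        assert rel.max() < 1e-4

    def test_objective_trace_non_increasing(self, small_fit):
        trace = np.asarray(small_fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_per_example_feature_norms_are_one(self, small_fit):
        norms = np.linalg.norm(small_fit.features, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-9

    def test_full_objective_scale_invariant(self, tiny_phantom):
        expr, _, _ = tiny_phantom
        model = SparseFilter(expr, 2)
        rng = np.random.default_rng(3)
        w = rng.standard_normal((2, expr.n_genes))
        base = model.objective(w)
        scaled = vs.ExpressionMatrix(7.0 * expr.values, expr.voxel_coords,
                                     expr.gene_ids)
        model7 = SparseFilter(scaled, 2)
        assert model7.objective(w) == pytest.approx(base, rel=1e-6)

    def test_objective_invariant_to_weight_row_rescaling(self, tiny_phantom):
        # the first normalization divides out any per-feature scale; the
        # soft-absolute epsilon leaves a small curvature-floor residual
        expr, _, _ = tiny_phantom
        model = SparseFilter(expr, 3)
        rng = np.random.default_rng(4)
        w = rng.standard_normal((3, expr.n_genes))
        scales = np.array([0.01, 1.0, 250.0])[:, None]
        assert model.objective(w * scales) == \
            pytest.approx(model.objective(w), rel=1e-5)

    def test_fixed_seed_bit_identical(self, tiny_phantom):
        expr, _, _ = tiny_phantom
        a = vs.sparse_filter(expr, 2, max_iter=60, seed=5)
        b = vs.sparse_filter(expr, 2, max_iter=60, seed=5)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.features, b.features)
        assert a.objective_trace == b.objective_trace

    def test_random_init_also_monotone(self, tiny_phantom):
        expr, _, _ = tiny_phantom
        res = vs.sparse_filter(expr, 2, max_iter=60, seed=1, init="random")
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_k_exceeding_voxels_rejected(self):
        expr = make_expression(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError, match="exceeds voxel count"):
            SparseFilter(expr, 6)

    def test_non_finite_input_rejected(self):
        vals = np.ones((4, 2)); vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            SparseFilter(make_expression(vals), 1)


class TestAdapters:
    def test_pca_exact_low_rank_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 2)) @ rng.standard_normal((2, 9))
        expr = make_expression(x)
        res = vs.decompose(expr, "pca", 2, seed=0)
        recon = res.features @ res.weights.T + x.mean(axis=0)
        assert np.abs(recon - x).max() < 1e-8

    def test_kpca_has_no_weights(self, tiny_phantom):
        expr, _, _ = tiny_phantom
        res = vs.decompose(expr, "kpca", 3, {"kernel": "quadratic"}, seed=0)
        assert res.weights is None and not res.has_weights
        assert res.features.shape == (expr.n_voxels, 3)
        with pytest.raises(ValueError, match="no gene weights"):
            res.top_genes(0)

    def test_ica_shapes(self, tiny_phantom):
        expr, _, _ = tiny_phantom
        res = vs.decompose(expr, "ica", 3, seed=0)
        assert res.features.shape == (expr.n_voxels, 3)
        assert res.weights.shape == (expr.n_genes, 3)

    @pytest.mark.parametrize("method,hp,msg", [
        ("banana", None, "unknown method"),
        ("kpca", {"kernel": "laplace"}, "unknown kernel"),
        ("spca", None, "requires the l1 penalty"),
        ("dlsc", {"alpha": -1.0}, "nonnegative"),
        ("kpca", None, "requires a 'kernel'"),
    ])
    def test_bad_arguments(self, tiny_phantom, method, hp, msg):
        expr, _, _ = tiny_phantom
        with pytest.raises(ValueError, match=msg):
            vs.decompose(expr, method, 2, hp, seed=0)


class TestSerialization:
    def test_roundtrip(self, tmp_path, small_fit, tiny_phantom):
        expr, _, _ = tiny_phantom
        small_fit.save(tmp_path / "comp")
        back = vs.DecompositionResults.load(tmp_path / "comp",
                                            expression=expr)
        assert np.allclose(back.weights, small_fit.weights)
        assert np.allclose(back.features, small_fit.features)
        assert back.method == "sft"
        assert back.objective_trace == small_fit.objective_trace
        assert back.gene_ids == small_fit.gene_ids

    def test_summary_mentions_method_and_objective(self, small_fit):
        s = small_fit.summary()
        assert "sft" in s and "objective" in s
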