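"""The factorization engine: unfoldings, updates, objective, fit diagnostics."""

import numpy as np
import pytest

from wonparafac import (SyntheticSpec, dt_similarity, explained_variation,
                        fit, khatri_rao, make_planted_cube,
                        normalize_and_sort, refold, unfold, update_factor,
                        weighted_objective)
from wonparafac.core import (MODES, FactorModel, greedy_cosine_match,
                             multiplicative_step, paired_khatri_rao)
from wonparafac.cube import DataCube, compute_weights


def _cube_from(values):
    values = np.asarray(values, dtype=float)
    g, c, d = values.shape
    return DataCube(values=values, gene_ids=[f"g{i}" for i in range(g)],
                    sample_ids=[f"s{i}" for i in range(c)],
                    layer_names=[f"L{i}" for i in range(d)])


def _random_model(shape, k, seed=0, w=0.0):
    rng = np.random.default_rng(seed)
    g, c, d = shape
    return FactorModel(G=rng.uniform(0.1, 1.0, (g, k)),
                       C=rng.uniform(0.1, 1.0, (c, k)),
                       D=rng.uniform(0.1, 1.0, (d, k)), k=k, w=w)


# --- straight-line transcriptions of the gene-mode update formulas ----------
# Independent of the package's unfolding/Khatri-Rao conventions: pure loops
# over genes i, samples j, layers l and factor indices.

def oracle_gene_numerator(X, W, C, D):
    g, c, d = X.shape
    k = C.shape[1]
    num = np.zeros((g, k))
    for i in range(g):
        for r in range(k):
            num[i, r] = sum(W[i, j, l] * X[i, j, l] * C[j, r] * D[l, r]
                            for j in range(c) for l in range(d))
    return num


def oracle_gene_denominator_plain(X, W, G, C, D):
    g, c, d = X.shape
    k = G.shape[1]
    Xhat = np.einsum("ir,jr,lr->ijl", G, C, D)
    den = np.zeros((g, k))
    for i in range(g):
        for r in range(k):
            den[i, r] = sum(W[i, j, l] * Xhat[i, j, l] * C[j, r] * D[l, r]
                            for j in range(c) for l in range(d))
    return den


def oracle_gene_denominator_orthogonal(X, W, G, C, D):
    g, c, d = X.shape
    k = G.shape[1]
    Xhat = np.einsum("ir,jr,lr->ijl", G, C, D)
    den = np.zeros((g, k))
    for i in range(g):
        for r in range(k):
            den[i, r] = sum(W[i, j, l] * Xhat[i, j, l] * X[i2, j, l] * G[i2, r]
                            for j in range(c) for l in range(d)
                            for i2 in range(g))
    return den


def oracle_gene_update(X, W, G, C, D, w):
    num = oracle_gene_numerator(X, W, C, D)
    den0 = oracle_gene_denominator_plain(X, W, G, C, D)
    den1 = oracle_gene_denominator_orthogonal(X, W, G, C, D)
    return G * num / ((1.0 - w) * den0 + w * den1)


class TestKhatriRao:
    def test_identity_columns(self):
        out = khatri_rao(np.eye(2), np.eye(2))
        expected = np.zeros((4, 2))
        expected[0, 0] = 1.0  # e1 (x) e1
        expected[3, 1] = 1.0  # e2 (x) e2
        np.testing.assert_array_equal(out, expected)

    def test_single_column_kronecker_ordering(self):
        out = khatri_rao(np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]]))
        np.testing.assert_array_equal(out.ravel(), [3.0, 4.0, 6.0, 8.0])

    def test_column_norms_multiply(self):
        rng = np.random.default_rng(5)
        A, B = rng.uniform(size=(4, 3)), rng.uniform(size=(5, 3))
        out = khatri_rao(A, B)
        np.testing.assert_allclose(np.linalg.norm(out, axis=0),
                                   np.linalg.norm(A, axis=0) * np.linalg.norm(B, axis=0))

    def test_column_mismatch_raises(self):
        with pytest.raises(ValueError):
            khatri_rao(np.ones((2, 2)), np.ones((2, 3)))


class TestUnfoldRefold:
    def test_each_unfolding_is_a_bijection_of_entries(self):
        X = np.arange(1.0, 9.0).reshape(2, 2, 2)
        for mode in MODES:
            assert sorted(unfold(X, mode).ravel()) == list(range(1, 9))

    @pytest.mark.parametrize("mode", MODES)
    def test_round_trip(self, mode):
        X = np.random.default_rng(2).uniform(size=(3, 4, 2))
        np.testing.assert_array_equal(refold(unfold(X, mode), mode, X.shape), X)

    @pytest.mark.parametrize("mode", MODES)
    def test_model_unfolding_matches_khatri_rao(self, mode):
        model = _random_model((3, 4, 2), k=2, seed=1)
        X = model.reconstruct()
        Y = paired_khatri_rao(model, mode)
        np.testing.assert_allclose(unfold(X, mode), Y @ model.factor(mode).T,
                                   atol=1e-12)


class TestUpdateFactor:
    def test_fixed_point_at_zero_residual(self):
        model = _random_model((5, 4, 3), k=2, seed=3, w=0.0)
        cube = _cube_from(model.reconstruct())
        for mode in MODES:
            updated = update_factor(cube, "uniform", model, mode)
            np.testing.assert_allclose(updated.factor(mode), model.factor(mode),
                                       atol=1e-10)

    @pytest.mark.parametrize("w", [0.0, 0.1, 1.0])
    def test_gene_update_matches_straight_line_oracle(self, w):
        rng = np.random.default_rng(11)
        X = rng.uniform(0.1, 1.0, size=(4, 3, 2))
        cube = _cube_from(X)
        model = _random_model(X.shape, k=2, seed=4, w=w)
        Wt = compute_weights(cube)
        expected = oracle_gene_update(X, Wt.values, model.G, model.C, model.D, w)
        out = update_factor(cube, Wt, model, "gene")
        np.testing.assert_allclose(out.G, expected, atol=1e-10)

    def test_non_negativity_preserved(self, random_cube):
        model = _random_model(random_cube.shape, k=3, seed=5, w=0.1)
        for mode in MODES:
            model = update_factor(random_cube, None, model, mode)
            assert model.factor(mode).min() >= 0.0


class TestWeightedObjective:
    def test_zero_residual_and_uniform_reduction(self):
        model = _random_model((4, 3, 2), k=2, seed=6)
        cube = _cube_from(model.reconstruct())
        assert weighted_objective(cube, "uniform", model) == pytest.approx(0.0, abs=1e-18)
        other = _cube_from(cube.values + 0.5)
        sse = np.sum((model.reconstruct() - other.values) ** 2)
        assert weighted_objective(other, "uniform", model) == pytest.approx(sse)

    def test_matches_triple_loop_oracle(self, random_cube):
        model = _random_model(random_cube.shape, k=2, seed=7)
        Wt = compute_weights(random_cube)
        Xhat = model.reconstruct()
        expected = sum(
            Wt.values[i, j, l] * (Xhat[i, j, l] - random_cube.values[i, j, l]) ** 2
            for i in range(random_cube.shape[0])
            for j in range(random_cube.shape[1])
            for l in range(random_cube.shape[2]))
        assert weighted_objective(random_cube, Wt, model) == pytest.approx(expected)


class TestFit:
    def test_planted_noiseless_recovery(self, small_planted):
        cube, truth = small_planted
        model = fit(cube, k=3, w=0.0, seed=1, tol=1e-12, max_iter=600)
        relerr = (np.linalg.norm(model.reconstruct() - cube.values)
                  / np.linalg.norm(cube.values))
        assert relerr < 1e-3
        assert greedy_cosine_match(truth.G, model.G).min() > 0.95
        assert greedy_cosine_match(truth.C, model.C).min() > 0.95

    def test_rank1_cube_recovered_for_any_w(self):
        spec = SyntheticSpec(g=15, c=10, d=3, k_true=1, noise_sd=0.0,
                             cis_factors=0, tissue_blocks=2, seed=4)
        cube, truth = make_planted_cube(spec)
        for w in (0.0, 0.5, 1.0):
            model = fit(cube, k=1, w=w, seed=2, tol=1e-12, max_iter=400)
            assert greedy_cosine_match(truth.G, model.G)[0] > 0.999
            assert greedy_cosine_match(truth.C, model.C)[0] > 0.999

    def test_default_mixing_weight_is_0p1(self, random_cube):
        model = fit(random_cube, k=2, seed=0, max_iter=5)
        assert model.w == 0.1

    def test_bit_reproducible_given_seed(self, random_cube):
        a = fit(random_cube, k=2, seed=9, max_iter=20)
        b = fit(random_cube, k=2, seed=9, max_iter=20)
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_array_equal(a.C, b.C)
        np.testing.assert_array_equal(a.D, b.D)

    def test_objective_trace_recorded_and_monotone(self, random_cube):
        model = fit(random_cube, k=3, w=0.1, seed=0, max_iter=60, tol=0.0)
        tr = np.asarray(model.objective_trace)
        assert len(tr) == 61
        assert np.all(np.diff(tr) <= tr[:-1] * 1e-8 + 1e-15)

    def test_matches_classical_nmf_on_single_layer(self):
        """With one layer, unit weights and w=0, alternating gene/sample
        multiplicative steps reproduce classical MU NMF (sklearn) from the
        same init, elementwise, for 5 iterations (layer mode frozen at 1)."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(12)
        X = rng.uniform(0.1, 1.0, size=(12, 9))
        k = 3
        W0 = rng.uniform(0.1, 1.0, size=(12, k))
        H0 = rng.uniform(0.1, 1.0, size=(k, 9))
        nmf = NMF(n_components=k, init="custom", solver="mu",
                  beta_loss="frobenius", max_iter=5, tol=0.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Wref = nmf.fit_transform(X, W=W0.copy(), H=H0.copy())
        Href = nmf.components_

        ones = np.ones_like(X)
        W, H = W0.copy(), H0.copy()
        for _ in range(5):
            W = multiplicative_step(X.T, ones.T, W, H.T)
            H = multiplicative_step(X, ones, H.T, W).T
        np.testing.assert_allclose(W, Wref, rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(H, Href, rtol=1e-6, atol=1e-10)

    def test_orthogonality_pressure_reduces_gene_overlap(self, small_planted):
        cube, _ = small_planted
        def offdiag(model):
            Gn = model.G / np.maximum(np.linalg.norm(model.G, axis=0), 1e-12)
            S = np.abs(Gn.T @ Gn)
            return S[np.triu_indices(model.k, k=1)].mean()
        m0 = fit(cube, k=3, w=0.0, seed=3, max_iter=300)
        m1 = fit(cube, k=3, w=1.0, seed=3, max_iter=300)
        assert offdiag(m1) < offdiag(m0)

    def test_invalid_arguments(self, random_cube):
        with pytest.raises(ValueError):
            fit(random_cube, k=0)
        with pytest.raises(ValueError):
            fit(random_cube, k=2, w=1.5)


class TestNormalizeAndSort:
    def test_norm_product_and_unit_columns(self):
        g = np.zeros((3, 1)); g[0] = 2.0
        c = np.zeros((2, 1)); c[0] = 3.0
        d = np.zeros((2, 1)); d[0] = 4.0
        model = normalize_and_sort(FactorModel(G=g, C=c, D=d, k=1))
        assert model.scales[0] == pytest.approx(24.0)
        for F in (model.G, model.C, model.D):
            assert np.linalg.norm(F, axis=0)[0] == pytest.approx(1.0)

    def test_idempotent_and_reconstruction_invariant(self):
        model = _random_model((5, 4, 3), k=3, seed=8)
        once = normalize_and_sort(model)
        twice = normalize_and_sort(once)
        np.testing.assert_allclose(once.reconstruct(), model.reconstruct(), atol=1e-10)
        np.testing.assert_allclose(twice.scales, once.scales, rtol=1e-12)
        np.testing.assert_allclose(twice.G, once.G, atol=1e-12)

    def test_scales_sorted_and_zero_factor_flagged(self):
        rng = np.random.default_rng(9)
        G = rng.uniform(size=(4, 3)); G[:, 1] = 0.0
        model = normalize_and_sort(FactorModel(G=G, C=rng.uniform(size=(3, 3)),
                                               D=rng.uniform(size=(2, 3)), k=3))
        assert np.all(np.diff(model.scales) <= 0)
        assert model.scales[-1] == 0.0
        assert model.zero_factors == [2]


class TestDiagnostics:
    def test_explained_variation_extremes(self, random_cube):
        model = _random_model(random_cube.shape, k=2, seed=10)
        perfect = _cube_from(model.reconstruct())
        assert explained_variation(perfect, model) == pytest.approx(1.0)
        zero = FactorModel(G=np.zeros((random_cube.shape[0], 1)),
                           C=np.zeros((random_cube.shape[1], 1)),
                           D=np.zeros((random_cube.shape[2], 1)), k=1)
        assert explained_variation(random_cube, zero) == pytest.approx(0.0)

    def test_per_sample_matches_fiber_oracle(self, random_cube):
        model = _random_model(random_cube.shape, k=2, seed=11)
        ev = explained_variation(random_cube, model, by="sample")
        Xhat = model.reconstruct()
        for j in range(random_cube.shape[1]):
            num = np.sum((Xhat[:, j, :] - random_cube.values[:, j, :]) ** 2)
            den = np.sum(random_cube.values[:, j, :] ** 2)
            assert ev[j] == pytest.approx(1.0 - num / den)

    def test_dt_similarity_examples(self):
        D = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        model = FactorModel(G=np.ones((3, 2)), C=np.ones((2, 2)), D=D, k=2)
        S = dt_similarity(model)
        assert S[0, 1] == pytest.approx(1.0 / np.sqrt(2.0))
        assert S[0, 2] == pytest.approx(0.0)
        assert S[0, 0] == 1.0 and S[1, 1] == 1.0
        assert np.isnan(S[3, 0]) and np.isnan(S[0, 3])
        np.testing.assert_allclose(S[:3, :3], S[:3, :3].T)
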