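"""PCA, cone fitting, refinement, clustering, and reconstruction.

The small-scale oracles here are independent of the implementation: dense
SVD for PCA, exhaustive conic-subset search (non-negative least squares over
all column subsets) for the extreme-vector selection, and direct
construction for back-projection and reconstruction.
"""

import itertools
import warnings

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.optimize import nnls

import conefit as cf


# ---------------------------------------------------------------- PCA

class TestPCA:
    def test_rank_one_movie_exact(self, rng):
        t = rng.normal(size=20)
        img = rng.normal(size=30)
        A = np.outer(t, img)
        model = cf.pca(A, k=1)
        np.testing.assert_allclose(model.loadings @ model.components, A, atol=1e-8)

    def test_matches_dense_svd_oracle(self, rng):
        A = rng.normal(size=(20, 30))
        A -= A.mean(axis=0)
        model = cf.pca(A, k=5)
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        angles = subspace_angles(model.components.T, Vt[:5].T)
        assert angles.max() < 1e-6
        np.testing.assert_allclose(
            model.eigenvalues, s[:5] ** 2 / (A.shape[0] - 1), rtol=1e-8
        )

    def test_components_orthonormal_and_eigenvalues_sorted(self, rng):
        A = rng.normal(size=(25, 40))
        model = cf.pca(A, k=6)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_tall_matrix_path(self, rng):
        # n < m exercises the pixel-side Gram branch
        A = rng.normal(size=(50, 12))
        model = cf.pca(A, k=4)
        _, s, Vt = np.linalg.svd(A, full_matrices=False)
        assert subspace_angles(model.components.T, Vt[:4].T).max() < 1e-6

    def test_sampling_fraction_one_is_exact_path(self, rng):
        A = rng.normal(size=(20, 30))
        a = cf.pca(A, k=3, sampling_fraction=1.0, seed=5)
        b = cf.pca(A, k=3, sampling_fraction=1.0, seed=99)
        np.testing.assert_array_equal(a.components, b.components)
        np.testing.assert_array_equal(a.loadings, b.loadings)

    def test_sampling_approximates_full_pca(self, rng):
        # strong low-rank structure: sampled pixels still see every source
        t = rng.normal(size=(100, 3))
        imgs = np.abs(rng.normal(size=(3, 200)))
        A = t @ imgs + 0.01 * rng.normal(size=(100, 200))
        full = cf.pca(A, k=3)
        sub = cf.pca(A, k=3, sampling_fraction=0.3, seed=1)
        assert subspace_angles(full.components.T, sub.components.T).max() < 0.05

    def test_sampling_is_seed_deterministic(self, rng):
        A = rng.normal(size=(30, 50))
        a = cf.pca(A, k=3, sampling_fraction=0.5, seed=2)
        b = cf.pca(A, k=3, sampling_fraction=0.5, seed=2)
        np.testing.assert_array_equal(a.components, b.components)

    def test_k_out_of_range_errors(self, rng):
        A = rng.normal(size=(10, 8))
        with pytest.raises(ValueError):
            cf.pca(A, k=0)
        with pytest.raises(ValueError):
            cf.pca(A, k=9)

    def test_rank_deficient_truncates_with_warning(self, rng):
        A = np.outer(rng.normal(size=12), rng.normal(size=15))
        with pytest.warns(RuntimeWarning, match="rank"):
            model = cf.pca(A, k=4)
        assert model.k == 1

    def test_reduced_preserves_column_geometry(self, rng):
        A = rng.normal(size=(20, 15))
        model = cf.pca(A, k=min(A.shape))
        B = model.reduced()
        np.testing.assert_allclose(B.T @ B, A.T @ A, atol=1e-8)


# ---------------------------------------------------------- cone fitting

def _conic_mixture_matrix(rng, m=6, q=3, n=10):
    """Columns = scaled pure generators (first q) + strictly mixed columns.

    Mixture weights sum to < 1 so mixtures sit strictly inside the cone
    section spanned by the generators, as at glomerulus fringes where
    scattered light attenuates rather than amplifies the pure signals.
    """
    G = np.abs(rng.normal(size=(m, q))) + 0.1
    cols = [G[:, j] * rng.uniform(0.9, 1.2) for j in range(q)]
    while len(cols) < n:
        w = np.zeros(q)
        pick = rng.choice(q, size=2, replace=False)
        a = rng.uniform(0.3, 0.7)
        w[pick] = rng.uniform(0.6, 0.85) * np.array([a, 1.0 - a])
        cols.append(G @ w)
    return np.column_stack(cols), list(range(q))


def _exhaustive_pure_subset(A, q, tol=1e-8):
    """Oracle: the q-subsets whose conic span reconstructs every column."""
    n = A.shape[1]
    good = []
    for subset in itertools.combinations(range(n), q):
        basis = A[:, subset]
        ok = True
        for j in range(n):
            _, resid = nnls(basis, A[:, j])
            if resid > tol * max(1.0, np.linalg.norm(A[:, j])):
                ok = False
                break
        if ok:
            good.append(set(subset))
    return good


class TestConeFitting:
    def test_two_pure_columns_selected_from_mixture(self):
        e1, e2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        A = np.column_stack([e1, e2, 0.5 * e1 + 0.5 * e2])
        for seed in range(5):
            model = cf.cone_fitting(A, c=2, seed=seed)
            assert set(model.source_pixels) == {0, 1}
            np.testing.assert_allclose(model.T @ model.S, A, atol=1e-10)

    def test_identical_columns_single_extreme_vector(self):
        v = np.array([3.0, 4.0])
        A = np.tile(v[:, None], (1, 5))
        model = cf.cone_fitting(A, c=1, seed=0)
        np.testing.assert_allclose(model.T[:, 0], v / 5.0, atol=1e-12)
        R = A - model.T @ model.S
        assert np.linalg.norm(R) < 1e-10

    @pytest.mark.parametrize("q,n", [(2, 8), (3, 10), (4, 12)])
    def test_recovers_unique_pure_generator_subset(self, q, n):
        rng = np.random.default_rng(100 + q)
        A, pure = _conic_mixture_matrix(rng, m=q + 3, q=q, n=n)
        oracle_subsets = _exhaustive_pure_subset(A, q)
        assert oracle_subsets == [set(pure)], "construction must have unique pure subset"
        model = cf.cone_fitting(A, c=q, seed=0)
        assert set(model.source_pixels) == set(pure)

    def test_monotone_frobenius_decrease(self, rng):
        A = rng.normal(size=(15, 40))
        norms = []
        R = A.copy()
        model = cf.cone_fitting(A, c=10, seed=0)
        for r in range(model.c):
            t = R[:, model.source_pixels[r]] if r == 0 else None
            norms.append(np.linalg.norm(R))
            tt = R[:, model.source_pixels[r]]
            tt = tt / np.linalg.norm(tt)
            s0 = np.maximum(R.T @ tt, 0.0)
            R = R - np.outer(tt, s0)
        norms.append(np.linalg.norm(R))
        diffs = np.diff(norms)
        assert np.all(diffs <= 1e-9)

    def test_non_negative_S_and_unit_norm_T(self, rng):
        A = rng.normal(size=(12, 30))
        model = cf.cone_fitting(A, c=8, seed=3)
        assert np.all(model.S >= 0)
        np.testing.assert_allclose(np.linalg.norm(model.T, axis=0), 1.0, atol=1e-10)

    def test_selected_columns_never_reselected(self, rng):
        A = np.abs(rng.normal(size=(10, 25)))
        model = cf.cone_fitting(A, c=12, seed=1)
        assert len(set(model.source_pixels)) == model.c

    def test_nested_prefix_property(self, rng):
        A = rng.normal(size=(12, 40))
        small = cf.cone_fitting(A, c=5, seed=9)
        big = cf.cone_fitting(A, c=10, seed=9)
        assert cf.nested_prefix_check(small, big)
        assert cf.nested_prefix_check(small, small)

    def test_nested_check_rejects_different_seeds(self, rng):
        A = rng.normal(size=(12, 40))
        a = cf.cone_fitting(A, c=5, seed=1)
        b = cf.cone_fitting(A, c=8, seed=2)
        with pytest.raises(ValueError):
            cf.nested_prefix_check(a, b)

    def test_early_stop_on_low_rank_input(self, rng):
        A = np.abs(np.outer(rng.normal(size=8), rng.normal(size=12)))
        with pytest.warns(RuntimeWarning, match="residual"):
            model = cf.cone_fitting(A, c=5, seed=0)
        assert model.c < 5

    def test_c_out_of_range(self, rng):
        A = rng.normal(size=(5, 6))
        with pytest.raises(ValueError):
            cf.cone_fitting(A, c=7)

    def test_pca_space_matches_full_space_selection(self, rng):
        A = np.abs(rng.normal(size=(15, 25)))
        A -= A.mean(axis=0)
        model_full = cf.cone_fitting(A, c=4, seed=0)
        reduced = cf.pca(A, k=min(A.shape)).reduced()
        model_red = cf.cone_fitting(reduced, c=4, seed=0)
        assert model_full.source_pixels == model_red.source_pixels


# ------------------------------------------------------------- refinement

class TestRefine:
    def test_noise_free_disjoint_members_exact(self, small_noise_free_disjoint):
        movie, truth = small_noise_free_disjoint
        res = cf.extract_sources(movie, k=8, c=8, min_similarity=0.0)
        got = {frozenset(mem.tolist()) for mem in res.refined.members}
        want = {frozenset(mask.tolist()) for mask in truth.masks}
        assert got == want
        score = cf.correlation_score(res.refined.T_hat, truth.U)
        assert all(rho > 1 - 1e-9 for _, rho in score.per_signal)

    def test_min_similarity_one_keeps_only_duplicates(self, small_noise_free_disjoint):
        movie, truth = small_noise_free_disjoint
        z, _ = cf.zscore(movie)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cf.cone_fitting(cf.pca(z, k=8).reduced(), c=4, seed=0)
        refined = cf.refine(z, model, min_similarity=1.0)
        # each member set is exactly the pixels duplicating the basis column
        for r, mem in zip(refined.kept, refined.members):
            basis_col = z.data[:, model.source_pixels[r]]
            for p in mem:
                np.testing.assert_allclose(z.data[:, p], basis_col, atol=1e-9)

    def test_overlap_pixels_unassigned_at_high_threshold(self):
        # with a pure-source basis, additive mixtures at cluster fringes have
        # cosine sqrt((1+rho)/2) < 0.87 to every pure signal (|rho| < 0.5),
        # so a 0.9 threshold whitens exactly the overlap seams
        spec = cf.SyntheticSpec(
            n_sources=4, m=160, height=24, width=24, cluster_radius=7.0,
            sigma_noise=0.0, seed=5,
        )
        movie, truth = cf.generate_movie(spec)
        assert truth.overlap_pixels().size > 0
        z, _ = cf.zscore(movie)
        centres = [truth.pure_pixels(j)[0] for j in range(4)]
        basis = z.data[:, centres]
        basis /= np.linalg.norm(basis, axis=0)
        model = cf.FactorModel(
            T=basis,
            S=np.maximum(z.data.T @ basis, 0.0).T,
            order=list(range(4)),
            source_pixels=centres,
            init_seed=0,
        )
        refined = cf.refine(z, model, min_similarity=0.9)
        assigned = np.concatenate(refined.members)
        assert np.intersect1d(assigned, truth.overlap_pixels()).size == 0
        # while every single-source pixel stays assigned to its own cluster
        got = {frozenset(mem.tolist()) for mem in refined.members}
        want = {frozenset(truth.pure_pixels(j).tolist()) for j in range(4)}
        assert got == want

    def test_disjoint_supports(self, small_spec):
        movie, _ = cf.generate_movie(small_spec)
        res = cf.extract_sources(movie, k=6, c=6)
        supports = [set(np.flatnonzero(row)) for row in res.refined.S_hat]
        for a, b in itertools.combinations(supports, 2):
            assert not (a & b)

    def test_invalid_refine_arguments_rejected(self, small_spec):
        movie, _ = cf.generate_movie(small_spec)
        z, _ = cf.zscore(movie)
        model = cf.cone_fitting(z.data, c=1, seed=0)
        with pytest.raises(ValueError):
            cf.refine(z, model, assign_metric="euclidean")
        with pytest.raises(ValueError):
            cf.refine(z, model, min_similarity=1.5)


# ---------------------------------------------- clustering / projection

class TestInducedClustering:
    def test_argmax_labels(self):
        S = np.array([[1.0, 0.0], [0.0, 2.0]])
        lm = cf.induced_clustering(S, (1, 2))
        np.testing.assert_array_equal(lm.labels, [[1, 2]])

    def test_zero_column_gets_label_zero(self):
        S = np.array([[1.0, 0.0], [2.0, 0.0]])
        lm = cf.induced_clustering(S, (1, 2))
        np.testing.assert_array_equal(lm.labels, [[2, 0]])

    def test_tie_breaks_to_smallest_row(self):
        S = np.array([[3.0], [3.0]])
        lm = cf.induced_clustering(S, (1, 1))
        assert lm.labels[0, 0] == 1

    def test_negative_S_rejected(self):
        with pytest.raises(ValueError):
            cf.induced_clustering(np.array([[-1.0]]), (1, 1))


class TestBackProject:
    def test_orthonormal_rows_equal_transpose(self, rng):
        S, _ = np.linalg.qr(rng.normal(size=(8, 3)))
        S = S.T  # 3 orthonormal rows of length 8
        A = rng.normal(size=(10, 8))
        np.testing.assert_allclose(cf.back_project(A, S), A @ S.T, atol=1e-10)

    def test_exact_factorisation_recovered(self, rng):
        T0 = rng.normal(size=(20, 4))
        S = np.abs(rng.normal(size=(4, 30)))
        np.testing.assert_allclose(cf.back_project(T0 @ S, S), T0, atol=1e-8)

    def test_single_indicator_row_picks_pixel(self, rng):
        A = rng.normal(size=(6, 5))
        S = np.zeros((1, 5))
        S[0, 0] = 1.0
        np.testing.assert_allclose(cf.back_project(A, S)[:, 0], A[:, 0])

    def test_rank_deficient_S_errors(self, rng):
        S = np.vstack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError):
            cf.back_project(rng.normal(size=(4, 5)), S)


class TestLowRankMovie:
    def test_rank_bound_and_single_map_proportionality(self, small_spec):
        movie, _ = cf.generate_movie(small_spec)
        res = cf.extract_sources(movie, k=6, c=6)
        recon = cf.low_rank_movie(res.refined)
        rank = np.linalg.matrix_rank(recon.data)
        assert rank <= res.refined.c
        assert (recon.height, recon.width) == (movie.height, movie.width)

    def test_noise_free_reconstruction_error(self, small_noise_free_disjoint):
        movie, truth = small_noise_free_disjoint
        res = cf.extract_sources(movie, k=8, c=8, min_similarity=0.0)
        z, _ = cf.zscore(movie)
        recon = cf.low_rank_movie(res.refined)
        assigned = np.concatenate(res.refined.members)
        err = np.linalg.norm(recon.data[:, assigned] - z.data[:, assigned])
        assert err / np.linalg.norm(z.data[:, assigned]) < 1e-6

    def test_c_one_frames_proportional_to_map(self, small_noise_free_disjoint):
        movie, _ = cf.generate_movie(
            cf.SyntheticSpec(n_sources=2, m=60, height=16, width=16,
                             cluster_radius=4.0, sigma_noise=0.0, seed=2)
        )
        res = cf.extract_sources(movie, k=2, c=1, min_similarity=0.0)
        recon = cf.low_rank_movie(res.refined).frames()
        flat_map = res.refined.S_hat[0].reshape(16, 16)
        for t in range(recon.shape[0]):
            np.testing.assert_allclose(
                recon[t], res.refined.T_hat[t, 0] * flat_map, atol=1e-10
            )
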