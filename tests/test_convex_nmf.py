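import itertools

import numpy as np
import pytest

from ssse.convex_nmf import (ConvexNMF, DegenerateSourceError, ConvexFactors,
                             convex_nmf, mixing_proportions, spectral_sources)


def reconstruction(Y, f):
    return Y @ f.W @ f.G.T


class TestFactorisation:
    def test_duplicated_column_groups_are_recovered(self):
        rng = np.random.default_rng(0)
        cols = rng.normal(size=(3, 2)) * [2.0, -1.0]
        Y = np.column_stack([cols[:, 0]] * 3 + [cols[:, 1]] * 3)
        f = convex_nmf(Y, k=2, seed=0, max_iter=5000, tol=1e-15)
        assert np.sum((Y - reconstruction(Y, f)) ** 2) < 1e-6
        S = spectral_sources(Y, f).S_spec
        # each source matches one group column to 1e-3
        for j in range(2):
            err = np.linalg.norm(S - cols[:, j][:, None], axis=0).min()
            assert err < 1e-3

    def test_objective_trace_non_increasing(self):
        Y = np.random.default_rng(1).normal(size=(6, 15))
        f = convex_nmf(Y, k=3, seed=1, max_iter=200)
        t = f.objective_trace
        assert np.all(np.diff(t) <= 1e-9 * np.maximum(t[:-1], 1.0))

    def test_k1_source_is_convex_combination_of_data(self):
        Y = np.random.default_rng(2).normal(size=(4, 8))
        f = convex_nmf(Y, k=1, seed=0)
        src = spectral_sources(Y, f)
        assert np.all(src.weights >= 0)
        np.testing.assert_allclose(src.weights.sum(axis=0), 1.0, atol=1e-12)
        # lies in the convex hull: representable by its own weights
        np.testing.assert_allclose(src.S_spec[:, 0], Y @ src.weights[:, 0])

    def test_noiseless_rank_k_reconstructed_for_all_seeds(self):
        # rank-2 data whose pure patterns appear as duplicated columns;
        # the multiplicative updates then converge well inside the budget
        rng = np.random.default_rng(3)
        S = rng.normal(size=(5, 2))
        H = np.column_stack([np.tile([[1.0], [0.0]], 4), np.tile([[0.0], [1.0]], 5)])
        Y = S @ H
        for seed in range(5):
            f = convex_nmf(Y, k=2, seed=seed, max_iter=5000, tol=1e-15)
            assert f.objective_trace[-1] < 1e-6 * np.sum(Y**2)

    def test_invalid_inputs_rejected(self):
        Y = np.ones((3, 4))
        with pytest.raises(ValueError, match="exceeds"):
            convex_nmf(Y, k=5)
        Y2 = Y.copy()
        Y2[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            convex_nmf(Y2, k=2)

    def test_best_restart_matches_exhaustive_grid_search(self):
        """On a tiny exactly-representable instance, the best of 200
        randomly initialised runs reaches (within 2%, plus a small
        numerical floor for the multiplicative updates' asymptotic tail)
        the optimum found by exhaustively enumerating convex weight
        vectors on a 0.05 grid."""
        rng = np.random.default_rng(0)
        cols = rng.normal(size=(2, 2))
        Y = np.column_stack([cols[:, 0]] * 2 + [cols[:, 1]] * 2)
        best = min(
            convex_nmf(Y, k=2, seed=s, max_iter=2000, tol=1e-13,
                       init="random").objective_trace[-1]
            for s in range(200)
        )

        # enumerate all weight vectors on the simplex grid (step 0.05)
        steps = 20
        grid = [
            np.array(c, dtype=float) / steps
            for c in itertools.product(range(steps + 1), repeat=4)
            if sum(c) == steps
        ]
        sources = np.array(grid) @ Y.T         # n_w x 2  (each row: Y @ w)
        SS = sources @ sources.T               # gram of all candidate sources
        B = sources @ Y                        # n_w x 4: <s_i, y_col>
        yy = np.sum(Y**2, axis=0)              # per-column squared norm
        norms = np.diag(SS)

        # for every unordered source pair, solve the 2-variable NNLS per
        # column in closed form (active-set cases) and sum the residuals
        ia, ja = np.triu_indices(len(sources))
        grid_best = np.inf
        for lo in range(0, len(ia), 100_000):
            i, j = ia[lo:lo + 100_000], ja[lo:lo + 100_000]
            g11, g22, g12 = norms[i, None], norms[j, None], SS[i, j][:, None]
            b1, b2 = B[i], B[j]
            obj1 = yy - np.where(g11 > 0, np.maximum(b1, 0) ** 2 / np.where(g11 > 0, g11, 1), 0)
            obj2 = yy - np.where(g22 > 0, np.maximum(b2, 0) ** 2 / np.where(g22 > 0, g22, 1), 0)
            det = g11 * g22 - g12**2
            safe = np.where(det > 1e-12, det, 1.0)
            g1 = (b1 * g22 - b2 * g12) / safe
            g2 = (b2 * g11 - b1 * g12) / safe
            interior_ok = (det > 1e-12) & (g1 >= 0) & (g2 >= 0)
            obj_int = np.where(interior_ok, yy - (g1 * b1 + g2 * b2), np.inf)
            per_pair = np.minimum.reduce([np.broadcast_to(yy, obj1.shape), obj1, obj2, obj_int]).sum(axis=1)
            grid_best = min(grid_best, float(per_pair.min()))
        assert best <= grid_best * 1.02 + 1e-6 * np.sum(Y**2)


class TestSourcesAndMixing:
    def _factors(self, W, G, Y=None):
        return ConvexFactors(W=W, G=G, objective_trace=np.array([0.0]))

    def test_one_hot_weight_selects_voxel_spectrum(self):
        Y = np.random.default_rng(4).normal(size=(5, 6))
        W = np.zeros((6, 2))
        W[2, 0] = 1.0
        W[4, 1] = 2.0  # rescaled to unit sum
        G = np.ones((6, 2))
        src = spectral_sources(Y, self._factors(W, G))
        np.testing.assert_allclose(src.S_spec[:, 0], Y[:, 2])
        np.testing.assert_allclose(src.S_spec[:, 1], Y[:, 4])

    def test_uniform_weights_give_mean_spectrum(self):
        Y = np.random.default_rng(5).normal(size=(5, 8))
        W = np.ones((8, 1))
        src = spectral_sources(Y, self._factors(W, np.ones((8, 1))))
        np.testing.assert_allclose(src.S_spec[:, 0], Y.mean(axis=1))

    def test_zero_weight_column_rejected(self):
        Y = np.ones((3, 4))
        W = np.zeros((4, 2))
        W[:, 0] = 0.25
        with pytest.raises(DegenerateSourceError):
            spectral_sources(Y, self._factors(W, np.ones((4, 2))))

    def test_normalisation_preserves_reconstruction(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(4, 9))
        f = convex_nmf(Y, k=2, seed=0, max_iter=50)
        W_hat = spectral_sources(Y, f).weights
        H = mixing_proportions(f).H
        np.testing.assert_allclose(
            Y @ f.W @ f.G.T, Y @ W_hat @ H, atol=1e-9
        )

    def test_proportions_are_per_voxel_simplex(self):
        Y = np.random.default_rng(8).normal(size=(4, 9))
        f = convex_nmf(Y, k=3, seed=0)
        P = mixing_proportions(f).proportions
        assert np.all(P >= 0) and np.all(P <= 1)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_abundance_column_warns_and_is_uniform(self):
        W = np.ones((3, 2))
        G = np.ones((3, 2))
        G[1] = 0.0
        with pytest.warns(UserWarning, match="uniform"):
            P = mixing_proportions(self._factors(W, G)).proportions
        np.testing.assert_allclose(P[:, 1], 0.5)

    def test_deep_tumour_voxel_dominated_by_tumour_source(self, noiseless_case):
        truth = noiseless_case["truth"]
        res = noiseless_case["unsupervised"]
        j = int(np.argmax(truth.true_abundances[0]))
        s = list(res.log["source_classes"]).index(1)
        assert res.mixing.proportions[s, j] > 0.9


class TestEstimator:
    def test_fit_transform_shapes_and_components(self):
        X = np.random.default_rng(9).normal(size=(12, 5))  # 12 samples
        est = ConvexNMF(n_components=2, random_state=0)
        H = est.fit_transform(X)
        assert H.shape == (12, 2)
        assert est.components_.shape == (2, 5)
        # components live in the convex hull of the samples
        np.testing.assert_allclose(est.normalized_weights_.sum(axis=0), 1.0)

    def test_transform_projects_new_samples_nonnegatively(self):
        X = np.random.default_rng(10).normal(size=(10, 4))
        est = ConvexNMF(n_components=2, random_state=1).fit(X)
        H = est.transform(X[:3])
        assert H.shape == (3, 2) and np.all(H >= 0)
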