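import numpy as np
import pytest
from scipy import linalg

from mirgenet import (
    cim_similarity,
    correlation_circle,
    fit_rcca,
    select_dimensions,
    tune_rcca,
)
from mirgenet.rcca import default_lambda_grids

from conftest import toy_matrix


def cca_oracle(X, Z):
    """Classical CCA correlations via the generalized eigenvalue problem."""
    Xc = (X - X.mean(0)) / X.std(0, ddof=1)
    Zc = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    n = X.shape[0]
    Cxx = Xc.T @ Xc / (n - 1)
    Czz = Zc.T @ Zc / (n - 1)
    Cxz = Xc.T @ Zc / (n - 1)
    A = Cxz @ linalg.solve(Czz, Cxz.T)
    vals = linalg.eigh(A, Cxx, eigvals_only=True)
    vals = np.clip(vals, 0, 1)
    return np.sqrt(np.sort(vals)[::-1])


class TestFit:
    def test_lambda_zero_matches_generalized_eigen_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(20, 5))
            Z = rng.normal(size=(20, 4))
            model = fit_rcca(toy_matrix(X), toy_matrix(Z, prefix="G"), 0.0, 0.0)
            expected = cca_oracle(X, Z)[:4]
            np.testing.assert_allclose(
                model.canonical_correlations, expected, atol=1e-8
            )

    def test_identical_single_columns_fully_correlated(self, rng):
        v = rng.normal(size=(6, 1))
        model = fit_rcca(toy_matrix(v), toy_matrix(v.copy(), prefix="G"), 0.0, 0.0)
        assert model.canonical_correlations[0] == pytest.approx(1.0)

    def test_singular_covariance_at_lambda_zero_advises_ridge(self, rng):
        X = rng.normal(size=(5, 10))  # p > n: singular covariance
        Z = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="lambda > 0"):
            fit_rcca(toy_matrix(X), toy_matrix(Z, prefix="G"), 0.0, 0.1)

    def test_small_toy_matches_angle_grid_oracle(self, rng):
        # 3x2 vs 3x2, lambda 0.1: maximize the regularized correlation
        # over a fine grid of weight angles
        X = rng.normal(size=(3, 2))
        Z = rng.normal(size=(3, 2))
        lam = 0.1
        model = fit_rcca(toy_matrix(X), toy_matrix(Z, prefix="G"), lam, lam)
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        Zc = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        Cxx = Xc.T @ Xc / 2 + lam * np.eye(2)
        Czz = Zc.T @ Zc / 2 + lam * np.eye(2)
        Cxz = Xc.T @ Zc / 2
        best = -np.inf
        for ta in np.linspace(0, np.pi, 2000, endpoint=False):
            a = np.array([np.cos(ta), np.sin(ta)])
            for tb in np.linspace(0, np.pi, 200, endpoint=False):
                b = np.array([np.cos(tb), np.sin(tb)])
                rho = abs(a @ Cxz @ b) / np.sqrt((a @ Cxx @ a) * (b @ Czz @ b))
                best = max(best, rho)
        assert model.regularized_correlations[0] == pytest.approx(best, abs=1e-3)

    def test_feature_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 6))
        Z = rng.normal(size=(15, 5))
        m1 = fit_rcca(toy_matrix(X), toy_matrix(Z, prefix="G"), 0.05, 0.05)
        perm = rng.permutation(6)
        Xp = toy_matrix(X[:, perm])
        Xp.feature_ids = [f"F{j + 1}" for j in perm]
        m2 = fit_rcca(Xp, toy_matrix(Z, prefix="G"), 0.05, 0.05)
        np.testing.assert_allclose(
            m1.canonical_correlations, m2.canonical_correlations, atol=1e-10
        )

    def test_large_lambda_shrinks_toward_cross_covariance_direction(self, rng):
        X = rng.normal(size=(20, 5))
        Z = rng.normal(size=(20, 4))
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        Zc = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        pls_dir = np.linalg.svd(Xc.T @ Zc)[0][:, 0]
        cosines = []
        for lam in [0.01, 0.1, 1.0, 10.0, 100.0]:
            m = fit_rcca(toy_matrix(X), toy_matrix(Z, prefix="G"), lam, lam)
            w = m.x_weights[:, 0]
            cosines.append(abs(w @ pls_dir) / np.linalg.norm(w))
        assert cosines[-1] > 0.999
        assert cosines[-1] > cosines[0]

    def test_independent_blocks_give_small_first_correlation(self, rng):
        rhos = []
        for n in (50, 400):
            X = rng.normal(size=(n, 4))
            Z = rng.normal(size=(n, 3))
            m = fit_rcca(toy_matrix(X), toy_matrix(Z, prefix="G"), 0.0, 0.0)
            rhos.append(m.canonical_correlations[0])
        assert rhos[1] < rhos[0] < 0.7


class TestTune:
    def test_default_grids_match_study_region(self):
        g1, g2 = default_lambda_grids()
        assert len(g1) == len(g2) == 100
        assert 0.001 < g1[0] and g1[-1] < 0.05
        assert 0.0001 < g2[0] and g2[-1] < 0.05

    def test_deterministic_surface(self, rng):
        X = rng.normal(size=(24, 5))
        Z = np.column_stack([X[:, 0] + rng.normal(0, 0.5, 24), rng.normal(size=(24, 2))])
        mx, mz = toy_matrix(X), toy_matrix(Z, prefix="G")
        out1 = tune_rcca(mx, mz, [0.01, 0.1], [0.01, 0.1], folds=4, seed=2)
        out2 = tune_rcca(mx, mz, [0.01, 0.1], [0.01, 0.1], folds=4, seed=2)
        assert out1[:2] == out2[:2]
        assert out1[2].equals(out2[2])

    def test_planted_shared_signal_tunes_near_oracle(self, rng):
        # one shared latent dimension; the tuned pair must achieve a CV
        # score within 0.05 of the best cell on the surface by definition,
        # and that best score must be clearly positive
        latent = rng.normal(size=30)
        X = np.column_stack([latent + rng.normal(0, 0.4, 30) for _ in range(4)])
        Z = np.column_stack([-latent + rng.normal(0, 0.4, 30) for _ in range(3)])
        l1, l2, surface = tune_rcca(
            toy_matrix(X), toy_matrix(Z, prefix="G"),
            np.geomspace(1e-3, 1.0, 6), np.geomspace(1e-3, 1.0, 6),
            folds=5, seed=0,
        )
        best = surface["cv_score"].max()
        chosen = surface.set_index(["lambda1", "lambda2"]).loc[(l1, l2), "cv_score"]
        assert chosen == pytest.approx(best)
        assert best > 0.8

    def test_tiny_fold_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        Z = rng.normal(size=(8, 2))
        with pytest.raises(ValueError, match="fold"):
            tune_rcca(toy_matrix(X), toy_matrix(Z, prefix="G"), [0.1], [0.1], folds=8)


class TestDimensions:
    def test_gap_detection(self):
        assert select_dimensions([0.9, 0.85, 0.2, 0.1]) == 2
        assert select_dimensions([0.9, 0.1]) == 1

    def test_degenerate_profiles_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="no clear gap"):
            assert select_dimensions([0.5, 0.5, 0.5, 0.5]) == 1
        with pytest.warns(UserWarning, match="no clear gap"):
            assert select_dimensions([0.8, 0.6, 0.4, 0.2]) == 1

    def test_override_honored_with_log(self):
        with pytest.warns(UserWarning, match="override"):
            assert select_dimensions([0.9, 0.85, 0.2], override=3) == 3


class TestCircleAndCim:
    def _fitted(self, rng, n=40):
        latent1 = rng.normal(size=n)
        latent2 = rng.normal(size=n)
        X = np.column_stack(
            [latent1 + rng.normal(0, 0.3, n), latent2 + rng.normal(0, 0.3, n),
             rng.normal(size=n)]
        )
        Z = np.column_stack(
            [-latent1 + rng.normal(0, 0.3, n), -latent2 + rng.normal(0, 0.3, n),
             rng.normal(size=n), rng.normal(size=n)]
        )
        mx, mz = toy_matrix(X), toy_matrix(Z, prefix="G")
        return fit_rcca(mx, mz, 0.1, 0.1), mx, mz

    def test_coordinates_are_pearson_with_compromise_variate(self, rng):
        model, mx, mz = self._fitted(rng)
        points = correlation_circle(model, mx, mz, inner_radius=0.3, ndim=2)
        comp = (model.x_variates[:, :2] + model.z_variates[:, :2]) / 2
        for _, row in points.iterrows():
            mat = mx if row["block"] == "mirna" else mz
            v = mat.feature_vector(row["feature_id"])
            for h in (0, 1):
                r = np.corrcoef(v, comp[:, h])[0, 1]
                assert row[f"dim{h + 1}"] == pytest.approx(r, abs=1e-10)
            assert row["radius"] == pytest.approx(
                np.hypot(row["dim1"], row["dim2"])
            )
        # signal features survive the 0.3 ring; coordinates bounded by 1
        assert {"F1", "F2", "G1", "G2"} <= set(points["feature_id"])
        assert (points[["dim1", "dim2"]].abs() <= 1 + 1e-12).all().all()

    def test_noise_features_fall_inside_inner_circle(self, rng):
        # pure-noise features at large n concentrate near the origin
        n = 400
        latent = rng.normal(size=n)
        X = np.column_stack([latent] + [rng.normal(size=n) for _ in range(100)])
        Z = np.column_stack([-latent] + [rng.normal(size=n) for _ in range(100)])
        mx, mz = toy_matrix(X), toy_matrix(Z, prefix="G")
        model = fit_rcca(mx, mz, 0.5, 0.5)
        points = correlation_circle(model, mx, mz, inner_radius=0.3, ndim=2)
        noise_kept = [
            f for f in points["feature_id"] if f not in ("F1", "G1")
        ]
        assert len(noise_kept) <= 2  # < 1% retention

    def test_cim_inner_product_and_average_linkage_oracle(self):
        import pandas as pd

        points = pd.DataFrame(
            {
                "feature_id": ["m1", "m2", "m3", "m4", "g1", "g2", "g3"],
                "block": ["mirna"] * 4 + ["gene"] * 3,
                "dim1": [1.0, -1.0, 0.6, 0.5, 1.0, -0.8, 0.2],
                "dim2": [0.0, 0.0, 0.5, -0.5, 0.0, 0.3, 0.9],
                "radius": [1.0, 1.0, 0.78, 0.71, 1.0, 0.85, 0.92],
            }
        )
        sim, row_order, col_order = cim_similarity(points)
        M = points[points.block == "mirna"][["dim1", "dim2"]].to_numpy()
        G = points[points.block == "gene"][["dim1", "dim2"]].to_numpy()
        np.testing.assert_allclose(sim.to_numpy(), M @ G.T, atol=1e-12)
        assert sim.loc["m1", "g1"] == pytest.approx(1.0)
        assert sim.loc["m2", "g1"] == pytest.approx(-1.0)
        assert sorted(row_order) == [0, 1, 2, 3]
        assert sorted(col_order) == [0, 1, 2]
        # average-linkage merge heights, first merge checked by hand:
        # closest pair of rows in Euclidean distance must merge first
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        link = hierarchy.linkage(sim.to_numpy(), "average", "euclidean")
        d = pdist(sim.to_numpy())
        assert link[0, 2] == pytest.approx(d.min())
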