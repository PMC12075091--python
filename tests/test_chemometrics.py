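"""PCA/Mahalanobis, OSC, NIPALS PLS, PCR, CV and metrics contracts."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from aquaredox import chemometrics as chem
from aquaredox import spectra_core as core
from aquaredox import synthetic_spectra as synth


def _ols_predict(X, y, X_new):
    """Normal-equations least squares on centered data (oracle)."""
    xm, ym = X.mean(axis=0), np.asarray(y, float).mean(axis=0)
    Xc = X - xm
    b = np.linalg.pinv(Xc.T @ Xc) @ Xc.T @ (y - ym)
    return (X_new - xm) @ b + ym


@pytest.fixture(scope="module")
def random_regression():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(20, 8))
    y = rng.normal(size=20)
    return X, y


class TestPCA:
    def test_line_data_single_component(self):
        t = np.linspace(0, 1, 15)
        X = np.outer(t, [1.0, -2.0, 0.5])
        m = chem.fit_pca(X, 1)
        assert m.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_full_reconstruction_and_score_definition(self, random_regression):
        X, _ = random_regression
        m = chem.fit_pca(X, 8)
        np.testing.assert_allclose(
            m.mean + m.scores @ m.loadings.T, X, atol=1e-8
        )
        np.testing.assert_allclose(
            m.scores, (X - m.mean) @ m.loadings, atol=1e-10
        )

    def test_loadings_orthonormal_variance_sorted(self, random_regression):
        X, _ = random_regression
        m = chem.fit_pca(X, 5)
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(5),
                                   atol=1e-8)
        assert np.all(np.diff(m.explained_variance_ratio) <= 1e-12)
        assert m.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_k_too_large_rejected(self, random_regression):
        X, _ = random_regression
        with pytest.raises(ValueError):
            chem.fit_pca(X, 9)


class TestMahalanobisScreen:
    def test_centroid_sample_distance_zero(self):
        X = np.array([[0.0, 0], [2, 0], [1, 1], [1, -1], [1, 0]])
        m = chem.fit_pca(X, 2)
        rep = chem.mahalanobis_screen(m)
        assert rep.distance[-1] == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_points_equal_distance(self):
        X = np.array([[1.0, 0, 0], [-1.0, 0, 0]] * 3) + np.random.default_rng(
            0).normal(scale=1e-6, size=(6, 3))
        m = chem.fit_pca(X, 1)
        rep = chem.mahalanobis_screen(m)
        assert np.allclose(rep.distance, rep.distance[0], rtol=1e-3)

    def test_injected_outliers_all_flagged(self, gsh_series):
        """Large injected artifacts separate cleanly from clean spectra."""
        sset, _ = gsh_series
        spiked, flags = synth.inject_outliers(sset, 0.02, magnitude=0.5, seed=13)
        proc = core.snv(core.mask_regions(spiked, [[1100, 1850], [2050, 2400]]))
        _, rep = chem.screen_outliers(proc.absorbance,
                                      threshold_quantile=0.999)
        assert rep.removed[flags].all()
        assert rep.distance[flags].min() > 2 * rep.distance[~flags].max()


class TestOSC:
    def test_removed_scores_orthogonal_to_y(self, gsh_series):
        sset, _ = gsh_series
        X = sset.absorbance[:100]
        y = sset.meta["concentration_mM"].to_numpy()[:100]
        model, Xc = chem.fit_osc(X, y, n_components=2)
        yc = y - y.mean()
        for t in model.scores:
            assert abs(t @ yc) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(yc)

    def test_zero_components_is_identity(self, random_regression):
        X, y = random_regression
        _, Xc = chem.fit_osc(X, y, n_components=0)
        np.testing.assert_allclose(Xc, X, atol=1e-12)

    def test_y_aligned_structure_survives(self):
        """When y is carried by one direction, OSC removes variance without
        harming a 1-LV PLS fit on the corrected matrix."""
        rng = np.random.default_rng(5)
        t_sig = rng.normal(size=40)
        t_noise = rng.normal(size=40) * 3.0
        p_sig, p_noise = rng.normal(size=12), rng.normal(size=12)
        X = np.outer(t_sig, p_sig) + np.outer(t_noise, p_noise)
        y = 2.0 * t_sig
        osc, Xc = chem.fit_osc(X, y, n_components=1)
        m = chem.fit_plsr(Xc, y, n_lv=1)
        rmse, r2 = chem.metrics(y, chem.predict(m, Xc))
        assert rmse <= 1e-8

    def test_prediction_invariant_to_removed_component(self, gsh_series):
        """Adding an OSC-removed direction to a spectrum must not change
        the downstream PLS prediction."""
        sset, _ = gsh_series
        X = sset.absorbance[:150]
        y = sset.meta["concentration_mM"].to_numpy()[:150]
        osc, Xc = chem.fit_osc(X, y, n_components=1)
        m = chem.fit_plsr(Xc, y, n_lv=2)
        x0 = X[7:8]
        perturbed = x0 + 0.3 * osc.loadings[0]
        p0 = chem.predict(m, osc.apply(x0))
        p1 = chem.predict(m, osc.apply(perturbed))
        assert abs(p1 - p0) < 1e-6


class TestPLSR:
    def test_rank_one_exact_fit(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=25)
        X = np.outer(t, rng.normal(size=6))
        y = 3.0 * t + 1.0
        m = chem.fit_plsr(X, y, n_lv=1)
        rmse, _ = chem.metrics(y, chem.predict(m, X))
        assert rmse <= 1e-10

    def test_full_rank_equals_ols_oracle(self, random_regression):
        X, y = random_regression
        m = chem.fit_plsr(X, y, n_lv=8)
        np.testing.assert_allclose(
            chem.predict(m, X), _ols_predict(X, y, X), atol=1e-6
        )

    def test_matches_sklearn_cross_check(self, random_regression):
        X, y = random_regression
        for a in (1, 2, 4):
            ours = chem.fit_plsr(X, y, n_lv=a)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y)
            np.testing.assert_allclose(
                chem.predict(ours, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_channel_permutation_equivariance(self, random_regression):
        X, y = random_regression
        perm = np.random.default_rng(1).permutation(X.shape[1])
        m = chem.fit_plsr(X, y, n_lv=3)
        mp = chem.fit_plsr(X[:, perm], y, n_lv=3)
        np.testing.assert_allclose(mp.b, m.b[perm], atol=1e-10)
        np.testing.assert_allclose(
            chem.predict(mp, X[:, perm]), chem.predict(m, X), atol=1e-10
        )

    def test_score_orthogonality_and_two_route_prediction(self, random_regression):
        X, y = random_regression
        m = chem.fit_plsr(X, y, n_lv=4)
        G = m.T.T @ m.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)
        # route 2: prediction through the score/loading sequence
        via_scores = m.T @ m.q + m.y_mean
        np.testing.assert_allclose(chem.predict(m, X), via_scores, atol=1e-8)

    def test_exceeding_rank_is_error(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="rank"):
            chem.fit_plsr(X, t, n_lv=2)

    def test_constant_y_rejected(self, random_regression):
        X, _ = random_regression
        with pytest.raises(ValueError):
            chem.fit_plsr(X, np.ones(20), n_lv=1)


class TestPCR:
    def test_exact_linear_recovery_at_full_rank(self, random_regression):
        X, _ = random_regression
        B = np.random.default_rng(2).normal(size=(8, 2))
        Y = X @ B + 1.0
        m = chem.fit_pcr(X, Y, k=8)
        np.testing.assert_allclose(chem.predict(m, X), Y, atol=1e-8)

    def test_full_rank_pcr_equals_pls_equals_ols(self, random_regression):
        X, y = random_regression
        pcr = chem.fit_pcr(X, y, k=8)
        pls = chem.fit_plsr(X, y, n_lv=8)
        ols = _ols_predict(X, y, X)
        np.testing.assert_allclose(chem.predict(pcr, X), ols, atol=1e-6)
        np.testing.assert_allclose(chem.predict(pls, X), ols, atol=1e-6)

    def test_orthogonal_signatures_mixture_recovery(self):
        """Two orthogonal band signatures under the paired mixture design
        (1:4.5 ... 9:0.5 mM): concentrations recovered exactly from
        noiseless spectra.  The paired design is affinely collinear, so the
        centered spectra have rank 1 and a single component suffices."""
        s1 = np.zeros(30); s1[5:10] = 1.0
        s2 = np.zeros(30); s2[20:25] = 1.0
        pairs = [(g, (10.0 - g) / 2.0) for g in range(1, 10)]
        Y = np.array(pairs * 3)
        X = Y @ np.vstack([s1, s2])
        m = chem.fit_pcr(X, Y, k=1)
        np.testing.assert_allclose(chem.predict(m, X), Y, atol=1e-8)

    def test_k_exceeding_rank_rejected(self):
        t = np.linspace(0, 1, 12)
        X = np.outer(t, np.arange(4.0))
        with pytest.raises(ValueError):
            chem.fit_pcr(X, t, k=2)


class TestMetricsAndCV:
    @pytest.mark.parametrize("y, yhat, rmse, r2", [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0, 1.0),
        ([0.0, 2.0], [1.0, 1.0], 1.0, 0.0),
        ([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], np.sqrt(1 / 3), 0.5),
    ])
    def test_hand_computed_metrics(self, y, yhat, rmse, r2):
        got = chem.metrics(y, yhat)
        assert got == (pytest.approx(rmse), pytest.approx(r2))

    def test_constant_y_true_rejected(self):
        with pytest.raises(ValueError):
            chem.metrics([1.0, 1.0], [1.0, 2.0])

    def test_loo_holds_each_sample_out_once(self, random_regression):
        X, y = random_regression
        cv = chem.cross_validate(X, y, scheme="loo", n_lv=2)
        assert len(np.unique(cv.folds)) == 20
        assert np.isfinite(cv.y_pred).all()

    def test_leave_five_out_fold_sizes(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        cv = chem.cross_validate(X, y, scheme="leave_k_out", k_out=5,
                                 seed=1, n_lv=2)
        _, counts = np.unique(cv.folds, return_counts=True)
        assert counts.tolist() == [5] * 5

    def test_noiseless_data_near_zero_heldout_error(self):
        rng = np.random.default_rng(6)
        T = rng.normal(size=(30, 2))
        P = rng.normal(size=(2, 10))
        X = T @ P
        y = T @ [1.0, -0.5] + 2.0
        cv = chem.cross_validate(X, y, scheme="loo", n_lv=2)
        assert cv.rmse <= 1e-8

    def test_k_out_too_large_rejected(self, random_regression):
        X, y = random_regression
        with pytest.raises(ValueError):
            chem.cross_validate(X, y, scheme="leave_k_out", k_out=20)


class TestRegressionVectorPeaks:
    def test_flat_vector_no_peaks(self):
        grid = np.arange(1300.0, 1601.0, 2.0)
        peaks = chem.regression_vector_peaks(np.ones(grid.size), grid=grid)
        assert peaks == []

    def test_sign_follows_band_amplitude(self):
        grid = np.arange(1300.0, 1601.0, 2.0)
        bump = np.exp(-0.5 * ((grid - 1450) / 10) ** 2)
        up = chem.regression_vector_peaks(bump, grid=grid)
        down = chem.regression_vector_peaks(-bump, grid=grid)
        assert up[0] == (1450.0, 1)
        assert down[0] == (1450.0, -1)

    def test_window_outside_grid_rejected(self):
        grid = np.arange(1300.0, 1601.0, 2.0)
        with pytest.raises(ValueError):
            chem.regression_vector_peaks(np.ones(grid.size), grid=grid,
                                         wavelength_window=(1000, 1200))
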