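"""PCA (deflation) and hyperplane-fit tests."""

import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA

from paceopt import (ConfigError, DegenerateInputError, fit_plane, pca)
from paceopt.analysis import composite_replot_r2


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=30)
        axis = np.array([0.6, 0.8, 0.0])
        X = 1.0 + np.outer(t, axis)
        res = pca(X)
        assert abs(abs(res.loadings[0] @ axis) - 1.0) < 1e-9
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_deflation_matches_eigendecomposition(self, seed):
        """Deflation loadings equal covariance eigenvectors up to sign."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 6)) @ np.diag([3, 2.5, 1.5, 1, 0.5, 0.2])
        res = pca(X)
        sk = SkPCA(n_components=6).fit(X)
        for k in range(6):
            dot = abs(res.loadings[k] @ sk.components_[k])
            assert dot == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(np.sort(res.explained_variance)[::-1],
                           sk.explained_variance_, rtol=1e-6)

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        res = pca(X)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-9)

    def test_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        res = pca(X)
        recon = res.scores @ res.loadings + res.mean
        assert np.allclose(recon, X, atol=1e-9)

    def test_variances_non_increasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 5)) * np.array([5, 3, 2, 1, 0.5])
        res = pca(X)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_sign_convention(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        for w in pca(X).loadings:
            assert w[np.argmax(np.abs(w))] >= 0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pca(np.ones((10, 3)))


# reference trade-off plane used as a synthetic-data generator:
# 0.762*a - 0.619*b + 0.191*c = 0.333554
PLANE_COEF = np.array([0.762, -0.619, 0.191])
PLANE_CONST = 0.333554


def points_on_plane(n, noise, rng):
    a = 1.0 + rng.uniform(-0.1, 0.1, n)
    c = 1.0 + rng.uniform(-0.1, 0.1, n)
    b = (PLANE_COEF[0] * a + PLANE_COEF[2] * c - PLANE_CONST) / (-PLANE_COEF[1])
    pts = np.column_stack([a, b, c])
    pts += noise * rng.standard_normal(pts.shape)
    return pts


class TestFitPlane:
    def test_exact_plane_recovered(self):
        rng = np.random.default_rng(0)
        pts = points_on_plane(20, 0.0, rng)
        fit = fit_plane(pts, ("ha", "K1", "bNSC"))
        assert fit.r2_ols == pytest.approx(1.0, abs=1e-9)
        ratio = fit.coef / np.linalg.norm(PLANE_COEF) / PLANE_COEF
        assert np.allclose(ratio, ratio[0], atol=1e-9)
        assert fit.constant / (fit.coef[0] / PLANE_COEF[0]) == pytest.approx(
            PLANE_CONST, abs=1e-9)

    def test_noisy_plane_recovered_within_tolerance(self):
        rng = np.random.default_rng(1)
        pts = points_on_plane(200, 0.003, rng)
        fit = fit_plane(pts, ("ha", "K1", "bNSC"))
        unit = PLANE_COEF / np.linalg.norm(PLANE_COEF)
        assert abs(abs(fit.coef @ unit) - 1.0) < 1e-3
        assert fit.r2_ols > 0.8

    def test_underdetermined_rejected(self):
        with pytest.raises(ConfigError):
            fit_plane(np.ones((3, 3)) + np.eye(3) * 0.1, ("a", "b", "c"))

    def test_degenerate_identical_points(self):
        with pytest.raises(DegenerateInputError):
            fit_plane(np.ones((10, 3)), ("a", "b", "c"))

    def test_collinear_regressors_named(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=12)
        pts = np.column_stack([a, 2 * a, rng.normal(size=12)])
        with pytest.raises(DegenerateInputError):
            fit_plane(pts, ("x1", "x2", "y"), response="y")

    def test_point_order_invariance(self):
        rng = np.random.default_rng(3)
        pts = points_on_plane(30, 0.01, rng)
        f1 = fit_plane(pts, ("a", "b", "c"))
        f2 = fit_plane(pts[::-1], ("a", "b", "c"))
        assert np.allclose(f1.coef, f2.coef, atol=1e-9)
        assert f1.r2_ols == pytest.approx(f2.r2_ols, abs=1e-12)

    def test_independent_noise_low_r2(self):
        """Mutually independent columns fit no plane better than chance."""
        rng = np.random.default_rng(4)
        r2s = []
        for _ in range(20):
            pts = 1.0 + 0.03 * rng.standard_normal((20, 3))
            r2s.append(fit_plane(pts, ("a", "b", "c")).r2_ols)
        # independent data: typical R2 well below the ~0.87 of a true plane
        assert np.median(r2s) < 0.55

    def test_composite_replot(self):
        rng = np.random.default_rng(5)
        pts = points_on_plane(50, 0.001, rng)
        fit = fit_plane(pts, ("ha", "K1", "bNSC"))
        r2 = composite_replot_r2(fit, ("ha", "bNSC"), "K1")
        assert 0.9 < r2 <= 1.0


class TestComplementarityReport:
    def _orp_on_plane(self, n=25, noise=0.002, seed=0):
        from paceopt import ScalingFactors
        from paceopt.optimize import OrpResult, PSRun
        rng = np.random.default_rng(seed)
        a = 1.0 + rng.uniform(-0.1, 0.1, n)
        c = 1.0 + rng.uniform(-0.1, 0.1, n)
        b = (PLANE_COEF[0] * a + PLANE_COEF[2] * c - PLANE_CONST) / (-PLANE_COEF[1])
        pts = np.column_stack([a, b, c]) + noise * rng.standard_normal((n, 3))
        runs = [PSRun(names=("ha", "K1", "bNSC"), bp_history=[], eval_log=[],
                      final_sf=ScalingFactors(ha=p[0], K1=p[1], bNSC=p[2]),
                      final_mse=1e-3 * (1 + i), converged=True)
                for i, p in enumerate(pts)]
        return OrpResult(runs=runs, names=("ha", "K1", "bNSC"),
                         sf_true=ScalingFactors(), range_pct=0.1, seed=seed)

    def test_plane_and_composite_on_synthetic_tradeoff(self):
        from paceopt import complementarity_report
        rep = complementarity_report(self._orp_on_plane(), ("ha", "K1", "bNSC"),
                                     k=20)
        assert rep["r2_ols"] > 0.8
        assert rep["composite_r2"] > 0.8

    def test_unoptimized_current_rejected(self):
        from paceopt import ConfigError, complementarity_report
        with pytest.raises(ConfigError):
            complementarity_report(self._orp_on_plane(), ("ha", "Kr"), k=20)
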