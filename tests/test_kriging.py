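import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

import hgkrige as h
from hgkrige.geo import stable_exponential_cov
from hgkrige.kriging import restricted_loglik


def _manual_model(canal, vp, beta=(0.5, -0.3, 0.1), spec=None):
    spec = spec or h.DriftSpec("quadratic")
    return h.KrigingModel(
        drift_spec=spec, beta=np.asarray(beta, float),
        beta_cov=np.eye(len(beta)), vp=vp, gamma=vp.gamma, canal=canal,
        distance_floor=1.0, reml_loglik=0.0, converged=True, n=0,
    )


def _bordered_system_oracle(model, pts, y, targets):
    """Independent universal-kriging oracle via the Lagrange bordered system:
    [[Sigma, X], [X', 0]] [lam; mu] = [c0; x0]."""
    vp = model.vp
    X = model.drift_design(pts)
    n, p = X.shape
    sigma = vp.sill_sigma2 * np.exp(-((squareform(pdist(pts)) / vp.range_alpha) ** vp.gamma))
    sigma[np.diag_indices(n)] += vp.nugget_tau2
    A = np.block([[sigma, X], [X.T, np.zeros((p, p))]])
    X0 = model.drift_design(targets)
    c0 = vp.sill_sigma2 * np.exp(-((cdist(pts, targets) / vp.range_alpha) ** vp.gamma))
    rhs = np.vstack([c0, X0.T])
    sol = np.linalg.solve(A, rhs)
    lam, mu = sol[:n], sol[n:]
    mean = lam.T @ y
    var = vp.sill_sigma2 - np.einsum("ij,ij->j", lam, c0) - np.einsum("ij,ij->j", mu, X0.T)
    return mean, var


class TestKrigePredict:
    def test_matches_bordered_system_oracle(self, canal):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(8, 21))
            pts = rng.uniform(0, 400, size=(n, 2))
            vp = h.VariogramParams(rng.uniform(0.1, 1.0), rng.uniform(0.001, 0.1),
                                   rng.uniform(20, 120), 0.5)
            model = _manual_model(canal, vp)
            y = rng.standard_normal(n)
            targets = rng.uniform(0, 400, size=(4, 2))
            preds = h.krige_predict(model, (pts, y), targets)
            mean, var = _bordered_system_oracle(model, pts, y, targets)
            np.testing.assert_allclose([p.mean for p in preds], mean, atol=1e-8)
            np.testing.assert_allclose([p.se**2 for p in preds], var, atol=1e-8)

    def test_exact_interpolation_with_zero_nugget(self, canal):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 300, size=(25, 2))
        y = rng.standard_normal(25)
        model = _manual_model(canal, h.VariogramParams(0.5, 0.0, 50.0))
        preds = h.krige_predict(model, (pts, y), pts)
        np.testing.assert_allclose([p.mean for p in preds], y, atol=1e-6)
        np.testing.assert_allclose([p.se for p in preds], 0.0, atol=1e-5)

    def test_zero_sill_reduces_to_drift_regression(self, canal):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 300, size=(40, 2))
        model0 = _manual_model(canal, h.VariogramParams(0.0, 0.2, 50.0))
        X = model0.drift_design(pts)
        beta = np.array([0.5, -0.3, 0.1])
        y = X @ beta + np.sqrt(0.2) * rng.standard_normal(40)
        t = rng.uniform(0, 300, size=(5, 2))
        preds = h.krige_predict(model0, (pts, y), t)
        bhat = np.linalg.lstsq(X, y, rcond=None)[0]
        X0 = model0.drift_design(t)
        np.testing.assert_allclose([p.mean for p in preds], X0 @ bhat, atol=1e-8)
        # SE equals the regression-mean SE under the fitted nugget scale
        s2 = 0.2
        se_reg = np.sqrt(s2 * np.einsum("ij,jk,ik->i", X0, np.linalg.inv(X.T @ X), X0))
        np.testing.assert_allclose([p.se for p in preds], se_reg, rtol=1e-6)

    def test_drift_exactness_in_noiseless_limit(self, canal):
        rng = np.random.default_rng(14)
        pts = rng.uniform(0, 300, size=(30, 2))
        model = _manual_model(canal, h.VariogramParams(1e-10, 1e-12, 50.0))
        beta = np.array([0.5, -0.3, 0.1])
        y = model.drift_design(pts) @ beta
        t = rng.uniform(0, 300, size=(6, 2))
        preds = h.krige_predict(model, (pts, y), t)
        np.testing.assert_allclose([p.mean for p in preds],
                                   model.drift_design(t) @ beta, atol=1e-6)

    def test_variance_nonnegative_and_shrinks_with_colocated_obs(self, canal):
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 300, size=(30, 2))
        y = rng.standard_normal(30)
        model = _manual_model(canal, h.VariogramParams(0.4, 0.01, 60.0))
        target = np.array([[150.0, 150.0]])
        before = h.krige_predict(model, (pts, y), target)[0]
        assert before.se >= 0
        pts2 = np.vstack([pts, target])
        y2 = np.append(y, 0.3)
        after = h.krige_predict(model, (pts2, y2), target)[0]
        assert after.se <= before.se + 1e-10

    def test_rejects_nonfinite_targets(self, canal):
        model = _manual_model(canal, h.VariogramParams(0.4, 0.01, 60.0))
        with pytest.raises(ValueError):
            h.krige_predict(model, (np.zeros((3, 2)), np.zeros(3)),
                            np.array([[np.nan, 0.0]]))


class TestRemlFit:
    def test_degenerate_zero_variances_reduce_to_ols(self, small_field):
        soil, cfg, _ = small_field
        spec = h.DriftSpec("quadratic")
        m = h.reml_fit(soil, spec, cfg.canal, fix={"sigma2": 0.0, "tau2": 0.0})
        from hgkrige.geo import distances_to_polyline, log_distance

        X = h.build_drift_design(log_distance(distances_to_polyline(
            soil[["x", "y"]].to_numpy(float), cfg.canal)), spec)
        bhat = np.linalg.lstsq(X, soil["log10_hg"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(m.beta, bhat, atol=1e-8)

    def test_optimum_beats_random_parameter_points(self, small_field):
        soil, cfg, _ = small_field
        sub = soil.iloc[:120]
        spec = h.DriftSpec("quadratic")
        m = h.reml_fit(sub, spec, cfg.canal)
        pts = sub[["x", "y"]].to_numpy(float)
        from hgkrige.geo import distances_to_polyline, log_distance

        X = h.build_drift_design(log_distance(distances_to_polyline(pts, cfg.canal)), spec)
        y = sub["log10_hg"].to_numpy()
        ll_opt = restricted_loglik(pts, X, y, m.vp)
        rng = np.random.default_rng(16)
        for _ in range(20):
            vp = h.VariogramParams(rng.uniform(0.05, 1.5), rng.uniform(0.0, 0.3),
                                   rng.uniform(5, 300), 0.5)
            assert restricted_loglik(pts, X, y, vp) <= ll_opt + 1e-4

    def test_duplicate_locations_jittered_with_warning(self, canal):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 300, size=(40, 2))
        pts[1] = pts[0]
        import pandas as pd

        X = _manual_model(canal, h.VariogramParams(0.3, 0.01, 50.0)).drift_design(pts)
        y = X @ [0.5, -0.3, 0.1] + 0.3 * rng.standard_normal(40)
        df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "log10_hg": y})
        with pytest.warns(UserWarning, match="jittered"):
            h.reml_fit(df, h.DriftSpec("quadratic"), canal, n_starts=1)

    def test_constant_response_rejected(self, canal):
        import pandas as pd

        rng = np.random.default_rng(18)
        df = pd.DataFrame({"x": rng.uniform(0, 100, 30), "y": rng.uniform(0, 100, 30),
                           "log10_hg": np.ones(30)})
        with pytest.raises(ValueError):
            h.reml_fit(df, h.DriftSpec("quadratic"), canal)


class TestPredictGrid:
    def test_single_cell_equals_point_prediction(self, canal):
        rng = np.random.default_rng(19)
        pts = rng.uniform(0, 100, size=(20, 2))
        y = rng.standard_normal(20)
        model = _manual_model(canal, h.VariogramParams(0.4, 0.01, 40.0))
        grid = h.predict_grid(model, (pts, y), (40, 40, 60, 60), 20.0)
        p = h.krige_predict(model, (pts, y), np.array([[50.0, 50.0]]))[0]
        assert grid.mean.shape == (1, 1)
        assert grid.mean[0, 0] == pytest.approx(p.mean)
        assert grid.se[0, 0] == pytest.approx(p.se)

    def test_se_higher_far_from_samples(self, small_field):
        # train on the left part of the domain only, so the right part is a
        # genuinely unsampled region more than 100 m from any observation
        soil, cfg, _ = small_field
        xmin, ymin, xmax, ymax = cfg.bbox
        left = soil[soil["x"] < xmin + 0.6 * (xmax - xmin)].reset_index(drop=True)
        model = h.reml_fit(left, h.DriftSpec("quadratic"), cfg.canal, n_starts=1)
        grid = h.predict_grid(model, left, (xmin, ymin, xmax, ymax),
                              (xmax - xmin) / 40)
        pts = left[["x", "y"]].to_numpy(float)
        xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
        cells = np.column_stack([xx.ravel(), yy.ravel()])
        dmin = cdist(cells, pts).min(axis=1)
        far, near = dmin >= 100, dmin <= 20
        assert far.sum() > 3 and near.sum() > 3
        assert grid.se.ravel()[far].mean() > grid.se.ravel()[near].mean()


    def test_constant_field_zero_nugget_constant_means(self, canal):
        rng = np.random.default_rng(20)
        pts = rng.uniform(0, 200, size=(25, 2))
        y = np.full(25, 0.7)
        model = _manual_model(canal, h.VariogramParams(0.4, 0.0, 60.0),
                              beta=(0.7, 0.0, 0.0))
        grid = h.predict_grid(model, (pts, y), (0, 0, 200, 200), 50.0)
        np.testing.assert_allclose(grid.mean, 0.7, atol=1e-6)

    def test_cell_cap_enforced(self, canal):
        model = _manual_model(canal, h.VariogramParams(0.4, 0.01, 60.0))
        with pytest.raises(ValueError, match="cap"):
            h.predict_grid(model, (np.zeros((3, 2)), np.zeros(3)),
                           (0, 0, 1000, 1000), 1.0, cell_cap=100)


class TestQQResiduals:
    def test_three_points_three_monotone_pairs(self, canal):
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 100, size=(3, 2))
        model = _manual_model(canal, h.VariogramParams(0.3, 0.05, 40.0))
        y = model.drift_design(pts) @ model.beta + rng.standard_normal(3)
        theo, obs = h.qq_residuals(model, (pts, y))
        assert len(theo) == len(obs) == 3
        assert np.all(np.diff(theo) > 0) and np.all(np.diff(obs) >= 0)

    def test_gaussian_simulation_whitens_correctly(self, canal):
        """On data simulated from the model, whitened residuals have ~unit
        variance and the QQ line has slope near 1."""
        rng = np.random.default_rng(22)
        n = 400
        pts = rng.uniform(0, 600, size=(n, 2))
        vp = h.VariogramParams(0.32, 0.02, 46.67, 0.5)
        model = _manual_model(canal, vp)
        from hgkrige.geo import cov_matrix

        L = np.linalg.cholesky(cov_matrix(pts, vp))
        y = model.drift_design(pts) @ model.beta + L @ rng.standard_normal(n)
        theo, obs = h.qq_residuals(model, (pts, y))
        assert np.var(obs) == pytest.approx(1.0, abs=0.2)
        slope = np.polyfit(theo, obs, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)
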