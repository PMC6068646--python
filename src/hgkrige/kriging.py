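"""External-drift (universal) kriging with REML variance estimation.

Model for the log10 concentration Y at location s:

    Y(s) = x(s)' beta + B(s) + eps,

where x(s) collects drift regressors (functions of log10 distance to the
canal), B is a zero-mean stationary Gaussian field with stable exponential
covariance sigma^2 exp(-(r/alpha)^gamma), and eps is iid noise with nugget
variance tau^2. (sigma^2, tau^2, alpha) are estimated by restricted maximum
likelihood with the shape exponent gamma fixed (0.5 by default); beta is the
GLS estimate at the REML optimum. Prediction is the universal-kriging BLUP
of the signal Z(s) = x(s)' beta + B(s), whose variance includes the
drift-estimation uncertainty but excludes the nugget (a flag adds it back
for response prediction).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats
from scipy.spatial.distance import cdist, pdist, squareform

from .drift import DriftSpec, build_drift_design
from .geo import Polyline, VariogramParams, distances_to_polyline, log_distance

__all__ = [
    "KrigingModel",
    "PredictionResult",
    "GridPrediction",
    "reml_fit",
    "restricted_loglik",
    "krige_predict",
    "predict_grid",
    "qq_residuals",
]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
#: Jitter (m) applied to duplicated sample locations so the covariance stays
#: non-singular.
DUPLICATE_JITTER = 1e-3
#: Default cap on the number of grid cells in predict_grid.
DEFAULT_CELL_CAP = 250_000


@dataclasses.dataclass
class KrigingModel:
    """A fitted external-drift spatial linear model."""

    drift_spec: DriftSpec
    beta: np.ndarray
    beta_cov: np.ndarray
    vp: VariogramParams
    gamma: float
    canal: Polyline
    distance_floor: float
    reml_loglik: float
    converged: bool
    n: int
    training_ref: str = ""

    def drift_design(self, points: np.ndarray) -> np.ndarray:
        ld = log_distance(distances_to_polyline(points, self.canal), self.distance_floor)
        return build_drift_design(ld, self.drift_spec)


@dataclasses.dataclass
class PredictionResult:
    """Kriging prediction of the signal at one location (log10 mg/kg)."""

    location: tuple[float, float]
    mean: float
    se: float


@dataclasses.dataclass
class GridPrediction:
    """Row-major raster of kriging means and standard errors."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    mean: np.ndarray  # shape (ny, nx)
    se: np.ndarray

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "mean_log10": self.mean.ravel(),
                "se_log10": self.se.ravel(),
            }
        )


def _coerce_samples(samples) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with x, y, log10_hg columns, a (points, values)
    tuple, or a list of (point, value) pairs; return (n,2) coords and values."""
    if hasattr(samples, "columns"):
        pts = samples[["x", "y"]].to_numpy(dtype=float)
        z = samples["log10_hg"].to_numpy(dtype=float)
        return pts, z
    if isinstance(samples, tuple) and len(samples) == 2:
        return np.asarray(samples[0], dtype=float), np.asarray(samples[1], dtype=float)
    pts = np.array([[p[0][0] if not hasattr(p[0], "x") else p[0].x,
                     p[0][1] if not hasattr(p[0], "x") else p[0].y] for p in samples])
    z = np.array([p[1] for p in samples], dtype=float)
    return pts, z


def _jitter_duplicates(points: np.ndarray, seed: int = 0) -> np.ndarray:
    pts = np.array(points, dtype=float, copy=True)
    _, inv, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inv] > 1
    if np.any(dup):
        warnings.warn(
            f"{int(dup.sum())} duplicated sample locations jittered by {DUPLICATE_JITTER} m",
            stacklevel=3,
        )
        rng = np.random.default_rng(seed)
        pts[dup] += rng.normal(scale=DUPLICATE_JITTER, size=(int(dup.sum()), 2))
    return pts


def _corr_matrix(D: np.ndarray, alpha: float, gamma: float) -> np.ndarray:
    return np.exp(-((D / alpha) ** gamma))


def restricted_loglik(points, X, y, vp: VariogramParams) -> float:
    """Restricted log-likelihood of (sigma^2, tau^2, alpha) given the data.

    Uses the standard REML criterion
    -0.5 [ (n-p) log 2pi + log|Sigma| + log|X' Sigma^-1 X| + r' Sigma^-1 r ]
    with Sigma = sigma^2 C_alpha + tau^2 I and r the GLS residual.
    """
    pts = np.asarray(points, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    D = squareform(pdist(pts))
    sigma = vp.sill_sigma2 * _corr_matrix(D, vp.range_alpha, vp.gamma)
    sigma[np.diag_indices(n)] += vp.nugget_tau2
    L = linalg.cholesky(sigma, lower=True)
    Xs = linalg.solve_triangular(L, X, lower=True)
    ys = linalg.solve_triangular(L, y, lower=True)
    xtx = Xs.T @ Xs
    beta = linalg.solve(xtx, Xs.T @ ys, assume_a="pos")
    r = ys - Xs @ beta
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
    logdet_xtx = np.linalg.slogdet(xtx)[1]
    return float(-0.5 * ((n - p) * _LOG2PI + logdet_sigma + logdet_xtx + r @ r))


def _profiled_neg2(logtheta: float, logalpha: float, D: np.ndarray, X: np.ndarray,
                   y: np.ndarray, gamma: float) -> float:
    """-2 x profiled restricted loglik (up to constants) with the overall
    scale sigma^2 profiled out of Sigma = sigma^2 (C_alpha + theta I)."""
    theta = np.exp(logtheta)
    alpha = np.exp(logalpha)
    n, p = X.shape
    V = _corr_matrix(D, alpha, gamma)
    V[np.diag_indices(n)] += theta
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return np.inf
    Xs = linalg.solve_triangular(L, X, lower=True)
    ys = linalg.solve_triangular(L, y, lower=True)
    xtx = Xs.T @ Xs
    try:
        beta = linalg.solve(xtx, Xs.T @ ys, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf
    r = ys - Xs @ beta
    q = float(r @ r)
    if q <= 0:
        return np.inf
    sigma2 = q / (n - p)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    logdet_xtx = np.linalg.slogdet(xtx)[1]
    # full -2 logLik_R = (n-p) log sigma2 + logdet terms + (n-p) (1 + log 2pi)
    return (n - p) * np.log(sigma2) + logdet_v + logdet_xtx


def _gls(sigma: np.ndarray, X: np.ndarray, y: np.ndarray):
    L = linalg.cholesky(sigma, lower=True)
    Xs = linalg.solve_triangular(L, X, lower=True)
    ys = linalg.solve_triangular(L, y, lower=True)
    xtx = Xs.T @ Xs
    beta = linalg.solve(xtx, Xs.T @ ys, assume_a="pos")
    beta_cov = linalg.inv(xtx)
    return beta, beta_cov


def _variogram_starts(D: np.ndarray, X: np.ndarray, y: np.ndarray, n_starts: int):
    """Multi-start initial values for (log theta, log alpha) from OLS
    residual variance and pairwise-distance quantiles."""
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    s2 = max(float(np.var(resid)), 1e-8)
    pos = D[np.triu_indices_from(D, k=1)]
    qs = np.quantile(pos, [0.05, 0.10, 0.25])
    cands = [
        (1e-2, qs[1]),
        (1e-2, qs[2]),
        (0.2, qs[1]),
        (1e-3, qs[0]),
        (0.5, qs[2]),
        (1e-2, qs[0]),
    ]
    starts = [(np.log(t), np.log(max(a, 1e-3))) for t, a in cands[: max(1, n_starts)]]
    return starts, s2


def reml_fit(
    samples,
    drift_spec: DriftSpec,
    canal: Polyline,
    gamma: float = 0.5,
    fix: dict | None = None,
    n_starts: int = 3,
    distance_floor: float = 1.0,
    training_ref: str = "",
) -> KrigingModel:
    """Fit the spatial linear model by (plain Gaussian) REML.

    ``fix`` may pin any of ``sigma2``, ``tau2``, ``alpha`` to a value; with
    ``sigma2`` fixed at 0 the fit degenerates exactly to the OLS drift fit.
    The optimizer works on log-transformed parameters with multi-start
    initializations derived from the empirical variogram heuristics.
    """
    fix = dict(fix or {})
    pts, y = _coerce_samples(samples)
    pts = _jitter_duplicates(pts)
    X = build_drift_design(log_distance(distances_to_polyline(pts, canal), distance_floor),
                           drift_spec)
    n, p = X.shape
    if n < p + 3:
        raise ValueError("too few samples for REML fitting")
    if np.allclose(y, y[0]):
        raise ValueError("all-constant response")
    D = squareform(pdist(pts))

    if fix.get("sigma2") == 0.0:
        # Sigma proportional to I: GLS == OLS, tau2 is the REML residual variance.
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        tau2 = fix.get("tau2", rss / (n - p))
        tau2_eff = tau2 if tau2 > 0 else rss / (n - p) if rss > 0 else 1e-12
        beta_cov = tau2_eff * linalg.inv(X.T @ X)
        vp = VariogramParams(0.0, max(tau2, 0.0), fix.get("alpha", 1.0), gamma)
        ll = np.nan
        return KrigingModel(drift_spec, beta, beta_cov, vp, gamma, canal,
                            distance_floor, ll, True, n, training_ref)

    free_alpha = "alpha" not in fix
    free_tau = "tau2" not in fix

    starts, _ = _variogram_starts(D, X, y, n_starts)
    best = None
    opts = {"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400}
    # the all-ones correlation limit (alpha -> inf) is degenerate; cap the
    # range search at a multiple of the domain diameter
    log_amax = np.log(3.0 * float(D.max()))

    if free_tau and free_alpha:
        fun = lambda v: np.inf if v[1] > log_amax else _profiled_neg2(
            v[0], v[1], D, X, y, gamma)
        for s in starts:
            res = optimize.minimize(fun, np.asarray(s), method="Nelder-Mead", options=opts)
            if best is None or res.fun < best.fun:
                best = res
        logtheta, logalpha = best.x
    elif free_alpha:  # tau2 fixed
        t_fixed = float(fix["tau2"])
        if t_fixed == 0.0:
            fun = lambda v: np.inf if v[0] > log_amax else _profiled_neg2(
                np.log(1e-12), v[0], D, X, y, gamma)
            for s in starts:
                res = optimize.minimize(fun, np.asarray([s[1]]), method="Nelder-Mead",
                                        options=opts)
                if best is None or res.fun < best.fun:
                    best = res
            logtheta, logalpha = np.log(1e-12), best.x[0]
        else:
            # profile is invalid for fixed positive tau2: direct 2-D over (log sigma2, log alpha)
            def fun(v):
                vp = VariogramParams(np.exp(v[0]), t_fixed, np.exp(v[1]), gamma)
                try:
                    return -restricted_loglik(pts, X, y, vp)
                except linalg.LinAlgError:
                    return np.inf
            for s in starts:
                res = optimize.minimize(fun, np.asarray([0.0, s[1]]), method="Nelder-Mead",
                                        options=opts)
                if best is None or res.fun < best.fun:
                    best = res
            sigma2 = float(np.exp(best.x[0]))
            alpha = float(np.exp(best.x[1]))
            return _finalize(pts, D, X, y, sigma2, t_fixed, alpha, gamma, drift_spec,
                             canal, distance_floor, bool(best.success), n, training_ref)
    else:  # alpha fixed
        a_fixed = float(fix["alpha"])
        fun = lambda v: _profiled_neg2(v[0], np.log(a_fixed), D, X, y, gamma)
        for s in starts:
            res = optimize.minimize(fun, np.asarray([s[0]]), method="Nelder-Mead", options=opts)
            if best is None or res.fun < best.fun:
                best = res
        logtheta, logalpha = best.x[0], np.log(a_fixed)
        if not free_tau:
            raise ValueError("fixing both tau2 and alpha with free sigma2 is unsupported")

    theta = float(np.exp(logtheta))
    alpha = float(np.exp(logalpha))
    # recover profiled sigma^2
    V = _corr_matrix(D, alpha, gamma)
    V[np.diag_indices(n)] += theta
    L = linalg.cholesky(V, lower=True)
    Xs = linalg.solve_triangular(L, X, lower=True)
    ys = linalg.solve_triangular(L, y, lower=True)
    beta = linalg.solve(Xs.T @ Xs, Xs.T @ ys, assume_a="pos")
    q = float(np.sum((ys - Xs @ beta) ** 2))
    sigma2 = q / (n - p)
    tau2 = float(fix.get("tau2", theta * sigma2))
    return _finalize(pts, D, X, y, sigma2, tau2, alpha, gamma, drift_spec, canal,
                     distance_floor, bool(best.success), n, training_ref)


def _finalize(pts, D, X, y, sigma2, tau2, alpha, gamma, drift_spec, canal,
              distance_floor, converged, n, training_ref) -> KrigingModel:
    vp = VariogramParams(max(sigma2, 0.0), max(tau2, 0.0), alpha, gamma)
    sigma = sigma2 * _corr_matrix(D, alpha, gamma)
    sigma[np.diag_indices(n)] += max(tau2, 1e-12 * max(sigma2, 1.0))
    beta, beta_cov = _gls(sigma, X, y)
    ll = restricted_loglik(pts, X, y, vp) if sigma2 > 0 else np.nan
    if not converged:
        logger.warning("REML optimizer reported non-convergence")
    return KrigingModel(drift_spec, beta, beta_cov, vp, gamma, canal, distance_floor,
                        ll, converged, n, training_ref)


def _prediction_system(model: KrigingModel, pts: np.ndarray, y: np.ndarray):
    """Factorized training-covariance pieces reused across prediction calls."""
    vp = model.vp
    n = len(pts)
    X = model.drift_design(pts)
    if vp.sill_sigma2 == 0.0:
        sigma = (vp.nugget_tau2 if vp.nugget_tau2 > 0 else 1.0) * np.eye(n)
    else:
        D = squareform(pdist(pts))
        sigma = vp.sill_sigma2 * _corr_matrix(D, vp.range_alpha, model.gamma)
        sigma[np.diag_indices(n)] += vp.nugget_tau2 if vp.nugget_tau2 > 0 else 1e-12 * vp.sill_sigma2
    cf = linalg.cho_factor(sigma, lower=True)
    beta, _ = _gls(sigma, X, y)
    resid = y - X @ beta
    sigma_inv_resid = linalg.cho_solve(cf, resid)
    sigma_inv_X = linalg.cho_solve(cf, X)
    xtx_inv = linalg.inv(X.T @ sigma_inv_X)
    return X, beta, cf, sigma_inv_resid, sigma_inv_X, xtx_inv


def krige_predict(
    model: KrigingModel,
    samples,
    targets,
    include_nugget: bool = False,
) -> list[PredictionResult]:
    """Universal-kriging BLUP of the signal at target locations.

    mean(s0) = x0' beta + c0' Sigma^-1 (y - X beta);
    var(s0)  = sigma^2 - c0' Sigma^-1 c0 + d' (X' Sigma^-1 X)^-1 d,
    with d = x0 - X' Sigma^-1 c0 (drift-estimation uncertainty). With
    ``include_nugget`` the nugget tau^2 is added for response prediction.
    """
    pts, y = _coerce_samples(samples)
    tg = np.asarray([[t[0] if not hasattr(t, "x") else t.x,
                      t[1] if not hasattr(t, "x") else t.y] for t in np.atleast_2d(targets)],
                    dtype=float)
    if not np.all(np.isfinite(tg)):
        raise ValueError("target coordinates must be finite")
    X, beta, cf, sir, six, xtx_inv = _prediction_system(model, pts, y)
    vp = model.vp
    X0 = model.drift_design(tg)
    if vp.sill_sigma2 == 0.0:
        mean = X0 @ beta
        var = np.einsum("ij,jk,ik->i", X0, xtx_inv, X0)
        if include_nugget:
            var = var + vp.nugget_tau2
        se = np.sqrt(np.maximum(var, 0.0))
        return [PredictionResult((float(t[0]), float(t[1])), float(m), float(s))
                for t, m, s in zip(tg, mean, se)]
    d0 = cdist(tg, pts)
    c0 = vp.sill_sigma2 * _corr_matrix(d0, vp.range_alpha, model.gamma)  # (m, n)
    mean = X0 @ beta + c0 @ sir
    dvec = X0 - c0 @ six  # (m, p)
    var = (
        vp.sill_sigma2
        - np.einsum("ij,ij->i", c0, linalg.cho_solve(cf, c0.T).T)
        + np.einsum("ij,jk,ik->i", dvec, xtx_inv, dvec)
    )
    if include_nugget:
        var = var + vp.nugget_tau2
    se = np.sqrt(np.maximum(var, 0.0))
    return [PredictionResult((float(t[0]), float(t[1])), float(m), float(s))
            for t, m, s in zip(tg, mean, se)]


def predict_grid(
    model: KrigingModel,
    samples,
    bbox: Sequence[float],
    cell_size: float,
    include_nugget: bool = False,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> GridPrediction:
    """Kriging on a regular grid of cell centers over bbox = (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bbox must be non-degenerate")
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    xs = np.arange(xmin + cell_size / 2, xmax, cell_size)
    ys = np.arange(ymin + cell_size / 2, ymax, cell_size)
    if xs.size * ys.size > cell_cap:
        raise ValueError(f"grid of {xs.size * ys.size} cells exceeds cap {cell_cap}")
    xx, yy = np.meshgrid(xs, ys)
    targets = np.column_stack([xx.ravel(), yy.ravel()])
    preds = krige_predict(model, samples, targets, include_nugget=include_nugget)
    mean = np.array([p.mean for p in preds]).reshape(ys.size, xs.size)
    se = np.array([p.se for p in preds]).reshape(ys.size, xs.size)
    return GridPrediction(xs, ys, mean, se)


def qq_residuals(model: KrigingModel, samples) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical Gaussian quantile, observed whitened-residual quantile) pairs.

    Residuals are decorrelated by the Cholesky factor of the fitted
    covariance (which whitens them to unit variance under the model) and
    sorted against standard-normal plotting positions.
    """
    pts, y = _coerce_samples(samples)
    vp = model.vp
    n = len(pts)
    D = squareform(pdist(pts))
    sigma = vp.sill_sigma2 * _corr_matrix(D, vp.range_alpha, model.gamma)
    sigma[np.diag_indices(n)] += max(vp.nugget_tau2, 1e-12 * max(vp.sill_sigma2, 1.0))
    try:
        L = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("fitted covariance is singular") from exc
    X = model.drift_design(pts)
    resid = y - X @ model.beta
    white = linalg.solve_triangular(L, resid, lower=True)
    obs = np.sort(white)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, obs
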