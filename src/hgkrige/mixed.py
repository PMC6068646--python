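"""Linear mixed models of log10 HBM outcomes with a family random intercept.

The outcome (log10 urinary mercury in µg/g creatinine, or log10 hair mercury
in µg/g) is regressed on soil exposure and questionnaire covariates; family
membership enters as an independent Gaussian random intercept so mothers and
children can be analysed in a single model. Estimation is REML (statsmodels
MixedLM); inference is Wald with a Gaussian reference (CI multiplier 1.96).
p-values are mapped to the Bland evidence categories used for lay
communication.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

__all__ = [
    "EVIDENCE_LABELS",
    "MixedModelFit",
    "categorize_evidence",
    "wald_inference",
    "fit_lmm",
    "run_outcome_models",
    "report_table",
    "lmm_reml_loglik",
]

# ordered from strongest to weakest evidence
EVIDENCE_LABELS = ("very_strong", "strong", "evidence", "weak", "little_or_none")

_META_COLS = ("participant_id", "family_id", "outcome", "exposure_se")


@dataclasses.dataclass
class MixedModelFit:
    """REML fit of the family-random-intercept model."""

    beta: pd.DataFrame  # index term; estimate, se, ci_low, ci_high, p_value
    sigma2_family: float
    sigma2_family_ci: tuple[float, float]
    sigma2_resid: float
    sigma2_resid_ci: tuple[float, float]
    n: int
    n_families: int
    converged: bool
    loglik: float
    terms: tuple[str, ...] = ()


def categorize_evidence(p: float) -> str:
    """Bland evidence category for a two-sided p-value.

    <0.001 very strong; <0.01 strong; [0.01, 0.05) evidence; [0.05, 0.1)
    weak; >=0.1 little or none. Exact 0.05 and 0.1 fall on the
    lower-evidence side.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "very_strong"
    if p < 0.01:
        return "strong"
    if p < 0.05:
        return "evidence"
    if p < 0.1:
        return "weak"
    return "little_or_none"


def wald_inference(estimates, ses) -> pd.DataFrame:
    """Wald z inference: CI = estimate +/- 1.96 SE, p from the Gaussian tail."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se < 0):
        raise ValueError("standard errors must be finite and non-negative")
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), np.where(est == 0, 1.0, 0.0))
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
            "p_value": p,
        }
    )


def lmm_reml_loglik(y, X, groups, s2f: float, s2e: float, d=None) -> float:
    """Restricted log-likelihood of the random-intercept model.

    Sigma = s2f * (same-family indicator) + diag(s2e + d); ``d`` holds
    optional per-observation known variance offsets (used by the Berkson
    error model; zero for the plain model).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    g = pd.factorize(np.asarray(groups))[0]
    n, p = X.shape
    dvec = np.zeros(n) if d is None else np.asarray(d, dtype=float)
    if s2f < 0 or s2e < 0 or np.any(s2e + dvec <= 0):
        return -np.inf
    sigma = s2f * (g[:, None] == g[None, :]).astype(float)
    sigma[np.diag_indices(n)] += s2e + dvec
    try:
        L = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    Xs = linalg.solve_triangular(L, X, lower=True)
    ys = linalg.solve_triangular(L, y, lower=True)
    xtx = Xs.T @ Xs
    beta = linalg.solve(xtx, Xs.T @ ys, assume_a="pos")
    r = ys - Xs @ beta
    return float(
        -0.5 * ((n - p) * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(L)))
                + np.linalg.slogdet(xtx)[1] + r @ r)
    )


def _variance_ci(y, X, groups, s2f: float, s2e: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Wald CIs for the variance components on the log scale, via a numerical
    Hessian of the REML log-likelihood. A near-zero family variance gets a
    degenerate [0, 0] interval."""
    if s2f < 1e-8:
        h = 1e-4
        f = lambda le: lmm_reml_loglik(y, X, groups, 0.0, np.exp(le))
        le = np.log(s2e)
        d2 = (f(le + h) - 2 * f(le) + f(le - h)) / h**2
        se_log = np.sqrt(-1.0 / d2) if d2 < 0 else np.inf
        return (0.0, 0.0), (s2e * np.exp(-1.96 * se_log), s2e * np.exp(1.96 * se_log))
    lf, le = np.log(s2f), np.log(s2e)
    h = 1e-4

    def f(a, b):
        return lmm_reml_loglik(y, X, groups, np.exp(a), np.exp(b))

    h11 = (f(lf + h, le) - 2 * f(lf, le) + f(lf - h, le)) / h**2
    h22 = (f(lf, le + h) - 2 * f(lf, le) + f(lf, le - h)) / h**2
    h12 = (f(lf + h, le + h) - f(lf + h, le - h) - f(lf - h, le + h) + f(lf - h, le - h)) / (4 * h**2)
    hess = np.array([[h11, h12], [h12, h22]])
    try:
        cov = linalg.inv(-hess)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except linalg.LinAlgError:
        sd = np.array([np.inf, np.inf])
    return (
        (s2f * np.exp(-1.96 * sd[0]), s2f * np.exp(1.96 * sd[0])),
        (s2e * np.exp(-1.96 * sd[1]), s2e * np.exp(1.96 * sd[1])),
    )


def _design(records: pd.DataFrame, covariates=None):
    cols = [c for c in records.columns if c not in _META_COLS] if covariates is None else \
        ["exposure", *covariates]
    if "exposure" in cols:
        cols = ["exposure"] + [c for c in cols if c != "exposure"]
    X = np.column_stack([np.ones(len(records))] + [records[c].to_numpy(dtype=float) for c in cols])
    names = ["intercept", *cols]
    return X, names


def fit_lmm(records: pd.DataFrame, covariates=None) -> MixedModelFit:
    """REML fit of outcome ~ exposure + covariates + (1 | family)."""
    if records["family_id"].nunique() < 2:
        raise ValueError("need at least two families")
    X, names = _design(records, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")
    y = records["outcome"].to_numpy(dtype=float)
    groups = records["family_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        # some near-collinear designs break individual optimizers; walk a chain
        for methods in (["lbfgs", "bfgs"], ["powell"], ["nm", "bfgs"], ["cg"]):
            try:
                res = model.fit(reml=True, method=methods)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is None:
            raise RuntimeError("mixed-model REML failed to converge with all optimizers")
    s2f = float(np.asarray(res.cov_re)[0, 0])
    s2e = float(res.scale)
    beta = wald_inference(np.asarray(res.fe_params), np.asarray(res.bse_fe))
    beta.index = names
    ci_f, ci_e = _variance_ci(y, X, groups, s2f, s2e)
    return MixedModelFit(
        beta=beta,
        sigma2_family=s2f,
        sigma2_family_ci=ci_f,
        sigma2_resid=s2e,
        sigma2_resid_ci=ci_e,
        n=len(records),
        n_families=int(records["family_id"].nunique()),
        converged=bool(res.converged),
        loglik=lmm_reml_loglik(y, X, groups, s2f, s2e),
        terms=tuple(names),
    )


def report_table(fit: MixedModelFit) -> pd.DataFrame:
    """Coefficient table with evidence categories, variance components appended."""
    tab = fit.beta.copy()
    tab["evidence_category"] = [categorize_evidence(p) for p in tab["p_value"]]
    var_rows = pd.DataFrame(
        {
            "estimate": [fit.sigma2_family, fit.sigma2_resid],
            "ci_low": [fit.sigma2_family_ci[0], fit.sigma2_resid_ci[0]],
            "ci_high": [fit.sigma2_family_ci[1], fit.sigma2_resid_ci[1]],
        },
        index=["family_variance", "residual_variance"],
    )
    out = pd.concat([tab, var_rows])
    out.index.name = "variable"
    return out.reset_index()


def run_outcome_models(
    records_urine: pd.DataFrame,
    records_hair: pd.DataFrame,
    exposure_kind: str = "measured",
) -> dict[str, dict]:
    """Fit the urine and hair models for one exposure kind.

    Record tables are expected to already carry the exposure kind's encoding
    (det-limit indicator and the age x mother interaction appear in
    measured-exposure models only).
    """
    if exposure_kind not in ("measured", "predicted"):
        raise ValueError("exposure_kind must be 'measured' or 'predicted'")
    out = {}
    for outcome, rec in (("urine", records_urine), ("hair", records_hair)):
        fit = fit_lmm(rec)
        out[outcome] = {"fit": fit, "table": report_table(fit),
                        "exposure_kind": exposure_kind}
    return out
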