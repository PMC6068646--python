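"""Candidate drift regressions of log10 soil Hg on log10 canal distance.

Four Gaussian linear models of the concentration-vs-distance trend are fit
and compared by AIC: linear, quadratic, broken-stick (continuous hinge at a
breakpoint on the log10-distance axis), and an inverse model that adds the
regressor (1 + logdist)^-1. The winning drift is then used as the external
drift of the spatial model; by convention the quadratic drift is the
downstream default regardless of a per-run selection, and callers may
override.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DRIFT_KINDS",
    "DriftSpec",
    "DriftFitResult",
    "build_drift_design",
    "fit_drift_ols",
    "fit_all_drifts",
    "select_drift",
    "drift_table",
]

# Fixed enum order; used as the last tie-break in model selection.
DRIFT_KINDS = ("linear", "quadratic", "broken_stick", "inverse")


@dataclasses.dataclass(frozen=True)
class DriftSpec:
    """A drift-model choice; ``breakpoint`` only matters for broken_stick."""

    kind: str = "quadratic"
    breakpoint: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in DRIFT_KINDS:
            raise ValueError(f"unknown drift kind {self.kind!r}")
        if not math.isfinite(self.breakpoint):
            raise ValueError("breakpoint must be finite")

    @property
    def n_coef(self) -> int:
        return 2 if self.kind == "linear" else 3

    def column_names(self) -> list[str]:
        base = ["intercept", "logdist"]
        if self.kind == "linear":
            return base
        if self.kind == "quadratic":
            return base + ["logdist_sq"]
        if self.kind == "broken_stick":
            return base + [f"hinge_{self.breakpoint:g}"]
        return base + ["inv_1p_logdist"]


@dataclasses.dataclass
class DriftFitResult:
    spec: DriftSpec
    coefficients: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high, p_value
    residual_variance: float  # MLE sigma^2 = RSS / n
    loglik: float
    aic: float
    bic: float
    n: int

    @property
    def k(self) -> int:
        """Parameter count used in AIC/BIC: regression coefficients + error variance."""
        return len(self.coefficients) + 1


def build_drift_design(logdist, spec: DriftSpec) -> np.ndarray:
    """Design matrix (with intercept) for one drift specification.

    linear:       (1, d)
    quadratic:    (1, d, d^2)
    broken_stick: (1, d, max(0, d - breakpoint))
    inverse:      (1, d, (1 + d)^-1)
    """
    d = np.atleast_1d(np.asarray(logdist, dtype=float))
    if not np.all(np.isfinite(d)):
        raise ValueError("logdist must be finite")
    one = np.ones_like(d)
    if spec.kind == "linear":
        cols = [one, d]
    elif spec.kind == "quadratic":
        cols = [one, d, d * d]
    elif spec.kind == "broken_stick":
        cols = [one, d, np.maximum(0.0, d - spec.breakpoint)]
    else:  # inverse
        if np.any(1.0 + d == 0.0):
            raise ValueError("inverse drift undefined where 1 + logdist = 0")
        cols = [one, d, 1.0 / (1.0 + d)]
    return np.column_stack(cols)


def fit_drift_ols(y, X, spec: DriftSpec | None = None) -> DriftFitResult:
    """Gaussian OLS fit of one drift design with Wald CIs and AIC/BIC.

    AIC = 2k - 2 logL and BIC = k ln(n) - 2 logL where logL is the Gaussian
    log-likelihood at the MLE variance (RSS/n) and k counts the regression
    coefficients plus the variance parameter.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient drift design")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    sigma2_mle = rss / n
    if sigma2_mle > 0:
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2_mle) + 1.0)
    else:  # perfect fit: report +inf likelihood surrogate via a tiny floor
        loglik = math.inf
    k = p + 1
    aic = 2 * k - 2 * loglik
    bic = k * math.log(n) - 2 * loglik
    ci = res.conf_int(alpha=0.05)
    names = spec.column_names() if spec is not None else [f"x{i}" for i in range(p)]
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p_value": res.pvalues,
        },
        index=names,
    )
    return DriftFitResult(
        spec=spec if spec is not None else DriftSpec("linear"),
        coefficients=coef,
        residual_variance=sigma2_mle,
        loglik=loglik,
        aic=aic,
        bic=bic,
        n=n,
    )


def fit_all_drifts(y, logdist, breakpoint: float = 2.0) -> list[DriftFitResult]:
    """Fit the four candidate drifts on the same data."""
    out = []
    for kind in DRIFT_KINDS:
        spec = DriftSpec(kind, breakpoint)
        out.append(fit_drift_ols(y, build_drift_design(logdist, spec), spec))
    return out


def select_drift(results: list[DriftFitResult]) -> DriftSpec:
    """Drift with minimal AIC; ties broken by fewer parameters, then enum order."""
    if not results:
        raise ValueError("no drift fits to select from")
    order = {k: i for i, k in enumerate(DRIFT_KINDS)}
    best = min(results, key=lambda r: (r.aic, r.k, order[r.spec.kind]))
    return best.spec


def drift_table(results: list[DriftFitResult]) -> pd.DataFrame:
    """One row per model: coefficients, AIC and BIC, for reporting/export."""
    rows = []
    for r in results:
        slope_terms = r.coefficients.iloc[1:]
        rows.append(
            {
                "model": r.spec.kind,
                "coefficients": "; ".join(
                    f"{t}={v:.3g}" for t, v in slope_terms["estimate"].items()
                ),
                "p_values": "; ".join(f"{v:.3g}" for v in slope_terms["p_value"]),
                "aic": r.aic,
                "bic": r.bic,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)
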