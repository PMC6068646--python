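"""k-fold cross-validation of the kriging model with calibration diagnostics.

Per fold the full spatial model (variogram parameters by REML plus the GLS
drift coefficients) is refit on the training portion and the held-out
samples are predicted; folds are random, not spatially blocked. The summary
mirrors the usual calibration diagnostics: Pearson correlation between
measured and predicted log10 concentrations and the least-squares line of
predicted on measured (a slope below 1 reflects smoothing shrinkage:
high values underestimated, low values overestimated).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .drift import DriftSpec
from .geo import Polyline
from .kriging import krige_predict, reml_fit

__all__ = ["CVResult", "kfold_split", "cross_validate"]


@dataclasses.dataclass
class CVResult:
    fold_assignment: np.ndarray
    measured: np.ndarray
    predicted: np.ndarray
    pearson_r: float
    calib_slope: float
    calib_intercept: float
    k: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": np.arange(len(self.measured)),
                "fold": self.fold_assignment,
                "measured_log10": self.measured,
                "predicted_log10": self.predicted,
            }
        )

    def summary(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "calib_slope": self.calib_slope,
            "calib_intercept": self.calib_intercept,
            "k": self.k,
            "seed": self.seed,
        }


def kfold_split(n: int, k: int = 6, seed: int = 0) -> np.ndarray:
    """Uniformly random partition of n items into k folds of near-equal size."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("k may not exceed n")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k
    return folds[rng.permutation(n)]


def cross_validate(
    samples,
    drift_spec: DriftSpec,
    canal: Polyline,
    k: int = 6,
    seed: int = 0,
    gamma: float = 0.5,
    n_starts: int = 2,
) -> CVResult:
    """k-fold CV with a full per-fold refit (REML variogram + GLS drift)."""
    df = samples if hasattr(samples, "columns") else None
    if df is None:
        raise TypeError("cross_validate expects a soil DataFrame with x, y, log10_hg")
    n = len(df)
    folds = kfold_split(n, k=k, seed=seed)
    measured = df["log10_hg"].to_numpy(dtype=float)
    predicted = np.full(n, np.nan)
    for fold in range(k):
        test = folds == fold
        train = ~test
        try:
            model = reml_fit(df.loc[train], drift_spec, canal, gamma=gamma,
                             n_starts=n_starts)
        except Exception as exc:
            raise RuntimeError(f"model fit failed on fold {fold}") from exc
        targets = df.loc[test, ["x", "y"]].to_numpy(dtype=float)
        preds = krige_predict(model, df.loc[train], targets)
        predicted[test] = [p.mean for p in preds]
    r = float(np.corrcoef(measured, predicted)[0, 1])
    slope, intercept = np.polyfit(measured, predicted, 1)
    return CVResult(folds, measured, predicted, r, float(slope), float(intercept), k, seed)
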