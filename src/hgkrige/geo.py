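"""Spatial primitives: geometry, covariance functions, empirical variograms.

Everything downstream (drift regressions, kriging, the simulator) works on
planar coordinates in meters (a Swiss-grid-like projection is assumed; no
geodesic computation) and on log10-transformed mercury concentrations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import LineString
from shapely.geometry import Point as _ShapelyPoint

__all__ = [
    "Point2D",
    "Polyline",
    "SoilSample",
    "VariogramParams",
    "EmpiricalVariogram",
    "distance_to_polyline",
    "distances_to_polyline",
    "log_distance",
    "stable_exponential_cov",
    "cov_matrix",
    "matheron_variogram",
    "default_lag_bins",
]

#: Distance floor (m) applied before taking log10 of a distance to the canal.
#: Keeps the logarithm finite for points on the canal; 1 m is negligible at
#: the scale of the study region.
DEFAULT_DISTANCE_FLOOR = 1.0


class Point2D(NamedTuple):
    """A planar location: easting/northing in meters."""

    x: float
    y: float


@dataclasses.dataclass(frozen=True)
class Polyline:
    """An ordered 2-D polyline, e.g. the contaminating canal.

    Wraps a ``shapely.LineString`` for distance queries. Consecutive
    vertices must be distinct and the total length positive.
    """

    vertices: tuple[Point2D, ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        pts = np.asarray(self.vertices, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("polyline vertices must be finite")
        seglen = np.hypot(*(np.diff(pts, axis=0).T))
        if np.any(seglen == 0.0):
            raise ValueError("consecutive polyline vertices must be distinct")
        object.__setattr__(self, "vertices", tuple(Point2D(*v) for v in pts))

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)

    @classmethod
    def from_coords(cls, coords: Sequence[Sequence[float]]) -> "Polyline":
        return cls(tuple(Point2D(float(x), float(y)) for x, y in coords))


@dataclasses.dataclass
class SoilSample:
    """One georeferenced total-mercury soil measurement.

    ``hg`` is in mg/kg after any below-LOD substitution; ``below_lod`` marks
    values that were substituted with half the limit of determination.
    """

    location: Point2D
    hg: float
    depth_layer: str = "0-20cm"
    parcel_id: str = ""
    below_lod: bool = False

    def __post_init__(self) -> None:
        if not self.hg > 0:
            raise ValueError("hg must be positive after LOD substitution")


@dataclasses.dataclass(frozen=True)
class VariogramParams:
    """Parameters of the stable exponential spatial covariance.

    sill_sigma2
        Variance of the spatially autocorrelated field, (log10 mg/kg)^2.
    nugget_tau2
        Variance of the iid micro-scale/measurement error.
    range_alpha
        Distance scale (m) of the correlation decay.
    gamma
        Shape exponent in (0, 2]; 0.5 by default (1 gives the exponential
        model).
    """

    sill_sigma2: float
    nugget_tau2: float
    range_alpha: float
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.sill_sigma2 < 0 or self.nugget_tau2 < 0:
            raise ValueError("variances must be non-negative")
        if not self.range_alpha > 0:
            raise ValueError("range_alpha must be positive")
        if not 0 < self.gamma <= 2:
            raise ValueError("gamma must lie in (0, 2]")


@dataclasses.dataclass
class EmpiricalVariogram:
    """Method-of-moments semivariogram: one semivariance per lag bin."""

    lag_bin_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.lag_bin_centers = np.asarray(self.lag_bin_centers, dtype=float)
        self.semivariances = np.asarray(self.semivariances, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)


def _as_xy(p) -> tuple[float, float]:
    x, y = (p.x, p.y) if hasattr(p, "x") else (p[0], p[1])
    return float(x), float(y)


def distance_to_polyline(p, canal: Polyline) -> float:
    """Minimum Euclidean distance (m) from a point to any segment of the canal."""
    x, y = _as_xy(p)
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("point coordinates must be finite")
    return float(canal.line.distance(_ShapelyPoint(x, y)))


def distances_to_polyline(points: np.ndarray, canal: Polyline) -> np.ndarray:
    """Vectorized :func:`distance_to_polyline` for an (n, 2) coordinate array."""
    pts = np.ascontiguousarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    geoms = shapely.points(pts)
    return shapely.distance(geoms, canal.line)


def log_distance(d, floor: float = DEFAULT_DISTANCE_FLOOR):
    """log10 of a distance, floored at ``floor`` meters (default 1 m).

    The floor keeps the transform finite for residences or samples sitting on
    the canal itself; at 1 m it is negligible relative to the study extent.
    """
    if not floor > 0:
        raise ValueError("floor must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.log10(np.maximum(d, floor))
    return float(out) if out.ndim == 0 else out


def stable_exponential_cov(r, vp: VariogramParams):
    """Stable exponential covariance C(r) = sigma^2 * exp(-(r/alpha)^gamma).

    ``gamma = 1`` recovers the exponential model; ``gamma = 0.5`` (the
    default) gives a continuous but non-differentiable field, appropriate
    when contamination was deposited in a pointwise manner.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("lag distances must be non-negative")
    out = vp.sill_sigma2 * np.exp(-((r / vp.range_alpha) ** vp.gamma))
    return float(out) if out.ndim == 0 else out


def cov_matrix(points: np.ndarray, vp: VariogramParams, nugget: bool = True) -> np.ndarray:
    """Dense covariance matrix of the spatial model on a point set.

    Returns sigma^2 * C + tau^2 * I (tau^2 omitted when ``nugget=False``).
    """
    pts = np.asarray(points, dtype=float)
    d = squareform(pdist(pts))
    k = stable_exponential_cov(d, vp)
    if nugget:
        k = k + vp.nugget_tau2 * np.eye(len(pts))
    return k


def theoretical_semivariogram(h, vp: VariogramParams):
    """Semivariogram implied by the covariance model: tau^2 + sigma^2 (1 - C(h)/sigma^2)."""
    h = np.asarray(h, dtype=float)
    return vp.nugget_tau2 + vp.sill_sigma2 * (1.0 - np.exp(-((h / vp.range_alpha) ** vp.gamma)))


def default_lag_bins(points: np.ndarray, n_bins: int = 15) -> np.ndarray:
    """Equal-width lag bin edges up to half the maximum pairwise distance."""
    d = pdist(np.asarray(points, dtype=float))
    if d.size == 0:
        raise ValueError("need at least two points to define lag bins")
    return np.linspace(0.0, 0.5 * float(d.max()), n_bins + 1)


def matheron_variogram(
    points: np.ndarray,
    values: np.ndarray,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 15,
) -> EmpiricalVariogram:
    """Method-of-moments (Matheron) empirical semivariogram.

    For each lag bin, gamma_hat(h) = (1 / (2 N(h))) * sum over pairs in the
    bin of (z_i - z_j)^2. Empty bins get NaN semivariance and pair count 0.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two samples")
    if bin_edges is None:
        bin_edges = default_lag_bins(pts, n_bins=n_bins)
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    d = pdist(pts)
    sq = pdist(z[:, None], metric="sqeuclidean")
    idx = np.digitize(d, edges) - 1  # pairs outside [edges[0], edges[-1]) dropped
    inside = (idx >= 0) & (idx < len(edges) - 1) & (d >= edges[0]) & (d < edges[-1])
    if not np.any(inside):
        raise ValueError("no point pairs fall inside the lag bins")
    nb = len(edges) - 1
    counts = np.bincount(idx[inside], minlength=nb)
    sums = np.bincount(idx[inside], weights=sq[inside], minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts)
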