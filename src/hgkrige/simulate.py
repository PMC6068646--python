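"""Synthetic soil fields, canal geometry, and participant cohorts.

The generator reproduces the statistical structure the analysis assumes:
~3000 topsoil samples whose log10 mercury follows a quadratic-in-log-distance
drift plus a stationary Gaussian random field with stable exponential
covariance (drawn exactly by Cholesky factorization) and nugget noise, with
sampling denser near the canal; and a cohort of 64 families (64 mothers, 107
children by default) whose log10 urine and hair outcomes follow the linear
mixed models with a shared family intercept. Questionnaire covariate
distributions are invented (documented here and in the fixture manifest):
amalgam fillings Poisson(2) for mothers and Poisson(0.2) for children, sea
fish portions Poisson(3), family-level binary indicators with the
probabilities listed in :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd
import yaml
from scipy import linalg
from scipy.spatial.distance import cdist, pdist, squareform

from .geo import (
    Polyline,
    VariogramParams,
    distances_to_polyline,
    log_distance,
    stable_exponential_cov,
)

__all__ = [
    "SimulationConfig",
    "FieldModel",
    "simulate_soil_field",
    "simulate_participants",
    "make_fixture_suite",
    "scaled_study_config",
]

# Default outcome-model coefficients (log10 scale), keyed by encoded
# covariate name; exposure is the log10 soil mercury term.
URINE_COEFS = {
    "intercept": 0.2,
    "exposure": 0.02,
    "det_limit": -0.08,
    "age": -0.04,
    "mother": -0.97,
    "age_x_mother": 0.05,
    "amalgam_sqrt": 0.33,
    "seafish_sqrt": 0.08,
    "seafish_last3d": 0.32,
    "smoking": 0.30,
    "near_sea_birth": -0.01,
    "veg_region": 0.07,
}
HAIR_COEFS = {
    "intercept": -0.5,
    "exposure": 0.05,
    "det_limit": -0.02,
    "age": 0.01,
    "mother": -0.67,
    "age_x_mother": 0.01,
    "amalgam_sqrt": 0.04,
    "seafish_sqrt": 0.17,
    "smoking": 0.12,
    "near_sea_birth": 0.19,
    "veg_region": 0.06,
    "hair_dyeing": -0.19,
}

_DEFAULT_CANAL = ((0.0, 420.0), (600.0, 400.0), (1200.0, 380.0),
                  (1800.0, 410.0), (2400.0, 390.0))


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the study simulator with study-scale defaults."""

    seed: int = 0
    n_soil: int = 3000
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 2400.0, 800.0)
    canal_vertices: tuple = _DEFAULT_CANAL
    drift_beta: tuple[float, float, float] = (2.34, -2.23, 0.38)
    variogram: VariogramParams = dataclasses.field(
        default_factory=lambda: VariogramParams(0.32, 0.003, 46.67, 0.5)
    )
    lod: float | None = 0.1  # None disables LOD censoring (pure-field studies)
    near_frac: float = 0.6  # fraction of samples placed within near_band of the canal
    near_band: float = 200.0
    deeper_frac: float = 0.15  # extra non-topsoil samples, as a fraction of n_soil
    parcel_size: float = 100.0  # square land parcels, m
    distance_floor: float = 1.0
    # cohort
    n_families: int = 64
    n_children_total: int = 107  # conditioned total across families
    mother_age: tuple[float, float] = (25.0, 45.0)
    child_age: tuple[float, float] = (2.0, 11.0)
    residence_sd: float = 120.0  # spread of residences around village centers
    amalgam_mean_mother: float = 2.0
    amalgam_mean_child: float = 0.2
    seafish_mean: float = 3.0
    p_last3d: float = 0.3  # family-level
    p_smoking_mother: float = 0.25
    p_near_sea: float = 0.25  # family-level
    p_veg: float = 0.5  # family-level
    p_dyeing_mother: float = 0.3
    p_dyeing_child: float = 0.05
    creatinine_out_frac: float = 0.03  # fraction outside the WHO range
    urine_coefs: dict = dataclasses.field(default_factory=lambda: dict(URINE_COEFS))
    hair_coefs: dict = dataclasses.field(default_factory=lambda: dict(HAIR_COEFS))
    urine_family_sd: float = float(np.sqrt(0.03))
    urine_resid_sd: float = float(np.sqrt(0.06))
    hair_family_sd: float = float(np.sqrt(0.01))
    hair_resid_sd: float = float(np.sqrt(0.11))

    def __post_init__(self) -> None:
        if self.n_soil < 10:
            raise ValueError("n_soil must be at least 10")
        for sd in (self.urine_family_sd, self.urine_resid_sd,
                   self.hair_family_sd, self.hair_resid_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")

    @property
    def canal(self) -> Polyline:
        return Polyline.from_coords(self.canal_vertices)


def scaled_study_config(n_soil: int, seed: int = 0, **overrides) -> SimulationConfig:
    """A config whose bounding box is shrunk so the sampling density matches
    the full-scale default (3000 samples on 2400 x 800 m), keeping a 3:1
    aspect and the canal along the long axis."""
    density = 3000.0 / (2400.0 * 800.0)
    area = n_soil / density
    width = float(np.sqrt(3.0 * area))
    height = area / width
    ymid = height / 2.0
    xs = np.linspace(0.0, width, 5)
    wiggle = 0.04 * height * np.array([0.5, -0.5, -1.0, 0.75, -0.25])
    canal = tuple((float(x), float(ymid + w)) for x, w in zip(xs, wiggle))
    cfg = SimulationConfig(seed=seed, n_soil=n_soil, bbox=(0.0, 0.0, width, height),
                           canal_vertices=canal,
                           near_band=min(200.0, height / 4.0), **overrides)
    return cfg


@dataclasses.dataclass
class FieldModel:
    """The latent Gaussian field realized at the soil locations.

    Supports exact conditional draws at new locations (used to give
    participants their true latent soil exposure, consistent with the
    simulated samples).
    """

    points: np.ndarray
    field: np.ndarray  # zero-mean spatial component B at the soil locations
    vp: VariogramParams
    canal: Polyline
    drift_beta: np.ndarray
    distance_floor: float
    _cf: tuple = dataclasses.field(default=None, repr=False)

    def drift(self, points: np.ndarray) -> np.ndarray:
        ld = log_distance(distances_to_polyline(points, self.canal), self.distance_floor)
        return self.drift_beta[0] + self.drift_beta[1] * ld + self.drift_beta[2] * ld**2

    def conditional_draw(self, points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Latent log10 value (drift + field, no nugget) at new points, drawn
        from the conditional law given the realized field."""
        pts = np.asarray(points, dtype=float)
        mu = self.drift(pts)
        if self.vp.sill_sigma2 == 0.0:
            return mu
        if self._cf is None:
            self._cf = linalg.cho_factor(_field_cov(self.points, self.vp), lower=True)
        k_ns = stable_exponential_cov(cdist(pts, self.points), self.vp)
        w = linalg.cho_solve(self._cf, k_ns.T)  # (n_soil, m)
        cmean = k_ns @ linalg.cho_solve(self._cf, self.field)
        ccov = stable_exponential_cov(cdist(pts, pts), self.vp) - k_ns @ w
        ccov = 0.5 * (ccov + ccov.T)
        ccov[np.diag_indices(len(pts))] += 1e-10
        draw = rng.multivariate_normal(np.zeros(len(pts)), ccov, method="cholesky")
        return mu + cmean + draw


def _field_cov(points: np.ndarray, vp: VariogramParams) -> np.ndarray:
    k = stable_exponential_cov(squareform(pdist(points)), vp)
    k[np.diag_indices(len(points))] += 1e-10  # Cholesky jitter
    return k


def _sample_locations(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sampling-intensity mixture: near_frac of points within near_band of the
    canal (rejection sampling), the rest uniform over the bbox."""
    xmin, ymin, xmax, ymax = cfg.bbox
    n_near = int(round(cfg.near_frac * n))
    canal = cfg.canal
    near = np.empty((0, 2))
    while len(near) < n_near:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(max(4 * n_near, 256), 2))
        d = distances_to_polyline(cand, canal)
        near = np.vstack([near, cand[d <= cfg.near_band]])
    near = near[:n_near]
    far = rng.uniform([xmin, ymin], [xmax, ymax], size=(n - n_near, 2))
    return np.vstack([near, far])


def _parcel_ids(cfg: SimulationConfig, points: np.ndarray) -> list[str]:
    ix = np.floor(points[:, 0] / cfg.parcel_size).astype(int)
    iy = np.floor(points[:, 1] / cfg.parcel_size).astype(int)
    return [f"P{a}_{b}" for a, b in zip(ix, iy)]


def simulate_soil_field(cfg: SimulationConfig, return_field: bool = False):
    """Simulate the soil-sample table (mg/kg scale).

    Topsoil log10 values are drift + exact-Cholesky Gaussian field + nugget
    noise; values below the LOD (when enabled) are substituted with half the
    LOD and flagged. A smaller batch of deeper-layer samples (shifted drift,
    independent noise) exercises the topsoil filter downstream.
    """
    rng = np.random.default_rng(cfg.seed)
    pts = _sample_locations(cfg, cfg.n_soil, rng)
    field = FieldModel(pts, np.zeros(len(pts)), cfg.variogram, cfg.canal,
                       np.asarray(cfg.drift_beta, dtype=float), cfg.distance_floor)
    mu = field.drift(pts)
    vp = cfg.variogram
    if vp.sill_sigma2 > 0:
        k = _field_cov(pts, vp)
        L = linalg.cholesky(k, lower=True)
        b = L @ rng.standard_normal(len(pts))
    else:
        b = np.zeros(len(pts))
    field.field = b
    eps = np.sqrt(vp.nugget_tau2) * rng.standard_normal(len(pts)) if vp.nugget_tau2 > 0 else 0.0
    ylog = mu + b + eps
    hg = 10.0**ylog
    below = np.zeros(len(pts), dtype=bool)
    if cfg.lod is not None:
        below = hg < cfg.lod
        hg = np.where(below, cfg.lod / 2.0, hg)
    rows = pd.DataFrame({
        "x": pts[:, 0], "y": pts[:, 1], "hg_mgkg": hg,
        "depth_layer": "0-20cm", "parcel_id": _parcel_ids(cfg, pts),
        "below_lod": below,
    })
    n_deep = int(round(cfg.deeper_frac * cfg.n_soil))
    if n_deep:
        dpts = _sample_locations(cfg, n_deep, rng)
        dlog = field.drift(dpts) - 0.4 + 0.5 * rng.standard_normal(n_deep)
        dhg = 10.0**dlog
        dbelow = np.zeros(n_deep, dtype=bool)
        if cfg.lod is not None:
            dbelow = dhg < cfg.lod
            dhg = np.where(dbelow, cfg.lod / 2.0, dhg)
        deep = pd.DataFrame({
            "x": dpts[:, 0], "y": dpts[:, 1], "hg_mgkg": dhg,
            "depth_layer": rng.choice(["20-40cm", "deeper"], size=n_deep),
            "parcel_id": _parcel_ids(cfg, dpts), "below_lod": dbelow,
        })
        rows = pd.concat([rows, deep], ignore_index=True)
    if return_field:
        return rows, field
    return rows


def _children_counts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-family child counts: one child each, extras multinomially assigned
    so the total is exactly n_children_total."""
    extra = cfg.n_children_total - cfg.n_families
    if extra < 0:
        raise ValueError("need at least one child per family")
    counts = np.ones(cfg.n_families, dtype=int)
    counts += rng.multinomial(extra, np.full(cfg.n_families, 1.0 / cfg.n_families))
    return counts


def _village_centers(cfg: SimulationConfig) -> np.ndarray:
    """Three residential clusters offset from the canal, mimicking the
    study's villages."""
    xmin, ymin, xmax, ymax = cfg.bbox
    xs = xmin + np.array([0.15, 0.5, 0.85]) * (xmax - xmin)
    canal = cfg.canal
    centers = []
    for x in xs:
        # place the village center ~30% of the box height away from the canal
        ytry = np.linspace(ymin, ymax, 41)
        d = distances_to_polyline(np.column_stack([np.full_like(ytry, x), ytry]), canal)
        target = 0.3 * (ymax - ymin)
        centers.append((x, ytry[np.argmin(np.abs(d - target))]))
    return np.asarray(centers)


def simulate_participants(cfg: SimulationConfig, field: FieldModel):
    """Simulate the participant table and the generation truth.

    Families live in village clusters; every member shares the family's
    residence and its true latent log10 soil value (a conditional draw from
    the same Gaussian field as the soil samples). Outcomes follow the linear
    mixed models with the configured coefficients, a shared family intercept,
    and Gaussian residuals. Returns ``(participants, truth)`` where truth
    records the latent exposures and generating parameters.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    nf = cfg.n_families
    counts = _children_counts(cfg, rng)
    centers = _village_centers(cfg)
    zone = rng.integers(0, len(centers), size=nf)
    xmin, ymin, xmax, ymax = cfg.bbox
    res = centers[zone] + cfg.residence_sd * rng.standard_normal((nf, 2))
    res[:, 0] = np.clip(res[:, 0], xmin + 1, xmax - 1)
    res[:, 1] = np.clip(res[:, 1], ymin + 1, ymax - 1)
    true_expo_fam = field.conditional_draw(res, rng)
    lod_log = np.log10(cfg.lod) if cfg.lod is not None else -np.inf
    fam_urine = cfg.urine_family_sd * rng.standard_normal(nf)
    fam_hair = cfg.hair_family_sd * rng.standard_normal(nf)
    near_sea = rng.random(nf) < cfg.p_near_sea
    veg = rng.random(nf) < cfg.p_veg
    last3d = rng.random(nf) < cfg.p_last3d

    rows, truth_rows = [], []
    pid = 0
    for f in range(nf):
        members = [("mother", rng.uniform(*cfg.mother_age))]
        members += [("child", rng.uniform(*cfg.child_age)) for _ in range(counts[f])]
        for role, age in members:
            mother = role == "mother"
            amalgam = rng.poisson(cfg.amalgam_mean_mother if mother else cfg.amalgam_mean_child)
            seafish = rng.poisson(cfg.seafish_mean)
            smoking = bool(mother and rng.random() < cfg.p_smoking_mother)
            dyeing = bool(rng.random() < (cfg.p_dyeing_mother if mother else cfg.p_dyeing_child))
            enc = {
                "exposure": true_expo_fam[f],
                "det_limit": float(true_expo_fam[f] < lod_log),
                "age": age,
                "mother": float(mother),
                "age_x_mother": age * float(mother),
                "amalgam_sqrt": np.sqrt(amalgam),
                "seafish_sqrt": np.sqrt(seafish),
                "seafish_last3d": float(last3d[f]),
                "smoking": float(smoking),
                "near_sea_birth": float(near_sea[f]),
                "veg_region": float(veg[f]),
                "hair_dyeing": float(dyeing),
            }
            lu = cfg.urine_coefs.get("intercept", 0.0) + sum(
                v * enc.get(k, 0.0) for k, v in cfg.urine_coefs.items() if k != "intercept"
            ) + fam_urine[f] + cfg.urine_resid_sd * rng.standard_normal()
            lh = cfg.hair_coefs.get("intercept", 0.0) + sum(
                v * enc.get(k, 0.0) for k, v in cfg.hair_coefs.items() if k != "intercept"
            ) + fam_hair[f] + cfg.hair_resid_sd * rng.standard_normal()
            # creatinine ~ lognormal around 1 g/L; a small fraction outside the
            # WHO range exercises the exclusion rule
            if rng.random() < cfg.creatinine_out_frac:
                crea = float(rng.choice([0.2, 3.5]))
            else:
                crea = float(np.clip(np.exp(0.3 * rng.standard_normal()), 0.35, 2.9))
            pid += 1
            rows.append({
                "id": f"S{pid:04d}",
                "family_id": f"F{f:03d}",
                "mother": mother,
                "age": age,
                "x": res[f, 0],
                "y": res[f, 1],
                "urine_hg": 10.0**lu * crea,  # µg/L so that adjustment recovers 10^lu
                "creatinine": crea,
                "hair_hg": 10.0**lh,
                "amalgam_count": int(amalgam),
                "seafish_portions_30d": int(seafish),
                "seafish_last3d": bool(last3d[f]),
                "smoking": smoking,
                "birth_country_near_sea": bool(near_sea[f]),
                "eats_vegetables_region": bool(veg[f]),
                "hair_dyeing_6m": dyeing,
                "parcel_id": _parcel_ids(cfg, res[f:f + 1])[0],
            })
            truth_rows.append({"id": f"S{pid:04d}", "family_id": f"F{f:03d}",
                               "true_log10_soil": true_expo_fam[f],
                               "log10_urine": lu, "log10_hair": lh})
    participants = pd.DataFrame(rows)
    truth = {
        "participants": pd.DataFrame(truth_rows),
        "urine_coefs": dict(cfg.urine_coefs),
        "hair_coefs": dict(cfg.hair_coefs),
        "variogram": dataclasses.asdict(cfg.variogram),
        "drift_beta": list(cfg.drift_beta),
        "seed": cfg.seed,
    }
    return participants, truth


def make_fixture_suite(out_dir, small_seed: int = 101, full_seed: int = 202,
                       sets: tuple[str, ...] = ("small", "full")) -> dict:
    """Write a small and a full-scale fixture set (CSV/GeoJSON) plus a
    manifest of seeds and true parameters. Regeneration with the same seeds
    is byte-identical."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"sets": {}}
    configs = {
        "small": scaled_study_config(200, seed=small_seed, n_families=20,
                                     n_children_total=33),
        "full": SimulationConfig(seed=full_seed),
    }
    configs = {k: v for k, v in configs.items() if k in sets}
    for name, cfg in configs.items():
        d = out / name
        d.mkdir(exist_ok=True)
        soil, fieldm = simulate_soil_field(cfg, return_field=True)
        participants, truth = simulate_participants(cfg, fieldm)
        soil.to_csv(d / "soil.csv", index=False)
        participants.to_csv(d / "participants.csv", index=False)
        (d / "canal.geojson").write_text(json.dumps({
            "type": "Feature", "properties": {"name": "canal"},
            "geometry": {"type": "LineString",
                         "coordinates": [list(v) for v in cfg.canal_vertices]},
        }))
        truth["participants"].to_csv(d / "truth_participants.csv", index=False)
        manifest["sets"][name] = {
            "seed": cfg.seed,
            "n_soil": cfg.n_soil,
            "n_families": cfg.n_families,
            "bbox": list(cfg.bbox),
            "variogram": dataclasses.asdict(cfg.variogram),
            "drift_beta": list(cfg.drift_beta),
            "urine_coefs": dict(cfg.urine_coefs),
            "hair_coefs": dict(cfg.hair_coefs),
            "covariate_distributions": {
                "amalgam": "Poisson(2) mothers, Poisson(0.2) children; sqrt-encoded",
                "seafish_portions_30d": "Poisson(3); sqrt-encoded",
                "last3d/near_sea/veg": "family-level Bernoulli(0.3/0.25/0.5)",
                "smoking": "mothers Bernoulli(0.25)",
                "hair_dyeing": "Bernoulli(0.3 mothers, 0.05 children)",
                "creatinine": "lognormal around 1 g/L, 3% outside [0.3, 3.0]",
            },
        }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
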