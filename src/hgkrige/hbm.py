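"""Preprocessing of soil and human-biomonitoring inputs.

Implements the study's data rules: topsoil-only filtering (0-20 cm), half-LOD
substitution for soil values below the 0.1 mg/kg limit of determination,
creatinine adjustment of urinary mercury with exclusion outside the WHO
validity range [0.3, 3.0] g/L, covariate encodings (square-root transformed
counts, binary indicators), and the construction of per-participant
regression records with measured or kriging-predicted soil exposure.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "EXCLUDED",
    "Participant",
    "creatinine_adjust",
    "substitute_lod",
    "filter_topsoil",
    "encode_covariates",
    "prepare_soil",
    "link_measured_exposure",
    "make_exposure_records",
]

#: WHO validity range for creatinine adjustment, g/L (closed interval).
CREATININE_RANGE = (0.3, 3.0)
#: Limit of determination for total soil mercury, mg/kg.
SOIL_LOD = 0.1
TOPSOIL_LAYER = "0-20cm"


class _Excluded:
    """Marker returned when a participant fails an inclusion rule."""

    def __repr__(self) -> str:  # pragma: no cover
        return "EXCLUDED"

    def __bool__(self) -> bool:
        return False


EXCLUDED = _Excluded()


@dataclasses.dataclass
class Participant:
    id: str
    family_id: str
    mother: bool
    age: float
    x: float
    y: float
    urine_hg: float  # µg/L
    creatinine: float  # g/L
    hair_hg: float  # µg/g
    amalgam_count: int = 0
    seafish_portions_30d: int = 0
    seafish_last3d: bool = False
    smoking: bool = False
    birth_country_near_sea: bool = False
    eats_vegetables_region: bool = False
    hair_dyeing_6m: bool = False
    parcel_id: str | None = None  # opaque label linking the residence to soil samples

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.amalgam_count < 0 or self.seafish_portions_30d < 0:
            raise ValueError("counts must be non-negative")


def creatinine_adjust(urine_ug_per_l: float, creatinine_g_per_l: float):
    """Creatinine-adjusted urinary mercury (µg/g creatinine), or EXCLUDED.

    Samples with creatinine outside the WHO range [0.3, 3.0] g/L are excluded
    from analysis (boundaries inclusive).
    """
    if urine_ug_per_l < 0 or creatinine_g_per_l < 0:
        raise ValueError("concentrations must be non-negative")
    lo, hi = CREATININE_RANGE
    if not lo <= creatinine_g_per_l <= hi:
        return EXCLUDED
    return urine_ug_per_l / creatinine_g_per_l


def substitute_lod(hg_mgkg: float, lod: float = SOIL_LOD) -> tuple[float, bool]:
    """Half-LOD substitution: values below the limit of determination are set
    to lod/2 and flagged. Idempotent (lod/2 stays lod/2)."""
    if hg_mgkg < 0:
        raise ValueError("concentration must be non-negative")
    if hg_mgkg < lod:
        return lod / 2.0, True
    return hg_mgkg, False


def filter_topsoil(soil: pd.DataFrame) -> pd.DataFrame:
    """Keep only the 0-20 cm layer (the layer humans are in contact with)."""
    out = soil[soil["depth_layer"] == TOPSOIL_LAYER].reset_index(drop=True)
    logger.info("topsoil filter retained %d of %d samples", len(out), len(soil))
    if out.empty:
        logger.warning("topsoil filter produced an empty sample set")
    return out


def prepare_soil(soil: pd.DataFrame, lod: float = SOIL_LOD) -> pd.DataFrame:
    """Topsoil filter, half-LOD substitution and log10 transform.

    Adds columns ``hg_sub`` (mg/kg after substitution), ``below_lod`` and
    ``log10_hg``.
    """
    out = filter_topsoil(soil).copy()
    sub = out["hg_mgkg"].map(lambda v: substitute_lod(float(v), lod))
    out["hg_sub"] = [s[0] for s in sub]
    out["below_lod"] = [s[1] for s in sub]
    out["log10_hg"] = np.log10(out["hg_sub"])
    return out


# covariate sets per outcome; det-limit indicator and the age x mother
# interaction are handled by flags in encode_covariates
_URINE_SET = ("age", "mother", "amalgam_sqrt", "seafish_sqrt", "seafish_last3d",
              "smoking", "near_sea_birth", "veg_region")
_HAIR_SET = ("age", "mother", "amalgam_sqrt", "seafish_sqrt",
             "smoking", "near_sea_birth", "veg_region", "hair_dyeing")


def encode_covariates(
    p: Participant,
    outcome_kind: str,
    include_det_limit: bool = True,
    include_interaction: bool = False,
) -> dict[str, float]:
    """Deterministic covariate encoding for one participant.

    Counts are square-root transformed; binaries become 0/1; the urine set
    includes the last-3-days sea-fish indicator, the hair set swaps it for
    hair dyeing. The below-determination-limit indicator is appended only for
    measured-exposure models (``include_det_limit``); its value is attached
    later from the linked soil sample.
    """
    if outcome_kind not in ("urine", "hair"):
        raise ValueError("outcome_kind must be 'urine' or 'hair'")
    if p.amalgam_count < 0 or p.seafish_portions_30d < 0:
        raise ValueError("counts must be non-negative")
    full = {
        "age": float(p.age),
        "mother": float(p.mother),
        "amalgam_sqrt": float(np.sqrt(p.amalgam_count)),
        "seafish_sqrt": float(np.sqrt(p.seafish_portions_30d)),
        "seafish_last3d": float(p.seafish_last3d),
        "smoking": float(p.smoking),
        "near_sea_birth": float(p.birth_country_near_sea),
        "veg_region": float(p.eats_vegetables_region),
        "hair_dyeing": float(p.hair_dyeing_6m),
    }
    keys = _URINE_SET if outcome_kind == "urine" else _HAIR_SET
    enc = {k: full[k] for k in keys}
    if include_interaction:
        enc["age_x_mother"] = full["age"] * full["mother"]
    if include_det_limit:
        enc["det_limit"] = 0.0  # filled in during exposure linkage
    return enc


def _participants(obj) -> list[Participant]:
    if isinstance(obj, pd.DataFrame):
        fields = {f.name for f in dataclasses.fields(Participant)}
        return [Participant(**{k: v for k, v in rec.items() if k in fields})
                for rec in obj.to_dict("records")]
    return list(obj)


def link_measured_exposure(participants, soil: pd.DataFrame) -> pd.DataFrame:
    """Measured-exposure linkage: nearest prepared topsoil sample on the
    participant's parcel.

    Participants whose parcel has no sample get NaN exposure (they can still
    receive a kriging-predicted exposure); the miss is logged. Returns one
    row per participant: exposure (log10 mg/kg), below-LOD flag, distance to
    the linked sample.
    """
    plist = _participants(participants)
    rows = []
    by_parcel = dict(tuple(soil.groupby("parcel_id"))) if "parcel_id" in soil else {}
    tree = cKDTree(soil[["x", "y"]].to_numpy(dtype=float))
    for p in plist:
        parcel = p.parcel_id
        if parcel is None or (isinstance(parcel, float) and np.isnan(parcel)):
            # no parcel on record: use the parcel of the overall-nearest sample
            _, j = tree.query([p.x, p.y])
            parcel = soil["parcel_id"].iloc[int(j)]
        sub = by_parcel.get(parcel)
        if sub is None or sub.empty:
            logger.warning("participant %s: no soil sample on parcel; measured exposure missing", p.id)
            rows.append({"participant_id": p.id, "exposure": np.nan,
                         "below_lod": np.nan, "link_distance": np.nan})
            continue
        d = np.hypot(sub["x"].to_numpy() - p.x, sub["y"].to_numpy() - p.y)
        i = int(np.argmin(d))
        rows.append({"participant_id": p.id,
                     "exposure": float(sub["log10_hg"].iloc[i]),
                     "below_lod": bool(sub["below_lod"].iloc[i]),
                     "link_distance": float(d[i])})
    return pd.DataFrame(rows)


def make_exposure_records(
    participants,
    outcome_kind: str,
    exposure: pd.Series | np.ndarray,
    exposure_se: pd.Series | np.ndarray | None = None,
    below_lod: pd.Series | np.ndarray | None = None,
    include_det_limit: bool = True,
    include_interaction: bool = False,
) -> pd.DataFrame:
    """Assemble the regression table for one (outcome, exposure-kind) model.

    One row per retained participant: log10 outcome, encoded covariates,
    exposure (log10 soil mercury) and its standard error (0 for measured
    exposure). Exclusions (creatinine out of range, missing exposure or
    outcome) are logged with their rule names.
    """
    plist = _participants(participants)
    exposure = np.asarray(exposure, dtype=float)
    se = np.zeros(len(plist)) if exposure_se is None else np.asarray(exposure_se, dtype=float)
    if np.any(se < 0):
        raise ValueError("exposure_se must be non-negative")
    bl = np.zeros(len(plist)) if below_lod is None else np.asarray(below_lod, dtype=float)
    rows, exclusions = [], []
    for i, p in enumerate(plist):
        if outcome_kind == "urine":
            adj = creatinine_adjust(p.urine_hg, p.creatinine)
            if adj is EXCLUDED:
                exclusions.append((p.id, "creatinine_out_of_range"))
                continue
            raw = adj
        else:
            raw = p.hair_hg
        if not np.isfinite(raw) or raw <= 0:
            exclusions.append((p.id, f"missing_{outcome_kind}_outcome"))
            continue
        if not np.isfinite(exposure[i]):
            exclusions.append((p.id, "missing_exposure"))
            continue
        enc = encode_covariates(p, outcome_kind, include_det_limit, include_interaction)
        if include_det_limit:
            enc["det_limit"] = float(bl[i]) if np.isfinite(bl[i]) else 0.0
        if not all(np.isfinite(v) for v in enc.values()):
            exclusions.append((p.id, "missing_covariate"))
            continue
        rows.append({"participant_id": p.id, "family_id": p.family_id,
                     "outcome": float(np.log10(raw)),
                     "exposure": float(exposure[i]), "exposure_se": float(se[i]),
                     **enc})
    for pid, rule in exclusions:
        logger.info("excluded participant %s: %s", pid, rule)
    df = pd.DataFrame(rows)
    df.attrs["exclusions"] = exclusions
    df.attrs["outcome_kind"] = outcome_kind
    return df
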