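"""Occurrence-record cleaning cascade.

Raw aggregated occurrence data are error prone; before any range metric
is computed the records pass through an ordered series of automated
filters: basis-of-record, coordinate uncertainty, exact duplicates,
suspicious coordinates (the 0/0 point, latitude equal to longitude, sea
points, gazetteer hits near capitals / country centroids / biodiversity
institutions) and per-species spatial outliers. Every step's removal
count is recorded in a :class:`QcReport` whose bookkeeping reconciles
exactly: ``input - sum(removals) = output``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km, pairwise_min_neighbor_km
from .layers import ReferenceLayers

LON = "decimalLongitude"
LAT = "decimalLatitude"
UNC = "coordinateUncertaintyInMeters"
BASIS = "basisOfRecord"

DEFAULT_ALLOWED_BASES = frozenset({"HUMAN_OBSERVATION", "PRESERVED_SPECIMEN", "LITERATURE"})
KNOWN_BASES = DEFAULT_ALLOWED_BASES | {"FOSSIL_SPECIMEN", "LIVING_SPECIMEN", "UNKNOWN"}

DEFAULT_STEPS = ("basis", "uncertainty", "duplicates", "coordinate_issues", "spatial_outliers")

COORDINATE_ISSUE_REASONS = ("zero_zero", "lat_eq_lon", "sea", "gazetteer")


@dataclass(frozen=True)
class QcConfig:
    allowed_bases: frozenset = DEFAULT_ALLOWED_BASES
    max_uncertainty_m: float = 100_000.0  # strict "< 100 km" rule
    drop_missing_uncertainty: bool = False  # strict mode; default keeps missing
    duplicate_precision: int = 6  # decimal places on the duplicate key
    zero_eps_deg: float = 1e-5  # half-width of the 0/0 exclusion box
    outlier_multiplier: float = 5.0
    min_records_outlier: int = 7
    steps_enabled: tuple = DEFAULT_STEPS
    gazetteer_radius_overrides: dict = field(default_factory=dict)  # type -> km

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "allowed_bases": sorted(self.allowed_bases),
                "max_uncertainty_m": self.max_uncertainty_m,
                "drop_missing_uncertainty": self.drop_missing_uncertainty,
                "duplicate_precision": self.duplicate_precision,
                "zero_eps_deg": self.zero_eps_deg,
                "outlier_multiplier": self.outlier_multiplier,
                "min_records_outlier": self.min_records_outlier,
                "steps_enabled": list(self.steps_enabled),
                "gazetteer_radius_overrides": dict(sorted(self.gazetteer_radius_overrides.items())),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class QcReport:
    input_count: int
    output_count: int
    removals: dict  # step name -> count removed
    details: dict  # auxiliary counts (unknown bases, issue reasons, ...)
    per_species_surviving: dict
    config_hash: str

    def reconciles(self) -> bool:
        return self.input_count - sum(self.removals.values()) == self.output_count

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "output_count": self.output_count,
                "removals": self.removals,
                "details": self.details,
                "per_species_surviving": self.per_species_surviving,
                "config_hash": self.config_hash,
            },
            indent=2,
        )


def validate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Coerce coordinates to numeric and drop malformed rows (missing or
    out-of-range lon/lat). Returns (valid records, n_malformed)."""
    rec = records.copy()
    rec[LON] = pd.to_numeric(rec[LON], errors="coerce")
    rec[LAT] = pd.to_numeric(rec[LAT], errors="coerce")
    ok = (
        rec[LON].notna()
        & rec[LAT].notna()
        & rec[LON].between(-180.0, 180.0)
        & rec[LAT].between(-90.0, 90.0)
    )
    return rec[ok], int((~ok).sum())


def filter_basis(records: pd.DataFrame, allowed_bases=DEFAULT_ALLOWED_BASES) -> pd.DataFrame:
    """Keep records whose basis-of-record is in the allowed set (by default
    human observations, preserved specimens and literature records). Unknown
    basis strings are treated as not allowed."""
    return records[records[BASIS].isin(allowed_bases)]


def filter_uncertainty(
    records: pd.DataFrame, max_uncertainty_m: float = 100_000.0, drop_missing: bool = False
) -> pd.DataFrame:
    """Keep records with coordinate uncertainty strictly below the cap.

    Missing uncertainty is kept by default (aggregator records commonly
    omit the field); negative values are rejected as malformed.
    """
    unc = pd.to_numeric(records[UNC], errors="coerce")
    keep = (unc >= 0) & (unc < max_uncertainty_m)
    if not drop_missing:
        keep = keep | unc.isna()
    return records[keep]


def remove_duplicates(records: pd.DataFrame, precision: int = 6) -> pd.DataFrame:
    """Keep the first record per (species, lon, lat) key with coordinates
    rounded to ``precision`` decimals (default 6, i.e. ~0.1 m)."""
    key = pd.DataFrame(
        {
            "species": records["species"],
            "lon": records[LON].round(precision),
            "lat": records[LAT].round(precision),
        }
    )
    return records[~key.duplicated(keep="first")]


def flag_coordinate_issues(
    records: pd.DataFrame, layers: ReferenceLayers | None, config: QcConfig = QcConfig()
) -> pd.Series:
    """Flag suspicious coordinates. Returns a Series aligned with
    ``records`` holding the first matching reason ('zero_zero',
    'lat_eq_lon', 'sea', 'gazetteer') or '' for clean records.

    Without reference layers only the mask-free tests (0/0, lat == lon)
    run.
    """
    lon = records[LON].to_numpy(dtype=float)
    lat = records[LAT].to_numpy(dtype=float)
    reason = np.full(lon.shape, "", dtype=object)

    eps = config.zero_eps_deg
    zz = (np.abs(lon) <= eps) & (np.abs(lat) <= eps)
    reason[zz] = "zero_zero"

    p = config.duplicate_precision
    eq = (np.round(lon, p) == np.round(lat, p)) & (reason == "")
    reason[eq] = "lat_eq_lon"

    if layers is not None:
        sea = ~layers.is_land(lon, lat)
        sea &= reason == ""
        reason[sea] = "sea"

        gaz = layers.gazetteer
        if len(gaz):
            radii = gaz["radius_km"].to_numpy(dtype=float).copy()
            for t, r in config.gazetteer_radius_overrides.items():
                radii[(gaz["type"] == t).to_numpy()] = r
            d = haversine_km(lon[:, None], lat[:, None], gaz["lon"].to_numpy()[None, :], gaz["lat"].to_numpy()[None, :])
            hit = (d <= radii[None, :]).any(axis=1) & (reason == "")
            reason[hit] = "gazetteer"

    return pd.Series(reason, index=records.index)


def flag_spatial_outliers(
    records: pd.DataFrame, outlier_multiplier: float = 5.0, min_records: int = 7
) -> pd.Series:
    """Flag spatial outliers within one species' records.

    Each point's minimum great-circle distance to any other conspecific
    point is computed; points whose minimum-neighbor distance exceeds
    Q3 + multiplier * IQR of those distances are flagged. Species with
    fewer than ``min_records`` points are left untouched. Single pass,
    no iteration to a fixpoint.
    """
    flags = pd.Series(False, index=records.index)
    for _, grp in records.groupby("species", sort=False):
        if len(grp) < min_records:
            continue
        dmin = pairwise_min_neighbor_km(grp[LON].to_numpy(dtype=float), grp[LAT].to_numpy(dtype=float))
        q1, q3 = np.percentile(dmin, [25.0, 75.0])
        thr = q3 + outlier_multiplier * (q3 - q1)
        flags.loc[grp.index[dmin > thr]] = True
    return flags


def clean(
    records: pd.DataFrame, layers: ReferenceLayers | None = None, config: QcConfig = QcConfig()
) -> tuple[pd.DataFrame, QcReport]:
    """Run the full cleaning cascade and return (cleaned records, report)."""
    input_count = len(records)
    removals: dict[str, int] = {}
    details: dict = {}

    rec, n_malformed = validate_records(records)
    removals["malformed"] = n_malformed

    for step in config.steps_enabled:
        before = len(rec)
        if step == "basis":
            details["unknown_basis"] = int((~rec[BASIS].isin(KNOWN_BASES)).sum())
            rec = filter_basis(rec, config.allowed_bases)
        elif step == "uncertainty":
            unc = pd.to_numeric(rec[UNC], errors="coerce")
            details["missing_uncertainty_kept"] = 0 if config.drop_missing_uncertainty else int(unc.isna().sum())
            details["negative_uncertainty"] = int((unc < 0).sum())
            rec = filter_uncertainty(rec, config.max_uncertainty_m, config.drop_missing_uncertainty)
        elif step == "duplicates":
            rec = remove_duplicates(rec, config.duplicate_precision)
        elif step == "coordinate_issues":
            reasons = flag_coordinate_issues(rec, layers, config)
            details["coordinate_issue_reasons"] = {
                r: int((reasons == r).sum()) for r in COORDINATE_ISSUE_REASONS
            }
            if layers is None:
                details["coordinate_issue_warning"] = "no reference layers: sea and gazetteer tests skipped"
            rec = rec[reasons == ""]
        elif step == "spatial_outliers":
            flags = flag_spatial_outliers(rec, config.outlier_multiplier, config.min_records_outlier)
            rec = rec[~flags]
        else:
            raise ValueError(f"unknown cleaning step {step!r}")
        removals[step] = before - len(rec)

    report = QcReport(
        input_count=input_count,
        output_count=len(rec),
        removals=removals,
        details=details,
        per_species_surviving={k: int(v) for k, v in rec["species"].value_counts().items()},
        config_hash=config.config_hash(),
    )
    assert report.reconciles()
    return rec, report
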