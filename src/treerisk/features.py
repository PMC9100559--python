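"""Per-species predictors from cleaned occurrences and reference layers.

For every species the feature set combines geographic range metrics —
occurrence count, extent of occurrence (EOO, convex-hull area), area of
occupancy (AOO, occupied 2x2 km grid cells), latitudinal range — with
biome presence bits, climate-layer summaries (mean and SD at occurrence
locations) and the distribution of human-footprint exposure over four
pressure categories. Species for which any feature is undefined (e.g.
a degenerate convex hull from fewer than three unique points) are
dropped, with the reason reported, unless the EOO->AOO fallback is
turned on.

Areas are computed in a per-species cylindrical equal-area projection
whose standard parallel sits at the mean latitude of the points, so
planar areas equal spherical areas exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from .geo import EqualAreaProjection
from .grids import Grid
from .layers import ReferenceLayers
from .qc import LAT, LON

DEFAULT_FOOTPRINT_EDGES = (0.0, 1.0, 10.0, 20.0, np.inf)


@dataclass(frozen=True)
class FeatureConfig:
    aoo_cell_km: float = 2.0  # IUCN standard 2 x 2 km cell
    footprint_bin_edges: tuple = DEFAULT_FOOTPRINT_EDGES
    eoo_fallback_aoo: bool = False  # if True, degenerate hull -> EOO := AOO


@dataclass
class FeatureMatrix:
    species: list[str]
    columns: list[str]
    raw: np.ndarray  # (n_species, n_features)
    normalized: np.ndarray | None = None
    norm_params: dict | None = None

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        mat = self.normalized if normalized else self.raw
        return pd.DataFrame(mat, index=self.species, columns=self.columns)


def compute_eoo(lons, lats) -> float:
    """Extent of occurrence: convex-hull area in km², equal-area projected.

    Returns NaN for fewer than 3 unique points or a collinear point set
    (a degenerate hull has no meaningful area).
    """
    pts = np.unique(np.column_stack([np.asarray(lons, float), np.asarray(lats, float)]), axis=0)
    if pts.shape[0] < 3:
        return float("nan")
    proj = EqualAreaProjection.for_points(pts[:, 0], pts[:, 1])
    x, y = proj.forward(pts[:, 0], pts[:, 1])
    hull = MultiPoint(np.column_stack([x, y])).convex_hull
    area = float(hull.area)
    return area if area > 0.0 else float("nan")


def compute_aoo(lons, lats, cell_km: float = 2.0) -> float:
    """Area of occupancy: occupied cells of a fixed-origin equal-area grid
    times the cell area. The grid origin is the projection origin, so AOO
    is deterministic for a given point set."""
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("AOO needs at least one point")
    proj = EqualAreaProjection.for_points(lons, lats)
    x, y = proj.forward(lons, lats)
    # grid cells are centered on the projection origin (the points' centroid),
    # so a tight cluster occupies a single cell rather than straddling corners
    half = cell_km / 2.0
    cells = {
        (int(np.floor((xi + half) / cell_km)), int(np.floor((yi + half) / cell_km))) for xi, yi in zip(x, y)
    }
    return len(cells) * cell_km**2


def compute_lat_range(lats) -> float:
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lats.size == 0:
        raise ValueError("latitudinal range needs at least one point")
    return float(lats.max() - lats.min())


def biome_presence(lons, lats, biome_polygons) -> tuple[np.ndarray, int]:
    """Binary presence per biome. A point on a shared boundary counts for
    the lowest biome id only. Returns (presence vector, n unassigned)."""
    pts = shapely.points(np.asarray(lons, float), np.asarray(lats, float))
    presence = np.zeros(len(biome_polygons), dtype=int)
    assigned = np.zeros(len(pts), dtype=bool)
    for b, poly in enumerate(biome_polygons):
        inside = shapely.covers(poly, pts) & ~assigned
        if inside.any():
            presence[b] = 1
            assigned |= inside
    return presence, int((~assigned).sum())


def climate_summary(lons, lats, grid: Grid) -> tuple[float, float, int]:
    """Mean and population SD of nearest-cell raster values at the points;
    missing cells are skipped and counted. (NaN, NaN, n) if nothing sampled."""
    vals = grid.sample(lons, lats)
    missing = int(np.isnan(vals).sum())
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), missing
    return float(vals.mean()), float(vals.std()), missing


def footprint_features(lons, lats, grid: Grid, bin_edges=DEFAULT_FOOTPRINT_EDGES) -> np.ndarray:
    """Fraction of sampled points per half-open footprint bin [e_k, e_{k+1});
    fractions sum to 1 over the sampled points. NaN vector if nothing sampled."""
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    vals = grid.sample(lons, lats)
    vals = vals[~np.isnan(vals)]
    k = edges.size - 1
    if vals.size == 0:
        return np.full(k, np.nan)
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, k - 1)
    counts = np.bincount(idx, minlength=k)
    return counts / vals.size


def assemble_features(
    cleaned: pd.DataFrame, layers: ReferenceLayers, config: FeatureConfig = FeatureConfig()
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """One feature vector per species from cleaned occurrences.

    Species with any undefined feature are dropped and listed with a
    reason (``eoo_undefined``, ``climate_undefined``, ...), unless the
    EOO fallback substitutes the AOO for a degenerate hull.
    """
    n_biomes = len(layers.biomes)
    climate_names = sorted(layers.climate)
    k_fp = len(config.footprint_bin_edges) - 1
    columns = (
        ["occ_count", "eoo_km2", "aoo_km2", "lat_range_deg"]
        + [f"biome_{b:02d}" for b in range(n_biomes)]
        + [f"climate_{n}_{s}" for n in climate_names for s in ("mean", "sd")]
        + [f"footprint_bin_{i}" for i in range(k_fp)]
    )

    species_ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    for sp, grp in cleaned.groupby("species", sort=True):
        lons = grp[LON].to_numpy(dtype=float)
        lats = grp[LAT].to_numpy(dtype=float)
        aoo = compute_aoo(lons, lats, config.aoo_cell_km)
        eoo = compute_eoo(lons, lats)
        if np.isnan(eoo):
            if config.eoo_fallback_aoo:
                eoo = aoo
            else:
                dropped.append((sp, "eoo_undefined"))
                continue
        presence, _ = biome_presence(lons, lats, layers.biomes)
        clim: list[float] = []
        bad_climate = False
        for name in climate_names:
            m, s, _ = climate_summary(lons, lats, layers.climate[name])
            if np.isnan(m):
                bad_climate = True
            clim.extend([m, s])
        if bad_climate:
            dropped.append((sp, "climate_undefined"))
            continue
        fp = footprint_features(lons, lats, layers.footprint, config.footprint_bin_edges)
        if np.isnan(fp).any():
            dropped.append((sp, "footprint_undefined"))
            continue
        row = np.concatenate([[len(grp), eoo, aoo, compute_lat_range(lats)], presence, clim, fp])
        species_ids.append(sp)
        rows.append(row)

    if not species_ids:
        raise ValueError("no species with a complete feature set")
    return FeatureMatrix(species=species_ids, columns=columns, raw=np.vstack(rows)), dropped


LOG_COLUMNS = ("occ_count", "eoo_km2", "aoo_km2")


def fit_normalization(raw: np.ndarray, columns: list[str]) -> dict:
    """Per-column transform parameters: log10(x+1) for count/area columns,
    z-scoring for continuous columns, pass-through for binary columns.
    Statistics must come from training rows only — pass those rows here."""
    params: dict = {"columns": list(columns), "per_column": []}
    for j, name in enumerate(columns):
        col = raw[:, j].astype(float)
        use_log = name in LOG_COLUMNS
        if use_log:
            col = np.log10(col + 1.0)
        binary = bool(np.all(np.isin(col, (0.0, 1.0))))
        if binary:
            params["per_column"].append({"name": name, "binary": True, "log10p1": False})
            continue
        mean = float(col.mean())
        sd = float(col.std())
        if sd == 0.0:
            sd = 1.0  # zero-variance column: centered to 0, scale left alone
        params["per_column"].append(
            {"name": name, "binary": False, "log10p1": use_log, "mean": mean, "sd": sd}
        )
    return params


def apply_normalization(raw: np.ndarray, params: dict) -> np.ndarray:
    out = raw.astype(float).copy()
    for j, p in enumerate(params["per_column"]):
        if p["binary"]:
            continue
        col = out[:, j]
        if p["log10p1"]:
            col = np.log10(col + 1.0)
        out[:, j] = (col - p["mean"]) / p["sd"]
    return out


def invert_normalization(norm: np.ndarray, params: dict) -> np.ndarray:
    out = norm.astype(float).copy()
    for j, p in enumerate(params["per_column"]):
        if p["binary"]:
            continue
        col = out[:, j] * p["sd"] + p["mean"]
        if p["log10p1"]:
            col = 10.0**col - 1.0
        out[:, j] = col
    return out


def normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Fit the normalization on the matrix's own rows and attach the
    normalized matrix and parameters."""
    params = fit_normalization(matrix.raw, matrix.columns)
    matrix.norm_params = params
    matrix.normalized = apply_normalization(matrix.raw, params)
    return matrix
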