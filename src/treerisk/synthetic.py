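"""Synthetic biodiversity worlds and occurrence datasets.

Real assessments draw on GBIF occurrence downloads, WWF biome polygons,
human-footprint and climate rasters, and IUCN Red List labels. This
module fabricates all of those with a known ground truth so the whole
pipeline — cleaning, feature extraction, model training, uncertainty
calibration, reporting — can be exercised and validated end to end
without any external download.

The key property is that a species' latent threat class drives its
spatial structure: more threatened species have (stochastically) smaller
range radii and fewer occurrence records, mirroring the fact that Red
List criteria are tied to range size and population size. Occurrence
tables are contaminated with the error classes that occurrence cleaning
is meant to remove (points at 0/0, lat == lon, sea points, gazetteer
hits, inflated coordinate uncertainty, exact duplicates, spatial
outliers, disallowed basis-of-record), at configurable rates, with the
per-record truth kept in a sidecar table that the pipeline never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo import local_tangent_offset, haversine_km
from .grids import Grid
from .layers import ReferenceLayers

CLASSES = ("LC", "NT", "VU", "EN", "CR")

#: Default 5-class mix, matching the composition of tree species on the
#: Red List (53.6% LC, 6.4% NT, 15.9% VU, 15.9% EN, 8.2% CR).
DEFAULT_CLASS_MIX = (0.536, 0.064, 0.159, 0.159, 0.082)

#: Median range radius (km) per class, log-normal with shared dispersion.
CLASS_RADIUS_MEDIAN_KM = {"LC": 500.0, "NT": 200.0, "VU": 80.0, "EN": 30.0, "CR": 10.0}
RADIUS_LOG_SIGMA = 0.5  # natural-log scale

#: Median occurrence-record count per class (rarer species are recorded less).
CLASS_RECORDS_MEDIAN = {"LC": 120.0, "NT": 80.0, "VU": 50.0, "EN": 30.0, "CR": 15.0}
RECORDS_LOG_SIGMA = 0.6

CLEAN_BASES = ("HUMAN_OBSERVATION", "PRESERVED_SPECIMEN", "LITERATURE")
CLEAN_BASIS_PROBS = (0.7, 0.2, 0.1)
BAD_BASES = ("FOSSIL_SPECIMEN", "LIVING_SPECIMEN", "UNKNOWN")

ERROR_TYPES = (
    "zero_zero",
    "lat_eq_lon",
    "sea_point",
    "gazetteer_hit",
    "high_uncertainty",
    "duplicate",
    "spatial_outlier",
    "bad_basis",
)

GAZETTEER_RADII_KM = {"capital": 10.0, "centroid": 1.0, "institution": 0.1}


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a toy world (reference layers)."""

    extent: tuple[float, float, float, float] = (-60.0, -56.0, 60.0, 60.0)  # lon_min, lat_min, lon_max, lat_max
    n_biomes: int = 14
    n_countries: int = 12
    raster_resolution_deg: float = 1.0
    footprint_gradient: dict = field(
        default_factory=lambda: {"base": 0.5, "amplitude": 30.0, "n_bumps": 6, "bump_sd_deg": 12.0}
    )
    climate_lapse: float = 0.45  # degrees C lost per degree of |latitude|
    land_fraction: float = 0.7
    n_gazetteer: int = 9
    seed: int = 0

    def validate(self) -> None:
        lon0, lat0, lon1, lat1 = self.extent
        if not (-180.0 <= lon0 < lon1 <= 180.0 and -90.0 <= lat0 < lat1 <= 90.0):
            raise InvalidConfigError(f"degenerate or out-of-range extent {self.extent}")
        if self.n_biomes < 1 or self.n_countries < 1:
            raise InvalidConfigError("need at least one biome and one country")
        res = self.raster_resolution_deg
        if res <= 0:
            raise InvalidConfigError("raster resolution must be positive")
        for span in (lon1 - lon0, lat1 - lat0):
            if abs(span / res - round(span / res)) > 1e-9:
                raise InvalidConfigError("raster cells must tile the extent exactly")
        if not 0.0 < self.land_fraction <= 1.0:
            raise InvalidConfigError("land_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SpeciesTruth:
    """Latent ground truth for one synthetic species."""

    species_id: str
    true_class: str  # LC | NT | VU | EN | CR
    range_center: tuple[float, float]  # lon, lat
    range_radius_km: float
    n_records: int
    footprint_affinity: float  # in [0, 1]


@dataclass(frozen=True)
class ContaminationConfig:
    """Per-record probabilities of each injected error class."""

    zero_zero: float = 0.01
    lat_eq_lon: float = 0.01
    sea_point: float = 0.02
    gazetteer_hit: float = 0.01
    high_uncertainty: float = 0.03
    duplicate: float = 0.05
    spatial_outlier: float = 0.02
    bad_basis: float = 0.05
    seed: int = 0

    def rates(self) -> dict[str, float]:
        return {t: float(getattr(self, t)) for t in ERROR_TYPES}

    def validate(self) -> None:
        rates = self.rates()
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise InvalidConfigError(f"contamination rate {name}={r} outside [0, 1]")
        if sum(rates.values()) > 1.0 + 1e-12:
            raise InvalidConfigError("contamination rates sum to more than 1")

    @classmethod
    def none(cls, seed: int = 0) -> "ContaminationConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, seed=seed)


def _partition_strips(lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n random strip breakpoints over [lo, hi] with a minimum strip width."""
    if n == 1:
        return np.array([lo, hi])
    raw = rng.dirichlet(np.full(n, 3.0))
    widths = (0.25 / n + 0.75 * raw) / (0.25 + 0.75)  # re-normalized, min width 0.25/n
    edges = lo + np.concatenate([[0.0], np.cumsum(widths)]) * (hi - lo)
    edges[-1] = hi
    return edges


def _smooth_field(lon_c, lat_c, n_bumps, sd_deg, rng):
    """Sum of random Gaussian bumps over cell-center meshes (nrows, ncols)."""
    field_vals = np.zeros(lon_c.shape)
    for _ in range(n_bumps):
        cx = rng.uniform(lon_c.min(), lon_c.max())
        cy = rng.uniform(lat_c.min(), lat_c.max())
        amp = rng.uniform(0.4, 1.0)
        field_vals += amp * np.exp(-((lon_c - cx) ** 2 + (lat_c - cy) ** 2) / (2.0 * sd_deg**2))
    return field_vals


def generate_world(config: WorldConfig) -> ReferenceLayers:
    """Build reference layers: biome/country polygons partitioning the
    extent, footprint and climate rasters, a land/sea mask and a
    gazetteer of excluded locations. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lon0, lat0, lon1, lat1 = config.extent
    res = config.raster_resolution_deg
    ncols = round((lon1 - lon0) / res)
    nrows = round((lat1 - lat0) / res)

    # biomes: latitudinal bands; countries: longitudinal strips. Both are
    # exact partitions of the extent (toy geography, by design).
    biome_edges = _partition_strips(lat0, lat1, config.n_biomes, rng)
    biomes = [box(lon0, biome_edges[i], lon1, biome_edges[i + 1]) for i in range(config.n_biomes)]
    country_edges = _partition_strips(lon0, lon1, config.n_countries, rng)
    countries = [box(country_edges[i], lat0, country_edges[i + 1], lat1) for i in range(config.n_countries)]
    country_names = [f"country_{i:02d}" for i in range(config.n_countries)]

    # cell centers, row 0 = northernmost
    lon_centers = lon0 + (np.arange(ncols) + 0.5) * res
    lat_centers = lat1 - (np.arange(nrows) + 0.5) * res
    lon_c, lat_c = np.meshgrid(lon_centers, lat_centers)

    # land/sea mask from a thresholded smooth field
    if config.land_fraction >= 1.0:
        land = np.ones((nrows, ncols))
    else:
        terrain = _smooth_field(lon_c, lat_c, 8, 18.0, rng) + 0.15 * rng.standard_normal((nrows, ncols))
        thresh = np.quantile(terrain, 1.0 - config.land_fraction)
        land = (terrain >= thresh).astype(float)
        if land.sum() == 0:  # pragma: no cover - quantile guarantees land
            land[nrows // 2, ncols // 2] = 1.0
    land_mask = Grid(values=land, xll=lon0, yll=lat0, cellsize=res)

    fg = config.footprint_gradient
    fp = fg["base"] + fg["amplitude"] * _smooth_field(lon_c, lat_c, fg["n_bumps"], fg["bump_sd_deg"], rng)
    footprint = Grid(values=np.clip(fp, 0.0, None), xll=lon0, yll=lat0, cellsize=res)

    temp = 30.0 - config.climate_lapse * np.abs(lat_c) + 0.5 * rng.standard_normal((nrows, ncols))
    climate = {"temperature": Grid(values=temp, xll=lon0, yll=lat0, cellsize=res)}

    # gazetteer entries sit exactly on land cell centers
    land_rows, land_cols = np.nonzero(land > 0.5)
    n_gaz = min(config.n_gazetteer, land_rows.size)
    idx = rng.choice(land_rows.size, size=n_gaz, replace=False)
    types = [list(GAZETTEER_RADII_KM)[i % 3] for i in range(n_gaz)]
    gaz_lon, gaz_lat = land_mask.cell_center(land_rows[idx], land_cols[idx])
    gazetteer = pd.DataFrame(
        {
            "name": [f"{t}_{i}" for i, t in enumerate(types)],
            "lon": gaz_lon,
            "lat": gaz_lat,
            "radius_km": [GAZETTEER_RADII_KM[t] for t in types],
            "type": types,
        }
    )

    return ReferenceLayers(
        biomes=biomes,
        countries=countries,
        country_names=country_names,
        footprint=footprint,
        climate=climate,
        land_mask=land_mask,
        gazetteer=gazetteer,
        extent=config.extent,
    )


def _min_gazetteer_distance_ok(lon, lat, gazetteer: pd.DataFrame) -> bool:
    if len(gazetteer) == 0:
        return True
    d = haversine_km(lon, lat, gazetteer["lon"].to_numpy(), gazetteer["lat"].to_numpy())
    return bool(np.all(d > gazetteer["radius_km"].to_numpy() * 1.5))


def generate_species(
    n_species: int,
    class_mix=DEFAULT_CLASS_MIX,
    world: ReferenceLayers | None = None,
    seed: int = 0,
) -> list[SpeciesTruth]:
    """Draw species with class-dependent range structure.

    Classes are i.i.d. from ``class_mix``; range centers fall on land and
    away from gazetteer exclusion zones; radius and record count are
    log-normal with class-specific medians (decreasing with threat
    severity) and shared dispersion.
    """
    if world is None:
        world = generate_world(WorldConfig())
    class_mix = np.asarray(class_mix, dtype=float)
    if class_mix.shape != (5,) or abs(class_mix.sum() - 1.0) > 1e-9 or (class_mix < 0).any():
        raise InvalidConfigError("class_mix must be 5 non-negative probabilities summing to 1")
    rng = np.random.default_rng(seed)
    if n_species == 0:
        return []

    mask = world.land_mask
    land_rows, land_cols = np.nonzero(mask.values > 0.5)
    if land_rows.size == 0:
        raise InvalidConfigError("world has no land cells")

    classes = rng.choice(5, size=n_species, p=class_mix)
    out: list[SpeciesTruth] = []
    for i in range(n_species):
        cls = CLASSES[classes[i]]
        # rejection-sample a land center clear of gazetteer zones
        for _ in range(200):
            j = rng.integers(land_rows.size)
            clon, clat = mask.cell_center(land_rows[j], land_cols[j])
            clon = float(clon + rng.uniform(-0.4, 0.4) * mask.cellsize)
            clat = float(clat + rng.uniform(-0.4, 0.4) * mask.cellsize)
            if _min_gazetteer_distance_ok(clon, clat, world.gazetteer):
                break
        radius = float(np.exp(np.log(CLASS_RADIUS_MEDIAN_KM[cls]) + RADIUS_LOG_SIGMA * rng.standard_normal()))
        n_rec = int(max(2, round(np.exp(np.log(CLASS_RECORDS_MEDIAN[cls]) + RECORDS_LOG_SIGMA * rng.standard_normal()))))
        affinity = float(rng.beta(1.0 + 0.5 * classes[i], 2.0))
        out.append(
            SpeciesTruth(
                species_id=f"species_{i:05d}",
                true_class=cls,
                range_center=(clon, clat),
                range_radius_km=radius,
                n_records=n_rec,
                footprint_affinity=affinity,
            )
        )
    return out


def _clean_points(sp: SpeciesTruth, world: ReferenceLayers, rng, n: int) -> np.ndarray:
    """n occurrences inside the species range: isotropic Gaussian on the
    local tangent plane, truncated at the range radius, rejected off-land,
    off-extent and out of gazetteer exclusion zones. Returns (n, 2) lon/lat."""
    clon, clat = sp.range_center
    r = sp.range_radius_km
    lon0, lat0, lon1, lat1 = world.extent
    gaz = world.gazetteer
    glon = gaz["lon"].to_numpy() if len(gaz) else None
    out: list[np.ndarray] = []
    have = 0
    for _ in range(25):
        m = max(4 * (n - have), 16)
        dx = rng.standard_normal(m) * (r / 2.0)
        dy = rng.standard_normal(m) * (r / 2.0)
        ok = dx * dx + dy * dy <= r * r
        lon, lat = local_tangent_offset(clon, clat, dx[ok], dy[ok])
        keep = (lon >= lon0) & (lon <= lon1) & (lat >= lat0) & (lat <= lat1)
        # keep clean points off the degenerate coordinate sets the cleaner
        # targets (the 0/0 box and the lat == lon diagonal)
        keep &= ~((np.abs(lon) <= 1.1e-5) & (np.abs(lat) <= 1.1e-5))
        keep &= np.round(lon, 6) != np.round(lat, 6)
        lon, lat = lon[keep], lat[keep]
        if lon.size:
            land = world.is_land(lon, lat)
            lon, lat = lon[land], lat[land]
        if lon.size and glon is not None:
            d = haversine_km(lon[:, None], lat[:, None], glon[None, :], gaz["lat"].to_numpy()[None, :])
            clear = np.all(d > gaz["radius_km"].to_numpy()[None, :] * 1.5, axis=1)
            lon, lat = lon[clear], lat[clear]
        if lon.size:
            out.append(np.column_stack([lon, lat]))
            have += lon.size
        if have >= n:
            break
    if have < n:
        # pathological range (e.g. tiny island): pad near the on-land center
        # with a jitter small enough to stay in the center's land cell and
        # inside the range radius, large enough to keep records distinct
        k = n - have
        j = min(0.5 * r, 0.1)  # km
        px, py = rng.uniform(-j, j, k), rng.uniform(-j, j, k)
        plon, plat = local_tangent_offset(clon, clat, px, py)
        out.append(np.column_stack([plon, plat]))
    return np.concatenate(out)[:n]


def generate_occurrences(
    species: list[SpeciesTruth],
    world: ReferenceLayers,
    contamination: ContaminationConfig | None = None,
):
    """Generate a Darwin-Core-style occurrence table plus a hidden-truth sidecar.

    Returns ``(occurrences, sidecar, injected_counts)``. The occurrence
    table carries only the columns the pipeline is allowed to see
    (record_id, species, decimalLatitude, decimalLongitude,
    coordinateUncertaintyInMeters, basisOfRecord); the sidecar holds the
    per-record injected-error flag and true class, and ``injected_counts``
    is the generation log of realized error draws.
    """
    if not species:
        raise InvalidConfigError("species list is empty")
    if contamination is None:
        contamination = ContaminationConfig.none()
    contamination.validate()
    rng = np.random.default_rng(contamination.seed)
    rates = contamination.rates()
    p = np.array([rates[t] for t in ERROR_TYPES] + [1.0 - sum(rates.values())])
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    choices = list(ERROR_TYPES) + ["none"]

    mask = world.land_mask
    sea_rows, sea_cols = np.nonzero(mask.values < 0.5)
    gaz = world.gazetteer
    lon0, lat0, lon1, lat1 = world.extent

    rows = []
    counter = 0
    for sp in species:
        draws = rng.choice(len(choices), size=sp.n_records, p=p)
        base = _clean_points(sp, world, rng, sp.n_records)
        clean_pool: list[dict] = []  # this species' clean rows, duplicate sources
        used_keys = {(round(b[0], 6), round(b[1], 6)) for b in base}  # duplicate-precision keys
        for i, d in enumerate(draws):
            err = choices[d]
            lon, lat = float(base[i, 0]), float(base[i, 1])
            basis = str(rng.choice(CLEAN_BASES, p=CLEAN_BASIS_PROBS))
            if rng.random() < 0.3:
                unc = np.nan
            else:
                unc = float(np.exp(np.log(30.0) + 1.0 * rng.standard_normal()))

            if err == "zero_zero":
                # coordinates unique per species at the 6-decimal duplicate
                # precision, so the duplicate filter cannot intercept them
                while True:
                    lon = round(float(rng.uniform(-9e-6, 9e-6)), 6)
                    lat = round(float(rng.uniform(-9e-6, 9e-6)), 6)
                    if (lon, lat) not in used_keys:
                        break
            elif err == "lat_eq_lon":
                lo = max(lon0, lat0)
                hi = min(lon1, lat1)
                while True:
                    v = round(float(rng.uniform(lo + 0.01, hi - 0.01)), 6)
                    if (v, v) not in used_keys:
                        break
                lon = lat = v
            elif err == "sea_point":
                if sea_rows.size == 0:
                    err = "none"
                else:
                    j = rng.integers(sea_rows.size)
                    slon, slat = mask.cell_center(sea_rows[j], sea_cols[j])
                    lon = float(slon + rng.uniform(-0.3, 0.3) * mask.cellsize)
                    lat = float(slat + rng.uniform(-0.3, 0.3) * mask.cellsize)
            elif err == "gazetteer_hit":
                if len(gaz) == 0:
                    err = "none"
                else:
                    g = gaz.iloc[int(rng.integers(len(gaz)))]
                    rad = min(float(g["radius_km"]) * 0.5, 5.0)
                    theta = rng.uniform(0, 2 * np.pi)
                    rr = rad * np.sqrt(rng.random())
                    lon, lat = local_tangent_offset(float(g["lon"]), float(g["lat"]), rr * np.cos(theta), rr * np.sin(theta))
                    lon, lat = float(lon), float(lat)
            elif err == "high_uncertainty":
                unc = float(rng.uniform(150_000.0, 1_000_000.0))
            elif err == "bad_basis":
                basis = str(rng.choice(BAD_BASES))
            elif err == "duplicate":
                if clean_pool:
                    src = clean_pool[int(rng.integers(len(clean_pool)))]
                    lon, lat, unc, basis = src["decimalLongitude"], src["decimalLatitude"], src["coordinateUncertaintyInMeters"], src["basisOfRecord"]
                else:
                    err = "none"
            elif err == "spatial_outlier":
                placed = False
                for _ in range(100):
                    theta = rng.uniform(0, 2 * np.pi)
                    dist = rng.uniform(1500.0, 3000.0)
                    olon, olat = local_tangent_offset(sp.range_center[0], sp.range_center[1], dist * np.cos(theta), dist * np.sin(theta))
                    if not (lon0 <= olon <= lon1 and lat0 <= olat <= lat1):
                        continue
                    if not world.is_land(olon, olat):
                        continue
                    if not _min_gazetteer_distance_ok(float(olon), float(olat), gaz):
                        continue
                    lon, lat = float(olon), float(olat)
                    placed = True
                    break
                if not placed:
                    err = "none"

            row = {
                "record_id": f"r{counter:07d}",
                "species": sp.species_id,
                "decimalLatitude": lat,
                "decimalLongitude": lon,
                "coordinateUncertaintyInMeters": unc,
                "basisOfRecord": basis,
                "_error": err,
                "_true_class": sp.true_class,
            }
            counter += 1
            used_keys.add((round(lon, 6), round(lat, 6)))
            if err == "none":
                clean_pool.append(row)
            rows.append(row)

    df = pd.DataFrame(rows)
    sidecar = df[["record_id", "species", "_error", "_true_class"]].rename(
        columns={"_error": "error", "_true_class": "true_class"}
    )
    occurrences = df[
        ["record_id", "species", "decimalLatitude", "decimalLongitude", "coordinateUncertaintyInMeters", "basisOfRecord"]
    ].copy()
    injected_counts = sidecar["error"].value_counts().drop("none", errors="ignore").to_dict()
    for t in ERROR_TYPES:
        injected_counts.setdefault(t, 0)
    return occurrences, sidecar, injected_counts


def make_labels(
    species: list[SpeciesTruth],
    labeled_fraction: float = 0.6,
    dd_fraction: float = 0.04,
    seed: int = 0,
) -> pd.DataFrame:
    """Red-List-style label table: a random subset of species carries its
    true category, a smaller subset is Data Deficient, the rest are absent
    (not evaluated)."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        u = rng.random()
        if u < labeled_fraction:
            rows.append({"species": sp.species_id, "category": sp.true_class})
        elif u < labeled_fraction + dd_fraction:
            rows.append({"species": sp.species_id, "category": "DD"})
    return pd.DataFrame(rows, columns=["species", "category"])


def make_taxonomy(species: list[SpeciesTruth], n_families: int = 20, n_orders: int = 6, seed: int = 0) -> pd.DataFrame:
    """Random nested taxonomy (species -> genus -> family -> order)."""
    rng = np.random.default_rng(seed)
    n_genera = max(n_families * 3, 1)
    genus_family = rng.integers(n_families, size=n_genera)
    family_order = rng.integers(n_orders, size=n_families)
    rows = []
    for sp in species:
        g = int(rng.integers(n_genera))
        f = int(genus_family[g])
        rows.append(
            {
                "species": sp.species_id,
                "genus": f"genus_{g:03d}",
                "family": f"family_{f:02d}",
                "order": f"order_{family_order[f]}",
            }
        )
    return pd.DataFrame(rows, columns=["species", "genus", "family", "order"])


def truth_table(species: list[SpeciesTruth]) -> pd.DataFrame:
    """Species-level ground truth as a DataFrame (testing/sidecar use only)."""
    return pd.DataFrame(
        {
            "species": [s.species_id for s in species],
            "true_class": [s.true_class for s in species],
            "center_lon": [s.range_center[0] for s in species],
            "center_lat": [s.range_center[1] for s in species],
            "range_radius_km": [s.range_radius_km for s in species],
            "n_records": [s.n_records for s in species],
            "footprint_affinity": [s.footprint_affinity for s in species],
        }
    )
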