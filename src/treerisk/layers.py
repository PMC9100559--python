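"""Reference layers: biome/country polygons, rasters, gazetteer.

A :class:`ReferenceLayers` bundle plays the role that WWF biome
shapefiles, country borders, a human-footprint raster, climate rasters
and location gazetteers play for real assessments. Layers round-trip to
a plain-text directory (GeoJSON, ASCII grids, CSV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grids import Grid


@dataclass
class ReferenceLayers:
    biomes: list[BaseGeometry]  # index = biome id, partition of the extent
    countries: list[BaseGeometry]  # index = country id, partition of the extent
    country_names: list[str]
    footprint: Grid  # human-footprint index, >= 0
    climate: dict[str, Grid]  # named climate layers
    land_mask: Grid  # 1 = land, 0 = sea
    gazetteer: pd.DataFrame  # columns: name, lon, lat, radius_km, type
    extent: tuple[float, float, float, float] = field(default=None)  # lon_min, lat_min, lon_max, lat_max

    def __post_init__(self):
        if self.extent is None:
            self.extent = self.land_mask.bounds

    def is_land(self, lons, lats):
        return self.land_mask.sample(lons, lats) > 0.5

    # -- persistence ---------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        _write_geojson(directory / "biomes.geojson", self.biomes, [{"biome_id": i} for i in range(len(self.biomes))])
        _write_geojson(
            directory / "countries.geojson",
            self.countries,
            [{"country_id": i, "name": n} for i, n in enumerate(self.country_names)],
        )
        self.footprint.write(directory / "footprint.asc")
        self.land_mask.write(directory / "land_mask.asc")
        for name, grid in self.climate.items():
            grid.write(directory / f"climate_{name}.asc")
        self.gazetteer.to_csv(directory / "gazetteer.csv", index=False)

    @classmethod
    def load(cls, directory) -> "ReferenceLayers":
        directory = Path(directory)
        biomes, _ = _read_geojson(directory / "biomes.geojson")
        countries, props = _read_geojson(directory / "countries.geojson")
        climate = {
            p.stem.removeprefix("climate_"): Grid.read(p) for p in sorted(directory.glob("climate_*.asc"))
        }
        return cls(
            biomes=biomes,
            countries=countries,
            country_names=[p.get("name", f"country_{i}") for i, p in enumerate(props)],
            footprint=Grid.read(directory / "footprint.asc"),
            climate=climate,
            land_mask=Grid.read(directory / "land_mask.asc"),
            gazetteer=pd.read_csv(directory / "gazetteer.csv"),
        )


def _write_geojson(path: Path, geoms: list[BaseGeometry], props: list[dict]) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p} for g, p in zip(geoms, props)
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def _read_geojson(path: Path):
    doc = json.loads(path.read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props
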