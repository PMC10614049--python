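"""Core data containers: the annual land-cover panel and the zone set.

``LandscapePanel`` holds per-pixel annual tree canopy cover (TCC, percent)
and a categorical land-cover state on a regular 30-m grid, together with
the binary forest layer derived from the land-cover classes. ``ZoneSet``
holds community-forest (CF) zones with establishment years plus the
exclusion masks (water, protected areas, concessions) that define the
eligible study frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, TemporalRangeError
from .geometry import mask_to_polygon, rasterize

# Land-cover class codes. "disturbance" marks pixels in the year a stand-
# replacing clearing is detected; like every non-forest class it maps to
# forest = 0.
NATURAL_FOREST = 1
PLANTATION_FOREST = 2
AGRICULTURE = 3
GRASS_SHRUB = 4
URBAN_WATER = 5
DISTURBANCE = 6

LANDCOVER_LABELS: dict[int, str] = {
    NATURAL_FOREST: "natural_forest",
    PLANTATION_FOREST: "plantation_forest",
    AGRICULTURE: "agriculture",
    GRASS_SHRUB: "grass_shrub",
    URBAN_WATER: "urban_water",
    DISTURBANCE: "disturbance",
}
FOREST_CLASSES = frozenset({NATURAL_FOREST, PLANTATION_FOREST})


@dataclass
class LandscapePanel:
    """Annual TCC / land-cover / forest state on one grid.

    Arrays are indexed ``[year_index, row, col]`` and share the calendar
    ``years`` list and grid geometry.
    """

    years: np.ndarray            # (Y,) calendar years, consecutive
    tcc: np.ndarray              # (Y, R, C) float, percent in [0, 100]
    landcover: np.ndarray        # (Y, R, C) int codes (LANDCOVER_LABELS)
    forest: np.ndarray           # (Y, R, C) uint8 {0, 1}
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.tcc.shape != self.landcover.shape or self.tcc.shape != self.forest.shape:
            raise ConfigurationError("tcc, landcover and forest must share one shape")
        if self.tcc.shape[0] != self.years.size:
            raise ConfigurationError("leading axis must match the year list")
        if self.tcc.size and (np.nanmin(self.tcc) < 0 or np.nanmax(self.tcc) > 100):
            raise ConfigurationError("TCC outside [0, 100]")
        if not np.isin(self.forest, (0, 1)).all():
            raise ConfigurationError("forest layer must be binary")

    # -- geometry / indexing -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.tcc.shape[1:]

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def year_index(self, year: int) -> int:
        if year < self.years[0] or year > self.years[-1]:
            raise TemporalRangeError(
                f"year {year} outside panel span {self.years[0]}-{self.years[-1]}"
            )
        return int(year - self.years[0])

    # -- derived layers ------------------------------------------------------
    @property
    def forest_throughout(self) -> np.ndarray:
        """Pixels that are forest in every panel year (R, C) bool."""
        return self.forest.astype(bool).all(axis=0)

    def outcome(self, name: str) -> np.ndarray:
        """Outcome cube by name: 'tcc' (percent) or 'forest' (0/1)."""
        if name == "tcc":
            return self.tcc
        if name == "forest":
            return self.forest
        raise KeyError(f"unknown outcome {name!r}; expected 'tcc' or 'forest'")

    def sample_series(self, name: str, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Outcome time series at pixel positions, shape (n_samples, n_years)."""
        return self.outcome(name)[:, np.asarray(rows), np.asarray(cols)].T


@dataclass
class ZoneSet:
    """CF zones (establishment years) and exclusion masks on the panel grid."""

    table: pd.DataFrame                       # columns: zone_id, est_year
    labels: np.ndarray                        # (R, C) int, zone_id or -1 outside
    exclusions: dict[str, np.ndarray | BaseGeometry] = field(default_factory=dict)
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.table.empty and self.table["zone_id"].duplicated().any():
            raise ConfigurationError("zone ids must be unique")

    @property
    def zone_ids(self) -> np.ndarray:
        return self.table["zone_id"].to_numpy()

    @property
    def est_years(self) -> np.ndarray:
        return self.table["est_year"].to_numpy()

    def est_year_of(self, zone_id: int) -> int:
        row = self.table.loc[self.table["zone_id"] == zone_id, "est_year"]
        if row.empty:
            raise KeyError(f"unknown zone id {zone_id}")
        return int(row.iloc[0])

    def exclusion_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Union of all exclusion layers as a boolean pixel mask."""
        shape = shape or self.labels.shape
        out = np.zeros(shape, dtype=bool)
        for layer in self.exclusions.values():
            if isinstance(layer, np.ndarray):
                if layer.shape != shape:
                    from .errors import SpatialReferenceError

                    raise SpatialReferenceError(
                        f"exclusion mask shape {layer.shape} != grid {shape}"
                    )
                out |= layer.astype(bool)
            elif layer is not None:
                out |= rasterize(layer, shape, self.cell_size, self.origin)
        return out

    @cached_property
    def polygons(self) -> pd.DataFrame:
        """Zone outlines as shapely geometry (derived from the label raster)."""
        geoms = [
            mask_to_polygon(self.labels == zid, self.cell_size, self.origin)
            for zid in self.table["zone_id"]
        ]
        out = self.table.copy()
        out["geometry"] = geoms
        return out

    def membership(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Zone id at pixel positions (-1 outside every zone)."""
        return self.labels[np.asarray(rows), np.asarray(cols)]
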