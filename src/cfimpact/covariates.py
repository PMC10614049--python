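"""The nine potentially confounding variables, evaluated per sample at a
reference (CF establishment) year.

Five are static (elevation, slope, distances to road / village / district
center); four describe the forest condition in the reference year (binary
forest state, TCC, 8-neighbour grid distance to the nearest nonforest
pixel, and the proportion of forest within a 5-ha buffer, radius 126 m).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, MissingLayerError
from .panel import LandscapePanel

COVARIATE_NAMES = (
    "elevation",
    "slope",
    "dist_road",
    "dist_village",
    "dist_district",
    "forest_at_est",
    "tcc_at_est",
    "dist_nonforest_at_est",
    "forest_prop_buffer_at_est",
)
#: covariates entering the propensity model (forest_at_est is exact-matched)
PROPENSITY_COVARIATES = tuple(c for c in COVARIATE_NAMES if c != "forest_at_est")


def slope_from_dem(elevation: np.ndarray, cell_size: float = 30.0) -> np.ndarray:
    """Terrain slope in degrees from a DEM by Horn's 3x3 method.

    Horn's weighted finite differences are the de-facto standard for
    raster slope. Edges are handled by replicating the border row/column,
    which reduces to one-sided differences there.
    """
    elevation = np.asarray(elevation, dtype=float)
    if elevation.ndim != 2 or min(elevation.shape) < 2:
        raise ConfigurationError(
            f"slope needs a raster of at least 2x2 pixels, got shape {elevation.shape}"
        )
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8.0 * cell_size)
    gx = ndimage.convolve(elevation, kx[:, ::-1], mode="nearest")
    gy = ndimage.convolve(elevation, kx.T[::-1, :], mode="nearest")
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def euclidean_distance(
    point: tuple[float, float], features: list[BaseGeometry] | BaseGeometry
) -> float:
    """Planar distance from a point to the nearest feature geometry."""
    if isinstance(features, BaseGeometry):
        features = [features]
    features = [g for g in features if g is not None and not g.is_empty]
    if not features:
        raise MissingLayerError("empty feature layer: no geometry to measure to")
    p = shapely.Point(point)
    return min(p.distance(g) for g in features)


def feature_distance_raster(
    features: list[BaseGeometry],
    shape: tuple[int, int],
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Per-pixel Euclidean distance (m) to the nearest feature.

    Features are burned into the grid at half-cell resolution, then a
    Euclidean distance transform from the burned cells gives the distance
    of every pixel center to the nearest feature cell center.
    """
    if not features:
        raise MissingLayerError("empty feature layer")
    burned = np.zeros(shape, dtype=bool)
    x0, y0 = origin
    for geom in features:
        if geom.geom_type == "Point":
            pts = [(geom.x, geom.y)]
        else:
            n = max(2, int(np.ceil(geom.length / (cell_size / 2.0))) + 1)
            pts = [geom.interpolate(t, normalized=True).coords[0]
                   for t in np.linspace(0.0, 1.0, n)]
        for px, py in pts:
            r = int((py - y0) // cell_size)
            c = int((px - x0) // cell_size)
            if 0 <= r < shape[0] and 0 <= c < shape[1]:
                burned[r, c] = True
    if not burned.any():
        raise MissingLayerError("no feature intersects the raster extent")
    return ndimage.distance_transform_edt(~burned, sampling=cell_size)


@numba.njit(cache=True)
def _chamfer_sweep(dist: np.ndarray, orth: float, diag: float) -> np.ndarray:
    """Two-pass sequential chamfer distance transform on a 3x3 mask.

    For a 3x3 neighbourhood the forward + backward raster sweeps give the
    exact chamfer distance (Borgefors' classic result), and the (1, sqrt 2)
    chamfer distance equals the 8-connected shortest-path metric.
    """
    rows, cols = dist.shape
    for r in range(rows):
        for c in range(cols):
            d = dist[r, c]
            if r > 0:
                if dist[r - 1, c] + orth < d:
                    d = dist[r - 1, c] + orth
                if c > 0 and dist[r - 1, c - 1] + diag < d:
                    d = dist[r - 1, c - 1] + diag
                if c < cols - 1 and dist[r - 1, c + 1] + diag < d:
                    d = dist[r - 1, c + 1] + diag
            if c > 0 and dist[r, c - 1] + orth < d:
                d = dist[r, c - 1] + orth
            dist[r, c] = d
    for r in range(rows - 1, -1, -1):
        for c in range(cols - 1, -1, -1):
            d = dist[r, c]
            if r < rows - 1:
                if dist[r + 1, c] + orth < d:
                    d = dist[r + 1, c] + orth
                if c > 0 and dist[r + 1, c - 1] + diag < d:
                    d = dist[r + 1, c - 1] + diag
                if c < cols - 1 and dist[r + 1, c + 1] + diag < d:
                    d = dist[r + 1, c + 1] + diag
            if c < cols - 1 and dist[r, c + 1] + orth < d:
                d = dist[r, c + 1] + orth
            dist[r, c] = d
    return dist


def grid_distance_raster(forest: np.ndarray, cell_size: float = 30.0) -> np.ndarray:
    """8-neighbour shortest-path distance (m) from every pixel to the
    nearest nonforest pixel.

    Moves between pixel centers cost ``cell_size`` orthogonally and
    ``cell_size * sqrt(2)`` diagonally (the gridDistance convention).
    Nonforest pixels are at distance 0. If no nonforest pixel exists,
    every pixel gets the sentinel ``(rows + cols) * cell_size`` and a
    warning is emitted; the sentinel is an upper bound on any within-grid
    path and is excluded from balance statistics if constant.
    """
    forest = np.asarray(forest).astype(bool)
    if forest.all():
        warnings.warn(
            "no nonforest pixel in layer; assigning sentinel grid distance",
            stacklevel=2,
        )
        return np.full(forest.shape, float(sum(forest.shape)) * cell_size)
    dist = np.where(forest, np.inf, 0.0)
    return _chamfer_sweep(dist, 1.0, float(np.sqrt(2.0))) * cell_size


def grid_distance_to_nonforest(
    forest: np.ndarray, point: tuple[int, int], cell_size: float = 30.0
) -> float:
    """Grid distance for one sample pixel (row, col); 0 if it is nonforest."""
    return float(grid_distance_raster(forest, cell_size)[point])


def buffer_offsets(cell_size: float = 30.0, radius: float = 126.0) -> np.ndarray:
    """Lattice offsets (dr, dc) whose centers lie within ``radius`` of the
    sample pixel center. For a 30-m grid and 126-m radius this is the
    57-pixel disc of the 5-ha buffer."""
    k = int(radius // cell_size)
    dr, dc = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1), indexing="ij")
    keep = np.hypot(dr, dc) * cell_size <= radius
    return np.stack([dr[keep], dc[keep]], axis=1)


def buffer_forest_proportion(
    forest: np.ndarray,
    point: tuple[int, int],
    cell_size: float = 30.0,
    radius: float = 126.0,
) -> float:
    """Fraction of forest pixels among those whose centers fall within
    ``radius`` of the sample pixel center (sample pixel included).

    Forest inside water / protected-area / concession polygons counts:
    exclusion masks restrict where samples can BE, not what the buffer
    sees. Samples whose buffer leaves the raster were filtered out at the
    border-buffer stage, so an out-of-extent buffer is an error here.
    """
    forest = np.asarray(forest)
    offs = buffer_offsets(cell_size, radius)
    r, c = point
    rr, cc = r + offs[:, 0], c + offs[:, 1]
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= forest.shape[0] or cc.max() >= forest.shape[1]:
        raise ConfigurationError(
            f"buffer around pixel {point} extends beyond the raster extent"
        )
    return float(np.mean(forest[rr, cc].astype(bool)))


def buffer_forest_raster(
    forest: np.ndarray, cell_size: float = 30.0, radius: float = 126.0
) -> np.ndarray:
    """Buffer forest proportion for every pixel (exact for pixels whose
    buffer is fully inside the raster; edge pixels see zero-padding)."""
    offs = buffer_offsets(cell_size, radius)
    k = int(radius // cell_size)
    kernel = np.zeros((2 * k + 1, 2 * k + 1))
    kernel[offs[:, 0] + k, offs[:, 1] + k] = 1.0
    counts = ndimage.convolve(np.asarray(forest, dtype=float), kernel, mode="constant")
    return counts / len(offs)


@dataclass
class SurfaceSet:
    """Static covariate rasters plus the vector features they derive from."""

    elevation: np.ndarray
    slope: np.ndarray
    dist_road: np.ndarray
    dist_village: np.ndarray
    dist_district: np.ndarray
    roads: list[BaseGeometry] = field(default_factory=list)
    villages: list[BaseGeometry] = field(default_factory=list)
    districts: list[BaseGeometry] = field(default_factory=list)
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def raster(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def rasters(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in
                ("elevation", "slope", "dist_road", "dist_village", "dist_district")}


class CovariateLayers:
    """Evaluates the nine confounders for sample tables, caching the two
    expensive reference-year rasters (grid distance and buffer proportion)
    per establishment year."""

    def __init__(self, panel: LandscapePanel, surfaces: SurfaceSet,
                 buffer_radius: float = 126.0):
        self.panel = panel
        self.surfaces = surfaces
        self.buffer_radius = buffer_radius
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _ref_rasters(self, ref_year: int) -> tuple[np.ndarray, np.ndarray]:
        if ref_year not in self._cache:
            yi = self.panel.year_index(ref_year)
            forest = self.panel.forest[yi]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-forest sentinel is fine here
                gdist = grid_distance_raster(forest, self.panel.cell_size)
            bprop = buffer_forest_raster(forest, self.panel.cell_size, self.buffer_radius)
            self._cache[ref_year] = (gdist, bprop)
        return self._cache[ref_year]

    def table(self, samples: pd.DataFrame, ref_year: int) -> pd.DataFrame:
        """CovariateRecord rows (one per sample) at ``ref_year``."""
        yi = self.panel.year_index(ref_year)  # validates the year
        r = samples["row"].to_numpy()
        c = samples["col"].to_numpy()
        gdist, bprop = self._ref_rasters(ref_year)
        out = pd.DataFrame(
            {
                "sample_id": samples["sample_id"].to_numpy(),
                "elevation": self.surfaces.elevation[r, c],
                "slope": self.surfaces.slope[r, c],
                "dist_road": self.surfaces.dist_road[r, c],
                "dist_village": self.surfaces.dist_village[r, c],
                "dist_district": self.surfaces.dist_district[r, c],
                "forest_at_est": self.panel.forest[yi, r, c].astype(float),
                "tcc_at_est": self.panel.tcc[yi, r, c],
                "dist_nonforest_at_est": gdist[r, c],
                "forest_prop_buffer_at_est": bprop[r, c],
            }
        )
        out["ref_year"] = ref_year
        return out


def assemble_covariates(
    samples: pd.DataFrame,
    layers: CovariateLayers,
    ref_year: int,
) -> pd.DataFrame:
    """One record per sample with all nine confounders at ``ref_year``."""
    return layers.table(samples, ref_year)


class PrecomputedCovariates:
    """Covariate provider backed by per-reference-year tables (e.g. CSVs
    written by the covariates pipeline stage); drop-in for
    :class:`CovariateLayers` in the matching stage."""

    def __init__(self, tables: dict[int, pd.DataFrame]):
        self._tables = {int(y): t.set_index("sample_id") for y, t in tables.items()}

    def table(self, samples: pd.DataFrame, ref_year: int) -> pd.DataFrame:
        if int(ref_year) not in self._tables:
            from .errors import TemporalRangeError

            raise TemporalRangeError(f"no covariate table for year {ref_year}")
        tab = self._tables[int(ref_year)]
        out = tab.loc[samples["sample_id"].to_numpy()].reset_index()
        return out
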