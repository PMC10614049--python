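"""Planar grid <-> vector helpers shared across the pipeline.

The study frame is a regular raster grid in a single planar coordinate
system. World coordinates put the origin at the top-left corner of pixel
(0, 0), x increasing with column and y increasing with row; a pixel's
center is offset half a cell from its corner. All distances are planar
meters (no geodesic computations).
"""
from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import SpatialReferenceError


def pixel_center_coords(
    rows: int, cols: int, cell_size: float, origin: tuple[float, float] = (0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, y) world coordinates of every pixel center, each (rows, cols)."""
    x0, y0 = origin
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    return x0 + (cc + 0.5) * cell_size, y0 + (rr + 0.5) * cell_size


def point_of(row: int, col: int, cell_size: float, origin=(0.0, 0.0)) -> tuple[float, float]:
    """World coordinates of the center of pixel (row, col)."""
    return origin[0] + (col + 0.5) * cell_size, origin[1] + (row + 0.5) * cell_size


def rasterize(
    geom: BaseGeometry,
    shape: tuple[int, int],
    cell_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Boolean mask of pixels whose CENTERS fall inside ``geom``.

    Pixel-center point-in-polygon is the membership convention used
    throughout the pipeline (standard raster convention; unambiguous for
    points exactly on cell boundaries is resolved by shapely's covers test).
    """
    if geom is None or geom.is_empty:
        return np.zeros(shape, dtype=bool)
    x, y = pixel_center_coords(shape[0], shape[1], cell_size, origin)
    return shapely.intersects_xy(geom, x.ravel(), y.ravel()).reshape(shape)


def mask_to_polygon(
    mask: np.ndarray, cell_size: float, origin: tuple[float, float] = (0.0, 0.0)
) -> BaseGeometry:
    """Union of the square cells of a boolean mask, as a (Multi)Polygon."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return shapely.Polygon()
    x0, y0 = origin
    boxes = [
        box(x0 + c * cell_size, y0 + r * cell_size,
            x0 + (c + 1) * cell_size, y0 + (r + 1) * cell_size)
        for r, c in zip(rows.tolist(), cols.tolist())
    ]
    return unary_union(boxes)


def grid_boundary(
    shape: tuple[int, int], cell_size: float, origin: tuple[float, float] = (0.0, 0.0)
) -> BaseGeometry:
    """Rectangular outline of the full raster extent."""
    x0, y0 = origin
    return box(x0, y0, x0 + shape[1] * cell_size, y0 + shape[0] * cell_size)


def check_same_grid(*arrays: np.ndarray) -> None:
    """Raise SpatialReferenceError unless all arrays share trailing 2-D shape."""
    shapes = {a.shape[-2:] for a in arrays}
    if len(shapes) > 1:
        raise SpatialReferenceError(f"layers do not share one grid: {sorted(shapes)}")
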