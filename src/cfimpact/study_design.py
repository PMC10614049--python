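"""Sample-frame construction: forest reclassification, exclusion masking,
random pixel sampling, and border-buffer filtering.

The unit of analysis is a 30-m pixel. Treated samples are pixels inside a
CF zone; controls are eligible pixels outside every zone. Eligibility
removes water, protected-area and concession pixels but is otherwise
independent of CF membership (both groups are drawn from one frame).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import ClassificationError, ConfigurationError
from .geometry import grid_boundary
from .panel import LANDCOVER_LABELS, LandscapePanel, ZoneSet


def reclassify_forest(
    landcover: np.ndarray, labels: dict[int, str] = LANDCOVER_LABELS
) -> np.ndarray:
    """Collapse the land-cover classification to binary forest/nonforest.

    Natural forest and plantation forest map to 1; every other class,
    including all disturbance classes, maps to 0. Idempotent in the sense
    that re-applying to the emitted 0/1 layer with the matching label set
    {0: nonforest, 1: natural_forest} returns it unchanged.

    Raises
    ------
    ClassificationError
        If the layer contains a code absent from ``labels``.
    """
    landcover = np.asarray(landcover)
    if landcover.size == 0:
        return np.zeros_like(landcover, dtype=np.uint8)
    codes = np.unique(landcover)
    unknown = [int(c) for c in codes if int(c) not in labels]
    if unknown:
        raise ClassificationError(f"unknown land-cover label(s): {unknown}")
    forest_codes = [c for c, name in labels.items() if name in
                    {"natural_forest", "plantation_forest"}]
    return np.isin(landcover, forest_codes).astype(np.uint8)


def eligible_pixels(panel: LandscapePanel, zones: ZoneSet) -> np.ndarray:
    """Mask of pixels whose centers fall outside every exclusion polygon.

    CF membership does NOT affect eligibility: treated and control samples
    are drawn from the same frame.
    """
    return ~zones.exclusion_mask(panel.shape)


def draw_samples(
    mask: np.ndarray,
    fraction: float,
    seed: int | np.random.Generator,
    cell_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Simple random sample (without replacement) of eligible pixels.

    Exactly ``floor(fraction * n_eligible)`` pixels are drawn (floor keeps
    the count conservative and deterministic). Returns a frame with
    sample_id, row, col and world coordinates of the pixel center.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError(f"sampling fraction must be in (0, 1], got {fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = np.flatnonzero(np.asarray(mask, dtype=bool))
    n = int(np.floor(fraction * flat.size))
    chosen = np.sort(rng.choice(flat, size=n, replace=False))
    rows, cols = np.unravel_index(chosen, mask.shape)
    x0, y0 = origin
    return pd.DataFrame(
        {
            "sample_id": np.arange(n, dtype=int),
            "row": rows.astype(int),
            "col": cols.astype(int),
            "x": x0 + (cols + 0.5) * cell_size,
            "y": y0 + (rows + 0.5) * cell_size,
        }
    )


def assign_groups(samples: pd.DataFrame, zones: ZoneSet) -> pd.DataFrame:
    """Label samples treated/control by zone membership of the pixel center.

    Treated samples carry their zone's establishment year; controls get
    est_year -1 until matching assigns the partner's year.
    """
    out = samples.copy()
    if zones.table.empty:
        out["group"] = "control"
        out["zone_id"] = -1
        out["est_year"] = -1
        return out
    zid = zones.membership(out["row"].to_numpy(), out["col"].to_numpy())
    est = np.full(zid.shape, -1, dtype=int)
    year_of = dict(zip(zones.table["zone_id"], zones.table["est_year"]))
    inside = zid >= 0
    est[inside] = [year_of[z] for z in zid[inside]]
    out["group"] = np.where(inside, "treated", "control")
    out["zone_id"] = zid
    out["est_year"] = est
    return out


def filter_border_buffers(
    samples: pd.DataFrame,
    boundary: BaseGeometry,
    radius: float = 126.0,
) -> pd.DataFrame:
    """Drop samples whose ``radius``-m buffer disc is not fully inside the
    study boundary.

    Only the outer boundary matters: buffers crossing water, protected-area
    or concession polygons are retained (forest inside those areas still
    counts toward the buffer forest proportion).
    """
    eroded = boundary.buffer(-radius)
    if eroded.is_empty:
        return samples.iloc[0:0].copy()
    keep = shapely.intersects_xy(eroded, samples["x"].to_numpy(), samples["y"].to_numpy())
    return samples.loc[keep].reset_index(drop=True)


def build_sample_frame(
    panel: LandscapePanel,
    zones: ZoneSet,
    fraction: float,
    seed: int | np.random.Generator,
    buffer_radius: float = 126.0,
    boundary: BaseGeometry | None = None,
) -> pd.DataFrame:
    """Eligibility mask -> random sample -> group labels -> border filter."""
    mask = eligible_pixels(panel, zones)
    samples = draw_samples(mask, fraction, seed, panel.cell_size, panel.origin)
    samples = assign_groups(samples, zones)
    if boundary is None:
        boundary = grid_boundary(panel.shape, panel.cell_size, panel.origin)
    return filter_border_buffers(samples, boundary, buffer_radius)
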