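"""Artifact serialization.

Rasters go to multi-page TIFF (one page per year or per surface) with a
YAML sidecar carrying the grid geometry and year list; vectors go to
GeoJSON; tables to CSV; configs and the run manifest to YAML. Everything
is plain, language-agnostic, and hash-stable for provenance checks.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import shape as shapely_shape

from .covariates import SurfaceSet
from .panel import LandscapePanel, ZoneSet
from .geometry import rasterize


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# panel

def save_panel(panel: LandscapePanel, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cube, dtype in (
        ("tcc", panel.tcc, np.float32),
        ("landcover", panel.landcover, np.int16),
        ("forest", panel.forest, np.uint8),
    ):
        p = outdir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(cube, dtype=dtype))
        paths.append(p)
    meta = {
        "years": [int(y) for y in panel.years],
        "cell_size": float(panel.cell_size),
        "origin": [float(v) for v in panel.origin],
    }
    mp = outdir / "panel.yaml"
    mp.write_text(yaml.safe_dump(meta, sort_keys=True))
    paths.append(mp)
    return paths


def load_panel(outdir: Path) -> LandscapePanel:
    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / "panel.yaml").read_text())
    return LandscapePanel(
        years=np.asarray(meta["years"], dtype=int),
        tcc=tifffile.imread(outdir / "tcc.tif").astype(float),
        landcover=tifffile.imread(outdir / "landcover.tif").astype(np.int16),
        forest=tifffile.imread(outdir / "forest.tif").astype(np.uint8),
        cell_size=float(meta["cell_size"]),
        origin=tuple(meta["origin"]),
    )


# ---------------------------------------------------------------------------
# surfaces

_SURFACE_NAMES = ("elevation", "slope", "dist_road", "dist_village", "dist_district")


def save_surfaces(surfaces: SurfaceSet, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = np.stack([surfaces.raster(n).astype(np.float32) for n in _SURFACE_NAMES])
    p = outdir / "surfaces.tif"
    tifffile.imwrite(p, stack)
    features = []
    for kind, geoms in (("road", surfaces.roads), ("village", surfaces.villages),
                        ("district", surfaces.districts)):
        for g in geoms:
            features.append(
                {"type": "Feature", "properties": {"kind": kind},
                 "geometry": json.loads(shapely.to_geojson(g))}
            )
    fp = outdir / "features.geojson"
    fp.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return [p, fp]


def load_surfaces(outdir: Path, cell_size: float = 30.0) -> SurfaceSet:
    outdir = Path(outdir)
    stack = tifffile.imread(outdir / "surfaces.tif").astype(float)
    fc = json.loads((outdir / "features.geojson").read_text())
    by_kind: dict[str, list] = {"road": [], "village": [], "district": []}
    for f in fc["features"]:
        by_kind[f["properties"]["kind"]].append(shapely_shape(f["geometry"]))
    return SurfaceSet(
        **dict(zip(_SURFACE_NAMES, stack)),
        roads=by_kind["road"], villages=by_kind["village"],
        districts=by_kind["district"], cell_size=cell_size,
    )


# ---------------------------------------------------------------------------
# zones

def save_zones(zones: ZoneSet, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features = []
    for row in zones.polygons.itertuples():
        features.append(
            {"type": "Feature",
             "properties": {"zone_id": int(row.zone_id),
                            "est_year": int(row.est_year)},
             "geometry": json.loads(shapely.to_geojson(row.geometry))}
        )
    zp = outdir / "zones.geojson"
    zp.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    ex_features = []
    from .geometry import mask_to_polygon

    for name, layer in zones.exclusions.items():
        geom = (mask_to_polygon(layer, zones.cell_size, zones.origin)
                if isinstance(layer, np.ndarray) else layer)
        if geom is None or geom.is_empty:
            continue
        ex_features.append(
            {"type": "Feature", "properties": {"kind": name},
             "geometry": json.loads(shapely.to_geojson(geom))}
        )
    ep = outdir / "exclusions.geojson"
    ep.write_text(json.dumps({"type": "FeatureCollection", "features": ex_features}))
    return [zp, ep]


def load_zones(outdir: Path, shape: tuple[int, int], cell_size: float = 30.0,
               origin: tuple[float, float] = (0.0, 0.0)) -> ZoneSet:
    outdir = Path(outdir)
    fc = json.loads((outdir / "zones.geojson").read_text())
    labels = np.full(shape, -1, dtype=np.int32)
    rows = []
    for f in fc["features"]:
        zid = int(f["properties"]["zone_id"])
        rows.append({"zone_id": zid, "est_year": int(f["properties"]["est_year"])})
        mask = rasterize(shapely_shape(f["geometry"]), shape, cell_size, origin)
        labels[mask] = zid
    exclusions: dict[str, np.ndarray] = {}
    ep = outdir / "exclusions.geojson"
    if ep.exists():
        for f in json.loads(ep.read_text())["features"]:
            exclusions[f["properties"]["kind"]] = rasterize(
                shapely_shape(f["geometry"]), shape, cell_size, origin
            )
    table = (pd.DataFrame(rows) if rows
             else pd.DataFrame(columns=["zone_id", "est_year"]).astype(int))
    return ZoneSet(table=table, labels=labels, exclusions=exclusions,
                   cell_size=cell_size, origin=origin)


# ---------------------------------------------------------------------------
# manifest

def write_manifest(outdir: Path, config_dict: dict, seed: int,
                   artifacts: list[Path]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "seed": int(seed),
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": {
            str(Path(p).relative_to(outdir)): sha256_of(p) for p in artifacts
        },
    }
    mp = outdir / "manifest.yaml"
    mp.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mp
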