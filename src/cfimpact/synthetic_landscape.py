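"""Synthetic landscape generator with known ground-truth effects.

Emulates the statistical structure the impact evaluation assumes: a
declining tree-canopy baseline with spatially autocorrelated initial
conditions, accessibility covariates (elevation, slope, distances to
roads / villages / district centers), confounder-biased zone placement
(community forests are not sited at random), optional stochastic
forest-to-nonforest clearing that favors accessible pixels, and
injectable post-establishment level and trend effects that may vary by
establishment cohort. Because the injected effects are known exactly,
the whole analysis chain can be validated by parameter recovery.

Noise is NON-accumulating observation noise around each pixel's
deterministic trend, so the matched difference series is serially
uncorrelated — the error structure the segmented-regression inference
assumes. Effects are added to the latent (pre-clipping) canopy value so
the ground truth stays linear.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point

from .covariates import SurfaceSet, feature_distance_raster, slope_from_dem
from .errors import ConfigurationError, GenerationError, SpatialReferenceError
from .panel import (
    AGRICULTURE,
    DISTURBANCE,
    GRASS_SHRUB,
    LandscapePanel,
    NATURAL_FOREST,
    PLANTATION_FOREST,
    URBAN_WATER,
    ZoneSet,
)
from .study_design import reclassify_forest

_STAGE_IDS = {"surfaces": 1, "panel": 2, "zones": 3, "inject": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream per generation stage."""
    return np.random.default_rng([int(seed), _STAGE_IDS[stage]])


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    The defaults describe the desk-scale reference scenario: a 200x200
    grid of 30-m pixels observed annually 1989-2019, 40 zones established
    1997-2010, a declining canopy baseline of -0.5 %/yr, placement biased
    toward high, road-remote terrain, observation noise of 5 TCC points,
    and a true establishment effect of +2.0 TCC points (level) and
    +0.5 %/yr (trend).
    """

    grid_rows: int = 200
    grid_cols: int = 200
    cell_size: float = 30.0
    years: tuple[int, int] = (1989, 2019)
    n_zones: int = 40
    establishment_years: tuple[int, ...] = tuple(range(1997, 2011))
    zone_target_area: int = 150          # pixels per zone (13.5 ha at 30 m)
    baseline_tcc_trend: float = -0.4     # %/yr; negative = decline
    effect_level: float = 2.0            # TCC points at establishment (beta2 truth)
    effect_trend: float = 0.5            # %/yr post-establishment (beta3 truth)
    cohort_effect_slope: float = 0.0     # change in both effects per est. year
    placement_bias_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"elevation": 0.8, "dist_road": 0.5}
    )
    noise_sd: float = 5.0                # TCC observation noise, % points
    deforestation_base_rate: float = 0.0  # clearing probability / yr
    protection_factor: float = 0.0       # post-establishment hazard reduction in zones
    seed: int = 0
    # landscape texture
    correlation_length: float = 8.0      # pixels; autocorrelation scale of fields
    elevation_mean: float = 200.0        # m
    elevation_sd: float = 120.0          # m
    tcc_init_mean: float = 50.0
    tcc_init_sd: float = 18.0
    # keeps latent trajectories away from the [0, 100] bounds over the
    # simulated span, so the injected effects remain the ITS estimand
    tcc_init_range: tuple[float, float] = (20.0, 88.0)
    tcc_elevation_loading: float = 5.0   # TCC points per elevation SD (confounding)
    forest_tcc_threshold: float = 30.0   # initial forest where TCC >= threshold
    plantation_fraction: float = 0.05
    water_fraction: float = 0.02
    protected_fraction: float = 0.03
    clearing_accessibility_scale: float = 0.5
    low_tcc_max: float = 8.0             # cleared/nonforest residual canopy cap
    n_roads: int = 2
    n_villages: int = 12
    n_districts: int = 3

    def __post_init__(self) -> None:
        if self.grid_rows < 32 or self.grid_cols < 32:
            raise ConfigurationError("grid dimensions must be at least 32 pixels")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        y0, y1 = self.years
        if y1 - y0 + 1 < 18:
            raise ConfigurationError(
                "the calendar span must cover at least 18 years (the pooled "
                "-8..+9 event window)"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.n_zones < 0 or self.zone_target_area < 1:
            raise ConfigurationError("n_zones and zone_target_area must be nonnegative")
        if not all(y0 <= e <= y1 for e in self.establishment_years):
            raise ConfigurationError("establishment years must fall inside the span")
        if not 0 <= self.deforestation_base_rate <= 1:
            raise ConfigurationError("deforestation_base_rate must be a probability")
        if not 0 <= self.protection_factor <= 1:
            raise ConfigurationError("protection_factor must be in [0, 1]")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def cohort_effects(self, est_year: int) -> tuple[float, float]:
        """Injected (level, trend) effect for a cohort: both shift by
        cohort_effect_slope per establishment year after the oldest."""
        dy = est_year - min(self.establishment_years)
        return (self.effect_level + self.cohort_effect_slope * dy,
                self.effect_trend + self.cohort_effect_slope * dy)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        d["establishment_years"] = list(self.establishment_years)
        d["tcc_init_range"] = list(self.tcc_init_range)
        d["placement_bias_coefs"] = dict(self.placement_bias_coefs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        for key in ("years", "establishment_years", "tcc_init_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Known injected effects: one row per zone plus pixel membership."""

    table: pd.DataFrame          # zone_id, est_year, level_effect, trend_effect
    labels: np.ndarray           # (R, C) zone id or -1

    def effect_of(self, zone_id: int) -> tuple[float, float]:
        row = self.table.loc[self.table["zone_id"] == zone_id].iloc[0]
        return float(row["level_effect"]), float(row["trend_effect"])


@dataclass
class _SimState:
    """Latent generator state carried on the panel for effect injection."""

    init: np.ndarray             # (R, C) latent initial TCC
    eps: np.ndarray              # (Y, R, C) observation noise
    cleared_year: np.ndarray     # (R, C) calendar year of clearing, -1 if never
    low_tcc: np.ndarray          # (R, C) residual canopy after clearing
    landcover0: np.ndarray       # (R, C) initial land-cover class
    hazard: np.ndarray           # (R, C) per-year clearing probability
    config: "ScenarioConfig" = None


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardized Gaussian-filtered white noise (unit variance)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def generate_surfaces(config: ScenarioConfig) -> SurfaceSet:
    """Static covariate rasters: autocorrelated elevation, Horn slope, and
    Euclidean distances to randomly placed roads, villages and district
    centers. Deterministic given the config seed."""
    rng = _stage_rng(config.seed, "surfaces")
    shape = (config.grid_rows, config.grid_cols)
    cell = config.cell_size
    width, height = config.grid_cols * cell, config.grid_rows * cell

    elevation = (config.elevation_mean
                 + config.elevation_sd * _smooth_field(rng, shape,
                                                       config.correlation_length))
    elevation = np.maximum(elevation, 0.0)
    slope = slope_from_dem(elevation, cell)

    roads = []
    for _ in range(config.n_roads):
        if rng.random() < 0.5:  # west-east road
            y_a, y_b = rng.uniform(0, height, size=2)
            roads.append(LineString([(0.0, y_a), (width, y_b)]))
        else:                   # north-south road
            x_a, x_b = rng.uniform(0, width, size=2)
            roads.append(LineString([(x_a, 0.0), (x_b, height)]))
    villages = [Point(rng.uniform(0, width), rng.uniform(0, height))
                for _ in range(config.n_villages)]
    districts = [Point(rng.uniform(0, width), rng.uniform(0, height))
                 for _ in range(config.n_districts)]

    return SurfaceSet(
        elevation=elevation,
        slope=slope,
        dist_road=feature_distance_raster(roads, shape, cell),
        dist_village=feature_distance_raster(villages, shape, cell),
        dist_district=feature_distance_raster(districts, shape, cell),
        roads=roads, villages=villages, districts=districts,
        cell_size=cell,
    )


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / (sd if sd > 0 else 1.0)


def _render_panel(sim: _SimState,
                  effect: np.ndarray | None = None) -> LandscapePanel:
    """Compose observed TCC / land-cover / forest cubes from latent state."""
    config = sim.config
    years = config.year_list
    ny = years.size
    shape = sim.init.shape
    trend = config.baseline_tcc_trend

    tcc = np.empty((ny,) + shape)
    landcover = np.empty((ny,) + shape, dtype=np.int16)
    cleared = sim.cleared_year
    for k, year in enumerate(years):
        latent = sim.init + trend * (year - years[0]) + sim.eps[k]
        if effect is not None:
            latent = latent + effect[k]
        vals = np.clip(latent, 0.0, 100.0)
        lc = sim.landcover0.copy()
        was_cleared = (cleared >= 0) & (cleared <= year)
        vals = np.where(was_cleared, sim.low_tcc, vals)
        lc[(cleared >= 0) & (cleared == year)] = DISTURBANCE
        lc[(cleared >= 0) & (cleared < year)] = AGRICULTURE
        tcc[k] = vals
        landcover[k] = lc
    forest = reclassify_forest(landcover)
    panel = LandscapePanel(years=years, tcc=tcc, landcover=landcover,
                           forest=forest, cell_size=config.cell_size)
    panel._sim = sim  # latent state for effect injection
    return panel


def simulate_panel(config: ScenarioConfig, surfaces: SurfaceSet) -> LandscapePanel:
    """Simulate the annual TCC / land-cover panel without zone effects.

    Initial canopy is a spatially autocorrelated field with a loading on
    elevation (the confounding the matching step must remove). Each pixel
    then follows tcc(year) = init + baseline_tcc_trend * (year - y0) +
    eps, clipped to [0, 100], with iid observation noise eps. Pixels may
    convert forest -> nonforest with a probability that increases with
    accessibility (near roads and villages); converted pixels keep a low
    residual canopy thereafter.
    """
    rng = _stage_rng(config.seed, "panel")
    shape = (config.grid_rows, config.grid_cols)
    years = config.year_list

    init = (config.tcc_init_mean
            + config.tcc_init_sd * _smooth_field(rng, shape, config.correlation_length)
            + config.tcc_elevation_loading * _standardize(surfaces.elevation))
    init = np.clip(init, *config.tcc_init_range)

    landcover0 = np.full(shape, GRASS_SHRUB, dtype=np.int16)
    forest0 = init >= config.forest_tcc_threshold
    landcover0[forest0] = NATURAL_FOREST
    plantation = forest0 & (rng.random(shape) < config.plantation_fraction)
    landcover0[plantation] = PLANTATION_FOREST
    nonforest = ~forest0
    agri = nonforest & (_smooth_field(rng, shape, config.correlation_length) > 0)
    landcover0[agri] = AGRICULTURE
    if config.water_fraction > 0:
        wf = _smooth_field(rng, shape, config.correlation_length)
        water = wf > np.quantile(wf, 1.0 - config.water_fraction)
        landcover0[water] = URBAN_WATER
        init[water] = 0.0

    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=(years.size,) + shape)
    else:
        eps = np.zeros((years.size,) + shape)
    eps[:, landcover0 == URBAN_WATER] = 0.0

    access = 0.5 * (_standardize(-surfaces.dist_road)
                    + _standardize(-surfaces.dist_village))
    hazard = np.clip(
        config.deforestation_base_rate
        * np.exp(config.clearing_accessibility_scale * access),
        0.0, 1.0,
    )

    cleared_year = np.full(shape, -1, dtype=np.int32)
    low_tcc = rng.uniform(0.0, config.low_tcc_max, size=shape)
    if config.deforestation_base_rate > 0:
        standing = (landcover0 == NATURAL_FOREST) | (landcover0 == PLANTATION_FOREST)
        for year in years[1:]:
            hit = standing & (rng.random(shape) < hazard)
            cleared_year[hit] = year
            standing &= ~hit

    sim = _SimState(init=init, eps=eps, cleared_year=cleared_year,
                    low_tcc=low_tcc, landcover0=landcover0, hazard=hazard,
                    config=config)
    return _render_panel(sim)


def placement_probabilities(
    config: ScenarioConfig, surfaces: SurfaceSet, eligible: np.ndarray
) -> np.ndarray:
    """Zone seed-pixel probabilities: logistic in the (standardized)
    placement covariates, normalized over eligible pixels. All-zero
    coefficients give the uniform distribution over eligible pixels."""
    z = np.zeros(eligible.shape)
    for name, coef in config.placement_bias_coefs.items():
        z += coef * _standardize(surfaces.raster(name))
    p = 1.0 / (1.0 + np.exp(-z))
    p = np.where(eligible, p, 0.0)
    total = p.sum()
    if total <= 0:
        raise GenerationError("no eligible pixels for zone placement")
    return p / total


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _grow_zone(rng: np.random.Generator, seed_pix: tuple[int, int],
               allowed: np.ndarray, target: int) -> list[tuple[int, int]]:
    """Randomized 8-connected region growth from a seed to ~target pixels."""
    patch = {seed_pix}
    frontier_list: list[tuple[int, int]] = []
    frontier_seen: set[tuple[int, int]] = set()
    rows, cols = allowed.shape

    def expand(p):
        r, c = p
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if (0 <= q[0] < rows and 0 <= q[1] < cols and allowed[q]
                    and q not in patch and q not in frontier_seen):
                frontier_list.append(q)
                frontier_seen.add(q)

    expand(seed_pix)
    while len(patch) < target and frontier_list:
        i = int(rng.integers(len(frontier_list)))
        frontier_list[i], frontier_list[-1] = frontier_list[-1], frontier_list[i]
        q = frontier_list.pop()
        frontier_seen.discard(q)
        patch.add(q)
        expand(q)
    return sorted(patch)


def place_zones(
    config: ScenarioConfig, surfaces: SurfaceSet, panel: LandscapePanel
) -> tuple[ZoneSet, GroundTruth]:
    """Place non-overlapping zones with confounder-biased seed pixels.

    Seeds are drawn with probability proportional to a logistic function
    of the placement covariates (the selection bias the matching stage
    exists to remove), then grown into contiguous patches of roughly
    ``zone_target_area`` pixels, disjoint from each other and from the
    exclusion masks. Establishment years are assigned by cycling through
    the configured cohort list in random order.
    """
    rng = _stage_rng(config.seed, "zones")
    shape = panel.shape
    labels = np.full(shape, -1, dtype=np.int32)

    water = panel.landcover[0] == URBAN_WATER
    protected = np.zeros(shape, dtype=bool)
    if config.protected_fraction > 0:
        pf = _smooth_field(rng, shape, config.correlation_length)
        protected = pf > np.quantile(pf, 1.0 - config.protected_fraction)
    concession = np.zeros(shape, dtype=bool)
    exclusions = {"water": water, "protected_area": protected,
                  "concession": concession}
    eligible = ~(water | protected | concession)

    if config.n_zones == 0:
        table = pd.DataFrame(columns=["zone_id", "est_year"]).astype(int)
        truth = GroundTruth(
            table=pd.DataFrame(
                columns=["zone_id", "est_year", "level_effect", "trend_effect"]
            ),
            labels=labels,
        )
        return (
            ZoneSet(table=table, labels=labels, exclusions=exclusions,
                    cell_size=panel.cell_size, origin=panel.origin),
            truth,
        )

    probs = placement_probabilities(config, surfaces, eligible)
    flat_probs = probs.ravel()
    placed = 0
    attempts = 0
    max_attempts = 30 * config.n_zones
    min_area = max(1, config.zone_target_area // 2)
    while placed < config.n_zones:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {config.n_zones} disjoint zones of "
                f"~{config.zone_target_area} pixels after {attempts - 1} attempts "
                f"({placed} placed); reduce n_zones or zone_target_area"
            )
        available = eligible & (labels < 0)
        p = np.where(available.ravel(), flat_probs, 0.0)
        total = p.sum()
        if total <= 0:
            raise GenerationError("eligible area exhausted during zone placement")
        idx = rng.choice(flat_probs.size, p=p / total)
        seed_pix = np.unravel_index(idx, shape)
        patch = _grow_zone(rng, tuple(map(int, seed_pix)), available,
                           config.zone_target_area)
        if len(patch) < min_area:
            continue
        rr = np.array([p_[0] for p_ in patch])
        cc = np.array([p_[1] for p_ in patch])
        labels[rr, cc] = placed
        placed += 1

    est_pool = np.tile(
        np.asarray(config.establishment_years, dtype=int),
        int(np.ceil(config.n_zones / len(config.establishment_years))),
    )[: config.n_zones]
    est_assigned = rng.permutation(est_pool)

    effects = [config.cohort_effects(int(y)) for y in est_assigned]
    table = pd.DataFrame(
        {"zone_id": np.arange(config.n_zones), "est_year": est_assigned}
    )
    truth = GroundTruth(
        table=table.assign(
            level_effect=[e[0] for e in effects],
            trend_effect=[e[1] for e in effects],
        ),
        labels=labels,
    )
    zones = ZoneSet(table=table, labels=labels, exclusions=exclusions,
                    cell_size=panel.cell_size, origin=panel.origin)
    return zones, truth


def inject_effect(
    panel: LandscapePanel,
    zones: ZoneSet,
    ground_truth: GroundTruth,
    protection_factor: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LandscapePanel:
    """Add the ground-truth effects to the latent canopy of zone pixels.

    For a pixel in a zone established in year y, every calendar year
    strictly after y gains level + trend * (year - y) TCC points on the
    latent (pre-clipping) value; year y itself is untouched, matching the
    intervention coding in which the establishment year is still
    pre-intervention. With ``protection_factor`` > 0, that fraction of
    post-establishment clearings inside zones is reverted (the reduced
    conversion hazard under community management).
    """
    sim: _SimState | None = getattr(panel, "_sim", None)
    if sim is None:
        raise SpatialReferenceError("panel lacks generator state; cannot inject")
    if zones.labels.shape != panel.shape:
        raise SpatialReferenceError("zone labels do not match the panel grid")
    known = set(zones.table["zone_id"].tolist())
    missing = set(ground_truth.table["zone_id"].tolist()) - known
    if missing:
        raise SpatialReferenceError(f"ground-truth zones missing from zone set: {missing}")

    years = panel.years
    shape = panel.shape
    effect = np.zeros((years.size,) + shape)
    cleared = sim.cleared_year.copy()
    if rng is None:
        rng = _stage_rng(sim.config.seed, "inject")
    for row in ground_truth.table.itertuples():
        mask = zones.labels == row.zone_id
        if not mask.any():
            continue
        est = int(row.est_year)
        for k, year in enumerate(years):
            if year > est:
                effect[k][mask] += row.level_effect + row.trend_effect * (year - est)
        if protection_factor > 0:
            hit = mask & (cleared > est)
            if hit.any():
                revert = hit & (rng.random(shape) < protection_factor)
                cleared[revert] = -1

    return _render_panel(replace(sim, cleared_year=cleared), effect)


def generate_scenario(config: ScenarioConfig):
    """Run the full generation chain: surfaces -> panel -> zones -> effects.

    Returns (surfaces, zones, ground_truth, panel) with effects applied.
    """
    surfaces = generate_surfaces(config)
    base_panel = simulate_panel(config, surfaces)
    zones, truth = place_zones(config, surfaces, base_panel)
    panel = inject_effect(
        base_panel, zones, truth,
        protection_factor=config.protection_factor,
        rng=_stage_rng(config.seed, "inject"),
    )
    return surfaces, zones, truth, panel
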