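"""Synthetic landscapes and partially migratory GPS tracks.

Generates raster landscapes (land cover, terrain, linear-feature densities,
wells, time-indexed NDVI and snow tiles) and movement tracks produced by a
habitat-biased step-selection kernel with known coefficients, so that every
downstream stage — migration classification, used-available design building,
model fitting, mapping, validation — can be exercised against ground truth.

Rasters are plain numpy grids on a shared extent; vectors are shapely
geometries.  All randomness flows through :func:`numpy.random.default_rng`
seeds, and identical configuration + seed reproduces bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from shapely.geometry import LineString, Point, Polygon, box, mapping

# Land-cover classification: 10 classes, code 0 (annual cropland) is the
# reference category everywhere downstream.
LANDCOVER_CLASSES = (
    "annual_cropland",
    "conifer",
    "deciduous",
    "developed",
    "exposed",
    "grassland",
    "pasture",
    "shrubland",
    "water",
    "wetland",
)
LANDCOVER_CODES = {name: code for code, name in enumerate(LANDCOVER_CLASSES)}

#: default class proportions for a prairie-steppe mosaic
DEFAULT_PROPORTIONS = {
    "annual_cropland": 0.15,
    "conifer": 0.02,
    "deciduous": 0.03,
    "developed": 0.02,
    "exposed": 0.05,
    "grassland": 0.40,
    "pasture": 0.15,
    "shrubland": 0.10,
    "water": 0.03,
    "wetland": 0.05,
}

NDVI_PERIOD_DAYS = 16.0
SNOW_PERIOD_DAYS = 8.0
SIM_EPOCH = np.datetime64("2008-01-01")


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    Distances are metres.  The default 100 m / 20x20 km grid keeps full runs
    at desk scale while preserving the structure of a 30 m landscape: several
    land-cover patches per home range, road/stream networks crossing the
    extent, and latitudinal phenology gradients.
    """

    resolution: float = 100.0
    width: float = 20_000.0
    height: float = 20_000.0
    x0: float = 0.0
    y0: float = 0.0
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    landcover_patch_scale: float = 800.0   # Gaussian smoothing length of the class field
    dem_relief: float = 150.0              # approximate elevation range
    dem_scale: float = 1_500.0             # horizontal correlation length of terrain
    n_paved_roads: int = 2
    n_unpaved_roads: int = 8
    n_streams: int = 5
    well_rate_per_km2: float = 0.15
    density_window_radius: float = 1_000.0  # circular window for density rasters
    n_days: float = 368.0                   # 23 NDVI tiles x 16 d = 46 snow tiles x 8 d
    ndvi_peak_day_south: float = 170.0
    ndvi_peak_lag_north: float = 30.0       # later green-up peak in the north
    snow_onset_day_south: float = 320.0
    snow_onset_advance_north: float = 25.0  # earlier fall snow onset in the north


@dataclass
class Landscape:
    """Raster covariate stack + vector features on one shared grid.

    Rasters are ``(ny, nx)`` arrays; row ``i``/col ``j`` has centre
    ``(x0 + (j + .5) dx, y0 + (i + .5) dx)`` so row 0 is the southern edge.
    """

    resolution: float
    x0: float
    y0: float
    landcover: np.ndarray          # int codes 0..9
    dem: np.ndarray
    slope: np.ndarray              # degrees
    aspect_southness: np.ndarray   # degrees from south, 0..180
    vrm: np.ndarray                # 0..1
    paved_road_density: np.ndarray     # m / m^2
    unpaved_road_density: np.ndarray   # m / m^2
    stream_density: np.ndarray         # m / m^2
    well_density: np.ndarray           # wells / m^2
    wells: pd.DataFrame            # columns x, y, spud_day
    ndvi_tiles: list               # [(start_day, end_day, raster)]
    snow_tiles: list               # [(start_day, end_day, raster)] binary
    study_area: Polygon
    paved_roads: list = field(default_factory=list)    # shapely LineStrings
    unpaved_roads: list = field(default_factory=list)
    streams: list = field(default_factory=list)

    @property
    def shape(self):
        return self.landcover.shape

    @property
    def extent(self):
        ny, nx = self.shape
        return (self.x0, self.y0,
                self.x0 + nx * self.resolution, self.y0 + ny * self.resolution)

    @property
    def diagonal(self) -> float:
        x0, y0, x1, y1 = self.extent
        return float(np.hypot(x1 - x0, y1 - y0))

    def cell_index(self, x, y):
        """Nearest-cell (row, col) indices, clipped to the grid."""
        ny, nx = self.shape
        j = np.clip(((np.asarray(x) - self.x0) / self.resolution).astype(int), 0, nx - 1)
        i = np.clip(((np.asarray(y) - self.y0) / self.resolution).astype(int), 0, ny - 1)
        return i, j

    def sample(self, raster: np.ndarray, x, y):
        i, j = self.cell_index(x, y)
        return raster[i, j]

    def contains(self, x, y):
        """Vectorised point-in-study-area test (rectangular fast path)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        minx, miny, maxx, maxy = self.study_area.bounds
        inside = (x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy)
        if self.study_area.equals(box(*self.study_area.bounds)):
            return inside
        out = np.zeros(np.shape(x), dtype=bool)
        flat = inside.ravel()
        xf, yf = x.ravel(), y.ravel()
        for k in np.nonzero(flat)[0]:
            out.ravel()[k] = self.study_area.contains(Point(xf[k], yf[k]))
        return out

    def continuous_raster_names(self):
        return ["slope", "aspect_southness", "vrm", "stream_density",
                "paved_road_density", "unpaved_road_density", "well_density"]

    def raster(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class StepKernel:
    """Gamma step lengths and von Mises turn angles of the movement model."""

    gamma_shape: float = 2.0
    gamma_scale: float = 150.0     # metres; mean step = shape * scale
    vonmises_kappa: float = 0.8

    def draw(self, rng: np.random.Generator, n: int):
        lengths = rng.gamma(self.gamma_shape, self.gamma_scale, size=n)
        turns = rng.vonmises(0.0, self.vonmises_kappa, size=n)
        return lengths, turns


@dataclass
class SimulationTruth:
    """Ground truth stored verbatim alongside generated tracks.

    ``beta_true`` is expressed on the landscape-standardised covariate scale
    (continuous rasters z-scored by their landscape-wide mean/SD; land-cover
    indicators raw 0/1), which is the scale a fit standardised with the same
    statistics estimates.
    """

    beta_true: dict
    population_mix: dict = field(default_factory=lambda: {
        "migratory": 0.5, "mixed_migratory": 0.1, "resident": 0.4})
    step_kernel: StepKernel = field(default_factory=StepKernel)
    directional_bias: float = 1.5       # heading-error weight during migration
    homing_bias: float = 1.2            # pull back toward the active range centre
    home_range_radius: float = 500.0    # metres; no homing inside this radius
    spring_start_day: float = 81.0      # ~March 22
    fall_start_day: float = 305.0       # ~November 1
    start_day_sd: float = 4.0
    stopover_prob: float = 0.0          # per-step chance of starting a stopover
    stopover_steps: int = 12
    migration_distance: float = 10_000.0
    seed: int = 0
    individuals: list = field(default_factory=list)
    covariate_stats: dict = field(default_factory=dict)

    def validate(self):
        total = sum(self.population_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population_mix must sum to 1, got {total}")


@dataclass
class Track:
    """One individual's ordered GPS relocations."""

    individual_id: str
    t: np.ndarray              # days since epoch, strictly increasing
    x: np.ndarray
    y: np.ndarray
    fix_interval: float        # hours
    epoch: np.datetime64 = SIM_EPOCH

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) < 2:
            raise ValueError("a Track needs at least 2 fixes")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.t)

    @property
    def timestamps(self):
        return self.epoch + (self.t * 86_400.0).astype("timedelta64[s]")


# --------------------------------------------------------------------------
# landscape generation
# --------------------------------------------------------------------------

def _smooth_field(rng, shape, sigma_px):
    """Standardised Gaussian random field via kernel-smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="reflect")
    return (f - f.mean()) / f.std()


def _random_polyline(rng, cfg: LandscapeConfig) -> LineString:
    """A wobbly polyline crossing the extent, entering from a random edge."""
    w, h = cfg.width, cfg.height
    edge = rng.integers(4)
    if edge == 0:     # west, heading east
        start = np.array([cfg.x0, cfg.y0 + rng.uniform(0.1, 0.9) * h]); heading = 0.0
    elif edge == 1:   # east
        start = np.array([cfg.x0 + w, cfg.y0 + rng.uniform(0.1, 0.9) * h]); heading = np.pi
    elif edge == 2:   # south, heading north
        start = np.array([cfg.x0 + rng.uniform(0.1, 0.9) * w, cfg.y0]); heading = np.pi / 2
    else:             # north
        start = np.array([cfg.x0 + rng.uniform(0.1, 0.9) * w, cfg.y0 + h]); heading = -np.pi / 2
    step = 4.0 * cfg.resolution
    pts = [start.copy()]
    pos = start.copy()
    for _ in range(int(3 * (w + h) / step)):
        heading += rng.normal(0.0, 0.25)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pts.append(pos.copy())
        if not (cfg.x0 - step <= pos[0] <= cfg.x0 + w + step
                and cfg.y0 - step <= pos[1] <= cfg.y0 + h + step):
            break
    line = LineString(pts)
    return line.intersection(box(cfg.x0, cfg.y0, cfg.x0 + w, cfg.y0 + h))


def _rasterize_line_length(lines, cfg: LandscapeConfig, shape):
    """Per-pixel total polyline length (metres) by dense point sampling."""
    ny, nx = shape
    length = np.zeros(shape)
    ds = cfg.resolution / 4.0
    for geom in lines:
        if geom.is_empty:
            continue
        parts = geom.geoms if geom.geom_type.startswith("Multi") else [geom]
        for line in parts:
            if line.length <= 0 or line.geom_type != "LineString":
                continue
            n = max(int(np.ceil(line.length / ds)), 1)
            d = (np.arange(n) + 0.5) * line.length / n
            pts = [line.interpolate(di) for di in d]
            xs = np.array([p.x for p in pts])
            ys = np.array([p.y for p in pts])
            j = np.clip(((xs - cfg.x0) / cfg.resolution).astype(int), 0, nx - 1)
            i = np.clip(((ys - cfg.y0) / cfg.resolution).astype(int), 0, ny - 1)
            np.add.at(length, (i, j), line.length / n)
    return length


def _disc_kernel(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2 <= radius_px ** 2).astype(float)


def _window_density_raster(per_pixel_amount, cfg: LandscapeConfig):
    """Circular moving-window density with edge-truncated window areas."""
    kernel = _disc_kernel(cfg.density_window_radius / cfg.resolution)
    total = signal.fftconvolve(per_pixel_amount, kernel, mode="same")
    # area of the part of the window that lies inside the extent
    coverage = signal.fftconvolve(np.ones_like(per_pixel_amount), kernel, mode="same")
    area = np.maximum(coverage, 1.0) * cfg.resolution ** 2
    return np.maximum(total, 0.0) / area


def _terrain(dem, resolution):
    """Slope (deg), aspect-southness (deg from south) and 3x3 VRM.

    VRM follows the resultant-vector method: decompose each cell's unit
    surface-normal into (x, y, z) components from slope and aspect, sum them
    over the 3x3 neighbourhood, and take 1 - |resultant| / n.
    """
    dzdy, dzdx = np.gradient(dem, resolution)
    slope_rad = np.arctan(np.hypot(dzdx, dzdy))
    slope = np.degrees(slope_rad)
    # downslope-facing direction, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = np.hypot(dzdx, dzdy) < 1e-12
    southness = np.abs(aspect - 180.0)
    southness[flat] = 90.0  # undefined aspect -> neutral
    xn = np.sin(slope_rad) * np.sin(np.radians(aspect))
    yn = np.sin(slope_rad) * np.cos(np.radians(aspect))
    zn = np.cos(slope_rad)
    n = 9.0
    sx = ndimage.uniform_filter(xn, 3, mode="nearest") * n
    sy = ndimage.uniform_filter(yn, 3, mode="nearest") * n
    sz = ndimage.uniform_filter(zn, 3, mode="nearest") * n
    vrm = 1.0 - np.sqrt(sx ** 2 + sy ** 2 + sz ** 2) / n
    return slope, southness, np.clip(vrm, 0.0, 1.0)


def generate_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> Landscape:
    """Generate a complete synthetic landscape.

    Land cover comes from one smoothed Gaussian field thresholded at the
    quantiles implied by the requested class proportions, which realises the
    proportions almost exactly.  Terrain, linear features, wells and the
    phenology tiles follow the conventions documented in the module docstring.

    Raises ``ValueError`` if the class proportions do not sum to 1.
    """
    cfg = config or LandscapeConfig()
    props = cfg.proportions
    if abs(sum(props.values()) - 1.0) > 1e-6:
        raise ValueError(f"land-cover proportions must sum to 1, got {sum(props.values()):.4f}")
    unknown = set(props) - set(LANDCOVER_CLASSES)
    if unknown:
        raise ValueError(f"unknown land-cover classes: {sorted(unknown)}")
    ny = int(round(cfg.height / cfg.resolution))
    nx = int(round(cfg.width / cfg.resolution))
    if ny < 50 or nx < 50:
        raise ValueError(f"grid must be at least 50x50 cells, got {ny}x{nx}")
    rng = np.random.default_rng(seed)

    # --- land cover: quantile-thresholded smooth field -------------------
    fieldv = _smooth_field(rng, (ny, nx), cfg.landcover_patch_scale / cfg.resolution)
    classes = [c for c in LANDCOVER_CLASSES if props.get(c, 0.0) > 0.0]
    cum = np.cumsum([props[c] for c in classes])
    thresholds = np.quantile(fieldv, np.clip(cum[:-1], 0.0, 1.0))
    landcover = np.full((ny, nx), LANDCOVER_CODES[classes[-1]], dtype=np.int16)
    prev = -np.inf
    for cls, thr in zip(classes[:-1], thresholds):
        mask = (fieldv > prev) & (fieldv <= thr)
        landcover[mask] = LANDCOVER_CODES[cls]
        prev = thr

    # --- terrain ---------------------------------------------------------
    dem = (cfg.dem_relief / 2.0) * (
        _smooth_field(rng, (ny, nx), cfg.dem_scale / cfg.resolution)
        + 0.35 * _smooth_field(rng, (ny, nx), cfg.dem_scale / (4 * cfg.resolution)))
    slope, southness, vrm = _terrain(dem, cfg.resolution)

    # --- linear features and densities -----------------------------------
    paved = [_random_polyline(rng, cfg) for _ in range(cfg.n_paved_roads)]
    unpaved = [_random_polyline(rng, cfg) for _ in range(cfg.n_unpaved_roads)]
    streams = [_random_polyline(rng, cfg) for _ in range(cfg.n_streams)]
    paved_d = _window_density_raster(_rasterize_line_length(paved, cfg, (ny, nx)), cfg)
    unpaved_d = _window_density_raster(_rasterize_line_length(unpaved, cfg, (ny, nx)), cfg)
    stream_d = _window_density_raster(_rasterize_line_length(streams, cfg, (ny, nx)), cfg)

    # --- wells: Poisson point process, uniform spud dates -----------------
    area_km2 = cfg.width * cfg.height / 1e6
    n_wells = rng.poisson(cfg.well_rate_per_km2 * area_km2)
    wells = pd.DataFrame({
        "x": cfg.x0 + rng.uniform(0, cfg.width, n_wells),
        "y": cfg.y0 + rng.uniform(0, cfg.height, n_wells),
        "spud_day": rng.uniform(0.0, cfg.n_days, n_wells),
    })
    well_px = np.zeros((ny, nx))
    if n_wells:
        i = np.clip(((wells.y.to_numpy() - cfg.y0) / cfg.resolution).astype(int), 0, ny - 1)
        j = np.clip(((wells.x.to_numpy() - cfg.x0) / cfg.resolution).astype(int), 0, nx - 1)
        np.add.at(well_px, (i, j), 1.0)
    well_d = _window_density_raster(well_px, cfg)

    # --- NDVI: south-to-north green-up, peaking mid-summer ----------------
    northness = ((np.arange(ny) + 0.5) / ny)[:, None] * np.ones((1, nx))
    greenness = 0.15 * _smooth_field(rng, (ny, nx), 10)
    peak_day = cfg.ndvi_peak_day_south + cfg.ndvi_peak_lag_north * northness
    ndvi_tiles = []
    t0 = 0.0
    while t0 < cfg.n_days - 1e-9:
        t1 = min(t0 + NDVI_PERIOD_DAYS, cfg.n_days)
        mid = 0.5 * (t0 + t1)
        seasonal = 0.55 * np.exp(-0.5 * ((mid - peak_day) / 55.0) ** 2)
        ndvi_tiles.append((t0, t1, np.clip(0.12 + greenness + seasonal, -1.0, 1.0)))
        t0 = t1

    # --- snow: north-biased fall onset, spring melt -----------------------
    patchiness = 6.0 * _smooth_field(rng, (ny, nx), 8)
    onset = cfg.snow_onset_day_south - cfg.snow_onset_advance_north * northness + patchiness
    melt = 85.0 + 20.0 * northness + patchiness
    snow_tiles = []
    t0 = 0.0
    while t0 < cfg.n_days - 1e-9:
        t1 = min(t0 + SNOW_PERIOD_DAYS, cfg.n_days)
        mid = 0.5 * (t0 + t1)
        snow_tiles.append((t0, t1, ((mid < melt) | (mid > onset)).astype(np.int8)))
        t0 = t1

    return Landscape(
        resolution=cfg.resolution, x0=cfg.x0, y0=cfg.y0,
        landcover=landcover, dem=dem, slope=slope, aspect_southness=southness,
        vrm=vrm, paved_road_density=paved_d, unpaved_road_density=unpaved_d,
        stream_density=stream_d, well_density=well_d, wells=wells,
        ndvi_tiles=ndvi_tiles, snow_tiles=snow_tiles,
        study_area=box(cfg.x0, cfg.y0, cfg.x0 + cfg.width, cfg.y0 + cfg.height),
        paved_roads=paved, unpaved_roads=unpaved, streams=streams,
    )


# --------------------------------------------------------------------------
# movement simulation
# --------------------------------------------------------------------------

def landscape_covariate_stats(landscape: Landscape) -> dict:
    """Landscape-wide mean/SD of each continuous raster (z-scoring reference)."""
    stats = {}
    for name in landscape.continuous_raster_names():
        r = landscape.raster(name)
        stats[name] = (float(r.mean()), float(r.std()))
    return stats


def _candidate_log_weights(landscape, stats, beta_true, x, y):
    """log habitat weight beta_true . z(x) at candidate endpoints."""
    lw = np.zeros(np.shape(x), dtype=float)
    if not beta_true:
        return lw
    lc = None
    for name, beta in beta_true.items():
        if beta == 0.0:
            continue
        if name in LANDCOVER_CODES:
            if lc is None:
                lc = landscape.sample(landscape.landcover, x, y)
            lw += beta * (lc == LANDCOVER_CODES[name])
        else:
            mean, sd = stats[name]
            vals = landscape.sample(landscape.raster(name), x, y)
            lw += beta * (vals - mean) / (sd if sd > 0 else 1.0)
    return lw


def make_population(truth: SimulationTruth, landscape: Landscape,
                    n_individuals: int, rng: np.random.Generator) -> list:
    """Assign status, seasonal range centres and switch dates per individual."""
    truth.validate()
    statuses = rng.choice(
        list(truth.population_mix.keys()),
        size=n_individuals,
        p=list(truth.population_mix.values()),
    )
    minx, miny, maxx, maxy = landscape.study_area.bounds
    margin = 0.1 * min(maxx - minx, maxy - miny)
    # migration distance capped so both seasonal ranges fit the study area
    d = min(truth.migration_distance, 0.85 * (maxy - miny - 2 * margin))
    individuals = []
    for k, status in enumerate(statuses):
        wx = rng.uniform(minx + margin, maxx - margin)
        wy = rng.uniform(miny + margin, max(maxy - margin - d, miny + margin + 1.0)
                         if status != "resident" else maxy - margin)
        winter = (wx, max(wy, miny + margin))
        angle = rng.uniform(np.radians(60), np.radians(120))  # roughly northward
        summer = (winter[0] + d * np.cos(angle), winter[1] + d * np.sin(angle))
        summer = (float(np.clip(summer[0], minx + margin, maxx - margin)),
                  float(np.clip(summer[1], miny + margin, maxy - margin)))
        alt = (float(np.clip(winter[0] + rng.uniform(-4000, 4000), minx + margin, maxx - margin)),
               float(np.clip(winter[1] + rng.uniform(-2000, 2000), miny + margin, maxy - margin)))
        individuals.append({
            "id": f"ind{k:03d}",
            "status": str(status),
            "winter_center": winter,
            "summer_center": summer,
            "alt_winter_center": alt if status == "mixed_migratory" else winter,
            "spring_day": float(truth.spring_start_day + rng.normal(0, truth.start_day_sd)),
            "fall_day": float(truth.fall_start_day + rng.normal(0, truth.start_day_sd)),
        })
    return individuals


def _simulate_one(landscape, truth, ind, fix_interval, t_start, t_end, K, rng):
    stats = truth.covariate_stats
    kernel = truth.step_kernel
    dt = fix_interval / 24.0
    # strictly before t_end so every fix falls inside the half-open tiling
    times = np.arange(t_start, t_end - 1e-9, dt)
    n = len(times)
    xs = np.empty(n)
    ys = np.empty(n)
    pos = np.array(ind["winter_center"], dtype=float)
    xs[0], ys[0] = pos
    heading = rng.uniform(-np.pi, np.pi)
    migratory = ind["status"] in ("migratory", "mixed_migratory")
    phase = "winter"
    stopover_left = 0
    for step in range(1, n):
        t = times[step]
        if migratory:
            if phase == "winter" and t >= ind["spring_day"]:
                phase = "spring"
            elif phase == "summer" and t >= ind["fall_day"]:
                phase = "fall"
        if phase == "spring":
            target = np.array(ind["summer_center"])
            if np.hypot(*(pos - target)) < 1.2 * truth.home_range_radius:
                phase = "summer"
        elif phase == "fall":
            target = np.array(ind["alt_winter_center"])
            if np.hypot(*(pos - target)) < 1.2 * truth.home_range_radius:
                phase = "winter2"
        if phase in ("winter", "winter2"):
            center = np.array(ind["alt_winter_center"] if phase == "winter2"
                              else ind["winter_center"])
        elif phase == "summer":
            center = np.array(ind["summer_center"])
        lengths, turns = kernel.draw(rng, K)
        if stopover_left > 0:
            lengths = lengths * 0.08
            stopover_left -= 1
        elif (phase in ("spring", "fall") and truth.stopover_prob > 0.0
              and rng.random() < truth.stopover_prob):
            stopover_left = truth.stopover_steps
            lengths = lengths * 0.08
        headings = heading + turns
        cx = pos[0] + lengths * np.cos(headings)
        cy = pos[1] + lengths * np.sin(headings)
        logw = _candidate_log_weights(landscape, stats, truth.beta_true, cx, cy)
        if phase in ("spring", "fall"):
            err = np.arctan2(target[1] - pos[1], target[0] - pos[0]) - headings
            logw = logw + truth.directional_bias * np.cos(err)
        else:
            dist = np.hypot(pos[0] - center[0], pos[1] - center[1])
            pull = np.clip((dist - truth.home_range_radius) / truth.home_range_radius, 0.0, 3.0)
            err = np.arctan2(center[1] - pos[1], center[0] - pos[0]) - headings
            logw = logw + truth.homing_bias * pull * np.cos(err)
        inside = landscape.contains(cx, cy)
        if not inside.any():
            # all candidates left the study area: step straight toward centre
            xs[step], ys[step] = pos
            heading = np.arctan2(center[1] - pos[1], center[0] - pos[0])
            continue
        logw = np.where(inside, logw, -np.inf)
        p = np.exp(logw - logw.max())
        p /= p.sum()
        k = rng.choice(K, p=p)
        pos = np.array([cx[k], cy[k]])
        heading = headings[k]
        xs[step], ys[step] = pos
    return Track(individual_id=ind["id"], t=times, x=xs, y=ys, fix_interval=fix_interval)


def simulate_tracks(landscape: Landscape, truth: SimulationTruth,
                    n_individuals: int, fix_interval: float = 4.0,
                    t_start: float = 0.0, t_end: float | None = None,
                    n_candidates: int = 50,
                    seed: int | None = None) -> list[Track]:
    """Simulate a partially migratory population by biased step selection.

    Each realised step is chosen among ``n_candidates`` candidate steps drawn
    from the gamma/von Mises kernel, with probability proportional to
    ``exp(beta_true . z + bias * cos(heading error))``.  Residents home on one
    range centre; migratory individuals switch to a directed phase toward the
    other seasonal centre on their configured dates; mixed-migratory
    individuals return to a different wintering location in fall.
    """
    if fix_interval not in (2.0, 4.0, 2, 4):
        raise ValueError("fix_interval must be 2 or 4 hours")
    if n_individuals < 0:
        raise ValueError("n_individuals must be >= 0")
    if n_individuals == 0:
        return []
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if not truth.covariate_stats:
        truth.covariate_stats = landscape_covariate_stats(landscape)
    if not truth.individuals:
        truth.individuals = make_population(truth, landscape, n_individuals, rng)
    for ind in truth.individuals:
        for key in ("winter_center", "summer_center", "alt_winter_center"):
            px, py = ind[key]
            if not landscape.contains(px, py):
                raise ValueError(f"{ind['id']}: {key} lies outside the study area")
    if t_end is None:
        t_end = float(len(landscape.ndvi_tiles) * NDVI_PERIOD_DAYS)
    tracks = []
    for ind in truth.individuals[:n_individuals]:
        tracks.append(_simulate_one(landscape, truth, ind, float(fix_interval),
                                    t_start, t_end, n_candidates, rng))
    return tracks


# --------------------------------------------------------------------------
# design-level simulators for estimator parameter recovery
# --------------------------------------------------------------------------

def simulate_choice_strata(landscape: Landscape, beta_true: dict,
                           n_strata: int, rng: np.random.Generator,
                           kernel: StepKernel | None = None,
                           n_candidates: int = 50, n_available: int = 5):
    """Matched used/available strata drawn exactly from the SSF choice model.

    For each stratum a start point is placed uniformly in the study area, the
    used endpoint is sampled among ``n_candidates`` kernel draws with
    probability proportional to ``exp(beta_true . z)``, and ``n_available``
    availability endpoints are fresh kernel draws.  Returns ``(X, names)``
    where ``X`` has shape ``(n_strata, 1 + n_available, p)`` with the used
    point first, on the same standardised scale as ``beta_true``.
    """
    kernel = kernel or StepKernel()
    stats = landscape_covariate_stats(landscape)
    names = list(beta_true.keys())
    minx, miny, maxx, maxy = landscape.study_area.bounds
    margin = 2_000.0
    sx = rng.uniform(minx + margin, maxx - margin, n_strata)
    sy = rng.uniform(miny + margin, maxy - margin, n_strata)

    def covs(px, py):
        cols = []
        for name in names:
            if name in LANDCOVER_CODES:
                cols.append((landscape.sample(landscape.landcover, px, py)
                             == LANDCOVER_CODES[name]).astype(float))
            else:
                mean, sd = stats[name]
                cols.append((landscape.sample(landscape.raster(name), px, py) - mean)
                            / (sd if sd > 0 else 1.0))
        return np.stack(cols, axis=-1)

    def endpoints(n_each):
        lengths = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, (n_strata, n_each))
        angles = rng.uniform(-np.pi, np.pi, (n_strata, n_each))
        return (sx[:, None] + lengths * np.cos(angles),
                sy[:, None] + lengths * np.sin(angles))

    cxx, cyy = endpoints(n_candidates)
    Xc = covs(cxx, cyy)                              # (S, K, p)
    beta = np.array([beta_true[n] for n in names])
    logw = Xc @ beta
    p = np.exp(logw - logw.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    used_idx = np.array([rng.choice(n_candidates, p=pi) for pi in p])
    X_used = Xc[np.arange(n_strata), used_idx]       # (S, p)
    axx, ayy = endpoints(n_available)
    X_avail = covs(axx, ayy)                          # (S, A, p)
    X = np.concatenate([X_used[:, None, :], X_avail], axis=1)
    return X, names


def simulate_binary_panel(beta: np.ndarray, intercept: float, sigma: float,
                          n_groups: int, n_per_group: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Grouped logistic data with a Normal(0, sigma^2) random intercept."""
    p = len(beta)
    rows = n_groups * n_per_group
    X = rng.standard_normal((rows, p))
    groups = np.repeat(np.arange(n_groups), n_per_group)
    b = rng.normal(0.0, sigma, n_groups)
    eta = intercept + b[groups] + X @ np.asarray(beta)
    y = (rng.random(rows) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    df["used"] = y
    df["individual_id"] = [f"g{g:03d}" for g in groups]
    return df


# --------------------------------------------------------------------------
# plain-text I/O (ESRI ASCII grid, GeoJSON, CSV, JSON)
# --------------------------------------------------------------------------

def write_ascii_grid(path, raster: np.ndarray, x0: float, y0: float, resolution: float):
    """Write a raster as an ESRI ASCII grid (text; row order north-to-south)."""
    ny, nx = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\nxllcorner {x0}\nyllcorner {y0}\n"
                 f"cellsize {resolution}\nNODATA_value -9999\n")
        for row in raster[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (raster, x0, y0, resolution)."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    raster = np.atleast_2d(data)[::-1]
    return raster, header["xllcorner"], header["yllcorner"], header["cellsize"]


def write_tracks_csv(path, tracks: list[Track]):
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "id": tr.individual_id,
            "timestamp": pd.to_datetime(tr.timestamps).strftime("%Y-%m-%dT%H:%M:%S"),
            "x": tr.x, "y": tr.y,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path, fix_interval: float = 4.0,
                    epoch: np.datetime64 = SIM_EPOCH) -> list[Track]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    tracks = []
    for tid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("timestamp")
        t = (grp.timestamp.to_numpy() - epoch) / np.timedelta64(1, "D")
        tracks.append(Track(str(tid), t, grp.x.to_numpy(), grp.y.to_numpy(),
                            fix_interval, epoch))
    return tracks


def write_landscape(outdir, landscape: Landscape):
    """Dump all rasters as ASCII grids and vectors/wells as GeoJSON/CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grids = {"landcover": landscape.landcover.astype(float), "dem": landscape.dem,
             "slope": landscape.slope, "aspect_southness": landscape.aspect_southness,
             "vrm": landscape.vrm}
    for name in landscape.continuous_raster_names():
        grids[name] = landscape.raster(name)
    for name, raster in grids.items():
        write_ascii_grid(outdir / f"{name}.asc", raster,
                         landscape.x0, landscape.y0, landscape.resolution)
    for label, lines in (("paved_roads", landscape.paved_roads),
                         ("unpaved_roads", landscape.unpaved_roads),
                         ("streams", landscape.streams)):
        features = [{"type": "Feature", "properties": {}, "geometry": mapping(g)}
                    for g in lines if not g.is_empty]
        (outdir / f"{label}.geojson").write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}))
    landscape.wells.to_csv(outdir / "wells.csv", index=False)
    (outdir / "study_area.geojson").write_text(json.dumps(mapping(landscape.study_area)))


def write_truth(path, truth: SimulationTruth):
    payload = dataclasses.asdict(truth)
    payload["step_kernel"] = dataclasses.asdict(truth.step_kernel)
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
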