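"""Covariate attachment: rasters, windowed densities, time-matched tiles.

Builds the design matrix used by both selection models: land-cover one-hot
indicators (annual cropland is the omitted reference), time-matched NDVI and
snow, terrain (slope + slope^2, aspect-southness, VRM), stream/road/well
densities (unpaved roads with a quadratic), and the distance to the nearest
well actively being drilled within a 16-day window of the location's
timestamp.  Continuous covariates are centred and standardised per order and
season; quadratic columns are exact squares of their standardised linear
partners, so the hierarchy is preserved in model building.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .synthetic import LANDCOVER_CLASSES, Landscape

DRILLING_WINDOW_DAYS = 16.0
DEFAULT_DENSITY_RADIUS = 1000.0

#: land-cover indicator columns (class 0, annual cropland, omitted)
LANDCOVER_COLUMNS = [f"lc_{name}" for name in LANDCOVER_CLASSES[1:]]

#: continuous covariates in design-matrix order
CONTINUOUS_COLUMNS = [
    "ndvi", "snow", "slope", "aspect_southness", "vrm",
    "stream_density", "paved_road_density", "unpaved_road_density",
    "well_density", "dist_active_drilling",
]

#: quadratic terms: column -> linear partner (squares of standardised columns)
QUADRATIC_PARTNERS = {
    "slope_sq": "slope",
    "unpaved_road_density_sq": "unpaved_road_density",
}

#: model terms: name -> columns; 'landcover' is a block tested jointly
TERM_COLUMNS = {"landcover": LANDCOVER_COLUMNS,
                **{c: [c] for c in CONTINUOUS_COLUMNS},
                **{q: [q] for q in QUADRATIC_PARTNERS}}


@dataclass
class DesignMatrix:
    """Standardised covariates aligned to design points.

    ``df`` holds metadata columns (point/stratum/individual ids, role, order,
    weight, coordinates, timestamp), the standardised covariate columns, and
    raw copies of the continuous covariates (``raw_`` prefix) from which the
    clamp bounds derive.
    """

    df: pd.DataFrame
    order: int
    season: str
    stats: dict = field(default_factory=dict)        # col -> (mean, sd)
    clamp_bounds: dict = field(default_factory=dict)  # col -> (min, max), raw scale
    dropped: list = field(default_factory=list)
    density_radius: float = DEFAULT_DENSITY_RADIUS
    drilling_cap: float = 0.0

    @property
    def feature_columns(self):
        cols = [c for c in LANDCOVER_COLUMNS if c in self.df.columns]
        cols += [c for c in CONTINUOUS_COLUMNS if c in self.df.columns]
        cols += [c for c in QUADRATIC_PARTNERS if c in self.df.columns]
        return cols

    @property
    def outcome(self):
        return (self.df["role"] == "used").astype(int).to_numpy()

    @property
    def weights(self):
        return self.df["weight"].to_numpy(dtype=float)

    def terms(self):
        """Term names available in this matrix (landcover as one block)."""
        out = []
        if any(c in self.df.columns for c in LANDCOVER_COLUMNS):
            out.append("landcover")
        out += [c for c in CONTINUOUS_COLUMNS if c in self.df.columns]
        out += [q for q in QUADRATIC_PARTNERS if q in self.df.columns]
        return out

    def columns_for(self, term_names):
        cols = []
        for t in term_names:
            # unknown names pass through as single columns (custom designs)
            cols.extend(c for c in TERM_COLUMNS.get(t, [t]) if c in self.df.columns)
        return cols


# --------------------------------------------------------------------------
# primitive operators
# --------------------------------------------------------------------------

def window_density(features, center, radius: float,
                   kind: str = "line") -> float:
    """Feature density in a circular window: m/m^2 (lines) or count/m^2 (points).

    ``features`` is an iterable of shapely geometries (or an ``(n, 2)`` array
    for points).  Line features are clipped to the window; the density is the
    clipped length (or point count) divided by the window area.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    area = np.pi * radius ** 2
    cx, cy = center
    if kind == "point":
        pts = np.asarray(features, dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            return 0.0
        d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        return float(np.count_nonzero(d2 <= radius ** 2)) / area
    window = Point(cx, cy).buffer(radius, quad_segs=64)
    total = 0.0
    for geom in features:
        if geom.is_empty:
            continue
        total += geom.intersection(window).length
    return total / area


def match_tile(tiles, day: float):
    """The tile whose half-open interval [start, end) contains ``day``."""
    for start, end, raster in tiles:
        if start <= day < end:
            return raster
    raise ValueError(f"day {day} is outside the tiled period")


def match_tile_index(tiles, day: float) -> int:
    for k, (start, end, _) in enumerate(tiles):
        if start <= day < end:
            return k
    raise ValueError(f"day {day} is outside the tiled period")


def dist_active_drilling(x, y, day, wells: pd.DataFrame, cap: float,
                         window_days: float = DRILLING_WINDOW_DAYS):
    """Distance (m) to the nearest well being drilled within the time window.

    A well is active when ``|spud_day - day| <= window_days``.  With no
    active well the configured cap is returned (default: the study-area
    diagonal, the neutral no-drilling state used for prediction maps).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    day = np.broadcast_to(np.atleast_1d(np.asarray(day, dtype=float)), x.shape)
    out = np.full(x.shape, cap, dtype=float)
    if wells is not None and len(wells):
        wx = wells["x"].to_numpy()
        wy = wells["y"].to_numpy()
        ws = wells["spud_day"].to_numpy()
        for k in range(len(x)):
            active = np.abs(ws - day[k]) <= window_days
            if active.any():
                d = np.hypot(wx[active] - x[k], wy[active] - y[k])
                out[k] = min(d.min(), cap)
    return out if out.size > 1 else float(out[0])


# --------------------------------------------------------------------------
# extraction
# --------------------------------------------------------------------------

def _raw_covariates(points: pd.DataFrame, landscape: Landscape,
                    wells, drilling_cap: float) -> pd.DataFrame:
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    t = points["t"].to_numpy(dtype=float)
    minx, miny, maxx, maxy = landscape.extent
    bad = ~((x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy))
    if bad.any():
        ids = points.loc[bad, "point_id"].tolist()[:5]
        raise ValueError(f"{bad.sum()} points outside the landscape extent, e.g. {ids}")
    out = {}
    lc = landscape.sample(landscape.landcover, x, y)
    for code, name in enumerate(LANDCOVER_CLASSES):
        if code == 0:
            continue  # annual cropland is the reference category
        out[f"lc_{name}"] = (lc == code).astype(float)
    for name in ("slope", "aspect_southness", "vrm", "stream_density",
                 "paved_road_density", "unpaved_road_density", "well_density"):
        out[name] = landscape.sample(landscape.raster(name), x, y).astype(float)
    ndvi_idx = np.array([match_tile_index(landscape.ndvi_tiles, ti) for ti in t])
    snow_idx = np.array([match_tile_index(landscape.snow_tiles, ti) for ti in t])
    i, j = landscape.cell_index(x, y)
    out["ndvi"] = np.array([landscape.ndvi_tiles[k][2][ii, jj]
                            for k, ii, jj in zip(ndvi_idx, i, j)], dtype=float)
    out["snow"] = np.array([landscape.snow_tiles[k][2][ii, jj]
                            for k, ii, jj in zip(snow_idx, i, j)], dtype=float)
    out["dist_active_drilling"] = np.atleast_1d(
        dist_active_drilling(x, y, t, wells, drilling_cap))
    return pd.DataFrame(out, index=points.index)


def extract(points: pd.DataFrame, landscape: Landscape,
            wells: pd.DataFrame | None = None,
            order: int = 3, season: str = "spring",
            reference_stats: dict | None = None,
            drilling_cap: float | None = None) -> DesignMatrix:
    """Attach all covariates to design points and standardise.

    ``points`` needs columns ``point_id, role, weight, x, y, t`` (plus ids).
    Raster covariates are nearest-cell lookups; NDVI/snow come from the tile
    covering each point's timestamp; drilling distance uses the 16-day active
    window.  Standardisation statistics are computed from these rows unless
    ``reference_stats`` is given (prediction time).  Quadratic terms are
    squares of the standardised linear columns.
    """
    wells = wells if wells is not None else landscape.wells
    cap = drilling_cap if drilling_cap is not None else landscape.diagonal
    raw = _raw_covariates(points, landscape, wells, cap)
    dm = DesignMatrix(df=points.copy(), order=order, season=season,
                      drilling_cap=cap)
    for col in LANDCOVER_COLUMNS:
        dm.df[col] = raw[col].to_numpy()
    for col in CONTINUOUS_COLUMNS:
        dm.df["raw_" + col] = raw[col].to_numpy()
        dm.clamp_bounds[col] = (float(raw[col].min()), float(raw[col].max()))
    standardize(dm, reference_stats)
    return dm


def standardize(matrix: DesignMatrix, reference_stats: dict | None = None) -> DesignMatrix:
    """Centre/scale continuous columns; build quadratic columns.

    Uses population SD (divisor n).  With ``reference_stats`` given, those
    means/SDs are applied instead (prediction time).  Zero-SD columns are
    dropped with a warning.
    """
    stats = {}
    for col in CONTINUOUS_COLUMNS:
        rawcol = "raw_" + col
        if rawcol not in matrix.df.columns:
            continue
        vals = matrix.df[rawcol].to_numpy(dtype=float)
        if reference_stats is not None:
            if col not in reference_stats:
                matrix.df.drop(columns=[rawcol], inplace=True, errors="ignore")
                matrix.dropped.append(col)
                continue
            mean, sd = reference_stats[col]
        else:
            mean, sd = float(vals.mean()), float(vals.std())
        if sd <= 0 or not np.isfinite(sd):
            warnings.warn(f"covariate {col!r} is constant; dropped from the design")
            matrix.df.drop(columns=[col], inplace=True, errors="ignore")
            matrix.dropped.append(col)
            continue
        stats[col] = (mean, sd)
        matrix.df[col] = (vals - mean) / sd
    matrix.stats = stats
    for quad, lin in QUADRATIC_PARTNERS.items():
        if lin in matrix.df.columns:
            matrix.df[quad] = matrix.df[lin] ** 2
    return matrix


def write_design_matrix(path, matrix: DesignMatrix):
    path = Path(path)
    matrix.df.to_csv(path, index=False)
    sidecar = {
        "order": matrix.order, "season": matrix.season,
        "stats": {k: list(v) for k, v in matrix.stats.items()},
        "clamp_bounds": {k: list(v) for k, v in matrix.clamp_bounds.items()},
        "dropped": matrix.dropped,
        "density_radius": matrix.density_radius,
        "drilling_cap": matrix.drilling_cap,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
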