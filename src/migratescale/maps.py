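"""Clamped, stretched prediction surfaces and the scale-integrated map.

Per pixel, the covariate vector is built exactly as at estimation time
except that time-dependent tiles are fixed to the season's central window
(spring: March 22 – April 6; fall: November 1 – 16) and the active-drilling
distance is set to its no-active cap (no wells assumed drilling on maps).
Each raw covariate is clamped into the [min, max] range sampled by the
estimation data, standardised with the stored statistics, and the relative
probability of selection is exp(x'beta) — intercept and random effect
omitted, since only the ranking of pixels is meaningful for an RSF/SSF map.

Maps are min-max rescaled to [0, 1] ("linear stretch").  The
scale-integrated step selection function (ISSF) map is the pixelwise product
of the stretched second- and third-order maps, restretched to [0, 1]; a
pixel with stretched second-order value 0.80 and third-order value 0.50 has
combined value 0.40 before that final restretch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import (CONTINUOUS_COLUMNS, QUADRATIC_PARTNERS, extract)
from .models import FittedSelectionModel
from .synthetic import Landscape

#: day-of-year central prediction windows (spring: Mar 22–Apr 6, fall: Nov 1–16)
SEASON_WINDOWS = {"spring": (81.0, 96.0), "fall": (305.0, 320.0)}


@dataclass
class PredictionRaster:
    """A relative-probability-of-selection surface on the landscape grid."""

    values: np.ndarray
    stretch_state: str           # "raw" | "stretched"
    provenance: dict = field(default_factory=dict)
    degenerate: bool = False

    def copy(self, **updates):
        out = PredictionRaster(self.values.copy(), self.stretch_state,
                               dict(self.provenance), self.degenerate)
        for k, v in updates.items():
            setattr(out, k, v)
        return out


def season_central_day(season: str) -> float:
    lo, hi = SEASON_WINDOWS[season]
    return 0.5 * (lo + hi)


def pixel_design_points(landscape: Landscape, season: str) -> pd.DataFrame:
    """One design point per pixel centre, timestamped to the season window."""
    ny, nx = landscape.shape
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    res = landscape.resolution
    return pd.DataFrame({
        "point_id": [f"px{k}" for k in range(ny * nx)],
        "stratum_id": "", "individual_id": "_map", "season": season,
        "role": "available", "order": 0, "weight": 1.0,
        "x": landscape.x0 + (jj.ravel() + 0.5) * res,
        "y": landscape.y0 + (ii.ravel() + 0.5) * res,
        "t": season_central_day(season),
    })


def predict_surface(model: FittedSelectionModel, landscape: Landscape,
                    season: str, link: str = "exp") -> PredictionRaster:
    """Raw relative-selection surface exp(x'beta) for one fitted model.

    Covariates are clamped into the model's stored sampled bounds before
    standardisation, so pixels beyond the sampled range predict exactly as
    pixels at the range limit.  ``link="logistic"`` gives the rank-equivalent
    inverse-logit variant.
    """
    if not model.stats:
        raise ValueError("model carries no standardisation statistics")
    points = pixel_design_points(landscape, season)
    # drilling distance at its cap: the no-active-drilling neutral state
    dm = extract(points, landscape, wells=landscape.wells.iloc[:0],
                 order=model.order, season=season,
                 reference_stats=model.stats)
    for col in CONTINUOUS_COLUMNS:
        if col not in model.stats or col not in dm.df.columns:
            continue
        lo, hi = model.clamp_bounds[col]
        mean, sd = model.stats[col]
        clamped = np.clip(dm.df["raw_" + col].to_numpy(dtype=float), lo, hi)
        dm.df[col] = (clamped - mean) / sd
    for quad, lin in QUADRATIC_PARTNERS.items():
        if quad in dm.df.columns and lin in dm.df.columns:
            dm.df[quad] = dm.df[lin] ** 2
    missing = [c for c in model.columns if c not in dm.df.columns]
    if missing:
        raise ValueError(f"model columns not derivable from landscape: {missing}")
    eta = dm.df[model.columns].to_numpy(dtype=float) @ model.coef_vector()
    vals = 1.0 / (1.0 + np.exp(-eta)) if link == "logistic" else np.exp(eta)
    ny, nx = landscape.shape
    return PredictionRaster(vals.reshape(ny, nx), "raw",
                            provenance={"order": model.order, "season": season,
                                        "link": link,
                                        "window": SEASON_WINDOWS[season],
                                        "clamped": True})


def linear_stretch(raster: PredictionRaster) -> PredictionRaster:
    """Min-max rescale to [0, 1]; a constant raster maps to all 0 + flag."""
    v = raster.values
    if not np.all(np.isfinite(v)):
        raise ValueError("raster has non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        import warnings
        warnings.warn("constant raster: stretch is degenerate (all zeros)")
        return raster.copy(values=np.zeros_like(v), stretch_state="stretched",
                           degenerate=True)
    return raster.copy(values=(v - lo) / (hi - lo), stretch_state="stretched")


def issf_product(map2: PredictionRaster, map3: PredictionRaster) -> PredictionRaster:
    """Pixelwise product of the two stretched maps (pre-restretch ISSF values)."""
    if map2.values.shape != map3.values.shape:
        raise ValueError("second- and third-order maps are on different grids")
    if map2.stretch_state != "stretched" or map3.stretch_state != "stretched":
        raise ValueError("ISSF combination expects stretched inputs")
    return PredictionRaster(map2.values * map3.values, "raw",
                            provenance={"orders": (map2.provenance.get("order"),
                                                   map3.provenance.get("order")),
                                        "stage": "issf_product"})


def issf_combine(map2: PredictionRaster, map3: PredictionRaster) -> PredictionRaster:
    """Scale-integrated map: product of stretched inputs, restretched to [0, 1]."""
    out = linear_stretch(issf_product(map2, map3))
    out.provenance["stage"] = "issf"
    return out
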