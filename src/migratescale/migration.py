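"""Migration classification from net squared displacement (NSD).

NSD — the squared straight-line distance from a track's first location to
each subsequent location — has a characteristic temporal profile for each
movement tactic: flat for residents, a single sigmoid for dispersers, a
double sigmoid returning to the origin for migrants, and a double sigmoid
settling on a different plateau for mixed-migrants (animals that winter at a
new location).  We fit all four nonlinear families to the daily NSD series
by least squares and classify by minimum AIC; mixed-migratory counts as
migratory downstream, residents and dispersers are dropped.

Migration bounds come from the fitted sigmoid midpoints: the interval
``midpoint +/- 2 * timescale`` covers ~88% of the logistic transition.
Pathways are then filtered: stopover clusters (runs of consecutive short
steps) collapse to a single location, and segments with fewer than 20
remaining observations are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic import Track

MIN_SEGMENT_OBS = 20
MODEL_FAMILIES = ("resident", "disperser", "migrant", "mixed_migrant")
# free mean-structure parameters per family (variance adds 1 in the AIC)
_N_PARAMS = {"resident": 1, "disperser": 3, "migrant": 5, "mixed_migrant": 6}


@dataclass
class NsdFit:
    """One nonlinear NSD model fit: family, parameters, AIC, convergence."""

    model_family: str
    parameters: dict
    aic: float
    converged: bool
    n_obs: int = 0

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model_family]


@dataclass
class MigrationSegment:
    """A filtered seasonal migratory pathway (stopovers collapsed)."""

    individual_id: str
    season: str                  # "spring" | "fall"
    start_day: float
    end_day: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fix_interval: float
    epoch: np.datetime64 = None

    @property
    def n_obs(self) -> int:
        return len(self.t)

    @property
    def start_date(self):
        return self.epoch + np.timedelta64(int(round(self.start_day * 86400)), "s")

    @property
    def end_date(self):
        return self.epoch + np.timedelta64(int(round(self.end_day * 86400)), "s")


def compute_nsd(track: Track) -> np.ndarray:
    """Squared Euclidean displacement (m^2) from the first fix to each fix."""
    if len(track) < 2:
        raise ValueError("NSD needs at least 2 fixes")
    return (track.x - track.x[0]) ** 2 + (track.y - track.y[0]) ** 2


def daily_nsd(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """One NSD value per day: the fix nearest local noon.

    Returns (day numbers relative to the track's first day, NSD series).
    """
    nsd = compute_nsd(track)
    day = np.floor(track.t).astype(int)
    frac = track.t - day
    df = pd.DataFrame({"day": day, "noon_dist": np.abs(frac - 0.5), "nsd": nsd})
    idx = df.groupby("day")["noon_dist"].idxmin()
    sel = df.loc[idx]
    return sel.day.to_numpy() - sel.day.iloc[0], sel.nsd.to_numpy()


# --------------------------------------------------------------------------
# nonlinear model families
# --------------------------------------------------------------------------

def _sigmoid(t, theta, phi):
    return 1.0 / (1.0 + np.exp(np.clip((theta - t) / phi, -500, 500)))


def _predict(family, params, t):
    if family == "resident":
        return np.full_like(t, params["c"], dtype=float)
    if family == "disperser":
        return params["delta"] * _sigmoid(t, params["theta1"], params["phi1"])
    if family == "migrant":
        return params["delta"] * (_sigmoid(t, params["theta1"], params["phi1"])
                                  - _sigmoid(t, params["theta2"], params["phi2"]))
    if family == "mixed_migrant":
        return (params["delta"] * _sigmoid(t, params["theta1"], params["phi1"])
                - params["delta2"] * _sigmoid(t, params["theta2"], params["phi2"]))
    raise ValueError(f"unknown family {family!r}")


def _gaussian_aic(resid, n, k):
    rss = float(resid @ resid)
    rss = max(rss, 1e-12 * n)
    return n * np.log(rss / n) + 2 * (k + 1)


def _fit_family(family, t, s):
    """Least-squares fit of one family on the unit-scaled NSD series ``s``."""
    n = len(t)
    if family == "resident":
        c = float(np.mean(s))
        resid = s - c
        return {"c": c}, _gaussian_aic(resid, n, 1), True
    t_lo, t_hi = float(t.min()), float(t.max())
    span = max(t_hi - t_lo, 1.0)
    smax = max(float(s.max()), 1e-6)
    starts = []
    # transition midpoints are constrained inside the observed window: a
    # "migration" the data never saw is a resident profile in disguise
    if family == "disperser":
        names = ["delta", "theta1", "phi1"]
        lb = [0.0, t_lo, 0.1]
        ub = [5.0 * smax, t_hi, span]
        for q in (0.25, 0.5, 0.75):
            starts.append([smax, t_lo + q * span, 0.05 * span])
    elif family == "migrant":
        names = ["delta", "theta1", "phi1", "theta2", "phi2"]
        lb = [0.0, t_lo, 0.1, t_lo, 0.1]
        ub = [5.0 * smax, t_hi, span, t_hi, span]
        for q1, q2 in ((0.2, 0.8), (0.3, 0.7), (0.15, 0.6)):
            starts.append([smax, t_lo + q1 * span, 0.03 * span,
                           t_lo + q2 * span, 0.03 * span])
    else:  # mixed_migrant
        names = ["delta", "theta1", "phi1", "theta2", "phi2", "delta2"]
        lb = [0.0, t_lo, 0.1, t_lo, 0.1, 0.0]
        ub = [5.0 * smax, t_hi, span, t_hi, span, 5.0 * smax]
        for q1, q2 in ((0.2, 0.8), (0.3, 0.7)):
            starts.append([smax, t_lo + q1 * span, 0.03 * span,
                           t_lo + q2 * span, 0.03 * span, 0.6 * smax])

    def residuals(p):
        return _predict(family, dict(zip(names, p)), t) - s

    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf",
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return {}, np.inf, False
    params = dict(zip(names, best.x))
    ok = bool(best.success) and np.isfinite(best.cost)
    if family in ("migrant", "mixed_migrant") and params["theta2"] <= params["theta1"]:
        ok = False  # departure must precede return
    resid = residuals(best.x)
    # identifiability: a transition amplitude indistinguishable from the
    # residual noise is a resident profile in disguise, not a migration
    if params.get("delta", np.inf) < 3.0 * resid.std():
        ok = False
    return params, _gaussian_aic(resid, n, len(names)), ok


def fit_nsd_models(days: np.ndarray, nsd: np.ndarray) -> list[NsdFit]:
    """Fit the four NSD families to a daily series and score each by AIC.

    The series is fitted on a unit scale (divided by its maximum) for
    numerical stability; asymptote-type parameters are reported back on the
    original m^2 scale.  AICs are comparable across families because every
    family is fitted to the identical scaled series.
    """
    t = np.asarray(days, dtype=float)
    s_raw = np.asarray(nsd, dtype=float)
    if len(t) < 30:
        raise ValueError(f"need at least 30 daily NSD values, got {len(t)}")
    scale = max(float(s_raw.max()), 1.0)
    s = s_raw / scale
    fits = []
    for family in MODEL_FAMILIES:
        params, aic, converged = _fit_family(family, t, s)
        rescaled = dict(params)
        for key in ("c", "delta", "delta2"):
            if key in rescaled:
                rescaled[key] *= scale
        fits.append(NsdFit(family, rescaled, float(aic), converged, n_obs=len(t)))
    return fits


def classify_track(fits: list[NsdFit]) -> str:
    """Minimum-AIC family; ties go to the simpler family.

    Returns one of ``{"migratory", "mixed_migratory", "resident",
    "disperser"}``.  Downstream, mixed-migratory is treated as migratory and
    residents/dispersers are excluded.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not usable:
        raise ValueError("no converged NSD fit: track cannot be classified")
    best = min(usable, key=lambda f: (f.aic, f.n_params))
    return {"migrant": "migratory", "mixed_migrant": "mixed_migratory",
            "resident": "resident", "disperser": "disperser"}[best.model_family]


def is_migratory(status: str) -> bool:
    return status in ("migratory", "mixed_migratory")


def migration_bounds(fit: NsdFit, season: str) -> tuple[float, float]:
    """(start, end) day numbers of the seasonal migration window.

    Spring uses the departure sigmoid (theta1 +/- 2 phi1), fall the return
    sigmoid (theta2 +/- 2 phi2).
    """
    if fit.model_family not in ("migrant", "mixed_migrant"):
        raise ValueError(f"bounds undefined for a {fit.model_family} fit")
    if season == "spring":
        theta, phi = fit.parameters["theta1"], fit.parameters["phi1"]
    elif season == "fall":
        theta, phi = fit.parameters["theta2"], fit.parameters["phi2"]
    else:
        raise ValueError("season must be 'spring' or 'fall'")
    return theta - 2.0 * phi, theta + 2.0 * phi


def _collapse_stopovers(t, x, y, q=0.25, run_length=4):
    """Collapse runs of >= run_length consecutive short steps to one location.

    A step is short when below the q-th percentile of the segment's step
    lengths.  The first location of each collapsed run is retained.
    """
    n = len(t)
    if n < 3:
        return np.ones(n, dtype=bool)
    steps = np.hypot(np.diff(x), np.diff(y))
    thr = np.quantile(steps, q)
    short = steps < thr
    keep = np.ones(n, dtype=bool)
    i = 0
    while i < len(short):
        if short[i]:
            j = i
            while j < len(short) and short[j]:
                j += 1
            if j - i >= run_length:
                # steps i..j-1 short: locations i..j cluster; keep location i
                keep[i + 1: j + 1] = False
            i = j
        else:
            i += 1
    return keep


def build_segment(track: Track, bounds: tuple[float, float], season: str,
                  stopover_quantile: float = 0.25, stopover_run: int = 4,
                  min_obs: int = MIN_SEGMENT_OBS):
    """Extract a migratory pathway segment, or exclude it with a reason.

    Returns ``(MigrationSegment, None)`` on success or ``(None, reason)``
    when the window is empty or fewer than ``min_obs`` locations remain
    after stopover collapse.
    """
    start, end = bounds
    t0 = track.t[0]
    lo, hi = t0 + start, t0 + end
    mask = (track.t >= lo) & (track.t <= hi)
    if not mask.any():
        return None, "empty migration window"
    t, x, y = track.t[mask], track.x[mask], track.y[mask]
    keep = _collapse_stopovers(t, x, y, stopover_quantile, stopover_run)
    t, x, y = t[keep], x[keep], y[keep]
    if len(t) < min_obs:
        return None, f"only {len(t)} observations after filtering (< {min_obs})"
    return MigrationSegment(track.individual_id, season, float(lo), float(hi),
                            t, x, y, track.fix_interval, track.epoch), None


# --------------------------------------------------------------------------
# per-track driver and reporting
# --------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    individual_id: str
    status: str
    fits: list
    segments: dict = field(default_factory=dict)      # season -> MigrationSegment
    exclusions: dict = field(default_factory=dict)    # season -> reason


def classify_and_segment(track: Track, seasons=("spring", "fall"),
                         status_override: str | None = None,
                         **segment_kwargs) -> ClassificationResult:
    """Run the full per-track chain: daily NSD, model fits, segments.

    ``status_override`` is the manual-override hook: a status supplied there
    replaces the AIC-based call (the fits are still reported).
    """
    days, nsd = daily_nsd(track)
    fits = fit_nsd_models(days, nsd)
    status = status_override or classify_track(fits)
    result = ClassificationResult(track.individual_id, status, fits)
    if not is_migratory(status):
        return result
    usable = [f for f in fits if f.converged and np.isfinite(f.aic)
              and f.model_family in ("migrant", "mixed_migrant")]
    if not usable:
        result.exclusions["all"] = "migratory status without a usable sigmoid fit"
        return result
    best = min(usable, key=lambda f: (f.aic, f.n_params))
    for season in seasons:
        seg, reason = build_segment(track, migration_bounds(best, season),
                                    season, **segment_kwargs)
        if seg is None:
            result.exclusions[season] = reason
        else:
            result.segments[season] = seg
    return result


def pool_segments(segments: list[MigrationSegment]) -> MigrationSegment:
    """Concatenate several same-individual same-season segments (multi-year)."""
    if not segments:
        raise ValueError("no segments to pool")
    first = segments[0]
    if any(s.individual_id != first.individual_id or s.season != first.season
           for s in segments):
        raise ValueError("pooled segments must share individual and season")
    ordered = sorted(segments, key=lambda s: s.start_day)
    return MigrationSegment(
        first.individual_id, first.season,
        ordered[0].start_day, ordered[-1].end_day,
        np.concatenate([s.t for s in ordered]),
        np.concatenate([s.x for s in ordered]),
        np.concatenate([s.y for s in ordered]),
        first.fix_interval, first.epoch)


def classification_summary(statuses: list[str]) -> dict:
    """Population tally: counts and percent migratory (mixed counts as migratory)."""
    n = len(statuses)
    n_mig = sum(is_migratory(s) for s in statuses)
    return {
        "n_animal_years": n,
        "n_migratory": n_mig,
        "n_resident": sum(s == "resident" for s in statuses),
        "n_disperser": sum(s == "disperser" for s in statuses),
        "percent_migratory": 100.0 * n_mig / n if n else float("nan"),
    }


def write_classification_report(path, results: list[ClassificationResult]):
    payload = []
    for r in results:
        payload.append({
            "individual_id": r.individual_id,
            "status": r.status,
            "family_aic": {f.model_family: (f.aic if f.converged else None)
                           for f in r.fits},
            "segments": {season: {"start_day": seg.start_day, "end_day": seg.end_day,
                                  "n_obs": seg.n_obs}
                         for season, seg in r.segments.items()},
            "exclusions": r.exclusions,
        })
    Path(path).write_text(json.dumps(payload, indent=2))
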