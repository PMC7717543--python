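"""Hierarchically nested used-available sampling design.

Third order (step scale): each used location along a migratory pathway is
matched to 5 available endpoints generated from the individual's empirical
step-length and turn-angle distributions, each weighted 0.2 so the available
mass per stratum equals the used mass (5 x 0.2 = 1).

Second order (neighborhood scale): every individual's third-order available
points, pooled, are relabelled as samples of *use* of a migratory
neighborhood, and contrasted 1:1 against uniform random points from the whole
study area.  The nesting is literal — the second-order used set is exactly
the third-order available set, carried over by point id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from .migration import MigrationSegment
from .synthetic import Landscape

AVAILABLE_PER_USED = 5
AVAILABLE_WEIGHT = 0.2


class MoveDistributions:
    """An individual's empirical step lengths (m) and turn angles (rad)."""

    def __init__(self, individual_id: str, step_lengths, turn_angles):
        self.individual_id = individual_id
        self.step_lengths = np.asarray(step_lengths, dtype=float)
        self.turn_angles = np.asarray(turn_angles, dtype=float)

    def percentile_length(self, q: float = 95.0) -> float:
        return float(np.percentile(self.step_lengths, q))


class Neighborhood:
    """Union of discs (radius = one step length) around pathway locations."""

    def __init__(self, individual_id, season, polygon, buffer_radius):
        self.individual_id = individual_id
        self.season = season
        self.polygon = polygon
        self.buffer_radius = buffer_radius

    @property
    def area(self) -> float:
        return float(self.polygon.area)


def empirical_move_distributions(segment: MigrationSegment) -> MoveDistributions:
    """Observed step lengths and turn angles of one pathway.

    n locations yield n-1 step lengths and n-2 turn angles (a turn needs
    three consecutive locations).  Raises for segments shorter than 3.
    """
    if segment.n_obs < 3:
        raise ValueError("empirical distributions need at least 3 locations")
    dx = np.diff(segment.x)
    dy = np.diff(segment.y)
    lengths = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    turns = np.angle(np.exp(1j * np.diff(headings)))  # wrapped to (-pi, pi]
    return MoveDistributions(segment.individual_id, lengths, turns)


def generate_strata(segment: MigrationSegment, dists: MoveDistributions,
                    landscape: Landscape, seed: int = 0,
                    n_available: int = AVAILABLE_PER_USED,
                    max_redraws: int = 100) -> pd.DataFrame:
    """Matched step strata: one used step + ``n_available`` weighted endpoints.

    For each used step (from location i-1 to i), available endpoints start at
    location i-1 with independently resampled (length, angle) pairs, where
    angle means the previous-step heading plus a resampled turn.  Endpoints
    falling outside the study area are redrawn up to ``max_redraws`` times,
    then placed uniformly within the disc of radius equal to that draw's
    length (clipped into the study area by the same rule).

    Returns a tidy frame with columns ``point_id, stratum_id, individual_id,
    season, role, order, weight, x, y, t``; available timestamps equal the
    matched used location's timestamp.
    """
    if segment.individual_id != dists.individual_id:
        raise ValueError("segment and move distributions are from different individuals")
    rng = np.random.default_rng(seed)
    t, x, y = segment.t, segment.x, segment.y
    headings = np.arctan2(np.diff(y), np.diff(x))
    rows = []
    # steps to location i (i >= 2 so a previous heading exists for the turn)
    for i in range(2, len(t)):
        sid = f"{segment.individual_id}-{segment.season}-s{i:04d}"
        rows.append({"point_id": f"{sid}-u", "stratum_id": sid,
                     "individual_id": segment.individual_id, "season": segment.season,
                     "role": "used", "order": 3, "weight": 1.0,
                     "x": x[i], "y": y[i], "t": t[i]})
        origin = np.array([x[i - 1], y[i - 1]])
        prev_heading = headings[i - 2]
        for a in range(n_available):
            px, py = _draw_available(rng, origin, prev_heading, dists,
                                     landscape, max_redraws)
            rows.append({"point_id": f"{sid}-a{a}", "stratum_id": sid,
                         "individual_id": segment.individual_id,
                         "season": segment.season, "role": "available",
                         "order": 3, "weight": AVAILABLE_WEIGHT,
                         "x": px, "y": py, "t": t[i]})
    return pd.DataFrame(rows)


def _draw_available(rng, origin, prev_heading, dists, landscape, max_redraws):
    for _ in range(max_redraws):
        length = rng.choice(dists.step_lengths)
        turn = rng.choice(dists.turn_angles)
        heading = prev_heading + turn
        px = origin[0] + length * np.cos(heading)
        py = origin[1] + length * np.sin(heading)
        if landscape.contains(px, py):
            return float(px), float(py)
    # fallback: uniform within the disc of radius = last drawn length
    for _ in range(1000):
        r = length * np.sqrt(rng.random())
        a = rng.uniform(-np.pi, np.pi)
        px, py = origin[0] + r * np.cos(a), origin[1] + r * np.sin(a)
        if landscape.contains(px, py):
            return float(px), float(py)
    return float(origin[0]), float(origin[1])


def build_neighborhood(segment: MigrationSegment, strata: pd.DataFrame | None,
                       dists: MoveDistributions,
                       radius_rule: str = "p95") -> Neighborhood:
    """Migratory neighborhood: discs of one step length around every location.

    "One step length" defaults to the individual's 95th-percentile observed
    step length (robust to outlier steps); ``radius_rule`` may also be
    ``"max"`` or ``"mean"``.  If any stratum point still falls outside the
    disc union, the polygon is expanded by buffering those points too.
    """
    if segment.n_obs == 0:
        raise ValueError("empty segment")
    if radius_rule == "p95":
        radius = dists.percentile_length(95.0)
    elif radius_rule == "max":
        radius = float(dists.step_lengths.max())
    elif radius_rule == "mean":
        radius = float(dists.step_lengths.mean())
    else:
        raise ValueError(f"unknown radius rule {radius_rule!r}")
    discs = [Point(px, py).buffer(radius, quad_segs=32)
             for px, py in zip(segment.x, segment.y)]
    poly = unary_union(discs)
    if strata is not None and len(strata):
        pts = strata[["x", "y"]].to_numpy()
        outside = [k for k in range(len(pts)) if not poly.covers(Point(*pts[k]))]
        if outside:
            poly = unary_union([poly] + [Point(*pts[k]).buffer(radius, quad_segs=32)
                                         for k in outside])
    return Neighborhood(segment.individual_id, segment.season, poly, radius)


def uniform_points_in_area(landscape: Landscape, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Uniform random points inside the study-area polygon (rejection)."""
    minx, miny, maxx, maxy = landscape.study_area.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = landscape.contains(xs, ys)
        out = np.vstack([out, np.column_stack([xs[ok], ys[ok]])])
    return out[:n]


def build_second_order_design(strata_by_individual: dict[str, pd.DataFrame],
                              landscape: Landscape, season: str,
                              seed: int = 0,
                              season_central_day: float | None = None,
                              grouping: str = "partition") -> pd.DataFrame:
    """Pooled second-order design: neighborhood points vs. study-area points.

    ``used`` rows are every individual's third-order *available* points
    (weight 1 at this order; original point ids retained so the nesting is
    verifiable), and ``available`` rows are an equal number of uniform random
    study-area points.  Available timestamps sample the season's central tile
    window so time-matched covariates are comparable.

    ``grouping`` controls the individual id carried by the shared available
    points for the random intercept: ``"partition"`` (default) deals them out
    among the individuals in proportion to used counts, so every random-effect
    group contains both outcomes and the intercept variance stays
    identifiable; ``"pooled"`` keeps them in a single ``_study_area``
    pseudo-group (in which group membership alone separates the outcome, so
    the variance component is only weakly identified).
    """
    if not strata_by_individual:
        raise ValueError("no individuals supplied")
    if grouping not in ("partition", "pooled"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    used_parts = []
    for ind, strata in strata_by_individual.items():
        av = strata[strata.role == "available"].copy()
        av["role"] = "used"
        av["order"] = 2
        av["weight"] = 1.0
        used_parts.append(av)
    used = pd.concat(used_parts, ignore_index=True)
    n = len(used)
    pts = uniform_points_in_area(landscape, n, rng)
    if season_central_day is None:
        season_central_day = float(np.median(used.t))
    t_avail = season_central_day + rng.uniform(-8.0, 8.0, n)
    if grouping == "pooled":
        avail_ids = ["_study_area"] * n
    else:
        # deal available points among individuals, matching used counts
        avail_ids = rng.permutation(used.individual_id.to_numpy()).tolist()
    avail = pd.DataFrame({
        "point_id": [f"so-{season}-a{k:06d}" for k in range(n)],
        "stratum_id": "", "individual_id": avail_ids,
        "season": season, "role": "available", "order": 2, "weight": 1.0,
        "x": pts[:, 0], "y": pts[:, 1], "t": t_avail,
    })
    return pd.concat([used, avail], ignore_index=True)


def write_design_csv(path, *designs: pd.DataFrame):
    pd.concat(designs, ignore_index=True).to_csv(path, index=False)
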