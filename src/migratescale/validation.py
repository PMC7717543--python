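"""k-fold cross-validation by individual with 10-bin Spearman evaluation.

Individuals (never points) are partitioned into k = 5 folds.  Per fold the
final model's term set is refit on the training individuals only — term
selection is not rerun — and the withheld individuals' used locations are
scored against the prediction surface.  Predictions over the evaluation
domain (study-area pixels for second order and ISSF; stratum available
points for third order) are cut into 10 equal-frequency ordinal bins; the
observed frequency of withheld used points per bin is area-adjusted (divided
by the bin's share of the domain and renormalised) and correlated with bin
rank by Spearman's rho.  This is the Boyce-style validation of habitat
models: a well-ranked map concentrates use in its high bins, giving rho
near 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import DesignMatrix
from .maps import PredictionRaster, issf_combine, linear_stretch, predict_surface
from .models import (ConditionalLogitFitter, FittedSelectionModel, GlmmFitter)
from .synthetic import Landscape

N_FOLDS = 5
N_BINS = 10


@dataclass
class FoldResult:
    withheld: list
    rho: float
    p: float
    bin_frequencies: list
    converged: bool = True


@dataclass
class ValidationReport:
    scale: str                 # "second" | "third" | "issf"
    season: str
    k: int
    folds: list = field(default_factory=list)
    pooled_rho: float = float("nan")
    pooled_p: float = float("nan")
    bin_definition: str = f"{N_BINS} equal-frequency bins of the evaluation-domain predictions, area-adjusted use"

    def to_json(self, path):
        payload = {
            "scale": self.scale, "season": self.season, "k": self.k,
            "pooled_rho": self.pooled_rho, "pooled_p": self.pooled_p,
            "bin_definition": self.bin_definition,
            "folds": [{"withheld": f.withheld, "rho": f.rho, "p": f.p,
                       "bin_frequencies": f.bin_frequencies,
                       "converged": f.converged} for f in self.folds],
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def kfold_split(individual_ids, k: int = N_FOLDS, seed: int = 0) -> dict:
    """Random partition of individuals into k near-equal folds."""
    ids = sorted(set(individual_ids))
    if len(ids) < k:
        raise ValueError(f"need at least {k} individuals, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = {i: [] for i in range(k)}
    for pos, idx in enumerate(perm):
        folds[pos % k].append(ids[idx])
    return {i: sorted(m) for i, m in folds.items()}


def bin_and_correlate(domain_predictions: np.ndarray,
                      withheld_predictions: np.ndarray,
                      n_bins: int = N_BINS):
    """Spearman rho between bin rank and area-adjusted use frequency.

    ``domain_predictions`` defines the habitat-quality bins (equal-frequency
    deciles of the evaluation domain); ``withheld_predictions`` are the
    prediction values at the withheld used locations.  The observed count per
    bin is divided by the bin's pixel share and renormalised before the rank
    correlation, so uneven realised bin sizes cannot masquerade as selection.
    Returns ``(rho, p, adjusted_frequencies)``.
    """
    domain = np.asarray(domain_predictions, dtype=float).ravel()
    used = np.asarray(withheld_predictions, dtype=float).ravel()
    if len(np.unique(domain)) < n_bins:
        raise ValueError("degenerate predictions: fewer distinct values than bins")
    qs = np.quantile(domain, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    # guard against ties collapsing bin edges
    for i in range(1, n_bins):
        if qs[i] <= qs[i - 1]:
            qs[i] = np.nextafter(qs[i - 1], np.inf)
    domain_bin = np.clip(np.searchsorted(qs, domain, side="right") - 1, 0, n_bins - 1)
    used_bin = np.clip(np.searchsorted(qs, used, side="right") - 1, 0, n_bins - 1)
    area = np.bincount(domain_bin, minlength=n_bins).astype(float)
    counts = np.bincount(used_bin, minlength=n_bins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.where(area > 0, counts / area, 0.0)
    total = adj.sum()
    if total > 0:
        adj = adj / total
    rho, p = stats.spearmanr(np.arange(1, n_bins + 1), adj)
    return float(rho), float(p), adj.tolist()


def _predictions_at_points(raster: PredictionRaster, landscape: Landscape,
                           x, y) -> np.ndarray:
    return landscape.sample(raster.values, np.asarray(x), np.asarray(y))


def run_validation(dm2: DesignMatrix | None, dm3: DesignMatrix | None,
                   landscape: Landscape, scale: str, season: str,
                   terms2=None, terms3=None,
                   k: int = N_FOLDS, seed: int = 0,
                   n_bins: int = N_BINS) -> ValidationReport:
    """k-fold validation of second-order, third-order or ISSF predictions.

    ``terms2``/``terms3`` are the final model term sets (selection is not
    rerun per fold; coefficients are re-estimated on training individuals).
    Second-order and ISSF predictions are evaluated against the full
    study-area pixel domain; third-order predictions against the withheld
    individuals' stratum available points.  Folds whose refit fails to
    converge are excluded from the pooled statistic with a warning.
    """
    if scale not in ("second", "third", "issf"):
        raise ValueError(f"unknown scale {scale!r}")
    ref_dm = dm2 if scale in ("second", "issf") else dm3
    used_ids = sorted(set(
        ref_dm.df.loc[ref_dm.df.role == "used", "individual_id"]) - {"_study_area"})
    folds = kfold_split(used_ids, k, seed)
    report = ValidationReport(scale=scale, season=season, k=k)
    all_adj = np.zeros(n_bins)
    n_ok = 0
    for fold_id, withheld in folds.items():
        train = [i for i in used_ids if i not in withheld]
        try:
            if scale == "second":
                model2 = _refit(dm2, train, GlmmFitter, terms2)
                raster = linear_stretch(predict_surface(model2, landscape, season))
                rho, p, adj = _eval_raster(raster, landscape, dm2, withheld, n_bins)
            elif scale == "third":
                model3 = _refit(dm3, train, ConditionalLogitFitter, terms3)
                rho, p, adj = _eval_points(model3, dm3, withheld, n_bins)
            else:
                model2 = _refit(dm2, train, GlmmFitter, terms2)
                model3 = _refit(dm3, train, ConditionalLogitFitter, terms3)
                raster = issf_combine(
                    linear_stretch(predict_surface(model2, landscape, season)),
                    linear_stretch(predict_surface(model3, landscape, season)))
                rho, p, adj = _eval_raster(raster, landscape, dm2, withheld, n_bins)
            report.folds.append(FoldResult(withheld, rho, p, adj))
            all_adj += np.asarray(adj)
            n_ok += 1
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"fold {fold_id} excluded: {err}")
            report.folds.append(FoldResult(withheld, float("nan"), float("nan"),
                                           [], converged=False))
    if n_ok:
        pooled = all_adj / n_ok
        rho, p = stats.spearmanr(np.arange(1, n_bins + 1), pooled)
        report.pooled_rho, report.pooled_p = float(rho), float(p)
    return report


def _refit(dm: DesignMatrix, train_ids, fitter_cls, terms) -> FittedSelectionModel:
    mask = dm.df.individual_id.isin(list(train_ids) + ["_study_area"])
    sub = DesignMatrix(df=dm.df.loc[mask].reset_index(drop=True),
                       order=dm.order, season=dm.season, stats=dm.stats,
                       clamp_bounds=dm.clamp_bounds, dropped=dm.dropped,
                       density_radius=dm.density_radius,
                       drilling_cap=dm.drilling_cap)
    model = fitter_cls(sub).fit(terms or sub.terms())
    if not model.converged:
        raise ValueError("refit did not converge")
    return model


def _eval_raster(raster: PredictionRaster, landscape: Landscape,
                 dm: DesignMatrix, withheld, n_bins):
    rows = dm.df[(dm.df.role == "used") & dm.df.individual_id.isin(withheld)]
    preds = _predictions_at_points(raster, landscape, rows.x.to_numpy(),
                                   rows.y.to_numpy())
    return bin_and_correlate(raster.values, preds, n_bins)


def _eval_points(model: FittedSelectionModel, dm: DesignMatrix, withheld, n_bins):
    sub = dm.df[dm.df.individual_id.isin(withheld)]
    beta = model.coef_vector()
    eta = sub[model.columns].to_numpy(dtype=float) @ beta
    preds = np.exp(eta - eta.max())
    domain = preds[(sub.role == "available").to_numpy()]
    used = preds[(sub.role == "used").to_numpy()]
    return bin_and_correlate(domain, used, n_bins)


def report_table(reports: list[ValidationReport]) -> pd.DataFrame:
    return pd.DataFrame([{"scale": r.scale, "season": r.season,
                          "rho": r.pooled_rho, "p": r.pooled_p,
                          "k": r.k} for r in reports])
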