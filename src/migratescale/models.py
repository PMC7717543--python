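"""Habitat-selection estimators and the variable-reduction protocol.

Two estimators:

* **Second order** — logistic GLMM: ``logit P(used) = b0 + b_i + x'beta`` with
  an individual random intercept ``b_i ~ Normal(0, sigma^2)``, fitted by
  maximising the Gauss–Hermite-quadrature approximation of the marginal
  likelihood (the integral over each group's intercept is one-dimensional, so
  20-node quadrature is essentially exact).
* **Third order** — weighted conditional (fixed-effect) logistic regression for
  the matched step design: the stratum log-likelihood is
  ``x_used' beta - log sum_j w_j exp(x_j' beta)`` with the 0.2 availability
  weights inside the denominator (importance-weighting the availability
  sample), maximised by Newton iteration with analytic gradient and Hessian.
  There is no intercept; standard errors come from the inverse observed
  information.

Variable reduction mirrors standard practice: univariate screening retains
terms at P < 0.20 (likelihood-ratio against the null; the land-cover
indicator block and quadratic+linear pairs are tested jointly), collinear
pairs at |r| >= 0.7 lose the member with the weaker univariate support, and
backward stepwise removal drops the single worst term with Wald P > 0.05
until only significant terms remain.  A quadratic term is removed before its
linear partner; the land-cover block is removed only on its joint
likelihood-ratio test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats

from .covariates import QUADRATIC_PARTNERS, DesignMatrix

SCREEN_P = 0.20
COLLINEAR_R = 0.7
STEPWISE_P = 0.05


@dataclass
class FittedSelectionModel:
    """Coefficients and Wald statistics of one fitted selection model."""

    order: int
    season: str
    terms: list
    columns: list
    beta: dict                    # column -> coefficient (standardised scale)
    se: dict
    z: dict
    p: dict
    log_likelihood: float
    converged: bool
    intercept: float | None = None          # order 2 only
    random_intercept_sd: float | None = None  # order 2 only
    stats: dict = field(default_factory=dict)
    clamp_bounds: dict = field(default_factory=dict)
    block_p: dict = field(default_factory=dict)  # term -> joint LR p
    n_obs: int = 0

    def coef_vector(self, columns=None):
        cols = columns or self.columns
        return np.array([self.beta[c] for c in cols])

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.columns,
            "beta": [self.beta[c] for c in self.columns],
            "se": [self.se[c] for c in self.columns],
            "z": [self.z[c] for c in self.columns],
            "p": [self.p[c] for c in self.columns],
        })

    def to_json(self, path):
        payload = {k: getattr(self, k) for k in
                   ("order", "season", "terms", "columns", "beta", "se", "z", "p",
                    "log_likelihood", "converged", "intercept",
                    "random_intercept_sd", "block_p", "n_obs")}
        payload["stats"] = {k: list(v) for k, v in self.stats.items()}
        payload["clamp_bounds"] = {k: list(v) for k, v in self.clamp_bounds.items()}
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


@dataclass
class ScreeningReport:
    """Where every candidate variable ended up during model reduction."""

    univariate_p: dict = field(default_factory=dict)
    retained: list = field(default_factory=list)
    screened_out: list = field(default_factory=list)
    collinear_pairs: list = field(default_factory=list)   # (kept, dropped, r)
    collinearity_dropped: list = field(default_factory=list)
    stepwise_removed: list = field(default_factory=list)  # (term, p at removal)

    def accounted(self):
        return (set(self.retained) | set(self.screened_out)
                | set(self.collinearity_dropped)
                | {t for t, _ in self.stepwise_removed})


def wald_p(z):
    return 2.0 * stats.norm.sf(np.abs(z))


# --------------------------------------------------------------------------
# third order: weighted conditional logistic regression
# --------------------------------------------------------------------------

def _stack_strata(dm: DesignMatrix, columns):
    """(S, J, p) covariate array with the used point first in each stratum."""
    df = dm.df
    order = np.argsort(df["stratum_id"].to_numpy(), kind="stable")
    df = df.iloc[order]
    strata = []
    weights = None
    for sid, grp in df.groupby("stratum_id", sort=True):
        grp = grp.sort_values("role", ascending=False)  # 'used' after 'available'
        grp = pd.concat([grp[grp.role == "used"], grp[grp.role == "available"]])
        strata.append(grp[columns].to_numpy(dtype=float))
        w = grp["weight"].to_numpy(dtype=float)
        if weights is None:
            weights = w
    X = np.stack(strata)
    return X, weights


def conditional_loglik(beta, X, w):
    """Weighted conditional log-likelihood; used point at index 0."""
    eta = X @ beta                                       # (S, J)
    m = eta.max(axis=1, keepdims=True)
    denom = np.log((w[None, :] * np.exp(eta - m)).sum(axis=1)) + m[:, 0]
    return float((eta[:, 0] - denom).sum())


def _cond_grad_hess(beta, X, w):
    eta = X @ beta
    m = eta.max(axis=1, keepdims=True)
    ew = w[None, :] * np.exp(eta - m)
    pi = ew / ew.sum(axis=1, keepdims=True)              # (S, J)
    xbar = np.einsum("sj,sjp->sp", pi, X)
    grad = (X[:, 0, :] - xbar).sum(axis=0)
    xx = np.einsum("sj,sjp,sjq->pq", pi, X, X)
    hess = -(xx - np.einsum("sp,sq->pq", xbar, xbar))
    ll = float((eta[:, 0] - (np.log(ew.sum(axis=1)) + m[:, 0])).sum())
    return ll, grad, hess


def fit_conditional_logit(X: np.ndarray, weights: np.ndarray,
                          columns=None, tol: float = 1e-10,
                          max_iter: int = 100):
    """Newton maximisation of the weighted conditional log-likelihood.

    ``X`` is ``(S, J, p)`` with the used point first; ``weights`` the
    within-stratum weights (used 1.0, each available 0.2 by default).
    Columns with no within-stratum contrast are dropped with a warning.
    Returns ``(beta, se, loglik, converged, kept_column_indices)``.
    """
    S, J, p = X.shape
    within_var = X.var(axis=1).max(axis=0)
    keep = np.nonzero(within_var > 1e-12)[0]
    if len(keep) < p:
        names = [columns[k] for k in range(p) if k not in keep] if columns else \
            [str(k) for k in range(p) if k not in keep]
        warnings.warn("no within-stratum contrast for "
                      f"{names}; dropped from the conditional fit")
    if len(keep) == 0:
        # nothing to estimate: likelihood at the null
        m = np.log((weights[None, :] * np.ones((S, J))).sum(axis=1)).sum()
        return (np.zeros(0), np.zeros(0), float(-m), True, keep)
    Xk = X[:, :, keep]
    beta = np.zeros(len(keep))
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cond_grad_hess(beta, Xk, weights)
        try:
            step = np.linalg.solve(hess - 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            break
        # step-halving line search on the ascent direction
        alpha = 1.0
        for _ in range(30):
            cand = beta - alpha * step
            if conditional_loglik(cand, Xk, weights) >= ll - 1e-12:
                break
            alpha /= 2.0
        beta = beta - alpha * step
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0) and np.abs(grad).max() < 1e-6:
            converged = True
            break
        ll_old = ll
    ll, grad, hess = _cond_grad_hess(beta, Xk, weights)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
        converged = False
    if not converged and np.abs(grad).max() < 1e-5:
        converged = True
    return beta, se, ll, converged, keep


def fit_third_order(dm: DesignMatrix, term_names=None,
                    weights_in_likelihood: bool = False) -> FittedSelectionModel:
    """Conditional logistic fit of the matched step design.

    By default the exact matched-design conditional likelihood is maximised
    (all within-stratum likelihood weights 1): conditioning on the stratum
    makes the availability-rebalancing weights unnecessary, and this form is
    unbiased for a step-selection generating model.  With
    ``weights_in_likelihood=True`` the design's 0.2 availability weights are
    applied inside the stratum denominators instead (importance-weighted
    variant).
    """
    terms = list(term_names) if term_names is not None else dm.terms()
    columns = dm.columns_for(terms)
    X, w = _stack_strata(dm, columns)
    if not np.isclose(w[0], 1.0) or len(w) < 2:
        raise ValueError("each stratum needs one used point with weight 1")
    if not weights_in_likelihood:
        w = np.ones_like(w)
    beta, se, ll, converged, keep = fit_conditional_logit(X, w, columns)
    kept_cols = [columns[k] for k in keep]
    z = {c: (b / s if s > 0 else np.nan) for c, b, s in zip(kept_cols, beta, se)}
    return FittedSelectionModel(
        order=3, season=dm.season, terms=terms, columns=kept_cols,
        beta=dict(zip(kept_cols, beta)), se=dict(zip(kept_cols, se)),
        z=z, p={c: float(wald_p(v)) if np.isfinite(v) else np.nan
                for c, v in z.items()},
        log_likelihood=ll, converged=converged,
        stats=dict(dm.stats), clamp_bounds=dict(dm.clamp_bounds),
        n_obs=X.shape[0])


# --------------------------------------------------------------------------
# second order: random-intercept logistic GLMM (Gauss–Hermite)
# --------------------------------------------------------------------------

class _GlmmData:
    def __init__(self, dm: DesignMatrix, columns, n_nodes=20):
        df = dm.df
        self.X = df[columns].to_numpy(dtype=float)
        self.y = dm.outcome.astype(float)
        groups, self.group_idx = np.unique(df["individual_id"].to_numpy(),
                                           return_inverse=True)
        self.groups = groups
        self.n_groups = len(groups)
        nodes, wts = hermgauss(n_nodes)
        self.nodes = nodes                    # physicists' Hermite
        self.logw = np.log(wts) - 0.5 * np.log(np.pi)
        self.columns = columns


def _group_modes(eta, data: _GlmmData, sigma, n_iter=30, tol=1e-10):
    """Posterior mode and curvature of each group's random intercept."""
    m = np.zeros(data.n_groups)
    for _ in range(n_iter):
        E = eta + m[data.group_idx]
        P = 1.0 / (1.0 + np.exp(-E))
        g = np.bincount(data.group_idx, weights=data.y - P,
                        minlength=data.n_groups) - m / sigma ** 2
        h = -np.bincount(data.group_idx, weights=P * (1.0 - P),
                         minlength=data.n_groups) - 1.0 / sigma ** 2
        step = g / h
        m = m - step
        if np.abs(step).max() < tol:
            break
    E = eta + m[data.group_idx]
    P = 1.0 / (1.0 + np.exp(-E))
    h = -np.bincount(data.group_idx, weights=P * (1.0 - P),
                     minlength=data.n_groups) - 1.0 / sigma ** 2
    return m, 1.0 / np.sqrt(-h)


def _glmm_negloglik_grad(params, data: _GlmmData):
    """Adaptive Gauss–Hermite marginal negative log-likelihood and gradient.

    Quadrature nodes are recentred on each group's posterior mode and scaled
    by its curvature, so a modest node count integrates sharply peaked
    integrands (large clusters) accurately.  The gradient treats the modes
    as fixed; the induced error is of the order of the quadrature error.
    """
    p = data.X.shape[1]
    b0, beta, logsig = params[0], params[1:1 + p], params[-1]
    sigma = np.exp(logsig)
    eta = b0 + data.X @ beta                              # (n,)
    mode, tau = _group_modes(eta, data, sigma)            # (G,), (G,)
    t = data.nodes                                        # (K,)
    B = mode[:, None] + np.sqrt(2.0) * tau[:, None] * t[None, :]   # (G, K)
    E = eta[:, None] + B[data.group_idx]                  # (n, K)
    llp = np.where(data.y[:, None] > 0.5, -np.logaddexp(0.0, -E),
                   -np.logaddexp(0.0, E))
    P = 1.0 / (1.0 + np.exp(-E))
    R = data.y[:, None] - P                               # (n, K)
    K = len(t)
    S = np.zeros((data.n_groups, K))
    np.add.at(S, data.group_idx, llp)
    # exponents of the transformed integrand, including the Normal prior
    M = (S - B ** 2 / (2.0 * sigma ** 2)
         + data.logw[None, :] + t[None, :] ** 2 + 0.5 * np.log(np.pi))
    m = M.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(M - m).sum(axis=1))
    ll = float((lse + np.log(np.sqrt(2.0) * tau)
                - 0.5 * np.log(2.0 * np.pi * sigma ** 2)).sum())
    alpha = np.exp(M - lse[:, None])                      # (G, K) softmax
    A = alpha[data.group_idx]                             # (n, K)
    g_eta = (A * R).sum(axis=1)                           # (n,)
    grad_b0 = g_eta.sum()
    grad_beta = data.X.T @ g_eta
    # d/dlogsig of (-b^2 / 2 sigma^2 - log sigma) at fixed nodes
    grad_logsig = float((alpha * (B ** 2 / sigma ** 2 - 1.0)).sum())
    grad = np.concatenate([[grad_b0], grad_beta, [grad_logsig]])
    return -ll, -grad


def fit_second_order(dm: DesignMatrix, term_names=None,
                     n_nodes: int = 20) -> FittedSelectionModel:
    """Random-intercept logistic GLMM of used vs. study-area-available points.

    Used points carry their individual's id; the shared pool of study-area
    available points forms a single pseudo-group, so the random intercept is
    an individual-level use effect.  Requires at least two individuals.
    """
    terms = list(term_names) if term_names is not None else dm.terms()
    columns = dm.columns_for(terms)
    used_ids = dm.df.loc[dm.df.role == "used", "individual_id"].nunique()
    if used_ids < 2:
        raise ValueError("the random intercept needs at least 2 individuals")
    data = _GlmmData(dm, columns, n_nodes)
    p = len(columns)
    # warm start from the pooled ordinary logistic fit
    x0 = np.zeros(p + 2)
    x0[-1] = np.log(0.5)
    try:
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = sm.GLM(data.y, sm.add_constant(data.X),
                            family=sm.families.Binomial()).fit()
        x0[:p + 1] = pooled.params
    except Exception:
        pass
    res = optimize.minimize(_glmm_negloglik_grad, x0, args=(data,), jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    params = res.x
    hess = _gradient_hessian(lambda q: _glmm_negloglik_grad(q, data)[1], params)
    se_all = np.full(len(params), np.nan)
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        se_all = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass
    converged = bool(res.success) and np.isfinite(res.fun)
    if np.abs(params[1:1 + p]).max(initial=0.0) > 30:
        warnings.warn("extreme coefficient magnitude: possible complete separation")
        converged = False
    beta = dict(zip(columns, params[1:1 + p]))
    se = dict(zip(columns, se_all[1:1 + p]))
    z = {c: (beta[c] / se[c] if se[c] and np.isfinite(se[c]) else np.nan)
         for c in columns}
    return FittedSelectionModel(
        order=2, season=dm.season, terms=terms, columns=columns,
        beta=beta, se=se, z=z,
        p={c: float(wald_p(v)) if np.isfinite(v) else np.nan for c, v in z.items()},
        log_likelihood=float(-res.fun), converged=converged,
        intercept=float(params[0]),
        random_intercept_sd=float(np.exp(params[-1])),
        stats=dict(dm.stats), clamp_bounds=dict(dm.clamp_bounds),
        n_obs=len(data.y))


def _gradient_hessian(grad_fn, x, eps=1e-5):
    """Hessian by central finite differences of an analytic gradient."""
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2 * eps)
    return 0.5 * (H + H.T)


# --------------------------------------------------------------------------
# fitter protocol (shared by screening and stepwise)
# --------------------------------------------------------------------------

class ConditionalLogitFitter:
    """Third-order fitter exposing loglik-based and Wald-based comparisons."""

    order = 3

    def __init__(self, dm: DesignMatrix, weights_in_likelihood: bool = False):
        self.dm = dm
        self.weights_in_likelihood = weights_in_likelihood

    def fit(self, terms) -> FittedSelectionModel:
        return fit_third_order(self.dm, terms, self.weights_in_likelihood)

    def loglik(self, terms) -> tuple[float, int]:
        if not terms:
            columns = self.dm.columns_for(self.dm.terms())[:1]
            X, w = _stack_strata(self.dm, columns)
            if not self.weights_in_likelihood:
                w = np.ones_like(w)
            return conditional_loglik(np.zeros(1), X * 0.0, w), 0
        model = self.fit(terms)
        return model.log_likelihood, len(model.columns)


class PooledLogisticFitter:
    """Ordinary (pooled) logistic for fast second-order screening."""

    order = 2

    def __init__(self, dm: DesignMatrix):
        self.dm = dm
        self.y = dm.outcome.astype(float)

    def loglik(self, terms) -> tuple[float, int]:
        import statsmodels.api as sm
        cols = self.dm.columns_for(terms)
        X = sm.add_constant(self.dm.df[cols].to_numpy(dtype=float)) if cols \
            else np.ones((len(self.y), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(self.y, X, family=sm.families.Binomial()).fit()
        return float(fit.llf), X.shape[1] - 1


class GlmmFitter:
    """Second-order fitter: GLMM fits for stepwise, pooled LR for blocks."""

    order = 2

    def __init__(self, dm: DesignMatrix, n_nodes: int = 20):
        self.dm = dm
        self.n_nodes = n_nodes
        self._screen = PooledLogisticFitter(dm)

    def fit(self, terms) -> FittedSelectionModel:
        return fit_second_order(self.dm, terms, self.n_nodes)

    def loglik(self, terms) -> tuple[float, int]:
        return self._screen.loglik(terms)


def screen_univariate(fitter, terms=None) -> ScreeningReport:
    """Likelihood-ratio screen of each term against the null (retain P < 0.20).

    The land-cover block is tested jointly (9 df); a quadratic term is tested
    jointly with its linear partner (2 df).
    """
    dm = fitter.dm
    if len(np.unique(dm.outcome)) < 2:
        raise ValueError("design is degenerate: only one outcome value")
    terms = list(terms) if terms is not None else dm.terms()
    if not terms:
        raise ValueError("no candidate terms to screen")
    report = ScreeningReport()
    ll0, _ = fitter.loglik([])
    for term in terms:
        test_set = [term]
        if term in QUADRATIC_PARTNERS:
            test_set = [QUADRATIC_PARTNERS[term], term]
        ll1, df = fitter.loglik(test_set)
        lr = max(2.0 * (ll1 - ll0), 0.0)
        pval = float(stats.chi2.sf(lr, max(df, 1)))
        report.univariate_p[term] = pval
        (report.retained if pval < SCREEN_P else report.screened_out).append(term)
    # hierarchy: a quadratic can only survive alongside its linear partner
    for quad, lin in QUADRATIC_PARTNERS.items():
        if quad in report.retained and lin not in report.retained:
            report.retained.append(lin)
            if lin in report.screened_out:
                report.screened_out.remove(lin)
    return report


def prune_collinear(dm: DesignMatrix, retained, report: ScreeningReport,
                    threshold: float = COLLINEAR_R):
    """Drop one member of each |r| >= 0.7 pair (the weaker univariate one).

    Correlations are Pearson r over the estimation rows among the retained
    linear continuous terms; quadratic columns are exact functions of their
    partners and the land-cover block is kept intact, so neither enters the
    scan.  Iterates until no offending pair remains.
    """
    singles = [t for t in retained
               if t != "landcover" and t not in QUADRATIC_PARTNERS]
    current = list(retained)
    while True:
        worst = None
        for a_i in range(len(singles)):
            for b_i in range(a_i + 1, len(singles)):
                a, b = singles[a_i], singles[b_i]
                if a not in current or b not in current:
                    continue
                r = float(np.corrcoef(dm.df[a], dm.df[b])[0, 1])
                if abs(r) >= threshold and (worst is None or abs(r) > abs(worst[2])):
                    worst = (a, b, r)
        if worst is None:
            return current
        a, b, r = worst
        pa = report.univariate_p.get(a, 1.0)
        pb = report.univariate_p.get(b, 1.0)
        drop = a if pa > pb else b
        keep = b if drop == a else a
        current.remove(drop)
        # a dropped linear partner takes its quadratic with it
        for quad, lin in QUADRATIC_PARTNERS.items():
            if lin == drop and quad in current:
                current.remove(quad)
                report.collinearity_dropped.append(quad)
        report.collinear_pairs.append((keep, drop, r))
        report.collinearity_dropped.append(drop)


def backward_stepwise(fitter, retained, report: ScreeningReport | None = None,
                      alpha: float = STEPWISE_P):
    """Remove the single worst term with P > 0.05 until all terms hold.

    Single terms are judged by their Wald P; the land-cover block only by its
    joint likelihood-ratio P (individual level Ps are reported, not acted
    on); a quadratic is removed before its linear partner, and a linear term
    becomes removable only once its quadratic is gone.  Returns the final
    model and the completed screening report.
    """
    report = report or ScreeningReport(retained=list(retained))
    terms = list(retained)
    if not terms:
        raise ValueError("no terms to reduce")
    model = fitter.fit(terms)
    while terms:
        candidates = {}
        for term in terms:
            if term == "landcover":
                ll1, df1 = fitter.loglik(terms)
                ll0, df0 = fitter.loglik([t for t in terms if t != "landcover"])
                lr = max(2.0 * (ll1 - ll0), 0.0)
                pval = float(stats.chi2.sf(lr, max(df1 - df0, 1)))
                model.block_p["landcover"] = pval
                candidates[term] = pval
            elif term in QUADRATIC_PARTNERS.values() and any(
                    q in terms for q, l in QUADRATIC_PARTNERS.items() if l == term):
                continue  # linear locked while its quadratic is in the model
            else:
                col = term
                pval = model.p.get(col, np.nan)
                candidates[term] = pval if np.isfinite(pval) else 1.0
        over = {t: p for t, p in candidates.items() if p > alpha}
        if not over:
            break
        worst = max(over, key=over.get)
        report.stepwise_removed.append((worst, float(over[worst])))
        terms.remove(worst)
        if not terms:
            warnings.warn("backward stepwise removed every term; null model returned")
            model = None
            break
        model = fitter.fit(terms)
    if report is not None:
        report.retained = terms
    return model, report


def reduce_and_fit(fitter, dm: DesignMatrix):
    """Full reduction chain: screen -> collinearity prune -> stepwise fit."""
    report = screen_univariate(fitter)
    retained = prune_collinear(dm, report.retained, report)
    report.retained = retained
    if not retained:
        raise ValueError("no variable survived univariate screening")
    return backward_stepwise(fitter, retained, report)
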