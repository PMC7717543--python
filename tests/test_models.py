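"""Selection estimators: conditional logit, GLMM, screening, stepwise."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from migratescale import models as mod
from migratescale import synthetic as syn
from migratescale.covariates import DesignMatrix


def _strata_dm(X, individual="ind000"):
    """Wrap an (S, 6, p) array as a third-order DesignMatrix."""
    S, J, p = X.shape
    rows = []
    for s in range(S):
        for j in range(J):
            rows.append({
                "point_id": f"s{s}-{j}", "stratum_id": f"s{s:04d}",
                "individual_id": individual, "season": "spring",
                "role": "used" if j == 0 else "available",
                "order": 3, "weight": 1.0 if j == 0 else 0.2,
                "x": 0.0, "y": 0.0, "t": 90.0,
                **{f"c{k}": X[s, j, k] for k in range(p)},
            })
    return DesignMatrix(df=pd.DataFrame(rows), order=3, season="spring")


class TestConditionalLogit:
    def test_loglik_maximum_matches_grid_search(self, rng):
        """Newton optimum vs. brute-force grid (step 1e-3) on 5 small strata,
        using the weighted-denominator likelihood."""
        X = rng.standard_normal((5, 6, 1))
        w = np.array([1.0] + [0.2] * 5)
        beta, se, ll, conv, _ = mod.fit_conditional_logit(X, w)
        grid = np.arange(-3.0, 3.0, 1e-3)
        lls = np.array([mod.conditional_loglik(np.array([b]), X, w)
                        for b in grid])
        assert conv
        assert ll >= lls.max() - 1e-4
        assert abs(beta[0] - grid[lls.argmax()]) <= 2e-3

    def test_matched_pair_closed_form(self, rng):
        """1 available per stratum, all weights 1, binary covariate: the
        conditional MLE is log(n10/n01) over discordant pairs."""
        n = 400
        X = rng.integers(0, 2, (n, 2, 1)).astype(float)
        beta, _, _, conv, _ = mod.fit_conditional_logit(X, np.ones(2))
        n10 = int(((X[:, 0, 0] == 1) & (X[:, 1, 0] == 0)).sum())
        n01 = int(((X[:, 0, 0] == 0) & (X[:, 1, 0] == 1)).sum())
        assert conv
        assert beta[0] == pytest.approx(np.log(n10 / n01), abs=1e-6)

    def test_agrees_with_statsmodels_conditional_logit(self, rng):
        """Unweighted multi-covariate fit vs. statsmodels ConditionalLogit."""
        import statsmodels.api as sm
        S = 150
        X = rng.standard_normal((S, 6, 2))
        eta = X @ np.array([0.8, -0.4])
        used = np.array([rng.choice(6, p=np.exp(e) / np.exp(e).sum())
                         for e in eta])
        for s, u in enumerate(used):  # move the chosen point to slot 0
            X[s, [0, u]] = X[s, [u, 0]]
        beta, se, _, conv, _ = mod.fit_conditional_logit(X, np.ones(6))
        y = np.zeros(S * 6)
        y[::6] = 1
        groups = np.repeat(np.arange(S), 6)
        ref = sm.ConditionalLogit(y, X.reshape(-1, 2), groups=groups).fit(disp=0)
        assert conv
        assert np.allclose(beta, ref.params, atol=1e-4)
        assert np.allclose(se, ref.bse, rtol=1e-3)

    def test_constant_within_strata_dropped(self, rng):
        X = rng.standard_normal((20, 6, 2))
        X[:, :, 1] = np.arange(20)[:, None]  # varies across, not within
        dm = _strata_dm(X)
        with pytest.warns(UserWarning, match="no within-stratum contrast"):
            model = mod.fit_third_order(dm, term_names=["c0", "c1"])
        assert model.columns == ["c0"]

    def test_weighted_variant_differs_from_exact(self, landscape, rng):
        X, names = syn.simulate_choice_strata(
            landscape, {"grassland": 1.0}, 400, rng)
        dm = _strata_dm(X)
        exact = mod.fit_third_order(dm, term_names=["c0"])
        weighted = mod.fit_third_order(dm, term_names=["c0"],
                                       weights_in_likelihood=True)
        assert exact.beta["c0"] != pytest.approx(weighted.beta["c0"], abs=1e-3)

    def test_wald_p_identity(self, dm3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = mod.fit_third_order(dm3)
        for c in model.columns:
            if np.isfinite(model.z[c]):
                assert model.z[c] == pytest.approx(model.beta[c] / model.se[c])
                assert model.p[c] == pytest.approx(
                    2 * stats.norm.sf(abs(model.z[c])))


class TestSecondOrderGlmm:
    @staticmethod
    def _panel_dm(df):
        df = df.copy()
        df["role"] = np.where(df.used == 1, "used", "available")
        df["weight"] = 1.0
        return DesignMatrix(df=df, order=2, season="spring")

    def test_sigma_zero_matches_pooled_logistic(self, rng):
        import statsmodels.api as sm
        df = syn.simulate_binary_panel(np.array([1.0, -0.5]), -0.3, 0.0,
                                       20, 150, rng)
        dm = self._panel_dm(df)
        model = mod.fit_second_order(dm, term_names=["x0", "x1"])
        pooled = sm.GLM(df.used, sm.add_constant(df[["x0", "x1"]]),
                        family=sm.families.Binomial()).fit()
        for name, col in (("x0", "x0"), ("x1", "x1")):
            assert abs(model.beta[name] - pooled.params[col]) \
                < 2 * pooled.bse[col]
        assert model.random_intercept_sd < 0.15

    def test_recovers_variance_component(self, rng):
        df = syn.simulate_binary_panel(np.array([0.8]), -0.2, 0.9, 40, 120, rng)
        model = mod.fit_second_order(self._panel_dm(df), term_names=["x0"])
        assert model.converged
        assert 0.6 < model.random_intercept_sd < 1.25

    def test_single_individual_rejected(self, rng):
        df = syn.simulate_binary_panel(np.array([0.5]), 0.0, 0.5, 1, 100, rng)
        with pytest.raises(ValueError, match="at least 2 individuals"):
            mod.fit_second_order(self._panel_dm(df), term_names=["x0"])


class TestScreening:
    def _toy_dm(self, x, y):
        df = pd.DataFrame({"role": np.where(y == 1, "used", "available"),
                           "weight": 1.0, "individual_id": "i0", "slope": x})
        return DesignMatrix(df=df, order=2, season="spring")

    def test_perfectly_separating_covariate_retained(self):
        y = np.array([1] * 10 + [0] * 10)
        dm = self._toy_dm(y.astype(float), y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = mod.screen_univariate(mod.PooledLogisticFitter(dm),
                                        terms=["slope"])
        assert "slope" in rep.retained
        assert rep.univariate_p["slope"] < 0.20

    def test_null_covariate_usually_dropped(self, rng):
        """P < 0.20 retains ~20% of independent covariates; over 30
        replicates of n=2000 most are screened out."""
        dropped = 0
        for _ in range(30):
            y = rng.integers(0, 2, 2000)
            x = rng.standard_normal(2000)
            dm = self._toy_dm(x, y)
            rep = mod.screen_univariate(mod.PooledLogisticFitter(dm),
                                        terms=["slope"])
            dropped += "slope" in rep.screened_out
        assert dropped / 30 >= 0.65

    def test_degenerate_design_rejected(self):
        dm = self._toy_dm(np.ones(5), np.ones(5, dtype=int))
        with pytest.raises(ValueError, match="degenerate"):
            mod.screen_univariate(mod.PooledLogisticFitter(dm))

    def test_every_variable_accounted_once(self, dm3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter = mod.ConditionalLogitFitter(dm3)
            rep = mod.screen_univariate(fitter)
            retained = mod.prune_collinear(dm3, rep.retained, rep)
            rep.retained = retained
            if retained:
                _, rep = mod.backward_stepwise(fitter, retained, rep)
        assert rep.accounted() == set(dm3.terms())


class TestPruneCollinear:
    def _dm_from_cols(self, **cols):
        n = len(next(iter(cols.values())))
        df = pd.DataFrame({"role": ["used", "available"] * (n // 2),
                           "weight": 1.0, **cols})
        return DesignMatrix(df=df, order=2, season="spring")

    def test_duplicated_column_one_dropped(self, rng):
        x = rng.standard_normal(100)
        dm = self._dm_from_cols(slope=x, vrm=x.copy())
        rep = mod.ScreeningReport(univariate_p={"slope": 0.01, "vrm": 0.05})
        kept = mod.prune_collinear(dm, ["slope", "vrm"], rep)
        assert kept == ["slope"]          # weaker univariate support dropped
        assert rep.collinearity_dropped == ["vrm"]

    def test_pair_below_threshold_kept(self, rng):
        x = rng.standard_normal(4000)
        y = 0.69 * x + np.sqrt(1 - 0.69 ** 2) * rng.standard_normal(4000)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < 0.7
        dm = self._dm_from_cols(slope=x, vrm=y)
        rep = mod.ScreeningReport(univariate_p={"slope": 0.01, "vrm": 0.05})
        kept = mod.prune_collinear(dm, ["slope", "vrm"], rep)
        assert set(kept) == {"slope", "vrm"}

    def test_three_mutually_correlated_end_below_threshold(self, rng):
        base = rng.standard_normal(500)
        dm = self._dm_from_cols(
            slope=base + 0.1 * rng.standard_normal(500),
            vrm=base + 0.1 * rng.standard_normal(500),
            ndvi=base + 0.1 * rng.standard_normal(500))
        rep = mod.ScreeningReport(
            univariate_p={"slope": 0.01, "vrm": 0.02, "ndvi": 0.03})
        kept = mod.prune_collinear(dm, ["slope", "vrm", "ndvi"], rep)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert abs(np.corrcoef(dm.df[a], dm.df[b])[0, 1]) < 0.7


class TestBackwardStepwise:
    def test_all_significant_model_unchanged(self, landscape, rng):
        X, names = syn.simulate_choice_strata(
            landscape, {"grassland": 1.5, "slope": -0.8}, 600, rng)
        dm = _strata_dm(X)
        fitter = mod.ConditionalLogitFitter(dm)
        model, rep = mod.backward_stepwise(fitter, ["c0", "c1"])
        assert rep.stepwise_removed == []
        assert model.terms == ["c0", "c1"]

    def test_noise_term_removed_first(self, landscape, rng):
        """A pure-noise covariate appended to a strong model is the first
        stepwise removal in nearly every replicate."""
        removed_first = 0
        reps = 20
        for _ in range(reps):
            X, _ = syn.simulate_choice_strata(landscape, {"grassland": 1.5},
                                              400, rng)
            noise = rng.standard_normal(X.shape[:2])[..., None]
            dm = _strata_dm(np.concatenate([X, noise], axis=2))
            fitter = mod.ConditionalLogitFitter(dm)
            model, rep = mod.backward_stepwise(fitter, ["c0", "c1"])
            if rep.stepwise_removed and rep.stepwise_removed[0][0] == "c1":
                removed_first += 1
        assert removed_first / reps >= 0.8

    def test_removal_sequence_shrinks_by_one(self, rng):
        X = rng.standard_normal((200, 6, 3))  # all noise: everything goes
        dm = _strata_dm(X)
        fitter = mod.ConditionalLogitFitter(dm)
        with pytest.warns(UserWarning, match="null model"):
            model, rep = mod.backward_stepwise(fitter, ["c0", "c1", "c2"])
        assert model is None
        assert [len(rep.retained)] == [0]
        assert len(rep.stepwise_removed) == 3

    def test_quadratic_removed_before_linear(self, dm3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter = mod.ConditionalLogitFitter(dm3)
            model, rep = mod.backward_stepwise(
                fitter, ["landcover", "slope", "slope_sq"])
        removed = [t for t, _ in rep.stepwise_removed]
        if "slope" in removed and "slope_sq" in removed:
            assert removed.index("slope_sq") < removed.index("slope")
        if model is not None and "slope_sq" in model.terms:
            assert "slope" in model.terms
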