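"""NSD computation, nonlinear classification, bounds, and pathway filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migratescale import migration as mig
from migratescale import synthetic as syn


def _track(xy, dt_hours=4.0):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * dt_hours / 24.0
    return syn.Track("t0", t, xy[:, 0], xy[:, 1], dt_hours)


class TestComputeNsd:
    def test_three_four_five_triangle(self):
        nsd = mig.compute_nsd(_track([(0, 0), (3, 4)]))
        assert np.allclose(nsd, [0.0, 25.0])

    def test_stationary_track_all_zero(self):
        nsd = mig.compute_nsd(_track([(5, 5)] * 10))
        assert np.allclose(nsd, 0.0)

    def test_single_fix_rejected(self):
        with pytest.raises(ValueError):
            syn.Track("t", [0.0], [0.0], [0.0], 4.0)

    @given(dx=st.floats(-1e5, 1e5), dy=st.floats(-1e5, 1e5),
           angle=st.floats(0, 2 * np.pi))
    @settings(max_examples=50, deadline=None)
    def test_translation_and_rotation_invariant(self, dx, dy, angle):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 1000, (20, 2))
        base = mig.compute_nsd(_track(xy))
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = xy @ rot.T + [dx, dy]
        assert np.allclose(mig.compute_nsd(_track(moved)), base, rtol=1e-9,
                           atol=1e-4)

    def test_migrant_max_nsd_near_squared_range_distance(self, landscape):
        truth = syn.SimulationTruth(beta_true={},
                                    population_mix={"migratory": 1.0}, seed=21)
        tr = syn.simulate_tracks(landscape, truth, 1, 4.0, t_end=200.0)[0]
        ind = truth.individuals[0]
        d2 = ((ind["summer_center"][0] - ind["winter_center"][0]) ** 2
              + (ind["summer_center"][1] - ind["winter_center"][1]) ** 2)
        _, nsd = mig.daily_nsd(tr)
        # summer plateau: average NSD after arrival
        plateau = nsd[-30:].mean()
        assert abs(plateau / d2 - 1.0) < 0.1


class TestDailyNsd:
    def test_one_value_per_day_nearest_noon(self):
        t = np.array([0.1, 0.45, 0.9, 1.2, 1.55])
        tr = syn.Track("t", t, np.arange(5.0), np.zeros(5), 4.0)
        days, nsd = mig.daily_nsd(tr)
        assert list(days) == [0, 1]
        assert np.allclose(nsd, [1.0, 16.0])  # fixes at 0.45 and 1.55


def _sigmoid_series(delta, th1, th2, phi, n_days=365, noise=0.01, seed=0,
                    delta2=None):
    rng = np.random.default_rng(seed)
    t = np.arange(n_days, dtype=float)
    d2 = delta if delta2 is None else delta2
    s = (delta / (1 + np.exp((th1 - t) / phi))
         - d2 / (1 + np.exp((th2 - t) / phi)))
    return t, s + rng.normal(0, noise * delta, n_days)


class TestFitNsdModels:
    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 30"):
            mig.fit_nsd_models(np.arange(10), np.ones(10))

    def test_constant_series_classified_resident(self):
        rng = np.random.default_rng(8)
        correct = 0
        for rep in range(100):
            t = np.arange(120.0)
            s = 1e6 + rng.normal(0, 5e4, 120)
            fits = mig.fit_nsd_models(t, s)
            if mig.classify_track(fits) == "resident":
                correct += 1
        assert correct >= 95

    def test_clean_double_sigmoid_recovers_migrant(self):
        t, s = _sigmoid_series(1e8, 80, 280, 5, seed=2)
        fits = mig.fit_nsd_models(t, s)
        best = min((f for f in fits if f.converged), key=lambda f: f.aic)
        assert best.model_family == "migrant"
        assert abs(best.parameters["delta"] / 1e8 - 1.0) < 0.1
        assert abs(best.parameters["theta1"] - 80) < 3
        assert abs(best.parameters["theta2"] - 280) < 3

    def test_mixed_migrant_distinct_return_level(self):
        t, s = _sigmoid_series(1e8, 80, 280, 5, seed=3, delta2=0.55e8)
        fits = mig.fit_nsd_models(t, s)
        best = min((f for f in fits if f.converged), key=lambda f: f.aic)
        assert best.model_family == "mixed_migrant"


class TestClassifyTrack:
    def test_minimum_aic_wins(self):
        fits = [mig.NsdFit("resident", {"c": 1.0}, 100.0, True),
                mig.NsdFit("migrant", {}, 50.0, True)]
        assert mig.classify_track(fits) == "migratory"

    def test_tie_goes_to_simpler_family(self):
        fits = [mig.NsdFit("migrant", {}, 80.0, True),
                mig.NsdFit("resident", {"c": 1.0}, 80.0, True)]
        assert mig.classify_track(fits) == "resident"

    def test_nonconverged_excluded(self):
        fits = [mig.NsdFit("migrant", {}, 10.0, False),
                mig.NsdFit("resident", {"c": 1.0}, 90.0, True)]
        assert mig.classify_track(fits) == "resident"

    def test_no_converged_fit_raises(self):
        with pytest.raises(ValueError, match="cannot be classified"):
            mig.classify_track([mig.NsdFit("resident", {}, np.inf, False)])

    def test_simulated_population_classification(self, classified, truth):
        want = [ind["status"] for ind in truth.individuals]
        got = [r.status for r in classified]
        agree = sum(mig.is_migratory(w) == mig.is_migratory(g)
                    for w, g in zip(want, got))
        assert agree / len(want) >= 0.9


class TestMigrationBounds:
    def test_spring_bounds_definition(self):
        fit = mig.NsdFit("migrant", {"theta1": 100.0, "phi1": 5.0,
                                     "theta2": 280.0, "phi2": 4.0}, 0.0, True)
        assert mig.migration_bounds(fit, "spring") == (90.0, 110.0)
        assert mig.migration_bounds(fit, "fall") == (272.0, 288.0)

    def test_small_phi_gives_tight_window(self):
        fit = mig.NsdFit("migrant", {"theta1": 100.0, "phi1": 0.5,
                                     "theta2": 280.0, "phi2": 4.0}, 0.0, True)
        lo, hi = mig.migration_bounds(fit, "spring")
        assert hi - lo == pytest.approx(2.0)

    def test_resident_fit_rejected(self):
        fit = mig.NsdFit("resident", {"c": 1.0}, 0.0, True)
        with pytest.raises(ValueError, match="undefined"):
            mig.migration_bounds(fit, "spring")

    def test_recovered_bounds_near_true_switch_dates(self, landscape):
        truth = syn.SimulationTruth(beta_true={},
                                    population_mix={"migratory": 1.0}, seed=31)
        trs = syn.simulate_tracks(landscape, truth, 5, 4.0)
        errors = []
        for tr, ind in zip(trs, truth.individuals):
            days, nsd = mig.daily_nsd(tr)
            fits = mig.fit_nsd_models(days, nsd)
            best = min((f for f in fits if f.converged
                        and f.model_family in ("migrant", "mixed_migrant")),
                       key=lambda f: f.aic)
            lo, hi = mig.migration_bounds(best, "spring")
            errors.append(abs(lo - ind["spring_day"]))
        assert np.median(errors) <= 4.0
        assert max(errors) <= 8.0


class TestBuildSegment:
    def _uniform_track(self, n, step=400.0):
        xy = np.column_stack([np.arange(n) * step, np.zeros(n)])
        return _track(xy)

    def test_under_twenty_observations_excluded(self):
        tr = self._uniform_track(19)
        seg, reason = mig.build_segment(tr, (0.0, 10.0), "spring")
        assert seg is None
        assert "< 20" in reason

    def test_clean_segment_unchanged(self):
        tr = self._uniform_track(40)
        seg, reason = mig.build_segment(tr, (0.0, 10.0), "spring")
        assert reason is None
        assert seg.n_obs == 40

    def test_stopover_cluster_collapsed_to_one_location(self, rng):
        # 20 long steps, a 12-fix tight cluster, 20 long steps: the short
        # steps are well under a quarter of all steps, so the 25th-percentile
        # threshold sits above every within-cluster step
        xs = list(np.arange(20) * 500.0)
        cluster_x = xs[-1] + 800.0  # entry/exit hops clearly longer than thr
        xs += [cluster_x + v for v in rng.uniform(-5, 5, 12)]
        xs += list(cluster_x + 800.0 + np.arange(20) * 500.0)
        tr = _track(np.column_stack([xs, np.zeros(len(xs))]))
        seg, reason = mig.build_segment(tr, (0.0, 10.0), "spring")
        assert reason is None
        # the 12-fix stopover keeps exactly its first location
        assert seg.n_obs == len(xs) - 11

    def test_empty_window_excluded(self):
        tr = self._uniform_track(30)
        seg, reason = mig.build_segment(tr, (100.0, 110.0), "spring")
        assert seg is None and "empty" in reason

    def test_never_more_locations_than_window(self, tracks):
        tr = tracks[0]
        seg, reason = mig.build_segment(tr, (70.0, 110.0), "spring")
        in_window = ((tr.t >= tr.t[0] + 70.0) & (tr.t <= tr.t[0] + 110.0)).sum()
        if seg is not None:
            assert seg.n_obs <= in_window


class TestSummaryAndPooling:
    def test_classification_summary_tally(self):
        statuses = ["migratory"] * 3 + ["mixed_migratory"] * 2 + ["resident"] * 5
        s = mig.classification_summary(statuses)
        assert s["n_migratory"] == 5 and s["n_resident"] == 5
        assert s["percent_migratory"] == pytest.approx(50.0)

    def test_pool_segments_concatenates_years(self, spring_segments):
        seg = spring_segments[0]
        shifted = mig.MigrationSegment(seg.individual_id, seg.season,
                                       seg.start_day + 365, seg.end_day + 365,
                                       seg.t + 365, seg.x, seg.y,
                                       seg.fix_interval, seg.epoch)
        pooled = mig.pool_segments([seg, shifted])
        assert pooled.n_obs == 2 * seg.n_obs
        with pytest.raises(ValueError, match="share individual"):
            mig.pool_segments([seg, mig.MigrationSegment(
                "other", seg.season, 0, 1, seg.t, seg.x, seg.y, 4.0, None)])
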