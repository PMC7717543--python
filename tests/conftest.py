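"""Shared fixtures: one synthetic landscape and simulated population.

Everything is generated at test time from fixed seeds; the heavier artifacts
are session-scoped so the chain landscape -> tracks -> classification ->
strata -> design matrices is built once and reused across modules.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from migratescale import covariates as cov
from migratescale import design as des
from migratescale import migration as mig
from migratescale import synthetic as syn


@pytest.fixture(scope="session")
def landscape():
    cfg = syn.LandscapeConfig(width=15_000.0, height=15_000.0)
    return syn.generate_landscape(cfg, seed=1)


@pytest.fixture(scope="session")
def truth():
    return syn.SimulationTruth(
        beta_true={"grassland": 1.0, "unpaved_road_density": -0.5},
        population_mix={"migratory": 0.6, "mixed_migratory": 0.1, "resident": 0.3},
        seed=2,
    )


@pytest.fixture(scope="session")
def tracks(landscape, truth):
    return syn.simulate_tracks(landscape, truth, n_individuals=8, fix_interval=4.0)


@pytest.fixture(scope="session")
def classified(tracks):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [mig.classify_and_segment(tr) for tr in tracks]


@pytest.fixture(scope="session")
def spring_segments(classified):
    segs = [r.segments["spring"] for r in classified if "spring" in r.segments]
    assert len(segs) >= 4, "fixture population must yield several spring pathways"
    return segs


@pytest.fixture(scope="session")
def strata_by_individual(spring_segments, landscape):
    out = {}
    for seg in spring_segments:
        dists = des.empirical_move_distributions(seg)
        out[seg.individual_id] = des.generate_strata(seg, dists, landscape, seed=7)
    return out


@pytest.fixture(scope="session")
def design3(strata_by_individual):
    return pd.concat(strata_by_individual.values(), ignore_index=True)


@pytest.fixture(scope="session")
def design2(strata_by_individual, landscape):
    return des.build_second_order_design(strata_by_individual, landscape,
                                         "spring", seed=3,
                                         season_central_day=88.5)


@pytest.fixture(scope="session")
def dm3(design3, landscape):
    return cov.extract(design3, landscape, order=3, season="spring")


@pytest.fixture(scope="session")
def dm2(design2, landscape):
    return cov.extract(design2, landscape, order=2, season="spring")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
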