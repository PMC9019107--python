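import dataclasses

import numpy as np
import pandas as pd
import pytest

import windkite as wk
from windkite import pipeline as pl


def run_annotation(tracks, turbines, wind, terrain):
    kept, _ = pl.filter_flying(tracks)
    kept, _ = pl.exclude_high_frequency(kept)
    annotated, _ = pl.annotate(kept, turbines, wind, terrain)
    return annotated


@pytest.fixture(scope="session")
def small_scenario():
    """A compact near-turbine scenario shared by the model tests."""
    cfg = wk.glmm_recovery_scenario(seed=11, n_birds=15, steps_per_bird=80)
    tracks, turbines, wind, terrain, truth = wk.simulate_scenario(cfg)
    return {"config": cfg, "tracks": tracks, "turbines": turbines,
            "wind": wind, "terrain": terrain, "truth": truth}


@pytest.fixture(scope="session")
def small_annotated(small_scenario):
    return run_annotation(small_scenario["tracks"], small_scenario["turbines"],
                          small_scenario["wind"], small_scenario["terrain"])


@pytest.fixture(scope="session")
def small_glmm_subset(small_annotated):
    subset, _ = pl.subset_glmm(small_annotated)
    return subset


@pytest.fixture(scope="session")
def avoidance_scenario():
    """Default avoidance scenario (distance ramp + wind effect active)."""
    cfg = wk.default_scenario(seed=5)
    tracks, turbines, wind, terrain, truth = wk.simulate_scenario(cfg)
    return {"config": cfg, "tracks": tracks, "turbines": turbines,
            "wind": wind, "terrain": terrain, "truth": truth}


@pytest.fixture(scope="session")
def avoidance_gamm_subset(avoidance_scenario):
    annotated = run_annotation(
        avoidance_scenario["tracks"], avoidance_scenario["turbines"],
        avoidance_scenario["wind"], avoidance_scenario["terrain"])
    subset, _ = pl.subset_gamm(annotated)
    return subset


@pytest.fixture(scope="session")
def avoidance_gamm_fit(avoidance_gamm_subset):
    return wk.fit_facing_gamm(avoidance_gamm_subset)


def make_tracks(rows):
    """Build an internal-dialect track frame from (bird, t_s, lon, lat,
    height, speed, heading) tuples."""
    t0 = np.datetime64("2013-08-15T10:00:00")
    recs = []
    for bird, t_s, lon, lat, h, v, hd in rows:
        recs.append({"bird_id": bird,
                     "timestamp": t0 + np.timedelta64(int(t_s), "s"),
                     "lon": lon, "lat": lat, "height_agl": h,
                     "ground_speed": v, "heading": hd,
                     "sex": "female", "age_class": "adult"})
    return pd.DataFrame(recs)
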