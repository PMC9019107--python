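import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import windkite as wk
from windkite import pipeline as pl
from windkite import simulate as sim

from conftest import run_annotation


class TestScenarioConfig:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError):
            sim.ScenarioConfig(seed=None)

    def test_height_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sim.ScenarioConfig(seed=1, height_mixture=(0.5, 0.5, 0.5))

    def test_yaml_round_trip(self, tmp_path):
        cfg = sim.default_scenario(seed=3)
        cfg.to_yaml(tmp_path / "s.yaml")
        back = sim.ScenarioConfig.from_yaml(tmp_path / "s.yaml")
        assert back == cfg


class TestLandscape:
    def test_single_row_spacing(self):
        cfg = sim.ScenarioConfig(seed=1, n_turbines=10, n_rows=1,
                                 turbine_spacing_m=500.0)
        turbines, _ = sim.simulate_landscape(cfg)
        assert len(turbines) == 10
        d = wk.great_circle_distance(
            turbines["lat"].to_numpy()[:-1], turbines["lon"].to_numpy()[:-1],
            turbines["lat"].to_numpy()[1:], turbines["lon"].to_numpy()[1:])
        assert np.all(np.abs(d - 500.0) < 1.0)

    def test_overlapping_turbines_rejected(self):
        cfg = sim.ScenarioConfig(seed=1, n_turbines=10, n_rows=1,
                                 turbine_spacing_m=40.0)
        with pytest.raises(ValueError, match="50 m"):
            sim.simulate_landscape(cfg)

    def test_flat_terrain_option(self):
        cfg = sim.ScenarioConfig(seed=1, ridge_slope_deg=0.0)
        _, terrain = sim.simulate_landscape(cfg)
        assert (terrain["slope_deg"] == 0.0).all()

    def test_seeded_run_reproducible(self):
        a = sim.simulate_landscape(sim.default_scenario(seed=8))
        b = sim.simulate_landscape(sim.default_scenario(seed=8))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestWind:
    def test_zero_concentration_is_circular_uniform(self):
        cfg = dataclasses.replace(sim.default_scenario(seed=2),
                                  wind_direction_kappa=0.0)
        wind = sim.simulate_wind(cfg, n_records=10_000)
        theta = np.radians(wind["wind_direction_deg"].to_numpy())
        # Rayleigh test for circular uniformity
        n = len(theta)
        R = np.hypot(np.sin(theta).sum(), np.cos(theta).sum()) / n
        p = np.exp(-n * R ** 2)
        assert p > 0.05

    def test_mean_speed_near_target(self):
        cfg = sim.default_scenario(seed=2)
        wind = sim.simulate_wind(cfg, n_records=10_000)
        assert wind["wind_speed_ms"].mean() == pytest.approx(
            cfg.wind_mean_speed_ms, rel=0.05)

    def test_ten_minute_cadence_and_reproducibility(self):
        cfg = sim.default_scenario(seed=2)
        a = sim.simulate_wind(cfg)
        b = sim.simulate_wind(cfg)
        pd.testing.assert_frame_equal(a, b)
        gaps = np.diff(a["timestamp"]).astype("timedelta64[s]").astype(float)
        assert np.all(gaps == 600.0)


class TestTracks:
    def test_null_generator_faces_one_third(self):
        cfg = sim.ScenarioConfig(seed=4, avoidance_depth=0.0, wind_slope=0.0,
                                 bird_intercept_sd=0.0, n_birds=20,
                                 steps_per_bird=250)
        tracks, turbines, wind, terrain, truth = wk.simulate_scenario(cfg)
        phat = truth.points["facing_true"].mean()
        n = len(truth.points)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(phat - 1 / 3) < 3 * se

    def test_strong_avoidance_suppresses_facing_near_turbines(self):
        # deep ramp: true facing probability ~0.07 right under the turbines
        cfg = dataclasses.replace(wk.default_scenario(seed=4),
                                  avoidance_depth=2.0, bird_intercept_sd=0.0)
        _, _, _, _, truth = wk.simulate_scenario(cfg)
        tp = truth.points
        near_low = tp[(tp["height_class"] == "low")
                      & (tp["distance_to_turbine_m"] < 200.0)]
        assert len(near_low) > 30
        assert near_low["facing_true"].mean() < 0.2

    def test_high_class_unaffected_by_distance(self):
        # no bird intercepts, so the binomial standard error is exact
        cfg = dataclasses.replace(wk.default_scenario(seed=4),
                                  bird_intercept_sd=0.0)
        _, _, _, _, truth = wk.simulate_scenario(cfg)
        tp = truth.points[truth.points["height_class"] == "high"]
        phat = tp["facing_true"].mean()
        se = np.sqrt((1 / 3) * (2 / 3) / len(tp))
        assert abs(phat - 1 / 3) < 3 * se

    def test_facing_heading_lies_in_cone(self, small_scenario):
        tracks = small_scenario["tracks"]
        tp = small_scenario["truth"].points
        dev = wk.angular_deviation(tracks["heading"].to_numpy(),
                                   tp["bearing_to_turbine_deg"].to_numpy())
        facing = tp["facing_true"].to_numpy().astype(bool)
        assert np.all(dev[facing] < 60.0)
        assert np.all(dev[~facing] >= 60.0)

    def test_ground_speeds_survive_flying_filter(self, small_scenario):
        kept, rep = pl.filter_flying(small_scenario["tracks"])
        assert rep.n_dropped_not_flying == 0

    def test_generator_annotator_consistency(self, small_scenario,
                                             small_annotated):
        """The pipeline recomputes the generator's internal geometry."""
        tp = small_scenario["truth"].points
        m = small_annotated.merge(tp, on=["bird_id", "timestamp"],
                                  suffixes=("", "_truth"))
        assert len(m) == len(small_annotated)
        for col in ("distance_to_turbine_m", "bearing_to_turbine_deg",
                    "wind_component_ms", "turbine_max_height_m"):
            np.testing.assert_allclose(
                m[col], m[col + "_truth"], rtol=1e-6,
                err_msg=f"generator/annotator mismatch in {col}")
        assert (m["height_class"] == m["height_class_truth"]).all()
        assert (m["facing"] == m["facing_true"]).all()

    def test_true_probability_stored_for_every_point(self, small_scenario):
        tp = small_scenario["truth"].points
        assert len(tp) == (small_scenario["config"].n_birds
                           * small_scenario["config"].steps_per_bird)
        assert tp["p_true"].between(0, 1).all()


class TestExportScenario:
    def test_round_trip_and_self_consistency(self, tmp_path, small_scenario):
        from windkite import io as wio
        paths = sim.export_scenario(
            tmp_path, small_scenario["tracks"], small_scenario["turbines"],
            small_scenario["wind"], small_scenario["terrain"],
            small_scenario["truth"])
        tracks = wio.read_tracks(paths["tracks"])
        turbines = wio.read_turbines(paths["turbines"])
        wind = wio.read_wind(paths["wind"])
        terrain = wio.read_terrain(paths["terrain"])
        assert len(tracks) == len(small_scenario["tracks"])
        np.testing.assert_allclose(tracks["lat"],
                                   small_scenario["tracks"]["lat"])
        # re-annotating the exported files reproduces the stored truth
        ann = run_annotation(tracks, turbines, wind, terrain)
        truth = pd.read_csv(paths["truth_points"],
                            parse_dates=["timestamp"])
        truth["bird_id"] = truth["bird_id"].astype(str)
        m = ann.merge(truth, on=["bird_id", "timestamp"],
                      suffixes=("", "_truth"))
        assert len(m) == len(ann)
        np.testing.assert_allclose(m["distance_to_turbine_m"],
                                   m["distance_to_turbine_m_truth"],
                                   rtol=1e-6)
        np.testing.assert_allclose(m["wind_component_ms"],
                                   m["wind_component_ms_truth"], rtol=1e-6,
                                   atol=1e-9)
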