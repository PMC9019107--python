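"""Synthetic turbine landscapes, wind series, terrain fields and bird tracks
with known avoidance parameters.

The generator emits exactly the quantities the annotation pipeline and the
avoidance models consume, with the generative truth stored alongside, so
every downstream stage can be validated by parameter recovery.  The
behavioural model is the facing statistic run generatively: at each step the
true facing logit is

    eta = eta0 + b_i
          - depth * invlogit((d0 - d) / shape) * 1[LOW]
          + beta_w * w_c * 1[LOW and d <= d0]

where ``d`` is the distance to the nearest turbine, ``w_c`` the wind
component blowing toward it, ``b_i`` a per-bird normal intercept, and the
avoidance ramp switches on smoothly inside ``d0`` = 750 m for birds below
the turbine tops.  Given the facing draw, the heading is uniform inside the
+/-60 degree cone toward the turbine (facing) or uniform over its complement
(not facing): the facing indicator is sufficient, and no finer angular
structure is imposed.  Movement is kinematically simple — straight steps
along the drawn heading plus a partial wind drift, reflected at the domain
boundary; the avoidance models only consume positions and headings, so no
soaring realism is attempted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import special

from . import covariates as cov
from . import geometry as geo
from . import pipeline as pl

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "simulate_landscape",
    "simulate_wind",
    "simulate_tracks",
    "simulate_scenario",
    "export_scenario",
    "default_scenario",
    "null_scenario",
    "glmm_recovery_scenario",
]

_DEG_PER_M_LAT = 1.0 / (np.pi / 180.0 * geo.EARTH_RADIUS_M)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass
class ScenarioConfig:
    """Ground-truth parameters of a synthetic tracking experiment.

    Defaults describe the study conditions: a facing baseline of logit(1/3)
    (random orientation), an avoidance ramp switching on inside 750 m of the
    turbines for low-flying birds, and a wind-component effect of -0.06 per
    m/s on the facing logit.
    """

    seed: int
    n_birds: int = 30
    steps_per_bird: int = 200
    step_interval_s: float = 60.0
    start_time: str = "2013-08-15T10:00:00"

    # landscape
    n_turbines: int = 30
    n_rows: int = 2
    turbine_spacing_m: float = 500.0
    row_separation_m: float = 2500.0
    rotor_diameter_mean_m: float = 58.0
    rotor_diameter_sd_m: float = 10.0
    origin_lat: float = 36.05
    origin_lon: float = -5.65
    domain_margin_m: float = 1500.0
    ridge_slope_deg: float = 12.0
    terrain_cell_m: float = 500.0
    surface_temp_mean_k: float = 303.0
    surface_temp_sd_k: float = 2.0

    # wind regime
    wind_mean_speed_ms: float = 8.0
    wind_mean_direction_deg: float = 90.0
    wind_direction_kappa: float = 2.0
    wind_interval_s: float = 600.0
    wind_drift_factor: float = 0.3

    # behaviour (the generative counterparts of the fitted model terms)
    baseline_facing_logit: float = _logit(1.0 / 3.0)
    avoidance_depth: float = 1.0
    avoidance_range_m: float = 750.0
    range_shape_m: float = 150.0
    wind_slope: float = -0.06
    bird_intercept_sd: float = 0.3
    height_mixture: Tuple[float, float, float] = (0.5, 0.3, 0.2)

    # flight kinematics
    airspeed_mean_ms: float = 8.0
    airspeed_shape: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not np.isclose(sum(self.height_mixture), 1.0):
            raise ValueError("height_mixture must sum to 1")
        for name in ("step_interval_s", "turbine_spacing_m", "avoidance_range_m",
                     "range_shape_m", "wind_interval_s", "terrain_cell_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["height_mixture"] = list(self.height_mixture)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "height_mixture" in d:
            d["height_mixture"] = tuple(d["height_mixture"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized generative state: config, per-bird intercepts, and per-point
    true covariates/probabilities (one row per emitted track point)."""

    config: ScenarioConfig
    bird_intercepts: Dict[str, float]
    points: pd.DataFrame  # bird_id, timestamp, d, b, w_c, class, p_true, ...
    n_reflections: int = 0


def default_scenario(seed: int) -> ScenarioConfig:
    """The default avoidance scenario (all behavioural effects active)."""
    return ScenarioConfig(seed=seed)


def null_scenario(seed: int) -> ScenarioConfig:
    """All behavioural effects off: facing is Bernoulli(1/3) everywhere up to
    the per-bird intercepts."""
    return ScenarioConfig(seed=seed, avoidance_depth=0.0, wind_slope=0.0)


def glmm_recovery_scenario(seed: int, n_birds: int = 100,
                           steps_per_bird: int = 160,
                           wind_slope: float = -0.06) -> ScenarioConfig:
    """Near-turbine scenario for wind-effect recovery: all birds low, tight
    domain so points concentrate within the 750 m modelling range, and no
    distance ramp so the near-turbine model is correctly specified."""
    return ScenarioConfig(
        seed=seed, n_birds=n_birds, steps_per_bird=steps_per_bird,
        avoidance_depth=0.0, wind_slope=wind_slope,
        height_mixture=(1.0, 0.0, 0.0), domain_margin_m=650.0,
        n_turbines=24, n_rows=2, row_separation_m=1200.0)


# ---------------------------------------------------------------------------
# landscape and wind
# ---------------------------------------------------------------------------


def simulate_landscape(config: ScenarioConfig
                       ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Turbines in linear rows along a synthetic ridge, plus a terrain grid
    with non-zero slope under the rows and flat ground elsewhere."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    per_row = int(np.ceil(config.n_turbines / config.n_rows))
    rows = []
    deg_lat = _DEG_PER_M_LAT
    deg_lon = _DEG_PER_M_LAT / np.cos(np.radians(config.origin_lat))
    tid = 0
    for r in range(config.n_rows):
        lon = config.origin_lon + r * config.row_separation_m * deg_lon
        for i in range(per_row):
            if tid >= config.n_turbines:
                break
            rotor = float(np.clip(
                rng.normal(config.rotor_diameter_mean_m,
                           config.rotor_diameter_sd_m), 25.0, 100.0))
            rows.append({
                "turbine_id": f"t{tid:03d}",
                "lon": lon,
                "lat": config.origin_lat + i * config.turbine_spacing_m * deg_lat,
                "rotor_diameter_m": rotor,
                "hub_height_m": np.nan,  # unknown; downstream uses 1.5 x rotor
            })
            tid += 1
    turbines = pd.DataFrame(rows)

    d = geo.great_circle_distance(
        turbines["lat"].to_numpy()[:, None], turbines["lon"].to_numpy()[:, None],
        turbines["lat"].to_numpy()[None, :], turbines["lon"].to_numpy()[None, :])
    np.fill_diagonal(d, np.inf)
    if np.min(d) < 50.0:
        raise ValueError("turbine layout places turbines closer than 50 m")

    margin = config.domain_margin_m
    lat_lo = turbines["lat"].min() - margin * deg_lat
    lat_hi = turbines["lat"].max() + margin * deg_lat
    lon_lo = turbines["lon"].min() - margin * deg_lon
    lon_hi = turbines["lon"].max() + margin * deg_lon
    cell_lat = config.terrain_cell_m * deg_lat
    cell_lon = config.terrain_cell_m * deg_lon
    lats = np.arange(lat_lo, lat_hi + cell_lat, cell_lat)
    lons = np.arange(lon_lo, lon_hi + cell_lon, cell_lon)
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel(), glat.ravel()
    # ridge: cells within 400 m (east-west) of a turbine row line
    row_lons = np.unique(turbines["lon"].to_numpy())
    dist_to_row = np.min(np.abs(glon[:, None] - row_lons[None, :]), axis=1) / deg_lon
    on_ridge = dist_to_row < 400.0
    if config.ridge_slope_deg > 0:
        slope = np.where(on_ridge, config.ridge_slope_deg, 0.0)
    else:
        slope = np.zeros(len(glon))
    aspect = np.where(on_ridge, config.wind_mean_direction_deg, 0.0)
    temps = rng.normal(config.surface_temp_mean_k, config.surface_temp_sd_k,
                       size=len(glon))
    terrain = pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(len(glon))],
        "lon": glon,
        "lat": glat,
        "aspect_deg": np.mod(aspect, 360.0),
        "slope_deg": slope,
        "surface_temp_k": temps,
    })
    return turbines, terrain


def simulate_wind(config: ScenarioConfig,
                  n_records: Optional[int] = None) -> pd.DataFrame:
    """10-minute wind series: von Mises directions around the regime mean
    (zero concentration = circular uniform), Gamma speeds at the regime
    mean."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if n_records is None:
        span = config.steps_per_bird * config.step_interval_s
        n_records = int(np.ceil(span / config.wind_interval_s)) + 3
    t0 = np.datetime64(config.start_time)
    ts = t0 + (np.arange(n_records) * config.wind_interval_s
               ).astype("timedelta64[s]")
    if config.wind_direction_kappa > 0:
        dirs = np.degrees(rng.vonmises(
            np.radians(config.wind_mean_direction_deg - 180.0),
            config.wind_direction_kappa, size=n_records)) + 180.0
    else:
        dirs = rng.uniform(0.0, 360.0, size=n_records)
    shape = config.airspeed_shape
    speeds = rng.gamma(shape, config.wind_mean_speed_ms / shape, size=n_records)
    return pd.DataFrame({
        "timestamp": ts.astype("datetime64[ns]"),
        "wind_direction_deg": np.mod(dirs, 360.0),
        "wind_speed_ms": speeds,
    })


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def simulate_tracks(config: ScenarioConfig, turbines: pd.DataFrame,
                    wind: pd.DataFrame
                    ) -> Tuple[pd.DataFrame, GroundTruth]:
    """Bird tracks over the landscape with the generative facing model.

    Returns the track table in the internal dialect plus the ground truth
    (per-point distance, bearing, wind component, class and true facing
    probability, computed with the same primitives the annotation pipeline
    uses, so the two agree to numerical precision).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    nb, ns = config.n_birds, config.steps_per_bird
    deg_lat = _DEG_PER_M_LAT
    deg_lon0 = _DEG_PER_M_LAT / np.cos(np.radians(config.origin_lat))

    bird_ids = np.array([f"b{i:03d}" for i in range(nb)])
    b_i = rng.normal(0.0, config.bird_intercept_sd, size=nb)
    sex = rng.choice(["female", "male"], size=nb)
    age = rng.choice(["juvenile", "adult"], size=nb)

    margin = config.domain_margin_m
    lat_lo = float(turbines["lat"].min() - margin * deg_lat)
    lat_hi = float(turbines["lat"].max() + margin * deg_lat)
    lon_lo = float(turbines["lon"].min() - margin * deg_lon0)
    lon_hi = float(turbines["lon"].max() + margin * deg_lon0)

    lat = rng.uniform(lat_lo, lat_hi, size=nb)
    lon = rng.uniform(lon_lo, lon_hi, size=nb)

    t0 = np.datetime64(config.start_time)
    step_ts = (t0 + (np.arange(ns) * config.step_interval_s
                     ).astype("timedelta64[s]")).astype("datetime64[ns]")
    wind_match = cov.match_wind(step_ts, wind)
    wdir = wind_match["wind_direction_deg"].to_numpy(dtype=float)
    wspd = wind_match["wind_speed_ms"].to_numpy(dtype=float)

    tb_sorted = turbines.sort_values("turbine_id", kind="mergesort")
    hmax_all = geo.max_turbine_height(
        tb_sorted["rotor_diameter_m"].to_numpy(dtype=float),
        tb_sorted["hub_height_m"].to_numpy(dtype=float)
        if "hub_height_m" in tb_sorted.columns else None)
    hmax_by_id = dict(zip(tb_sorted["turbine_id"], hmax_all))

    mix = np.asarray(config.height_mixture, dtype=float)
    eta0 = config.baseline_facing_logit
    d0 = config.avoidance_range_m
    n_reflect = 0

    recs: List[dict] = []
    truth: List[dict] = []
    dt = config.step_interval_s
    for t in range(ns):
        tid, dist, brng = pl.nearest_turbines(lat, lon, tb_sorted)
        hmax = np.array([hmax_by_id[i] for i in tid])
        cls_draw = rng.choice(3, size=nb, p=mix)
        u = rng.uniform(size=nb)
        height = np.where(
            cls_draw == 0, 2.0 + u * (0.97 * hmax - 2.0),
            np.where(cls_draw == 1, hmax * (1.03 + 0.94 * u),
                     hmax * (2.03 + 1.5 * u)))
        is_low = cls_draw == 0

        w_c = geo.wind_component_towards(wspd[t], wdir[t], brng)
        ramp = special.expit((d0 - dist) / config.range_shape_m)
        eta = (eta0 + b_i
               - config.avoidance_depth * ramp * is_low
               + config.wind_slope * w_c * (is_low & (dist <= d0)))
        p_true = special.expit(eta)
        facing = rng.uniform(size=nb) < p_true
        angle = np.where(facing,
                         rng.uniform(-60.0, 60.0, size=nb),
                         rng.uniform(60.0, 300.0, size=nb))
        heading = np.mod(brng + angle, 360.0)

        airspeed = rng.gamma(config.airspeed_shape,
                             config.airspeed_mean_ms / config.airspeed_shape,
                             size=nb)
        airspeed = np.maximum(airspeed,
                              1.0 + config.wind_drift_factor * wspd[t])
        hd = np.radians(heading)
        drift = config.wind_drift_factor
        wind_to = np.radians(wdir[t] + 180.0)
        vx = airspeed * np.sin(hd) + drift * wspd[t] * np.sin(wind_to)
        vy = airspeed * np.cos(hd) + drift * wspd[t] * np.cos(wind_to)
        gspeed = np.hypot(vx, vy)

        for i in range(nb):
            recs.append({
                "bird_id": bird_ids[i], "timestamp": step_ts[t],
                "lon": lon[i], "lat": lat[i], "height_agl": height[i],
                "ground_speed": gspeed[i], "heading": heading[i],
                "sex": sex[i], "age_class": age[i],
            })
            truth.append({
                "bird_id": bird_ids[i], "timestamp": step_ts[t],
                "nearest_turbine_id": tid[i],
                "distance_to_turbine_m": dist[i],
                "bearing_to_turbine_deg": brng[i],
                "wind_component_ms": w_c[i],
                "height_class": ("low", "medium", "high")[cls_draw[i]],
                "turbine_max_height_m": hmax[i],
                "p_true": p_true[i],
                "facing_true": int(facing[i]),
                "bird_intercept": b_i[i],
            })

        # advance, reflecting at the domain boundary
        new_lat = lat + vy * dt * deg_lat
        new_lon = lon + vx * dt * _DEG_PER_M_LAT / np.cos(np.radians(lat))
        refl = ((new_lat < lat_lo) | (new_lat > lat_hi)
                | (new_lon < lon_lo) | (new_lon > lon_hi))
        n_reflect += int(refl.sum())
        new_lat = np.where(new_lat > lat_hi, 2 * lat_hi - new_lat, new_lat)
        new_lat = np.where(new_lat < lat_lo, 2 * lat_lo - new_lat, new_lat)
        new_lon = np.where(new_lon > lon_hi, 2 * lon_hi - new_lon, new_lon)
        new_lon = np.where(new_lon < lon_lo, 2 * lon_lo - new_lon, new_lon)
        lat = np.clip(new_lat, lat_lo, lat_hi)
        lon = np.clip(new_lon, lon_lo, lon_hi)

    tracks = pd.DataFrame(recs)
    truth_df = pd.DataFrame(truth)
    gt = GroundTruth(config=config,
                     bird_intercepts=dict(zip(bird_ids, b_i)),
                     points=truth_df, n_reflections=n_reflect)
    return tracks, gt


def simulate_scenario(config: ScenarioConfig):
    """Landscape, wind, tracks and truth for one scenario config."""
    turbines, terrain = simulate_landscape(config)
    wind = simulate_wind(config)
    tracks, truth = simulate_tracks(config, turbines, wind)
    return tracks, turbines, wind, terrain, truth


def export_scenario(out_dir, tracks: pd.DataFrame, turbines: pd.DataFrame,
                    wind: pd.DataFrame, terrain: pd.DataFrame,
                    truth: GroundTruth) -> Dict[str, Path]:
    """Write a scenario in the exact CSV dialects the annotation pipeline
    reads, plus the ground truth (config + bird intercepts as JSON, point
    truth as CSV)."""
    from . import io as wio
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": out / "tracks.csv",
        "turbines": out / "turbines.csv",
        "wind": out / "wind.csv",
        "terrain": out / "terrain.csv",
        "truth_json": out / "truth.json",
        "truth_points": out / "truth_points.csv",
        "config": out / "scenario.yaml",
    }
    wio.write_tracks(tracks, paths["tracks"])
    turbines.to_csv(paths["turbines"], index=False)
    wind.to_csv(paths["wind"], index=False)
    terrain.to_csv(paths["terrain"], index=False)
    truth.points.to_csv(paths["truth_points"], index=False)
    cfg = dataclasses.asdict(truth.config)
    cfg["height_mixture"] = list(truth.config.height_mixture)
    paths["truth_json"].write_text(json.dumps({
        "config": cfg,
        "bird_intercepts": {k: float(v)
                            for k, v in truth.bird_intercepts.items()},
        "n_reflections": truth.n_reflections,
    }, indent=2, default=str))
    truth.config.to_yaml(paths["config"])
    return paths
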