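"""Reading and writing the pipeline's table formats.

Track tables use the Movebank CSV dialect on disk
(``individual-local-identifier``, ``timestamp``, ``location-long``,
``location-lat``, ``height-above-ground``, ``ground-speed``, ``heading``,
``sex``, ``age``) and an internal snake_case dialect in memory (``bird_id,
timestamp, lon, lat, height_agl, ground_speed, heading, sex, age_class``).
Validation reports the first offending row and column by name.  All
timestamps are ISO 8601 UTC; all angles are degrees.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

MOVEBANK_TO_INTERNAL = {
    "individual-local-identifier": "bird_id",
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "height-above-ground": "height_agl",
    "ground-speed": "ground_speed",
    "heading": "heading",
    "sex": "sex",
    "age": "age_class",
}
INTERNAL_TO_MOVEBANK = {v: k for k, v in MOVEBANK_TO_INTERNAL.items()}

TURBINE_COLUMNS = ["turbine_id", "lon", "lat", "rotor_diameter_m",
                   "hub_height_m"]
WIND_COLUMNS = ["timestamp", "wind_direction_deg", "wind_speed_ms"]
TERRAIN_COLUMNS = ["cell_id", "lon", "lat", "aspect_deg", "slope_deg"]


class SchemaError(ValueError):
    """A table violated its schema; the message names the first offender."""


def _fail(table: str, row, column: str, problem: str):
    where = f"row {row}" if row is not None else "table"
    raise SchemaError(f"{table}: {where}, column '{column}': {problem}")


def _check_range(table: str, df: pd.DataFrame, column: str,
                 lo: float, hi: float, hi_open: bool = False,
                 allow_nan: bool = False) -> None:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad_nan = vals.isna() & df[column].notna()
    if bad_nan.any():
        _fail(table, int(bad_nan.idxmax()), column, "not numeric")
    if vals.isna().any() and not allow_nan:
        _fail(table, int(vals.isna().idxmax()), column, "missing value")
    with np.errstate(invalid="ignore"):
        out = (vals < lo) | (vals > hi) | (hi_open & (vals == hi))
    out = out & vals.notna()
    if out.any():
        i = int(out.idxmax())
        interval = f"[{lo}, {hi}" + (")" if hi_open else "]")
        _fail(table, i, column, f"value {vals[i]} outside {interval}")


def validate_tracks(df: pd.DataFrame) -> None:
    for col in ("bird_id", "timestamp", "lon", "lat", "height_agl",
                "ground_speed", "heading"):
        if col not in df.columns:
            _fail("tracks", None, col, "column missing")
    if len(df) == 0:
        return
    _check_range("tracks", df, "lat", -90.0, 90.0)
    _check_range("tracks", df, "lon", -180.0, 180.0)
    _check_range("tracks", df, "heading", 0.0, 360.0, hi_open=True)
    _check_range("tracks", df, "ground_speed", 0.0, np.inf, allow_nan=True)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    if ts.isna().any():
        _fail("tracks", int(ts.isna().idxmax()), "timestamp",
              "not an ISO 8601 timestamp")


def read_tracks(path) -> pd.DataFrame:
    """Read a Movebank-dialect track CSV into the internal dialect."""
    raw = pd.read_csv(path)
    cols = {c: MOVEBANK_TO_INTERNAL[c] for c in raw.columns
            if c in MOVEBANK_TO_INTERNAL}
    df = raw.rename(columns=cols)
    validate_tracks(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True
                                     ).dt.tz_localize(None)
    df["bird_id"] = df["bird_id"].astype(str)
    return df


def write_tracks(df: pd.DataFrame, path) -> None:
    """Write internal-dialect tracks as a Movebank-dialect CSV."""
    validate_tracks(df)
    out = df.rename(columns={c: INTERNAL_TO_MOVEBANK.get(c, c)
                             for c in df.columns})
    out.to_csv(path, index=False)


def read_turbines(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("turbine_id", "lon", "lat", "rotor_diameter_m"):
        if col not in df.columns:
            _fail("turbines", None, col, "column missing")
    if "hub_height_m" not in df.columns:
        df["hub_height_m"] = np.nan
    _check_range("turbines", df, "lat", -90.0, 90.0)
    _check_range("turbines", df, "lon", -180.0, 180.0)
    rd = pd.to_numeric(df["rotor_diameter_m"], errors="coerce")
    if (rd <= 0).any() or rd.isna().any():
        i = int(((rd <= 0) | rd.isna()).idxmax())
        _fail("turbines", i, "rotor_diameter_m", "must be a positive number")
    df["turbine_id"] = df["turbine_id"].astype(str)
    return df


def read_wind(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in WIND_COLUMNS:
        if col not in df.columns:
            _fail("wind", None, col, "column missing")
    _check_range("wind", df, "wind_direction_deg", 0.0, 360.0, hi_open=True)
    _check_range("wind", df, "wind_speed_ms", 0.0, np.inf)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True
                                     ).dt.tz_localize(None)
    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def read_terrain(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in TERRAIN_COLUMNS:
        if col not in df.columns:
            _fail("terrain", None, col, "column missing")
    _check_range("terrain", df, "aspect_deg", 0.0, 360.0, hi_open=True)
    _check_range("terrain", df, "slope_deg", 0.0, 90.0, hi_open=True)
    if "surface_temp_k" in df.columns:
        _check_range("terrain", df, "surface_temp_k", 1e-6, np.inf,
                     allow_nan=True)
    df["cell_id"] = df["cell_id"].astype(str)
    return df


def read_annotated(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True
                                     ).dt.tz_localize(None)
    df["bird_id"] = df["bird_id"].astype(str)
    if "covariate_missing" in df.columns:
        df["covariate_missing"] = df["covariate_missing"].astype(bool)
    return df


def write_annotated(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_report(report, path) -> None:
    """Serialize a FilterReport (or a dict of them) as JSON."""
    if hasattr(report, "to_dict"):
        payload = report.to_dict()
    elif isinstance(report, dict):
        payload = {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                   for k, v in report.items()}
    else:
        payload = report
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def glmm_fit_to_dict(fit) -> dict:
    from .glmm import nakagawa_r2
    r2m, r2c = nakagawa_r2(fit)
    return {
        "config": fit.config,
        "coefficients": fit.coef.to_dict(orient="records"),
        "random_intercept_sd": fit.sigma_b,
        "random_intercept_var": fit.var_b,
        "r2_marginal": r2m,
        "r2_conditional": r2c,
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "n_birds": fit.n_groups,
        "converged": fit.converged,
        "warnings": fit.warnings_,
    }


def gamm_fit_to_dict(fit) -> dict:
    return {
        "smooths": fit.smooths.to_dict(orient="records"),
        "random_intercept_sd": fit.sigma_b,
        "edf_total": fit.edf_total,
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "lambdas": [float(l) for l in fit.lambdas],
        "converged": fit.converged,
        "cv_accuracy_mean": fit.cv_accuracy_mean,
        "cv_accuracy_sd": fit.cv_accuracy_sd,
        "warnings": fit.warnings_,
    }
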