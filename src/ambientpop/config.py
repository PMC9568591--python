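"""Flat YAML configuration with one key per tunable parameter."""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Any

import yaml

from .grid_io import GridSpec
from .gwr import GWRConfig
from .synthetic import ScenarioConfig

DEFAULTS: dict[str, Any] = {
    # grid
    "grid_origin_lon": 110.0,
    "grid_origin_lat": 35.0,
    "grid_cell_size": 0.01,
    "grid_n_rows": 100,
    "grid_n_cols": 100,
    # scenario
    "scenario_n_counties": 400,
    "scenario_n_towns_per_county": 4,
    "scenario_n_hotspots": 12,
    "scenario_hotspot_peak": 500.0,
    "scenario_background": 5.0,
    "scenario_a_min": 0.8,
    "scenario_a_max": 1.2,
    "scenario_b_min": 0.0,
    "scenario_b_max": 1.0,
    "scenario_field_mode": "ramp",
    "scenario_noise_sigma": 0.1,
    "scenario_day_sigma": 0.05,
    "scenario_n_days": 30,
    "scenario_start_date": "2018-03-01",
    "scenario_holiday_dates": ["2018-03-05", "2018-03-12", "2018-03-19", "2018-03-26"],
    "scenario_holiday_inflation": 3.0,
    "scenario_poisson_counts": False,
    # temporal averaging
    "calendar_year": 2018,
    "calendar_included_months": [3, 4, 5, 6, 9, 10, 11, 12],
    "calendar_excluded_dates": [],
    "nodata_mode": "strict",
    # GWR
    "gwr_kernel": "bisquare",
    "gwr_bandwidth_mode": "adaptive",
    "gwr_bandwidth": "auto",
    "gwr_selection_criterion": "aicc",
    # validation
    "population_scale": 1e4,
    "local_r2_threshold": 0.6,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Merge a flat YAML file over the defaults; unknown keys are rejected."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    unknown = sorted(set(user) - set(DEFAULTS))
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(unknown)}")
    cfg.update(user)
    return cfg


def grid_spec_from_config(cfg: dict[str, Any]) -> GridSpec:
    return GridSpec(
        origin_lon=cfg["grid_origin_lon"],
        origin_lat=cfg["grid_origin_lat"],
        cell_size=cfg["grid_cell_size"],
        n_rows=cfg["grid_n_rows"],
        n_cols=cfg["grid_n_cols"],
    )


def scenario_config_from_config(cfg: dict[str, Any], seed: int = 0) -> ScenarioConfig:
    return ScenarioConfig(
        grid=grid_spec_from_config(cfg),
        n_counties=cfg["scenario_n_counties"],
        n_towns_per_county=cfg["scenario_n_towns_per_county"],
        n_hotspots=cfg["scenario_n_hotspots"],
        hotspot_peak=cfg["scenario_hotspot_peak"],
        background=cfg["scenario_background"],
        a_field=(cfg["scenario_a_min"], cfg["scenario_a_max"]),
        b_field=(cfg["scenario_b_min"], cfg["scenario_b_max"]),
        field_mode=cfg["scenario_field_mode"],
        noise_sigma=cfg["scenario_noise_sigma"],
        day_sigma=cfg["scenario_day_sigma"],
        n_days=cfg["scenario_n_days"],
        start_date=cfg["scenario_start_date"],
        holiday_dates=tuple(cfg["scenario_holiday_dates"]),
        holiday_inflation=cfg["scenario_holiday_inflation"],
        poisson_counts=cfg["scenario_poisson_counts"],
        seed=seed,
    )


def gwr_config_from_config(cfg: dict[str, Any]) -> GWRConfig:
    bw = cfg["gwr_bandwidth"]
    return GWRConfig(
        kernel=cfg["gwr_kernel"],
        bandwidth_mode=cfg["gwr_bandwidth_mode"],
        bandwidth="auto" if bw == "auto" else float(bw),
        selection_criterion=cfg["gwr_selection_criterion"],
    )


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("ambientpop")
    root.handlers.clear()
    root.addHandler(handler)
    root.setLevel(level.upper())
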