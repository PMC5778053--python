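"""Coupled elevation-vegetation simulation through a sea-level scenario.

Each step applies, in order: (1) sea level — every subsite's mean sea
level is set to the base frame plus the scenario anomaly at the new year;
(2) elevation — the engine's SEC rate field, computed from the pre-step
classification and the new water level, advances the substrate by explicit
Euler; (3) vegetation — every cell is reclassified against the new frame
and the result is resolved against the previous class under the succession
policy. The slamm engine pairs with the slamm policy (retrogression only,
water absorbing); cm1/cm2 pair with boundary_free. Cells evolve
independently given the static distance fields — no lateral erosion or
overwash is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import (
    Cm1SecConfig,
    Cm2SecConfig,
    DistanceField,
    SlammSecConfig,
    advance_elevation,
    cm1_rate,
    cm2_rate,
    slamm_rate,
)
from .raster import ElevationGrid, SubsiteMap, VegetationGrid, area_by_class
from .tides import ConfigurationError, SLRScenario, TidalFrame
from .vegetation import SuccessionPolicy, ZonationBands, apply_succession, classify_grid

__all__ = ["SimulationState", "RunResult", "initial_state", "step", "run"]

ENGINES = ("slamm", "cm1", "cm2")


@dataclass
class SimulationState:
    """Full coupled state at one instant of a run."""

    year: float
    z: ElevationGrid
    veg: VegetationGrid
    base_frame: TidalFrame  # frame at the scenario start (anomaly 0)
    frame: TidalFrame  # base frame with the current anomaly applied
    scenario: SLRScenario
    subsites: SubsiteMap
    bands: ZonationBands
    engine: str
    policy: SuccessionPolicy
    engine_config: object
    distances: DistanceField | None = None
    covariates: pd.DataFrame | None = None
    start_year: float | None = None  # CM2 time origin (days counted from here)


@dataclass
class RunResult:
    """Per-step class areas (ha), optional per-step rasters, run metadata."""

    areas: pd.DataFrame
    metadata: dict
    rasters: list | None = None


def initial_state(dem: ElevationGrid, veg_map: VegetationGrid | None,
                  frame: TidalFrame, bands: ZonationBands, subsites: SubsiteMap,
                  scenario: SLRScenario, engine: str, engine_config,
                  *, distances: DistanceField | None = None,
                  covariates: pd.DataFrame | None = None,
                  policy: SuccessionPolicy | None = None,
                  start_year: float | None = None) -> SimulationState:
    """Build the starting state.

    The slamm engine uses a supplied vegetation map when given one (the
    photo-interpreted base map); cm1/cm2 — or any engine without a map —
    classify the initial vegetation from the DEM and the elevation bands.
    """
    if engine not in ENGINES:
        raise ConfigurationError(f"unknown engine {engine!r}")
    if engine == "slamm" and veg_map is None and bands is None:
        raise ConfigurationError("slamm engine needs a vegetation map or bands")
    if bands is None:
        raise ConfigurationError("elevation bands are required")
    if policy is None:
        policy = SuccessionPolicy("slamm" if engine == "slamm" else "boundary_free")
    y0 = scenario.start_year if start_year is None else start_year
    frame_now = frame.with_msl_shift(scenario.anomaly_at(y0))
    if engine == "slamm" and veg_map is not None:
        veg = veg_map.copy()
    else:
        codes = classify_grid(dem.values, subsites, frame_now, bands, dem.nodata_mask)
        veg = VegetationGrid(codes, dem.cell_size, dem.nodata_mask.copy(), dem.origin)
    return SimulationState(
        year=y0, z=dem.copy(), veg=veg, base_frame=frame, frame=frame_now,
        scenario=scenario, subsites=subsites, bands=bands, engine=engine,
        policy=policy, engine_config=engine_config, distances=distances,
        covariates=covariates, start_year=y0,
    )


def _rate_field(state: SimulationState, frame_new: TidalFrame) -> np.ndarray:
    if state.engine == "slamm":
        return slamm_rate(state.veg, state.z.values, state.subsites, frame_new,
                          state.bands, state.engine_config)
    if state.engine == "cm1":
        if state.distances is None:
            raise ConfigurationError("cm1 engine needs distance fields")
        return cm1_rate(state.z.values, state.distances.dist_channel,
                        state.subsites, frame_new, state.engine_config)
    # cm2
    if state.distances is None:
        raise ConfigurationError("cm2 engine needs distance fields")
    if state.covariates is None:
        raise ConfigurationError("cm2 engine needs a covariate series")
    cfg: Cm2SecConfig = state.engine_config
    year = int(round(state.year))
    rows = state.covariates[state.covariates["year"] == year]
    if rows.empty:
        raise ValueError(f"covariate series has no row for year {year}")
    cov = rows.iloc[0].to_dict()
    t_days = (state.year - state.start_year) * 365.25
    dist = (state.distances.dist_shore if cfg.distance_field == "shore"
            else state.distances.dist_channel)
    rate = cm2_rate(t_days, cov, dist, cfg)
    return np.broadcast_to(np.asarray(rate, float), state.z.shape).copy()


def step(state: SimulationState, dt: float) -> SimulationState:
    """Advance one time step (sea level -> elevation -> vegetation)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    y1 = state.year + dt
    if y1 > state.scenario.end_year + 1e-9:
        raise ValueError(
            f"scenario exhausted: step to {y1} beyond {state.scenario.end_year}"
        )
    frame1 = state.base_frame.with_msl_shift(state.scenario.anomaly_at(y1))
    rates = _rate_field(state, frame1)
    z1 = advance_elevation(state.z, rates, dt)
    proposed = classify_grid(z1.values, state.subsites, frame1, state.bands,
                             z1.nodata_mask)
    codes1 = apply_succession(state.veg.codes, proposed, state.policy)
    veg1 = VegetationGrid(codes1, state.veg.cell_size,
                          state.veg.nodata_mask.copy(), state.veg.origin,
                          state.veg.class_order)
    return replace(state, year=y1, z=z1, veg=veg1, frame=frame1)


def run(initial: SimulationState, end_year: float, dt: float = 10.0,
        record_rasters: bool = False) -> RunResult:
    """Iterate steps to end_year, recording per-step class areas.

    Deterministic given the inputs: two runs from identical state are
    bit-identical. The final step is shortened if end_year is not a whole
    number of steps away.
    """
    if end_year > initial.scenario.end_year + 1e-9:
        raise ValueError("end_year beyond scenario span")
    state = initial
    rows = {state.year: area_by_class(state.veg)}
    rasters = [(state.year, state.veg.copy(), state.z.copy())] if record_rasters else None
    while state.year < end_year - 1e-9:
        this_dt = min(dt, end_year - state.year)
        state = step(state, this_dt)
        rows[state.year] = area_by_class(state.veg)
        if record_rasters:
            rasters.append((state.year, state.veg.copy(), state.z.copy()))
    areas = pd.DataFrame(rows).T
    areas.index.name = "year"
    meta = {
        "engine": initial.engine,
        "scenario": initial.scenario.label,
        "policy": initial.policy.mode,
        "start_year": initial.year,
        "end_year": state.year,
        "dt": dt,
    }
    return RunResult(areas=areas, metadata=meta, rasters=rasters)
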