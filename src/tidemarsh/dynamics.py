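"""Surface-elevation-change (SEC) engines.

Three engines advance substrate elevation, all in mm/yr of net surface
elevation change (SEC subsumes accretion, autocompaction and shallow
subsidence, which is why SET-derived SEC rates replace raw accretion
rates):

* ``slamm`` — per-vegetation-class rates, optionally scaled linearly across
  the class's elevation band (the proportional-to-elevation option of
  SLAMM-like accretion).
* ``cm1``  — an exponential empirical surface: SEC decays exponentially
  with height above the lower intertidal limit and with distance from the
  channel (the sediment source). Re-evaluated against the current (risen)
  sea level each step, this is the minimal dynamic closure of a static
  sedimentation fit; it is what lets a channel-bank levee build and the
  shoreline prograde.
* ``cm2``  — a site-calibrated linear regression on time, previous-month
  rainfall, 6-month water level, distance to shore, 3-month SOI and mean
  sea level.

All engines share one explicit-Euler update (advance_elevation) at a
configurable step, decadal by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import INTERTIDAL_CLASSES, OPEN_WATER, UPLAND, ElevationGrid, SubsiteMap, VegetationGrid
from .tides import ConfigurationError, TidalFrame
from .vegetation import ZonationBands

__all__ = [
    "SlammSecConfig",
    "Cm1SecConfig",
    "Cm2SecConfig",
    "DistanceField",
    "slamm_rate",
    "cm1_rate",
    "cm2_rate",
    "advance_elevation",
    "distance_fields",
]


@dataclass(frozen=True)
class DistanceField:
    """Static morphometric distances (m), frozen at t0: Euclidean
    cell-centre distance to the nearest channel/water cell, and distance to
    the shore (estuary mouth)."""

    dist_channel: np.ndarray
    dist_shore: np.ndarray

    def __post_init__(self):
        if np.any(self.dist_channel < 0) or np.any(self.dist_shore < 0):
            raise ValueError("distances must be non-negative")


def distance_fields(channel_mask: np.ndarray, cell_size: float,
                    mouth_axis_distance: np.ndarray | None = None) -> DistanceField:
    """Distance fields from a boolean channel mask.

    dist_channel is zero on channel cells. dist_shore defaults to
    dist_channel unless an along-estuary distance matrix is supplied.
    """
    if channel_mask.any():
        dc = ndimage.distance_transform_edt(~channel_mask) * cell_size
    else:
        dc = np.zeros(channel_mask.shape, dtype=float)
    ds = dc if mouth_axis_distance is None else np.asarray(mouth_axis_distance, float)
    return DistanceField(dist_channel=dc, dist_shore=ds)


@dataclass(frozen=True)
class SlammSecConfig:
    """Per-class SEC rates (mm/yr).

    ``rates`` must cover the intertidal classes; open_water and upland
    default to 0 but may be set (e.g. for keep-pace experiments). In
    proportional mode the rate runs linearly from rate_at_lower to
    rate_at_upper across each class's elevation band.
    """

    rates: dict = field(default_factory=dict)
    elevation_proportional: bool = False
    rates_at_lower: dict = field(default_factory=dict)
    rates_at_upper: dict = field(default_factory=dict)

    def rate_of(self, cls: int) -> float:
        if cls in self.rates:
            return float(self.rates[cls])
        if cls in (OPEN_WATER, UPLAND):
            return 0.0
        raise ConfigurationError(f"no SEC rate configured for class code {cls}")


def slamm_rate(veg: VegetationGrid | np.ndarray, z: np.ndarray, subsites: SubsiteMap,
               frame: TidalFrame, bands: ZonationBands, cfg: SlammSecConfig) -> np.ndarray:
    """SLAMM-style SEC rate field (mm/yr) from the current classification."""
    codes = veg.codes if isinstance(veg, VegetationGrid) else np.asarray(veg)
    z = np.asarray(z, dtype=float)
    rates = np.zeros(codes.shape, dtype=float)
    classes = set(np.unique(codes).tolist())
    if not cfg.elevation_proportional:
        for cls in classes:
            rates[codes == cls] = cfg.rate_of(int(cls))
        return rates
    for sid in range(1, frame.n_subsites + 1):
        gt = frame.gt[sid - 1]
        sb = frame.salt_boundary[sid - 1]
        msl = frame.msl[sid - 1]
        in_sub = subsites.ids == sid
        for cls in classes:
            cls = int(cls)
            sel = in_sub & (codes == cls)
            if not sel.any():
                continue
            if cls in INTERTIDAL_CLASSES and cls in cfg.rates_at_lower:
                lo, hi = bands.band_interval(cls, gt, sb)
                pos = np.clip((z[sel] - msl - lo) / (hi - lo), 0.0, 1.0)
                rl = float(cfg.rates_at_lower[cls])
                ru = float(cfg.rates_at_upper[cls])
                rates[sel] = rl + (ru - rl) * pos
            else:
                rates[sel] = cfg.rate_of(cls)
    return rates


@dataclass(frozen=True)
class Cm1SecConfig:
    """Exponential SEC surface: rate = k exp(-l dz) exp(-m dc), with dz the
    height above the lower intertidal limit (local MSL - GT/2, clamped at 0)
    and dc the distance to the channel. k in mm/yr, l and m in 1/m; signs
    are fixed so accretion always decreases with elevation and channel
    distance (the published fits behave this way), the config carries
    magnitudes only."""

    k: float = 5.0
    l: float = 1.5
    m: float = 0.002

    def __post_init__(self):
        if self.k < 0 or self.l < 0 or self.m < 0:
            raise ConfigurationError("cm1 coefficients must be non-negative magnitudes")


def cm1_rate(z: np.ndarray, dist_channel: np.ndarray, subsites: SubsiteMap,
             frame: TidalFrame, cfg: Cm1SecConfig) -> np.ndarray:
    """CM1 SEC rate field (mm/yr); zero above the salt boundary."""
    z = np.asarray(z, dtype=float)
    dc = np.asarray(dist_channel, dtype=float)
    msl = frame.per_cell(subsites, "msl_offset") + frame.datum_correction
    gt = frame.per_cell(subsites, "gt")
    sb = frame.per_cell(subsites, "salt_boundary")
    lower_limit = msl - gt / 2.0
    dz = np.maximum(0.0, z - lower_limit)
    rate = cfg.k * np.exp(-cfg.l * dz) * np.exp(-cfg.m * dc)
    rate[z - msl >= sb] = 0.0
    return rate


@dataclass(frozen=True)
class Cm2SecConfig:
    """Site-calibrated linear SEC model (all coefficients in mm/yr per
    covariate unit). ``distance_field`` picks which static distance feeds
    the dist-to-shore term ("shore" or "channel") — the empirical fit does
    not pin this down."""

    intercept: float = 2.0
    coef_t_days: float = 0.0
    coef_rain_mm: float = 0.0
    coef_waterlevel_m: float = 0.0
    coef_dist_shore_m: float = 0.0
    coef_soi: float = 0.0
    coef_msl_m: float = 0.0
    distance_field: str = "shore"

    def __post_init__(self):
        if self.distance_field not in ("shore", "channel"):
            raise ConfigurationError("distance_field must be 'shore' or 'channel'")


def cm2_rate(t_days: float, covariates: dict, dist_shore: np.ndarray,
             cfg: Cm2SecConfig) -> np.ndarray:
    """CM2 SEC rate (mm/yr): intercept + dot(coefficients, covariates).

    ``covariates`` must carry rain_prev_month_mm, waterlevel_6mo_m, soi_3mo,
    msl_m; dist_shore is the spatial term (scalar or matrix).
    """
    try:
        scalar = (
            cfg.intercept
            + cfg.coef_t_days * t_days
            + cfg.coef_rain_mm * float(covariates["rain_prev_month_mm"])
            + cfg.coef_waterlevel_m * float(covariates["waterlevel_6mo_m"])
            + cfg.coef_soi * float(covariates["soi_3mo"])
            + cfg.coef_msl_m * float(covariates["msl_m"])
        )
    except KeyError as exc:
        raise ValueError(f"covariate missing for CM2: {exc}") from exc
    rate = scalar + cfg.coef_dist_shore_m * np.asarray(dist_shore, dtype=float)
    return rate


def advance_elevation(z_grid: ElevationGrid, rates: np.ndarray, dt: float) -> ElevationGrid:
    """Explicit-Euler elevation step: z' = z + rate(mm/yr) * dt(yr) / 1000.

    Masked cells are untouched; grid geometry is conserved.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != z_grid.shape:
        raise ValueError(
            f"rate field shape {rates.shape} != grid shape {z_grid.shape}"
        )
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = z_grid.values + np.where(z_grid.nodata_mask, 0.0, rates) * dt / 1000.0
    return ElevationGrid(new, z_grid.cell_size, z_grid.nodata_mask.copy(), z_grid.origin)
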