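"""Per-subsite tidal datums, attenuation, and inundation-frequency geometry.

Barrier estuaries attenuate the tide as it propagates upstream through the
constricted entrance and channel, so the great diurnal range (GT) — and with
it every intertidal elevation band — shrinks with along-channel distance.
The :class:`TidalFrame` holds one record per subsite (local mean-sea-level
offset, GT, salt-boundary elevation) plus estuary-wide globals (historic
sea-level trend, height-to-tidal-datum correction), and supports the
no-attenuation control in which every subsite is forced to a single
reference tidal range.

The frequency <-> elevation conversion assumes a single-constituent
sinusoidal tide of amplitude GT/2. That is the minimal defensible tide
model given only inundation-frequency zonation bands, and it is isolated
behind :func:`exceedance_elevation` / :func:`frequency_at` so a harmonic-sum
tide could replace it without touching anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .raster import SubsiteMap

__all__ = [
    "TidalFrame",
    "SLRScenario",
    "build_frame",
    "global_frame",
    "exceedance_elevation",
    "frequency_at",
    "backstep_datum",
]


class ConfigurationError(ValueError):
    """Inconsistent or incomplete run configuration."""


@dataclass(frozen=True)
class TidalFrame:
    """Per-subsite tidal parameters, indexed by contiguous subsite id 1..n.

    msl_offset is the local mean sea level relative to the height datum (m);
    gt the great diurnal range (m); salt_boundary the upper limit of tidal
    wetland in metres above local MSL. historic_slr_trend is mm/yr;
    datum_correction (m) is the height-to-tidal-datum shift applied on top
    of msl_offset wherever a water level is needed.
    """

    msl_offset: np.ndarray
    gt: np.ndarray
    salt_boundary: np.ndarray
    historic_slr_trend: float = 0.0
    datum_correction: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "msl_offset", np.atleast_1d(np.asarray(self.msl_offset, dtype=float)))
        object.__setattr__(self, "gt", np.atleast_1d(np.asarray(self.gt, dtype=float)))
        object.__setattr__(self, "salt_boundary", np.atleast_1d(np.asarray(self.salt_boundary, dtype=float)))
        if not (self.msl_offset.shape == self.gt.shape == self.salt_boundary.shape):
            raise ConfigurationError("tidal parameter arrays must have equal length")
        if np.any(self.gt <= 0):
            raise ConfigurationError("gt must be positive for every subsite")
        if np.any(self.salt_boundary <= 0):
            raise ConfigurationError("salt_boundary must be positive (m above local MSL)")

    @property
    def n_subsites(self) -> int:
        return self.msl_offset.size

    @property
    def msl(self) -> np.ndarray:
        """Effective local mean sea level (height datum + tidal correction)."""
        return self.msl_offset + self.datum_correction

    def per_cell(self, subsites: SubsiteMap, field: str) -> np.ndarray:
        """Broadcast a per-subsite parameter onto the grid via subsite ids."""
        arr = getattr(self, field)
        idx = np.clip(subsites.ids - 1, 0, self.n_subsites - 1)
        return arr[idx]

    def with_msl_shift(self, delta: float) -> "TidalFrame":
        return replace(self, msl_offset=self.msl_offset + delta)


def build_frame(subsites: SubsiteMap, table: pd.DataFrame, *,
                historic_slr_trend: float = 0.0,
                datum_correction: float = 0.0) -> TidalFrame:
    """Assemble a TidalFrame from a per-subsite parameter table.

    ``table`` needs columns subsite_id, msl_offset_m, gt_m, salt_boundary_m,
    one row per subsite id present in ``subsites``.
    """
    table = table.set_index("subsite_id") if "subsite_id" in table.columns else table
    missing = [i for i in range(1, subsites.n_subsites + 1) if i not in table.index]
    if missing:
        raise ConfigurationError(f"subsite table missing rows for ids {missing}")
    ids = np.arange(1, subsites.n_subsites + 1)
    return TidalFrame(
        msl_offset=table.loc[ids, "msl_offset_m"].to_numpy(dtype=float),
        gt=table.loc[ids, "gt_m"].to_numpy(dtype=float),
        salt_boundary=table.loc[ids, "salt_boundary_m"].to_numpy(dtype=float),
        historic_slr_trend=historic_slr_trend,
        datum_correction=datum_correction,
    )


def global_frame(frame: TidalFrame, reference: int = 1) -> TidalFrame:
    """No-attenuation control: every subsite gets the reference subsite's
    parameters (default: subsite 1, the most seaward — the open-coast value
    a single-tidal-range run would apply estuary-wide)."""
    i = reference - 1
    n = frame.n_subsites
    return replace(
        frame,
        msl_offset=np.full(n, frame.msl_offset[i]),
        gt=np.full(n, frame.gt[i]),
        salt_boundary=np.full(n, frame.salt_boundary[i]),
    )


def exceedance_elevation(f, gt):
    """Elevation (m relative to local MSL) submerged a fraction ``f`` of the
    time under a sinusoidal tide of amplitude gt/2.

    z = (gt/2) * cos(pi * f); f=0.5 -> exactly 0 (local MSL), f=1 -> -gt/2.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("inundation fraction must lie in (0, 1]")
    a = np.asarray(gt, dtype=float) / 2.0
    # sin form is exact at f=0.5 in floating point (cos(pi/2) is not 0.0)
    z = a * np.sin(np.pi * (0.5 - f))
    return float(z) if z.ndim == 0 else z


def frequency_at(z, gt):
    """Inverse of :func:`exceedance_elevation`: fraction of time submerged
    at elevation z (m relative to local MSL), clipped to the tidal frame."""
    a = np.asarray(gt, dtype=float) / 2.0
    ratio = np.clip(np.asarray(z, dtype=float) / a, -1.0, 1.0)
    f = 0.5 - np.arcsin(ratio) / np.pi
    return float(f) if f.ndim == 0 else f


def backstep_datum(frame: TidalFrame, rate: float, years: float) -> TidalFrame:
    """Shift every subsite's mean sea level back in time.

    Subtracts rate (mm/yr) x years from each msl_offset — equivalent to
    raising all land elevations relative to sea level by the same amount,
    which is how a contemporary DEM is forced to represent a historic year.
    Backstepping only: negative years are a domain error.
    """
    if years < 0:
        raise ValueError("backstep years must be >= 0")
    shift = rate * years / 1000.0
    return replace(frame, msl_offset=frame.msl_offset - shift)


@dataclass(frozen=True)
class SLRScenario:
    """Sea-level anomaly (m) by year, zero at the start year, non-decreasing."""

    years: np.ndarray
    anomaly: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=float))
        object.__setattr__(self, "anomaly", np.asarray(self.anomaly, dtype=float))
        if self.years.size < 1 or self.years.size != self.anomaly.size:
            raise ValueError("scenario needs matching year/anomaly arrays")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("scenario years must be strictly increasing")
        if self.anomaly[0] != 0.0:
            raise ValueError("scenario anomaly must be 0 at the start year")
        if np.any(np.diff(self.anomaly) < 0):
            raise ValueError("scenario anomaly must be non-decreasing")

    @property
    def start_year(self) -> float:
        return float(self.years[0])

    @property
    def end_year(self) -> float:
        return float(self.years[-1])

    def anomaly_at(self, year: float) -> float:
        if year < self.years[0] - 1e-9 or year > self.years[-1] + 1e-9:
            raise ValueError(
                f"year {year} outside scenario span [{self.years[0]}, {self.years[-1]}]"
            )
        # exact table hit returns the tabulated value bit-for-bit
        hit = np.nonzero(self.years == year)[0]
        if hit.size:
            return float(self.anomaly[hit[0]])
        return float(np.interp(year, self.years, self.anomaly))

    @classmethod
    def linear(cls, start_year: float, end_year: float, trend_mm_yr: float,
               step: float = 1.0, label: str = "linear") -> "SLRScenario":
        years = np.arange(start_year, end_year + 0.5 * step, step, dtype=float)
        if years[-1] != end_year:
            years = np.append(years, float(end_year))
        anomaly = trend_mm_yr * (years - start_year) / 1000.0
        return cls(years, anomaly, label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "anomaly_m": self.anomaly})

    @classmethod
    def from_csv(cls, path, label: str = "") -> "SLRScenario":
        df = pd.read_csv(path)
        return cls(df["year"].to_numpy(), df["anomaly_m"].to_numpy(), label)
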