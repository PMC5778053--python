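"""Elevation zonation, succession rules, and the vegetation preprocessor.

Intertidal vegetation in southeast-Australian barrier estuaries is zoned by
inundation frequency: mangrove where inundation is relatively high (50-25%
of the time and below), a mixed mangrove/saltmarsh ecotone and saltmarsh
where inundation is low (<25%), casuarina forest between highest tide and
the salt boundary, with mudflat between permanent water and the mangrove
lower limit. :class:`ZonationBands` turns those frequency bands (or
explicit elevation bounds) into a stack of half-open, lower-inclusive
elevation intervals per subsite.

Two succession modes are modelled. ``slamm`` mode enforces the
one-directional class sequence of SLAMM-like models: a cell may only
retrogress (move toward more frequent inundation) and open water is
absorbing — water never converts back to any vegetated class, which is why
such models cannot prograde a shoreline. ``boundary_free`` mode simply
reclassifies from elevation each step, allowing movement in both
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import (
    CASUARINA,
    CLASS_ORDER,
    MANGROVE,
    MIXED,
    MUDFLAT,
    OPEN_WATER,
    SALTMARSH,
    UPLAND,
    ElevationGrid,
    SubsiteMap,
    VegetationGrid,
)
from .tides import ConfigurationError, TidalFrame, exceedance_elevation

__all__ = [
    "ZonationBands",
    "SuccessionPolicy",
    "default_frequency_bands",
    "classify",
    "classify_grid",
    "apply_succession",
    "veg_to_dem",
]


@dataclass(frozen=True)
class ZonationBands:
    """Elevation bands for the intertidal classes.

    ``kind`` is "frequency" (bounds are inundation fractions, converted to
    elevations per subsite through the sinusoidal tide so bands scale with
    local GT) or "elevation" (explicit metres relative to local MSL, fixed
    across subsites). Bounds map class code -> (lower, upper); frequency
    bounds are (lower_freq, upper_freq) with lower frequency meaning higher
    elevation.
    """

    kind: str
    bounds: dict

    def __post_init__(self):
        if self.kind not in ("frequency", "elevation"):
            raise ConfigurationError(f"unknown band kind {self.kind!r}")

    def thresholds(self, gt: float, salt_boundary: float) -> np.ndarray:
        """Six ascending class boundaries (m rel. local MSL).

        thresholds[i] is the lower edge of class code i+1; class membership
        is lower-inclusive, so classify = searchsorted(thresholds, z, 'right').
        """
        if self.kind == "frequency":
            a = gt / 2.0
            t = [
                -a,  # open_water | mudflat
                exceedance_elevation(self.bounds[MUDFLAT][0], gt),
                exceedance_elevation(self.bounds[MANGROVE][0], gt),
                exceedance_elevation(self.bounds[MIXED][0], gt),
                a,  # saltmarsh | casuarina (highest tide)
                salt_boundary,  # casuarina | upland
            ]
        else:
            order = (MUDFLAT, MANGROVE, MIXED, SALTMARSH, CASUARINA)
            for lo_cls, hi_cls in zip(order[:-1], order[1:]):
                if self.bounds[lo_cls][1] != self.bounds[hi_cls][0]:
                    raise ConfigurationError(
                        f"elevation bands must tile: {CLASS_ORDER[lo_cls]} upper "
                        f"!= {CLASS_ORDER[hi_cls]} lower"
                    )
            t = [self.bounds[c][0] for c in order] + [self.bounds[CASUARINA][1]]
        t = np.asarray(t, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError(
                "zonation bands have a gap, overlap or zero width "
                f"(thresholds {t.tolist()})"
            )
        return t

    def band_interval(self, cls: int, gt: float, salt_boundary: float) -> tuple[float, float]:
        """[lower, upper) elevation interval of a class (m rel. local MSL).

        open_water and upland are unbounded; they get nominal gt/2-deep
        bands so the vegetation preprocessor has a finite interval to
        interpolate over.
        """
        t = self.thresholds(gt, salt_boundary)
        if cls == OPEN_WATER:
            return (t[0] - gt / 2.0, t[0])
        if cls == UPLAND:
            return (t[5], t[5] + gt / 2.0)
        return (t[cls - 1], t[cls])


def default_frequency_bands() -> ZonationBands:
    """The regional frequency zonation: mudflat 100-50%, mangrove 50-25%,
    mixed 25-12.5%, saltmarsh 12.5-0%."""
    return ZonationBands(
        kind="frequency",
        bounds={
            MUDFLAT: (0.5, 1.0),
            MANGROVE: (0.25, 0.5),
            MIXED: (0.125, 0.25),
            SALTMARSH: (0.0, 0.125),
        },
    )


def classify_grid(z: np.ndarray, subsites: SubsiteMap, frame: TidalFrame,
                  bands: ZonationBands, nodata_mask: np.ndarray | None = None):
    """Classify every cell of an elevation matrix against its subsite's bands.

    Returns an int16 code matrix; masked cells keep code 0. Classification
    is monotone in z (higher cells never map to a lower-ranked class).
    """
    z = np.asarray(z, dtype=float)
    out = np.zeros(z.shape, dtype=np.int16)
    valid = ~nodata_mask if nodata_mask is not None else np.ones(z.shape, bool)
    for sid in range(1, frame.n_subsites + 1):
        sel = (subsites.ids == sid) & valid
        if not sel.any():
            continue
        thr = bands.thresholds(frame.gt[sid - 1], frame.salt_boundary[sid - 1])
        rel = z[sel] - frame.msl[sid - 1]
        out[sel] = np.searchsorted(thr, rel, side="right").astype(np.int16)
    return out


def classify(z: float, subsite: int, frame: TidalFrame, bands: ZonationBands) -> int:
    """Single-cell classification (code into CLASS_ORDER)."""
    thr = bands.thresholds(frame.gt[subsite - 1], frame.salt_boundary[subsite - 1])
    return int(np.searchsorted(thr, z - frame.msl[subsite - 1], side="right"))


@dataclass(frozen=True)
class SuccessionPolicy:
    """mode "slamm": retrogression only, open water absorbing;
    mode "boundary_free": the elevation classification is taken as-is."""

    mode: str = "slamm"

    def __post_init__(self):
        if self.mode not in ("slamm", "boundary_free"):
            raise ConfigurationError(f"unknown succession mode {self.mode!r}")

    @property
    def allow_progradation(self) -> bool:
        return self.mode == "boundary_free"


def apply_succession(prev, proposed, policy: SuccessionPolicy):
    """Resolve a proposed reclassification against the previous class.

    slamm mode: landward moves (rank increases) are rejected and open water
    is absorbing — elementwise this is min(prev, proposed), which is
    idempotent and never increases rank. boundary_free: proposed wins.
    Works on scalars or code matrices.
    """
    prev = np.asarray(prev)
    proposed = np.asarray(proposed)
    if policy.mode == "slamm":
        out = np.minimum(prev, proposed)
    else:
        out = proposed
    return int(out) if out.ndim == 0 else out.astype(np.int16)


def veg_to_dem(veg: VegetationGrid, bands: ZonationBands, frame: TidalFrame,
               subsites: SubsiteMap) -> ElevationGrid:
    """Reconstruct an elevation surface from a vegetation map (the
    "vegetation preprocessor").

    Within each contiguous same-class region, elevations run linearly from
    the class's lower bound at the edge adjacent to the seaward
    (lower-ranked) class to its upper bound at the landward edge, along the
    distance-to-seaward-edge axis. Regions with no gradient defined
    (single cells, uniform maps) sit at the band midpoint.
    """
    codes = veg.codes
    valid = ~veg.nodata_mask
    frac = np.full(codes.shape, 0.5, dtype=float)

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for cls in range(len(veg.class_order)):
        cls_mask = (codes == cls) & valid
        if not cls_mask.any():
            continue
        seaward = (codes < cls) & valid
        landward = (codes > cls) & valid
        # distance (cells) to nearest seaward / landward cell; inf if none
        d_sea = (
            ndimage.distance_transform_edt(~seaward)
            if seaward.any()
            else np.full(codes.shape, np.inf)
        )
        d_land = (
            ndimage.distance_transform_edt(~landward)
            if landward.any()
            else np.full(codes.shape, np.inf)
        )
        labels, n = ndimage.label(cls_mask, structure=structure)
        for region in range(1, n + 1):
            rm = labels == region
            ds, dl = d_sea[rm], d_land[rm]
            if rm.sum() == 1 or not (np.isfinite(ds).all() and np.isfinite(dl).all()):
                continue  # midpoint
            denom = ds + dl - 2.0
            f = np.where(denom > 0, (ds - 1.0) / np.where(denom > 0, denom, 1.0), 0.5)
            frac[rm] = np.clip(f, 0.0, 1.0)

    z = np.zeros(codes.shape, dtype=float)
    for sid in range(1, frame.n_subsites + 1):
        gt = frame.gt[sid - 1]
        sb = frame.salt_boundary[sid - 1]
        msl = frame.msl[sid - 1]
        in_sub = (subsites.ids == sid) & valid
        for cls in range(len(veg.class_order)):
            sel = in_sub & (codes == cls)
            if not sel.any():
                continue
            lo, hi = bands.band_interval(cls, gt, sb)
            if hi <= lo:
                raise ConfigurationError(
                    f"class {veg.class_order[cls]} has a zero-width band"
                )
            z[sel] = msl + lo + frac[sel] * (hi - lo)
    return ElevationGrid(z, veg.cell_size, veg.nodata_mask.copy(), veg.origin)
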