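"""Raster containers and ESRI ASCII grid I/O.

The whole pipeline works on a single shared grid world: a substrate
elevation raster (m above a fixed height datum), a categorical vegetation
raster over the seven-class estuarine zonation, and a subsite-ID raster
that partitions the estuary into reaches with their own tidal parameters.
Grids are projection-agnostic: all operations use a local metric frame
(cell size in metres) and row 0 is the northernmost row, the usual raster
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASS_ORDER",
    "OPEN_WATER",
    "MUDFLAT",
    "MANGROVE",
    "MIXED",
    "SALTMARSH",
    "CASUARINA",
    "UPLAND",
    "ElevationGrid",
    "VegetationGrid",
    "SubsiteMap",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_class_grid",
    "read_subsite_grid",
    "area_by_class",
]

# Vegetation classes ordered from most- to least-frequently inundated.
# Codes are the rank in this order, so "landward of" is an integer
# comparison and succession direction is a sign.
CLASS_ORDER = (
    "open_water",
    "mudflat",
    "mangrove",
    "mixed",
    "saltmarsh",
    "casuarina",
    "upland",
)
OPEN_WATER, MUDFLAT, MANGROVE, MIXED, SALTMARSH, CASUARINA, UPLAND = range(7)
N_CLASSES = len(CLASS_ORDER)

#: Classes lying between permanent water and the terrestrial boundary.
INTERTIDAL_CLASSES = (MUDFLAT, MANGROVE, MIXED, SALTMARSH, CASUARINA)


class RasterFormatError(ValueError):
    """Malformed ESRI ASCII grid (bad header key or row shape)."""


@dataclass
class ElevationGrid:
    """Substrate elevation in metres above a fixed height datum.

    ``nodata_mask`` is True where the cell carries no data; nodata is
    propagated by every operation and never imputed.
    """

    values: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("elevation values must be a 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("unmasked elevations must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ElevationGrid":
        return ElevationGrid(
            self.values.copy(), self.cell_size, self.nodata_mask.copy(), self.origin
        )


@dataclass
class VegetationGrid:
    """Categorical raster of vegetation classes (codes index CLASS_ORDER)."""

    codes: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray = None
    origin: tuple[float, float] = (0.0, 0.0)
    class_order: tuple[str, ...] = field(default=CLASS_ORDER)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise ValueError("vegetation codes must be a 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.codes.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.codes.shape:
            raise ValueError("nodata_mask shape must match codes")
        valid = self.codes[~self.nodata_mask]
        if valid.size and (valid.min() < 0 or valid.max() >= len(self.class_order)):
            raise ValueError("unmasked codes must be members of class_order")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def copy(self) -> "VegetationGrid":
        return VegetationGrid(
            self.codes.copy(),
            self.cell_size,
            self.nodata_mask.copy(),
            self.origin,
            self.class_order,
        )


@dataclass
class SubsiteMap:
    """Partition of the grid into tidal subsites, ids contiguous 1..n."""

    ids: np.ndarray
    n_subsites: int
    nodata_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int32)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.ids.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        valid = self.ids[~self.nodata_mask]
        if valid.size:
            present = np.unique(valid)
            if present.min() < 1 or present.max() > self.n_subsites:
                raise ValueError(
                    "subsite ids must lie in 1..n_subsites; "
                    f"found range [{present.min()}, {present.max()}]"
                )


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _parse_header(lines: list[str], path) -> tuple[dict, int]:
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and not _is_number(parts[0]):
            key = parts[0].lower()
            if key not in _HEADER_KEYS and key != "nodata_value":
                raise RasterFormatError(f"{path}: unknown header key {parts[0]!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: header key {parts[0]!r} has non-numeric value {parts[1]!r}"
                ) from exc
        else:
            break
    else:
        i += 1
    for key in _HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"{path}: missing header key {key!r}")
    return header, i


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_ascii_grid(path) -> ElevationGrid:
    """Read an ESRI ASCII grid into an :class:`ElevationGrid`.

    The header must declare ncols/nrows/xllcorner/yllcorner/cellsize and may
    declare NODATA_value; NODATA cells are masked.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    header, start = _parse_header(lines, path)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    rows = []
    for r, line in enumerate(lines[start:]):
        vals = line.split()
        if len(vals) != ncols:
            raise RasterFormatError(
                f"{path}: row {r} has {len(vals)} values, expected ncols={ncols}"
            )
        rows.append([float(v) for v in vals])
    if len(rows) != nrows:
        raise RasterFormatError(
            f"{path}: found {len(rows)} data rows, expected nrows={nrows}"
        )
    values = np.array(rows, dtype=np.float64)
    mask = np.zeros(values.shape, dtype=bool)
    if "nodata_value" in header:
        mask = values == header["nodata_value"]
        values = np.where(mask, 0.0, values)
    return ElevationGrid(
        values,
        cell_size=header["cellsize"],
        nodata_mask=mask,
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def write_ascii_grid(grid, path, nodata_value: float = -9999.0, fmt: str = "%.17g") -> None:
    """Write an ElevationGrid/VegetationGrid/SubsiteMap as an ESRI ASCII grid.

    The default float format round-trips IEEE doubles bit-identically.
    """
    if isinstance(grid, VegetationGrid):
        values, mask, cell, origin = grid.codes, grid.nodata_mask, grid.cell_size, grid.origin
        fmt = "%d"
    elif isinstance(grid, SubsiteMap):
        values, mask, cell, origin = grid.ids, grid.nodata_mask, 1.0, (0.0, 0.0)
        fmt = "%d"
    else:
        values, mask, cell, origin = grid.values, grid.nodata_mask, grid.cell_size, grid.origin
    nrows, ncols = values.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.17g}\n")
        fh.write(f"yllcorner {origin[1]:.17g}\n")
        fh.write(f"cellsize {cell:.17g}\n")
        fh.write(f"NODATA_value {nodata_value:.17g}\n")
        out = np.where(mask, nodata_value, values)
        for row in out:
            fh.write(" ".join(fmt % v for v in row))
            fh.write("\n")


def read_class_grid(path) -> VegetationGrid:
    """Read a categorical ASCII grid as a VegetationGrid."""
    g = read_ascii_grid(path)
    return VegetationGrid(
        g.values.astype(np.int16), g.cell_size, g.nodata_mask, g.origin
    )


def read_subsite_grid(path) -> SubsiteMap:
    g = read_ascii_grid(path)
    ids = g.values.astype(np.int32)
    valid = ids[~g.nodata_mask]
    n = int(valid.max()) if valid.size else 0
    return SubsiteMap(ids, n_subsites=n, nodata_mask=g.nodata_mask)


def area_by_class(veg: VegetationGrid):
    """Per-class area in hectares: count * cell_size^2 / 10^4.

    Masked cells are excluded; classes absent from the map report 0 ha, so
    the series always covers the full class order and sums to the unmasked
    area exactly (in cell counts).
    """
    import pandas as pd

    codes = veg.codes[~veg.nodata_mask]
    counts = np.bincount(codes, minlength=len(veg.class_order))
    ha_per_cell = veg.cell_size**2 / 1e4
    return pd.Series(
        counts * ha_per_cell, index=list(veg.class_order), name="area_ha"
    )
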