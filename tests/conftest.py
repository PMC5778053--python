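"""Shared fixtures: a small synthetic estuary world and a 1-D strip world
with equal-width explicit elevation bands, where every expected value can
be computed by hand."""

import numpy as np
import pytest

from tidemarsh.dynamics import distance_fields
from tidemarsh.raster import ElevationGrid, SubsiteMap
from tidemarsh.synthetic import EstuaryRecipe, make_estuary
from tidemarsh.tides import TidalFrame
from tidemarsh.vegetation import ZonationBands, default_frequency_bands
from tidemarsh.raster import MUDFLAT, MANGROVE, MIXED, SALTMARSH, CASUARINA


@pytest.fixture(scope="session")
def estuary():
    """Default synthetic estuary (deterministic, seed 0)."""
    recipe = EstuaryRecipe(seed=0)
    dem, subsites, frame, distances = make_estuary(recipe)
    return {"recipe": recipe, "dem": dem, "subsites": subsites,
            "frame": frame, "distances": distances,
            "bands": default_frequency_bands()}


@pytest.fixture()
def strip_world():
    """One-row, single-subsite world with equal-width 0.25 m bands:
    thresholds [-0.5, -0.25, 0, 0.25, 0.5, 0.75], so a 0.25 m sea-level
    rise shifts every class exactly one band."""
    bands = ZonationBands(kind="elevation", bounds={
        MUDFLAT: (-0.5, -0.25),
        MANGROVE: (-0.25, 0.0),
        MIXED: (0.0, 0.25),
        SALTMARSH: (0.25, 0.5),
        CASUARINA: (0.5, 0.75),
    })
    frame = TidalFrame(msl_offset=[0.0], gt=[1.0], salt_boundary=[0.75])
    # band midpoints: open_water .. upland
    z = np.array([[-0.875, -0.375, -0.125, 0.125, 0.375, 0.625, 0.875]])
    dem = ElevationGrid(z, cell_size=10.0)
    subsites = SubsiteMap(np.ones_like(z, dtype=int), n_subsites=1)
    distances = distance_fields(z < -0.5, 10.0)
    return {"dem": dem, "subsites": subsites, "frame": frame,
            "bands": bands, "distances": distances}
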