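"""Coupled simulation stepping: ordering, conservation, succession
interplay, determinism, initial-condition modes."""

import numpy as np
import pandas as pd
import pytest

from tidemarsh.dynamics import Cm1SecConfig, SlammSecConfig
from tidemarsh.raster import (
    CASUARINA,
    MANGROVE,
    MIXED,
    MUDFLAT,
    OPEN_WATER,
    SALTMARSH,
    UPLAND,
    VegetationGrid,
    area_by_class,
)
from tidemarsh.simulate import initial_state, run, step
from tidemarsh.tides import ConfigurationError, SLRScenario, backstep_datum
from tidemarsh.vegetation import SuccessionPolicy, classify_grid

ZERO_RATES = SlammSecConfig(rates={c: 0.0 for c in range(7)})


def _state(world, scenario, engine="slamm", cfg=ZERO_RATES, veg_map=None,
           policy=None):
    return initial_state(
        world["dem"], veg_map, world["frame"], world["bands"], world["subsites"],
        scenario, engine, cfg, distances=world["distances"], policy=policy,
    )


class TestStep:
    def test_zero_slr_zero_sec_is_a_fixed_point(self, strip_world):
        scenario = SLRScenario.linear(2000, 2100, 0.0)
        s0 = _state(strip_world, scenario)
        s1 = step(s0, 10.0)
        assert s1.year == 2010.0
        assert np.array_equal(s1.veg.codes, s0.veg.codes)
        assert np.array_equal(s1.z.values, s0.z.values)

    def test_one_band_slr_retrogresses_each_class_once(self, strip_world):
        # 0.25 m rise = exactly one band width on the equal-band strip
        scenario = SLRScenario(years=[2000.0, 2010.0], anomaly=[0.0, 0.25])
        s0 = _state(strip_world, scenario)
        assert s0.veg.codes[0].tolist() == [
            OPEN_WATER, MUDFLAT, MANGROVE, MIXED, SALTMARSH, CASUARINA, UPLAND]
        s1 = step(s0, 10.0)
        assert s1.veg.codes[0].tolist() == [
            OPEN_WATER, OPEN_WATER, MUDFLAT, MANGROVE, MIXED, SALTMARSH, CASUARINA]

    def test_sec_keeping_pace_preserves_vegetation(self, strip_world):
        scenario = SLRScenario(years=[2000.0, 2010.0], anomaly=[0.0, 0.03])
        cfg = SlammSecConfig(rates={c: 3.0 for c in range(7)})
        s0 = _state(strip_world, scenario, cfg=cfg)
        s1 = step(s0, 10.0)
        assert np.array_equal(s1.veg.codes, s0.veg.codes)
        assert np.allclose(s1.z.values - s0.z.values, 0.03)

    def test_exhausted_scenario_is_a_range_error(self, strip_world):
        scenario = SLRScenario.linear(2000, 2010, 1.0)
        with pytest.raises(ValueError, match="scenario"):
            step(_state(strip_world, scenario), 20.0)


class TestRun:
    def test_emits_area_row_per_step_year(self, strip_world):
        scenario = SLRScenario.linear(1986, 1997, 2.1)
        result = run(_state(strip_world, scenario), 1997, dt=10.0)
        assert result.areas.index.tolist() == [1986.0, 1996.0, 1997.0]

    def test_run_to_start_year_returns_initial_areas(self, strip_world):
        scenario = SLRScenario.linear(2000, 2100, 1.0)
        s0 = _state(strip_world, scenario)
        result = run(s0, 2000)
        assert len(result.areas) == 1
        pd.testing.assert_series_equal(
            result.areas.iloc[0], area_by_class(s0.veg), check_names=False)

    def test_determinism_bit_identical(self, estuary):
        scenario = SLRScenario.linear(2000, 2100, 5.0)
        cfg = SlammSecConfig(rates={1: 3.0, 2: 2.5, 3: 2.0, 4: 1.5, 5: 0.5})
        r1 = run(_state(estuary, scenario, cfg=cfg), 2100)
        r2 = run(_state(estuary, scenario, cfg=cfg), 2100)
        assert r1.areas.equals(r2.areas)

    def test_area_conservation_every_step(self, estuary):
        scenario = SLRScenario.linear(2000, 2100, 8.0)
        cfg = SlammSecConfig(rates={1: 3.0, 2: 2.5, 3: 2.0, 4: 1.5, 5: 0.5})
        result = run(_state(estuary, scenario, cfg=cfg), 2100)
        total = (~estuary["dem"].nodata_mask).sum() * estuary["dem"].cell_size**2 / 1e4
        assert np.allclose(result.areas.sum(axis=1), total, rtol=1e-12)

    def test_monotone_inundation_under_dominating_scenario(self, estuary):
        # zero SEC + slamm policy: open water never shrinks in time, and a
        # pointwise-larger scenario gives pointwise-larger open water
        low = SLRScenario.linear(2000, 2100, 4.0)
        high = SLRScenario.linear(2000, 2100, 8.0)
        r_low = run(_state(estuary, low), 2100)
        r_high = run(_state(estuary, high), 2100)
        assert np.all(np.diff(r_low.areas["open_water"]) >= 0)
        assert np.all(r_high.areas["open_water"] >= r_low.areas["open_water"])


class TestInitialState:
    def test_slamm_uses_supplied_map(self, strip_world):
        scenario = SLRScenario.linear(2000, 2100, 0.0)
        codes = np.full((1, 7), SALTMARSH, dtype=np.int16)
        veg = VegetationGrid(codes, cell_size=10.0)
        s = _state(strip_world, scenario, veg_map=veg)
        assert np.array_equal(s.veg.codes, codes)

    def test_cm1_classifies_from_dem(self, strip_world):
        scenario = SLRScenario.linear(2000, 2100, 0.0)
        s = _state(strip_world, scenario, engine="cm1", cfg=Cm1SecConfig())
        expected = classify_grid(strip_world["dem"].values, strip_world["subsites"],
                                 strip_world["frame"], strip_world["bands"])
        assert np.array_equal(s.veg.codes, expected)
        assert s.policy.mode == "boundary_free"

    def test_map_consistent_with_zonation_matches_cm_modes(self, strip_world):
        scenario = SLRScenario.linear(2000, 2100, 0.0)
        expected = classify_grid(strip_world["dem"].values, strip_world["subsites"],
                                 strip_world["frame"], strip_world["bands"])
        veg = VegetationGrid(expected, cell_size=10.0)
        s_map = _state(strip_world, scenario, veg_map=veg)
        s_cm = _state(strip_world, scenario, engine="cm1", cfg=Cm1SecConfig())
        assert np.array_equal(s_map.veg.codes, s_cm.veg.codes)

    def test_unknown_engine_rejected(self, strip_world):
        scenario = SLRScenario.linear(2000, 2100, 0.0)
        with pytest.raises(ConfigurationError):
            _state(strip_world, scenario, engine="mem")


class TestBackstepRoundTrip:
    def test_forward_run_restores_initial_classification(self, estuary):
        rate, years = 2.1, 48.0
        frame = estuary["frame"]
        back = backstep_datum(frame, rate, years)
        scenario = SLRScenario.linear(1949.0, 1997.0, rate)
        state = initial_state(
            estuary["dem"], None, back, estuary["bands"], estuary["subsites"],
            scenario, "slamm", ZERO_RATES, distances=estuary["distances"],
            policy=SuccessionPolicy("boundary_free"),
        )
        result = run(state, 1997.0, dt=10.0, record_rasters=True)
        final = result.rasters[-1][1].codes
        expected = classify_grid(estuary["dem"].values, estuary["subsites"],
                                 frame, estuary["bands"],
                                 estuary["dem"].nodata_mask)
        assert np.array_equal(final, expected)


class TestCm1Levee:
    def test_channel_bank_out_accretes_distant_cells(self):
        # exponential distance decay builds a natural levee: among cells of
        # equal starting elevation, those nearest the channel accrete most,
        # so under rising sea level flooding onsets landward of the bank
        from tidemarsh.dynamics import DistanceField
        from tidemarsh.raster import ElevationGrid, SubsiteMap
        from tidemarsh.tides import TidalFrame
        from tidemarsh.vegetation import default_frequency_bands

        n = 20
        dem = ElevationGrid(np.zeros((1, n)), cell_size=10.0)
        sub = SubsiteMap(np.ones((1, n), int), n_subsites=1)
        frame = TidalFrame(msl_offset=[0.0], gt=[1.3], salt_boundary=[0.975])
        dist = DistanceField(dist_channel=np.linspace(0, 500, n)[None, :],
                             dist_shore=np.zeros((1, n)))
        scenario = SLRScenario.linear(2000, 2100, 8.0)
        cfg = Cm1SecConfig(k=6.0, l=1.5, m=0.005)
        s0 = initial_state(dem, None, frame, default_frequency_bands(), sub,
                           scenario, "cm1", cfg, distances=dist)
        s1 = step(s0, 10.0)
        gained = (s1.z.values - s0.z.values)[0]
        assert np.all(np.diff(gained) < 0)
        final = run(s0, 2100, record_rasters=True).rasters[-1][1].codes[0]
        # the bank keeps pace better than the interior behind it
        assert final[0] > final[-1]
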