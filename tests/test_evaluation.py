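"""Map-agreement statistics, the 10% validity rule, OAT sensitivity and
model comparison."""

import numpy as np
import pandas as pd
import pytest

from tidemarsh.evaluate import (
    disagreement_fraction,
    overlap_matrix,
    percent_area_difference,
    sensitivity_analysis,
    validity_check,
)
from tidemarsh.raster import CLASS_ORDER, MANGROVE, SALTMARSH, VegetationGrid
from tidemarsh.synthetic import EstuaryRecipe
from tidemarsh.workflows import RunSpec, oat_sensitivity

SMALL = EstuaryRecipe(shape=(60, 100), seed=0)


def _veg(codes):
    return VegetationGrid(np.asarray(codes, dtype=np.int16), cell_size=10.0)


class TestPercentAreaDifference:
    def idx(self, **kw):
        return pd.Series(kw, dtype=float)

    def test_signed_arithmetic(self):
        d = percent_area_difference(self.idx(saltmarsh=108.5), self.idx(saltmarsh=100))
        assert d["saltmarsh"] == pytest.approx(8.5)
        d = percent_area_difference(self.idx(mangrove=75), self.idx(mangrove=100))
        assert d["mangrove"] == pytest.approx(-25.0)

    def test_equal_areas_give_zero(self):
        d = percent_area_difference(self.idx(mangrove=42), self.idx(mangrove=42))
        assert d["mangrove"] == 0.0

    def test_zero_observed_is_undefined_not_infinite(self):
        d = percent_area_difference(self.idx(mixed=5), self.idx(mixed=0))
        assert np.isnan(d["mixed"])


class TestOverlapMatrix:
    def test_identical_maps_give_identity(self):
        v = _veg([[1, 2], [3, 4]])
        o = overlap_matrix(v, v)
        for c in (1, 2, 3, 4):
            assert o.iloc[c, c] == 1.0

    def test_half_and_half(self):
        modeled = _veg([[SALTMARSH, SALTMARSH], [SALTMARSH, SALTMARSH]])
        observed = _veg([[SALTMARSH, SALTMARSH], [MANGROVE, MANGROVE]])
        o = overlap_matrix(modeled, observed)
        assert o.loc["saltmarsh", "saltmarsh"] == 0.5
        assert o.loc["saltmarsh", "mangrove"] == 0.5

    def test_disjoint_maps_put_mass_off_diagonal(self):
        o = overlap_matrix(_veg([[MANGROVE]]), _veg([[SALTMARSH]]))
        assert o.loc["mangrove", "saltmarsh"] == 1.0

    def test_empty_modeled_rows_are_null(self):
        o = overlap_matrix(_veg([[MANGROVE]]), _veg([[MANGROVE]]))
        assert o.loc["saltmarsh"].isna().all()

    def test_rows_sum_to_one_against_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = _veg(rng.integers(0, 7, (10, 10)))
            b = _veg(rng.integers(0, 7, (10, 10)))
            o = overlap_matrix(a, b)
            for i, name in enumerate(CLASS_ORDER):
                n_i = (a.codes == i).sum()
                if n_i == 0:
                    continue
                assert o.loc[name].sum() == pytest.approx(1.0)
                for j, obs in enumerate(CLASS_ORDER):
                    brute = ((a.codes == i) & (b.codes == j)).sum() / n_i
                    assert o.loc[name, obs] == pytest.approx(brute)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_matrix(_veg([[1]]), _veg([[1, 2]]))


class TestValidityRule:
    def test_paper_style_diff_set(self):
        diffs = pd.Series({"mangrove": 1.7, "saltmarsh": 8.5,
                           "mangrove_49": -25.0, "saltmarsh_49": 94.0})
        flags, overall = validity_check(diffs)
        assert flags.tolist() == [True, True, False, False]
        assert overall is False

    def test_boundary_is_strict(self):
        flags, _ = validity_check(pd.Series({"x": 10.0}))
        assert not flags["x"]
        flags, _ = validity_check(pd.Series({"x": 9.999}))
        assert flags["x"]

    def test_monotone_in_threshold(self):
        diffs = pd.Series({"a": 3.0, "b": 12.0, "c": 40.0})
        counts = [validity_check(diffs, t)[0].sum() for t in (5, 15, 50)]
        assert counts == sorted(counts)


class TestSensitivity:
    def test_pathwayless_parameter_row_is_zero(self):
        spec = RunSpec(recipe=SMALL)
        table = oat_sensitivity(spec, ["historic_trend"])
        col = table.plus["historic_trend"].dropna()
        assert (col == 0.0).all()

    def test_first_order_linearity_on_cm2_intercept(self):
        # doubling the perturbation of a linear-response parameter roughly
        # doubles the area response
        spec = RunSpec(recipe=SMALL, engine="cm2", dt=10.0)
        t1 = oat_sensitivity(spec, ["cm2_intercept"], perturbation=0.05)
        t2 = oat_sensitivity(spec, ["cm2_intercept"], perturbation=0.10)
        a = t1.plus["cm2_intercept"]["open_water"]
        b = t2.plus["cm2_intercept"]["open_water"]
        if abs(a) > 0.5:  # only meaningful when the response is visible
            assert b / a == pytest.approx(2.0, rel=0.5)

    def test_unknown_parameter_rejected(self):
        from tidemarsh.tides import ConfigurationError

        with pytest.raises(ConfigurationError):
            RunSpec(recipe=SMALL).perturbed("not_a_parameter", 1.1)

    def test_both_directions_recorded(self):
        spec = RunSpec(recipe=SMALL, sec_rates={1: 0, 2: 0, 3: 0, 4: 0, 5: 0})
        table = sensitivity_analysis(spec, ["slr_by_2100"], perturbation=0.10)
        assert "slr_by_2100" in table.plus and "slr_by_2100" in table.minus
        assert table.headline.equals(table.plus)


class TestDisagreement:
    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(5)
        a = _veg(rng.integers(0, 7, (10, 10)))
        b = _veg(rng.integers(0, 7, (10, 10)))
        brute = sum(
            a.codes[i, j] != b.codes[i, j] for i in range(10) for j in range(10)
        ) / 100
        assert disagreement_fraction(a, b) == pytest.approx(brute)

    def test_identical_engines_zero_disagreement(self, strip_world):
        # three engines with all-zero rates and a forced boundary_free
        # policy are the same dynamical system
        from tidemarsh.dynamics import Cm1SecConfig, Cm2SecConfig, SlammSecConfig
        from tidemarsh.simulate import initial_state, run
        from tidemarsh.synthetic import CovariateRecipe, make_covariates
        from tidemarsh.tides import SLRScenario
        from tidemarsh.vegetation import SuccessionPolicy

        scenario = SLRScenario.linear(2000, 2050, 4.0)
        cov = make_covariates(CovariateRecipe(start_year=2000, end_year=2050,
                                              rain_sd_mm=0.0,
                                              waterlevel_noise_sd_m=0.0))
        cfgs = {
            "slamm": SlammSecConfig(rates={c: 0.0 for c in range(7)}),
            "cm1": Cm1SecConfig(k=0.0),
            "cm2": Cm2SecConfig(intercept=0.0),
        }
        finals = {}
        for engine, cfg in cfgs.items():
            s = initial_state(
                strip_world["dem"], None, strip_world["frame"],
                strip_world["bands"], strip_world["subsites"], scenario,
                engine, cfg, distances=strip_world["distances"],
                covariates=cov, policy=SuccessionPolicy("boundary_free"))
            finals[engine] = run(s, 2050, record_rasters=True).rasters[-1][1]
        assert disagreement_fraction(finals["slamm"], finals["cm1"]) == 0.0
        assert disagreement_fraction(finals["slamm"], finals["cm2"]) == 0.0
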