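"""End-to-end study workflows over the synthetic estuary.

A :class:`RunSpec` bundles everything one simulation needs — the estuary
recipe, the scenario, the engine and its coefficients, the elevation bands
— and knows how to perturb any named parameter for one-at-a-time
sensitivity. The module-level functions reproduce the study's four
analyses on the synthetic estuary: the tidal-attenuation contrast,
retrospective validation over two horizons, the three-engine comparison,
and the OAT sensitivity table. They are what the analysis scripts and the
acceptance script call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import Cm1SecConfig, Cm2SecConfig, SlammSecConfig
from .evaluate import (
    SensitivityTable,
    agreement_report,
    compare_models,
    sensitivity_analysis,
)
from .raster import (
    CASUARINA,
    INTERTIDAL_CLASSES,
    MANGROVE,
    MIXED,
    MUDFLAT,
    SALTMARSH,
    CLASS_ORDER,
    VegetationGrid,
    area_by_class,
)
from .simulate import RunResult, initial_state, run
from .synthetic import (
    CovariateRecipe,
    EstuaryRecipe,
    make_covariates,
    make_estuary,
    make_initial_veg,
    make_scenarios,
)
from .tides import ConfigurationError, SLRScenario, backstep_datum, global_frame
from .vegetation import SuccessionPolicy, ZonationBands, classify_grid, default_frequency_bands

__all__ = [
    "RunSpec",
    "default_sec_rates",
    "attenuation_contrast",
    "retrospective_validation",
    "model_comparison",
    "oat_sensitivity",
    "SENSITIVITY_PARAMETERS",
]


def default_sec_rates() -> dict:
    """Per-class SEC rates (mm/yr) in the low-mm/yr range SET benchmarks
    record in the region: highest on frequently flooded mudflat, tapering
    landward."""
    return {
        MUDFLAT: 3.0,
        MANGROVE: 2.5,
        MIXED: 2.0,
        SALTMARSH: 1.5,
        CASUARINA: 0.5,
    }


@dataclass(frozen=True)
class RunSpec:
    """A fully specified simulation on the synthetic estuary."""

    recipe: EstuaryRecipe = field(default_factory=EstuaryRecipe)
    engine: str = "slamm"
    start_year: float = 1997.0
    end_year: float = 2100.0
    dt: float = 10.0
    slr_by_2100: float = 0.9  # m, high-emissions-scenario class total
    sec_rates: dict = field(default_factory=default_sec_rates)
    cm1: Cm1SecConfig = field(default_factory=Cm1SecConfig)
    cm2: Cm2SecConfig = field(default_factory=lambda: Cm2SecConfig(
        intercept=2.2, coef_rain_mm=0.002, coef_soi=0.02,
        coef_dist_shore_m=-0.0005, coef_msl_m=1.0, distance_field="shore"))
    bands: ZonationBands = field(default_factory=default_frequency_bands)
    datum_correction: float = 0.08  # m, height-to-tidal-datum shift
    attenuation: bool = True  # False -> single-tidal-range control
    veg_perturbation: float = 0.0  # slamm base-map disagreement with zonation
    historic_scenario: bool = False  # force at the linear historic trend

    # ---- construction -------------------------------------------------

    def build(self):
        """Generate inputs (deterministic per recipe seed)."""
        dem, subsites, frame, distances = make_estuary(self.recipe)
        frame = replace(frame, datum_correction=self.datum_correction)
        if not self.attenuation:
            frame = global_frame(frame, reference=1)
        quad, historic = make_scenarios(
            self.slr_by_2100, frame.historic_slr_trend,
            start_year=self.start_year, label="accelerating",
        )
        scenario = historic if self.historic_scenario else quad
        covariates = None
        if self.engine == "cm2":
            covariates = make_covariates(CovariateRecipe(
                start_year=int(self.start_year), end_year=int(self.end_year),
                msl_scenario=scenario, seed=self.recipe.seed + 1,
            ))
        return dem, subsites, frame, distances, scenario, covariates

    def engine_config(self):
        if self.engine == "slamm":
            return SlammSecConfig(rates=dict(self.sec_rates))
        if self.engine == "cm1":
            return self.cm1
        return self.cm2

    def initial(self, veg_map: VegetationGrid | None = None,
                policy: SuccessionPolicy | None = None):
        dem, subsites, frame, distances, scenario, covariates = self.build()
        if veg_map is None and self.engine == "slamm" and self.veg_perturbation > 0:
            veg_map = make_initial_veg(
                dem, frame, self.bands, subsites,
                perturbation=self.veg_perturbation, seed=self.recipe.seed + 2,
            )
        return initial_state(
            dem, veg_map, frame, self.bands, subsites, scenario,
            self.engine, self.engine_config(), distances=distances,
            covariates=covariates, policy=policy,
        )

    def run(self, end_year: float | None = None,
            record_rasters: bool = False) -> RunResult:
        end = self.end_year if end_year is None else end_year
        return run(self.initial(), end, dt=self.dt, record_rasters=record_rasters)

    def final_areas(self, end_year: float | None = None) -> pd.Series:
        return self.run(end_year).areas.iloc[-1]

    # ---- OAT perturbation ---------------------------------------------

    def perturbed(self, name: str, factor: float) -> "RunSpec":
        """Return a copy with one named parameter scaled by ``factor``."""
        if name not in SENSITIVITY_PARAMETERS:
            raise ConfigurationError(
                f"unknown sensitivity parameter {name!r}; "
                f"known: {sorted(SENSITIVITY_PARAMETERS)}"
            )
        return SENSITIVITY_PARAMETERS[name](self, factor)


def _scale_recipe(spec: RunSpec, **kw) -> RunSpec:
    return replace(spec, recipe=replace(spec.recipe, **kw))


def _scale_sec(spec: RunSpec, cls: int, factor: float) -> RunSpec:
    rates = dict(spec.sec_rates)
    rates[cls] = rates.get(cls, 0.0) * factor
    return replace(spec, sec_rates=rates)


#: Addressable OAT parameters (the study's Table-1-style set plus engine
#: coefficients). historic_trend has no pathway into a scenario-forced
#: forward run — its row must come out exactly zero, which guards against
#: configuration leakage between parameters.
SENSITIVITY_PARAMETERS = {
    "slr_by_2100": lambda s, f: replace(s, slr_by_2100=s.slr_by_2100 * f),
    "gt": lambda s, f: _scale_recipe(s, gt_mouth_m=s.recipe.gt_mouth_m * f),
    "salt_boundary": lambda s, f: _scale_recipe(
        s, salt_boundary_m=s.recipe.salt_boundary_m * f),
    "datum_correction": lambda s, f: replace(
        s, datum_correction=s.datum_correction * f),
    "historic_trend": lambda s, f: _scale_recipe(
        s, historic_trend_mm_yr=s.recipe.historic_trend_mm_yr * f),
    "sec_mangrove": lambda s, f: _scale_sec(s, MANGROVE, f),
    "sec_saltmarsh": lambda s, f: _scale_sec(s, SALTMARSH, f),
    "cm1_k": lambda s, f: replace(s, cm1=replace(s.cm1, k=s.cm1.k * f)),
    "cm2_intercept": lambda s, f: replace(
        s, cm2=replace(s.cm2, intercept=s.cm2.intercept * f)),
    "cm2_rain": lambda s, f: replace(
        s, cm2=replace(s.cm2, coef_rain_mm=s.cm2.coef_rain_mm * f)),
}


# ---- study workflows ---------------------------------------------------


def attenuation_contrast(spec: RunSpec | None = None) -> dict:
    """Run the same scenario with per-subsite attenuated tidal ranges and
    with the single-tidal-range control, and contrast final class areas."""
    spec = spec or RunSpec()
    att = replace(spec, attenuation=True).run()
    glo = replace(spec, attenuation=False).run()
    final_att, final_glo = att.areas.iloc[-1], glo.areas.iloc[-1]
    return {
        "attenuated": att,
        "global": glo,
        "final_mangrove_ha": (float(final_att["mangrove"]), float(final_glo["mangrove"])),
        "final_casuarina_saltmarsh_ha": (
            float(final_att["casuarina"] + final_att["saltmarsh"]),
            float(final_glo["casuarina"] + final_glo["saltmarsh"]),
        ),
    }


def retrospective_validation(spec: RunSpec | None = None, years_back: float = 11.0,
                             observed_perturbation: float = 0.1,
                             dt: float | None = None) -> dict:
    """Rehearse the back-step validation on the synthetic estuary.

    The tidal frame is back-stepped by the historic trend over
    ``years_back`` (bathtub-style: land rises relative to sea), the model
    is run forward at that trend, and the final map is scored against a
    perturbed zonation map standing in for the photo-interpreted "observed"
    distribution of the final year.
    """
    spec = spec or RunSpec()
    dem, subsites, frame, distances, _, _ = spec.build()
    rate = frame.historic_slr_trend
    back = backstep_datum(frame, rate, years_back)
    y_end = spec.start_year
    y0 = y_end - years_back
    scenario = SLRScenario.linear(y0, y_end, rate, label="historic")
    state = initial_state(
        dem, None, back, spec.bands, subsites, scenario, spec.engine,
        spec.engine_config(), distances=distances,
    )
    result = run(state, y_end, dt=dt or spec.dt, record_rasters=True)
    modeled = result.rasters[-1][1]
    observed = make_initial_veg(dem, frame, spec.bands, subsites,
                                perturbation=observed_perturbation,
                                seed=spec.recipe.seed + 3)
    report = agreement_report(modeled, observed,
                              classes=[CLASS_ORDER[c] for c in INTERTIDAL_CLASSES])
    return {"run": result, "modeled": modeled, "observed": observed,
            "report": report, "years_back": years_back}


def model_comparison(spec: RunSpec | None = None) -> dict:
    """Run all three engines on the same grid, scenario and bands; the
    slamm engine starts from a (perturbed) vegetation map, cm1/cm2 from
    pure elevation zonation, as each model is meant to be applied."""
    spec = spec or RunSpec(veg_perturbation=0.1)
    runs = {}
    for engine in ("slamm", "cm1", "cm2"):
        runs[engine] = replace(spec, engine=engine).run(record_rasters=True)
    report = compare_models(runs)
    report["final_areas"] = pd.DataFrame(
        {e: runs[e].areas.iloc[-1] for e in runs}
    )
    report["runs"] = runs
    return report


def oat_sensitivity(spec: RunSpec | None = None,
                    parameters: list[str] | None = None,
                    perturbation: float = 0.10) -> SensitivityTable:
    """The study's OAT sensitivity table on the synthetic estuary."""
    spec = spec or RunSpec()
    parameters = parameters or [
        "historic_trend", "datum_correction", "salt_boundary",
        "sec_mangrove", "gt", "slr_by_2100",
    ]
    return sensitivity_analysis(spec, parameters, perturbation=perturbation)
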