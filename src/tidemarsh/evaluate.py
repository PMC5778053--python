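"""Validation, sensitivity and model-comparison procedures.

Map agreement uses two measures: the signed percent-area difference per
class (directional — a negative value is an underestimate of the observed
extent) and the overlap matrix O[modeled][observed], the fraction of each
modeled class's cells lying within each observed class; its diagonal is
the "correspondence" of a class. A class is statistically valid when its
absolute percent-area difference is strictly below the threshold (10% by
default), and a run is valid when every class is.

Sensitivity is one-at-a-time: each parameter is varied by +/- a fixed
fraction (10% by default) with everything else held fixed, the run is
repeated to the end year, and the percent change in each class's final
area is recorded. The headline table reports the +10% direction; the -10%
runs are retained alongside. Undefined ratios (zero observed or base
areas) are reported as nulls, never infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import CLASS_ORDER, VegetationGrid, area_by_class
from .tides import ConfigurationError

__all__ = [
    "AgreementReport",
    "SensitivityTable",
    "percent_area_difference",
    "overlap_matrix",
    "disagreement_fraction",
    "validity_check",
    "agreement_report",
    "sensitivity_analysis",
    "compare_models",
]


def percent_area_difference(modeled: pd.Series, observed: pd.Series) -> pd.Series:
    """Signed per-class difference: 100 * (modeled - observed) / observed.

    Directional by construction (it is not symmetric in its arguments);
    negative means the model underestimates the observed extent. Classes
    with zero observed area and nonzero modeled area are undefined (NaN);
    0/0 reports 0.
    """
    modeled, observed = modeled.astype(float), observed.astype(float)
    out = pd.Series(np.nan, index=observed.index, dtype=float)
    ok = observed > 0
    out[ok] = 100.0 * (modeled[ok] - observed[ok]) / observed[ok]
    both_zero = (observed == 0) & (modeled == 0)
    out[both_zero] = 0.0
    return out


def overlap_matrix(modeled: VegetationGrid, observed: VegetationGrid) -> pd.DataFrame:
    """O[i][j] = fraction of modeled-class-i cells observed as class j.

    Rows of empty modeled classes are NaN; non-empty rows sum to 1. Only
    cells unmasked in both grids are counted.
    """
    if modeled.shape != observed.shape:
        raise ValueError(
            f"grids not co-registered: {modeled.shape} vs {observed.shape}"
        )
    valid = ~(modeled.nodata_mask | observed.nodata_mask)
    n = len(CLASS_ORDER)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (modeled.codes[valid], observed.codes[valid]), 1)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(frac, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))


def disagreement_fraction(a: VegetationGrid, b: VegetationGrid) -> float:
    """Fraction of jointly unmasked cells whose classes differ."""
    if a.shape != b.shape:
        raise ValueError("grids not co-registered")
    valid = ~(a.nodata_mask | b.nodata_mask)
    if not valid.any():
        return 0.0
    return float(np.mean(a.codes[valid] != b.codes[valid]))


def validity_check(pct_diff: pd.Series, threshold: float = 10.0):
    """The strict 10% rule: a class is valid iff |diff| < threshold;
    undefined (NaN) differences are not valid. Returns (per-class Series,
    overall flag); overall requires every reported class to be valid."""
    per_class = pct_diff.abs() < threshold
    per_class[pct_diff.isna()] = False
    return per_class, bool(per_class.all())


@dataclass
class AgreementReport:
    """Modeled-vs-observed agreement: per-class areas and signed percent
    differences, the overlap matrix, and validity flags."""

    table: pd.DataFrame  # columns modeled_ha, observed_ha, pct_diff, valid
    overlap: pd.DataFrame
    valid: bool
    threshold: float = 10.0


def agreement_report(modeled: VegetationGrid, observed: VegetationGrid,
                     threshold: float = 10.0,
                     classes: list | None = None) -> AgreementReport:
    """Full agreement statistics between a modeled and an observed map.

    ``classes`` restricts the validity verdict (e.g. to wetland classes);
    all classes are always tabulated.
    """
    ma, oa = area_by_class(modeled), area_by_class(observed)
    diff = percent_area_difference(ma, oa)
    flags, _ = validity_check(diff, threshold)
    table = pd.DataFrame({
        "modeled_ha": ma, "observed_ha": oa, "pct_diff": diff, "valid": flags,
    })
    verdict_rows = table.loc[classes] if classes is not None else table
    considered = verdict_rows[verdict_rows["observed_ha"] > 0]
    overall = bool(considered["valid"].all()) if len(considered) else True
    return AgreementReport(table=table, overlap=overlap_matrix(modeled, observed),
                           valid=overall, threshold=threshold)


@dataclass
class SensitivityTable:
    """OAT sensitivity: percent change in final-year class area per
    parameter, for both perturbation directions."""

    plus: pd.DataFrame  # rows classes, columns parameters (+delta runs)
    minus: pd.DataFrame
    perturbation: float
    headline_direction: str = "+"

    @property
    def headline(self) -> pd.DataFrame:
        return self.plus if self.headline_direction == "+" else self.minus

    def summary_table(self) -> pd.DataFrame:
        """Headline table with min/max/mean/sd summary rows appended."""
        t = self.headline.copy()
        stats = pd.DataFrame({
            "Minimum": t.min(), "Maximum": t.max(),
            "Mean": t.mean(), "Standard deviation": t.std(ddof=1),
        }).T
        return pd.concat([t, stats])


def sensitivity_analysis(base_spec, parameters: list[str],
                         perturbation: float = 0.10,
                         end_year: float | None = None) -> SensitivityTable:
    """One-at-a-time sensitivity over a run specification.

    ``base_spec`` must expose ``perturbed(name, factor)`` returning a new
    spec with one parameter scaled, and ``final_areas(end_year)`` returning
    the final-year per-class areas. Each parameter is scaled by
    (1 +/- perturbation); entries are 100 * (perturbed - base) / base, NaN
    where the base class area is zero (undefined, reported as null).
    """
    base = base_spec.final_areas(end_year)
    cols_p, cols_m = {}, {}
    for name in parameters:
        for sign, store in ((1.0, cols_p), (-1.0, cols_m)):
            spec = base_spec.perturbed(name, 1.0 + sign * perturbation)
            final = spec.final_areas(end_year)
            with np.errstate(invalid="ignore", divide="ignore"):
                change = 100.0 * (final - base) / base
            change[base == 0] = np.nan
            store[name] = change
    plus = pd.DataFrame(cols_p, index=base.index)
    minus = pd.DataFrame(cols_m, index=base.index)
    return SensitivityTable(plus=plus, minus=minus, perturbation=perturbation)


def compare_models(runs: dict) -> dict:
    """Cross-engine comparison of finished runs.

    ``runs`` maps engine name -> RunResult (same grid, scenario and bands).
    Returns per-year cross-engine area deltas and, where per-step rasters
    were recorded, pairwise final-map disagreement fractions.
    """
    engines = list(runs)
    if not engines:
        raise ConfigurationError("no runs to compare")
    areas = pd.concat({e: runs[e].areas for e in engines}, names=["engine", "year"])
    deltas = {}
    for i, a in enumerate(engines):
        for b in engines[i + 1:]:
            deltas[f"{a}-{b}"] = runs[a].areas - runs[b].areas
    disagreement = {}
    for i, a in enumerate(engines):
        for b in engines[i + 1:]:
            ra, rb = runs[a].rasters, runs[b].rasters
            if ra and rb:
                disagreement[f"{a}-{b}"] = disagreement_fraction(ra[-1][1], rb[-1][1])
    return {"areas": areas, "deltas": deltas, "final_disagreement": disagreement}
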