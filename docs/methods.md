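# Methods

## World and datums

All stages share one raster world: a substrate-elevation grid (m above a
fixed height datum), a categorical vegetation grid over the ordered class
set `open_water < mudflat < mangrove < mixed < saltmarsh < casuarina <
upland` (codes are ranks, so succession direction is an integer
comparison), and a subsite-ID grid partitioning the estuary into reaches.
Grids are projection-agnostic (local metric frame, row 0 northernmost);
nodata is propagated and never imputed. Rasters are exchanged as ESRI
ASCII grids written at 17 significant digits so IEEE doubles round-trip
bit-identically; tables are UTF-8 CSV.

Each subsite carries a local mean-sea-level offset, a great diurnal range
GT, and a salt-boundary elevation stored in metres **above local MSL** so
it rides on the local datum. A global `datum_correction` (the
height-to-tidal-datum shift, default 0.08 m) is added wherever a water
level is needed; back-stepping for retrospection subtracts
`trend × years / 1000` from every `msl_offset`, which is exactly
equivalent to raising the land relative to the sea.

## Tide model and zonation bands

The only tide model is a single-constituent sinusoid of amplitude GT/2:
the elevation submerged a fraction `f` of the time is
`z = (GT/2)·cos(πf)`, implemented as `(GT/2)·sin(π(0.5 − f))` so `f = 0.5`
maps to exactly 0.0 in floating point. The conversion is isolated in two
inverse functions so a harmonic-sum tide could replace it.

Default frequency bands: mudflat 100–50 %, mangrove 50–25 %, mixed
25–12.5 %, saltmarsh 12.5–0 % of the time inundated; casuarina occupies
[GT/2, salt boundary) and upland everything above. Band intervals are
half-open and lower-inclusive, which makes classification deterministic at
boundaries (local MSL itself classifies as mangrove). Explicit elevation
bands (m relative to local MSL) are accepted as an alternative and must
tile without gaps; band validation rejects any gap, overlap or zero width.

The vegetation preprocessor inverts classification: within each contiguous
same-class region, elevation runs linearly from the class's lower bound at
the edge adjacent to the seaward (lower-ranked) neighbour to the upper
bound at the landward edge, using Euclidean distance transforms to the
nearest lower- and higher-ranked cells; regions with no defined gradient
(single cells, uniform maps, no seaward or landward neighbour) sit at the
band midpoint. Open water and upland, unbounded in reality, get nominal
GT/2-deep bands for this purpose only. The classify ∘ reconstruct round
trip is exact on interior cells; landward-edge cells touch the upper bound,
which belongs to the next band.

## SEC engines and time stepping

All engines produce net surface-elevation change in mm/yr (SEC subsumes
accretion minus autocompaction/shallow subsidence, matching what SET-MH
benchmarks measure; no separate subsidence term exists). The shared update
is explicit Euler at decadal steps — the comparison granularity — with the
step length configurable for convergence checks; the single-cell
exponential-engine trajectory at dt = 0.1 yr sits within 1 % of the
dt = 0.001 yr reference over 100 yr, and the decadal step's documented
discretisation gap is checked in the tests against the closed-form ODE
solution.

* **slamm**: per-class rates; optional proportional mode interpolates
  between configured rates at the band's lower and upper edge. Intertidal
  classes must be configured (a missing class is a configuration error);
  open water and upland default to 0 but are overridable.
* **cm1**: `k·exp(−l·max(0, z − z_low))·exp(−m·d_channel)`, `z_low` the
  local lower intertidal limit (MSL − GT/2); zero above the salt boundary.
  Re-evaluated each step against the current (risen) sea level — the
  minimal dynamic closure of a static empirical sedimentation surface.
  Coefficients are magnitudes with fixed signs (accretion decreases with
  elevation and channel distance) to prevent silent sign errors. Defaults
  `k = 5 mm/yr, l = 1.5 /m, m = 0.002 /m` are synthetic, chosen to put SEC
  in the low-mm/yr range of regional SET records; the published fits'
  coefficients are not deposited.
* **cm2**: `intercept + Σ coefficient × covariate` over days since start,
  previous-month rainfall, 6-month water level, distance to shore, 3-month
  SOI and mean sea level. Whether "distance to shore" means channel bank
  or estuary mouth is ambiguous in the source material; both static
  distance fields are computed at t₀ (Euclidean, cell-centre, frozen) and a
  config switch selects one (default: mouth distance). Covariates are
  piecewise-constant per step (value at the step's start year), so the
  stepped single-cell trajectory equals the left Riemann sum exactly —
  linear in t, quadratic when the time coefficient is nonzero. Default
  coefficients are likewise synthetic and documented as such.

Step order is sea level → elevation → vegetation, with rates computed from
the pre-step classification: this mirrors the accrete-then-reclassify
cycle of the model family and makes steps reproducible. Sea level is
applied as *base frame + absolute anomaly at the current year* rather than
accumulated per-step increments, so a back-step followed by a forward run
at the same trend restores the datum bit-exactly and reproduces the
initial classification identically.

The slamm engine pairs with the retrogression-only succession policy
(elementwise `min(previous, proposed)`, open water absorbing — which is
precisely why it cannot prograde a shoreline or re-vegetate water); cm1
and cm2 reclassify freely each step. There is no cell-neighbourhood
coupling: erosion, overwash, saturation, salinity and stochastic storm
forcing are out of scope.

## Evaluation procedures

Percent-area difference is signed and directional
(`100·(modelled − observed)/observed`); a class is valid strictly below
the 10 % threshold and a run is valid when all assessed (wetland) classes
are. Zero-observed/nonzero-modelled ratios are reported as nulls, never
infinities, so CSV outputs stay parseable. The overlap matrix normalises
by the modelled class (rows of non-empty classes sum to 1); its diagonal
is the class's correspondence. OAT sensitivity scales one parameter at a
time by 1 ± 0.1, reruns to the end year, and reports the percent change in
final-year class areas; the +10 % direction is the headline (the source
material does not state a direction convention — fixed here and recorded
in output metadata) with the −10 % runs retained. The historic-trend
parameter has no pathway into a scenario-forced forward run; its
structurally zero column is kept as a regression guard against
configuration leakage.

## Synthetic estuary

`make_estuary` builds, deterministically per seed: a sinusoidal meandering
channel (amplitude 150 m, wavelength 1 km) incised 1.5 m below datum in a
120 × 200-cell, 10 m grid; banks ramp to the mouth lower intertidal limit
over 50 m; a 0.004 m/m cross-shore floodplain ramp rises past the salt
boundary into upland; Gaussian microtopography (σ = 0.02 m) roughens the
surface. Eight subsites are along-channel distance bins with
`GT(s) = 1.3 m × (1 − 0.2)^km(s)` — mouth GT and attenuation rate of the
order seen in wave-dominated southeast-Australian barrier estuaries. The
salt boundary is a single absolute elevation (0.975 m = 0.75 × mouth GT)
for all subsites: the terrestrial limit tracks regional salt influence
rather than local range, and this is what lets an attenuated run preserve
more casuarina/saltmarsh than the single-tidal-range control, the
directional contrast the framework must reproduce. The historic trend is
2.1 mm/yr (the regional tide-gauge value); scenario curves are pure
acceleration (quadratic, zero at the start year) hitting a configured
total — 0.9 m by 2100 for the high scenario, 0.4 m for the low — tabulated
annually; historic runs use the linear trend. Perturbed vegetation maps
(default 10 % of intertidal cells swapped to an adjacent class, reflecting
at the ends of the intertidal sequence) stand in for photo-interpreted
mapping with known ground truth.

What the generator does **not** emulate: hydrodynamic tide propagation or
amplification, catchment hydrology, realistic floodplain morphology
(levees, back-swamps), mapping bias that is spatially autocorrelated
rather than i.i.d., and any correlation between microtopography and
vegetation. Passing tests therefore demonstrate the *mechanics and
directional behaviour* of the engines and procedures, not predictive skill
on a real estuary; site hectare outcomes depend entirely on undeposited
field data.

## Numerical choices and degenerate inputs

Classification uses `searchsorted` on the six band thresholds (right
side ⇒ lower-inclusive). Areas are `count × cell² / 10⁴` ha from integer
bincounts, so per-step totals conserve the unmasked cell count exactly.
Scenario lookups return tabulated values bit-for-bit at exact year hits
and interpolate linearly otherwise; stepping beyond the scenario span is a
range error, as is backstepping by negative years or an inundation
fraction outside (0, 1]. Empty modelled classes give null overlap rows;
zero-width bands, non-contiguous subsite ids, missing subsite table rows,
missing covariate years and malformed grid headers all fail loudly with
the offending key named.

## Problem sizes

The default test and analysis grids are 120 × 200 (24 000 cells, eleven
decadal steps, ~0.1 s per run) with 60 × 100 used inside the test matrix;
these sizes were chosen so the whole analysis reruns from scratch in
seconds while still containing every class, eight subsites and a full
meander wavelength. A 600 × 1000 "demo" recipe exists for figures.

## Known limitations

The succession sequence is strictly the rank order of the class set;
saltmarsh retreat beneath an intact casuarina canopy (observed regionally)
is not representable — deliberately, since demonstrating that inability in
the retrogression-only engine is part of the framework's purpose. CM1/CM2
coefficients are synthetic stand-ins; conclusions about *relative* engine
behaviour (progradation capacity, levee formation, linear-vs-exponential
divergence) are robust to this, absolute hectares are not. The bathtub
back-step used for retrospection is itself a model, different from the
forward model, so hindcast disagreement compounds with horizon length —
the decadal rehearsal scores better than the half-century one by
construction of the procedure, not by accident.
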