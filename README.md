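# tidemarsh

Spatially explicit simulation of coastal-wetland response to sea-level
rise in tidally attenuated barrier estuaries, with the validation,
sensitivity and model-comparison machinery needed to judge whether such a
simulation should be trusted.

## The problem

Intertidal vegetation — mudflat, mangrove, mixed ecotone, saltmarsh, and
the casuarina fringe up to the salt boundary — occupies narrow elevation
bands set by tidal inundation frequency. Rising sea level shifts those
bands landward; sediment accretion (net *surface elevation change*, SEC,
as measured by surface-elevation tables) lets the substrate keep pace, or
not. Readily available landscape models in the SLAMM family are widely
applied to such questions with minimal validation, especially outside the
North American marshes they were conceived for. This package implements a
validation-and-comparison framework for that model family: three
interchangeable SEC engines on a shared raster world, per-subsite tidal
attenuation, retrospective (hindcast) validation with a strict percent-area
rule, one-at-a-time sensitivity analysis, and cross-engine comparison — all
exercisable end-to-end on a deterministic synthetic barrier estuary.

## The model

A cell with substrate elevation `z` in subsite `s` is classified by its
elevation relative to local mean sea level against bands derived from
inundation frequency under a sinusoidal tide of amplitude `GT(s)/2`
(`GT` = great diurnal range), with `z_f = (GT/2)·cos(πf)` the elevation
submerged a fraction `f` of the time. Attenuation makes `GT` shrink
upstream, so all bands narrow with distance along the channel. Each decadal
step applies, in order:

1. **sea level** — local MSL = base datum + scenario anomaly at the new year;
2. **elevation** — `z' = z + SEC·Δt/1000` (explicit Euler), where SEC (mm/yr) is
   - `slamm`: a per-class rate (optionally scaled across the class band),
   - `cm1`: `k·exp(−l·max(0, z − z_low))·exp(−m·d_channel)` — exponential
     decay with height above the lower intertidal limit and with distance
     from the sediment source,
   - `cm2`: a site-calibrated linear function of time, rainfall, water
     level, shore distance, SOI and mean sea level;
3. **vegetation** — reclassify from elevation, then resolve against the
   previous class: the `slamm` succession policy permits only retrogression
   (landward class replacing seaward is blocked; open water is absorbing,
   so shorelines can never prograde), while `cm1`/`cm2` reclassify freely.

Validation compares modelled and observed class maps with the signed
percent-area difference `100·(modelled − observed)/observed` (strictly
valid below 10%) and the overlap matrix `O[modelled][observed]`, whose
diagonal is each class's correspondence. Retrospection back-steps the
tidal datum by `trend·T` (a bathtub adjustment of a modern DEM) and runs
forward to the mapped year.

## Worked example

```
python analysis/01_build_estuary.py     # write the synthetic input bundle
python analysis/02_tidal_attenuation.py
```

prints, for a 0.9 m rise by 2100 on the default synthetic estuary:

```
Final mangrove area:         33.11 ha (attenuated) vs   40.14 ha (single range)
Final casuarina+saltmarsh:   17.36 ha (attenuated) vs   12.45 ha (single range)
```

i.e. applying a single open-coast tidal range to the whole estuary
overstates mangrove proliferation upstream by ~7 ha and understates the
surviving high-intertidal classes by ~5 ha — the attenuation effect the
framework exists to expose. The remaining scripts rehearse retrospective
validation over 11- and 48-year horizons (`03`), compare the three engines
to 2100 (`04` — the exponential engine keeps ~6 ha more mangrove than the
SLAMM-style engine by building a channel-bank levee), and produce the
±10% OAT sensitivity table (`05` — sea-level rise, tidal range and the
salt-boundary elevation dominate). Each writes CSV tables under
`results/`. A thin CLI (`tidemarsh synth|simulate|backstep|validate|
sensitivity|compare`) exposes the same stages on user-supplied ESRI ASCII
grids and CSV tables.

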