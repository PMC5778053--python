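#!/usr/bin/env python
"""Tidal-attenuation contrast.

Runs the same sea-level scenario twice with the SLAMM-style engine: once
with per-subsite attenuated tidal ranges, once with the single mouth tidal
range applied estuary-wide (the naive control). Reports how the final
vegetation distribution differs — mangrove proliferates less, and more
casuarina and saltmarsh survive, when attenuation is accounted for.
"""

from pathlib import Path

import pandas as pd

from tidemarsh.synthetic import EstuaryRecipe
from tidemarsh.workflows import RunSpec, attenuation_contrast

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

spec = RunSpec(recipe=EstuaryRecipe(seed=0))
contrast = attenuation_contrast(spec)

areas = pd.concat({
    "attenuated": contrast["attenuated"].areas,
    "single_range": contrast["global"].areas,
}, names=["tidal_treatment", "year"])
areas.round(3).to_csv(OUT / "attenuation_areas.csv")

m_att, m_glo = contrast["final_mangrove_ha"]
cs_att, cs_glo = contrast["final_casuarina_saltmarsh_ha"]
print(f"Scenario: {spec.slr_by_2100} m rise by 2100, engine {spec.engine}")
print(f"\nFinal mangrove area:       {m_att:7.2f} ha (attenuated) "
      f"vs {m_glo:7.2f} ha (single range)")
print(f"Final casuarina+saltmarsh: {cs_att:7.2f} ha (attenuated) "
      f"vs {cs_glo:7.2f} ha (single range)")
print("\nAccounting for attenuation restrains modelled mangrove expansion "
      "upstream and\npreserves more of the high-intertidal classes.")
print(f"\nPer-step areas written to {OUT / 'attenuation_areas.csv'}")
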