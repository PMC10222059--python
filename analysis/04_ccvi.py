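#!/usr/bin/env python
"""Compute the Climate Change Vulnerability Index per plant and population.

Overlays the binary present distribution on each future suitability map,
standardizes against the minimum-suitable-habitat threshold, extracts
per-plant values, and averages per scenario set (all 2055 scenarios and
each emissions pathway).  Writes results/ccvi_plants.csv and
results/ccvi_populations.csv.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from popvuln import ccvi as vi
from popvuln import sdm
from popvuln.cli import _model_from_json
from popvuln.io import read_census
from popvuln.rasters import read_ascii_grid

ROOT = Path(__file__).resolve().parents[1] / "results"
model = _model_from_json(json.loads((ROOT / "sdm" / "model.json").read_text()))
binary = read_ascii_grid(ROOT / "sdm" / "binary_present.asc")
census = read_census(ROOT / "simulation" / "census.csv")
pts = census[["x", "y"]].to_numpy()

per_scenario = {}
for p in sorted((ROOT / "sdm").glob("suitability_gcm*.asc")):
    label = p.stem.replace("suitability_", "")
    surface = vi.vulnerability_surface(
        binary, sdm.SuitabilityMap(read_ascii_grid(p), label),
        center_mode="threshold", threshold=model.threshold,
    )
    per_scenario[label] = vi.extract_plant_ccvi(surface, pts)

plants = pd.DataFrame(per_scenario)
plants.insert(0, "plant_id", census["plant_id"])
plants.insert(1, "population", census["population"])
scenario_cols = list(per_scenario)
plants["ccvi_2055"] = plants[scenario_cols].mean(axis=1)
for ssp in ("SSP1-RCP2.6", "SSP5-RCP8.5"):
    plants[f"ccvi_{ssp}"] = plants[[c for c in scenario_cols if ssp in c]].mean(axis=1)
plants.to_csv(ROOT / "ccvi_plants.csv", index=False)

groups = {
    "Mean CCVI": vi.population_ccvi(plants["ccvi_2055"].to_numpy(), plants["population"]),
    "Mean CCVI SSP1-RCP2.6": vi.population_ccvi(plants["ccvi_SSP1-RCP2.6"].to_numpy(), plants["population"]),
    "Mean CCVI SSP5-RCP8.5": vi.population_ccvi(plants["ccvi_SSP5-RCP8.5"].to_numpy(), plants["population"]),
}
table = vi.population_ccvi_table(groups)
table.to_csv(ROOT / "ccvi_populations.csv")
print(table.to_string())
print(f"per-plant CCVI for {len(plants)} plants -> {ROOT / 'ccvi_plants.csv'}")
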