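#!/usr/bin/env python
"""Summarize each population's census into its demographic parameters.

Counts by life stage (30 cm threshold) and reproductive status, stem-length
mean/sd/skewness, occupied area, inter-plant distances, and densities.
Writes results/demography.csv.
"""
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from popvuln.demography import summarize_censuses
from popvuln.io import read_census

ROOT = Path(__file__).resolve().parents[1] / "results"
census = read_census(ROOT / "simulation" / "census.csv")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = summarize_censuses(census)
table.to_csv(ROOT / "demography.csv", index=False)
cols = ["population", "n_plants", "mean_stem_cm", "n_fruiting", "n_young",
        "n_adult", "skewness", "area_ha", "density_per_ha"]
print(table[cols].round(2).to_string(index=False))
print(f"total plants {table['n_plants'].sum()}; "
      f"species-wide mean density {table['density_per_ha'].mean():.0f}/ha")
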