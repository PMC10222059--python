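#!/usr/bin/env python
"""Fit the demography-vulnerability association models.

Population level: linear models of mean stem length and binomial models of
the young-plant proportion on mean CCVI (all-scenario and SSP5-RCP8.5
averages, plus the present-scenario null check).  Plant level: MM-robust
regression of fruiting-plant stem length on CCVI.  Writes
results/associations.json.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from popvuln import association as assoc
from popvuln.io import read_census

ROOT = Path(__file__).resolve().parents[1] / "results"
census = read_census(ROOT / "simulation" / "census.csv")
plants = pd.read_csv(ROOT / "ccvi_plants.csv")
demo = pd.read_csv(ROOT / "demography.csv")

pop = plants.groupby("population")[["ccvi_2055", "ccvi_SSP5-RCP8.5"]].mean()
table = demo.merge(pop, left_on="population", right_index=True)

fits = {}
for tag, col in (("2055", "ccvi_2055"), ("ssp585", "ccvi_SSP5-RCP8.5")):
    fits[f"mean_stem~ccvi_{tag}"] = assoc.linear_fit(table[col], table["mean_stem_cm"])
    fits[f"young_prop~ccvi_{tag}"] = assoc.binomial_fit(
        table["n_young"], table["n_plants"], table[col]
    )
fruiting = census["status"] == "fruiting"
merged = plants.loc[fruiting.to_numpy()]
stems = census.loc[fruiting, "stem_length_cm"].to_numpy()
for tag, col in (("2055", "ccvi_2055"), ("ssp585", "ccvi_SSP5-RCP8.5")):
    fits[f"fruiting_stem~ccvi_{tag}"] = assoc.robust_linear_fit(
        merged[col].to_numpy(), stems
    )

print(f"{'model':28s} {'slope':>9s} {'stat':>8s} {'p':>9s} {'fit':>6s}")
for name, f in fits.items():
    print(f"{name:28s} {f.slope:9.2f} {f.statistic_name}={f.statistic:6.2f} "
          f"{f.p_value:9.3g} {f.fit_measure:6.3f}")
(ROOT / "associations.json").write_text(
    json.dumps({k: vars(v) for k, v in fits.items()}, indent=2, default=float)
)
a, b = fits["fruiting_stem~ccvi_2055"], fits["fruiting_stem~ccvi_ssp585"]
cmp = assoc.slope_ci_compare(a, b)
print(f"fruiting-stem slope CIs {'disjoint' if cmp.disjoint else 'overlap'} ({cmp.order})")
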