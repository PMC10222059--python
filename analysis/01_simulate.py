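#!/usr/bin/env python
"""Generate the synthetic study system: landscape, futures, and census.

Writes the present climate stack, the ten future scenario stacks, the
1615-plant census over 13 populations, the occurrence points, and the
generative ground truth under results/simulation/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from popvuln.io import write_census
from popvuln.rasters import write_stack
from popvuln.synth import generate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"
SEED = 1

data = generate_dataset(seed=SEED)
write_stack(data.scenarios.present, OUT / "present")
for gcm, ssp, stack in data.scenarios.futures:
    write_stack(stack, OUT / "futures" / f"{gcm}_{ssp}")
write_census(data.census, OUT / "census.csv")
pd.DataFrame(data.occurrences, columns=["x", "y"]).to_csv(OUT / "occurrences.csv", index=False)
data.truth.to_json(OUT / "truth.json")

n_pop = data.census["population"].nunique()
print(f"simulated {len(data.census)} plants in {n_pop} populations (seed {SEED})")
print(f"planted vulnerability v_k spans {min(data.truth.v_k):.3f}..{max(data.truth.v_k):.3f}")
print(f"products under {OUT}")
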