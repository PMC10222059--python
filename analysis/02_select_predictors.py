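#!/usr/bin/env python
"""Filter the present climate stack to a low-collinearity predictor set.

Applies the |Pearson r| <= 0.7 then VIF < 10 filter and writes the
selection report to results/selection.json.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from popvuln.rasters import read_stack
from popvuln.select import correlation_matrix, select_predictors

ROOT = Path(__file__).resolve().parents[1] / "results"

stack = read_stack(ROOT / "simulation" / "present")
r = correlation_matrix(stack)
print("pairwise Pearson r:")
print(r.round(3).to_string())
report = select_predictors(stack)
(ROOT / "selection.json").write_text(json.dumps(report.to_dict(), indent=2))
print(f"kept {len(report.kept)}/{stack.n_layers}: {', '.join(report.kept)}")
for name, reason, value in report.dropped:
    print(f"dropped {name} ({reason} = {value:.3f})")
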