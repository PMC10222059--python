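"""Deterministic reproduction checks against the published census table.

From the packaged per-population table alone this recomputes, in under a
second, every quantity of the published analysis that does not require
the withheld plant coordinates: the species-level census arithmetic
(totals, density and distance averages, occupied area) and the
population-level association models (linear mean-stem-length models and
count-weighted binomial young-proportion models against the mean CCVI of
each scenario set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .association import binomial_fit, linear_fit
from .table1 import load_table1


@dataclass
class Check:
    name: str
    value: float
    expected: float
    tol: float
    passed: bool


def _check(name: str, value: float, expected: float, tol: float) -> Check:
    return Check(name, float(value), expected, tol, bool(abs(value - expected) <= tol))


def _bound(name: str, value: float, bound: float) -> Check:
    return Check(name, float(value), bound, 0.0, bool(value <= bound))


def reproduce_paper(table: pd.DataFrame | None = None) -> list[Check]:
    """Recompute the published reproducible quantities; return pass/fail checks."""
    df = table if table is not None else load_table1()
    checks = [
        _check("total_plants", df["n_plants"].sum(), 1615, 0),
        _check("mean_plant_density_per_ha", df["density_per_ha"].mean(), 792, 0.5),
        _check("mean_young_density_per_ha", df["young_density_per_ha"].mean(), 234, 0.5),
        _check("mean_interplant_distance_m", df["mean_distance_m"].mean(), 40, 0.5),
        _check("max_plant_density_per_ha", df["density_per_ha"].max(), 2383, 1.0),
        _bound("total_area_ha", df["area_ha"].sum(), 5.0),
    ]
    lin = linear_fit(df["ccvi_mean"], df["mean_stem_cm"])
    lin585 = linear_fit(df["ccvi_ssp585"], df["mean_stem_cm"])
    checks += [
        _check("stem_ccvi2055_linear_F", lin.statistic, 5.42, 0.02 * 5.42),
        _check("stem_ccvi2055_linear_R2", lin.fit_measure, 0.330, 0.01),
        _check("stem_ccvi585_linear_F", lin585.statistic, 5.79, 0.02 * 5.79),
        _check("stem_ccvi585_linear_R2", lin585.fit_measure, 0.345, 0.01),
    ]
    bino = binomial_fit(df["n_young"], df["n_plants"], df["ccvi_mean"])
    bino585 = binomial_fit(df["n_young"], df["n_plants"], df["ccvi_ssp585"])
    checks += [
        _check("young_ccvi2055_binomial_Z", bino.statistic, 9.15, 0.03 * 9.15),
        _check("young_ccvi2055_binomial_pseudoR2", bino.fit_measure, 0.670, 0.02),
        _check("young_ccvi585_binomial_Z", bino585.statistic, 9.68, 0.03 * 9.68),
        _check("young_ccvi585_binomial_pseudoR2", bino585.fit_measure, 0.723, 0.02),
    ]
    return checks


def report_json(checks: list[Check], path: str | Path | None = None) -> str:
    text = json.dumps([asdict(c) for c in checks], indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
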