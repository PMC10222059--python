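"""Census/occurrence CSV formats and pipeline configuration.

The census interchange format is a CSV with header
``plant_id,population,x,y,stem_length_cm,status`` where status is one of
non_reproductive, flowering, fruiting.  Rasters travel as ESRI ASCII
grids (see :mod:`popvuln.rasters`), which keeps the whole toolchain free
of compiled geospatial dependencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

CENSUS_COLUMNS = ["plant_id", "population", "x", "y", "stem_length_cm", "status"]
VALID_STATUS = {"non_reproductive", "flowering", "fruiting"}


def read_census(path: str | Path) -> pd.DataFrame:
    """Read and validate a census CSV.

    Errors name the offending CSV row (1-based, counting the header as
    row 1) for non-positive stem lengths, bad status labels, and duplicate
    plant ids.
    """
    df = pd.read_csv(path)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census file {path} is missing column(s): {missing}")
    bad_len = df.index[~(df["stem_length_cm"] > 0) | ~np.isfinite(df["stem_length_cm"])]
    if len(bad_len):
        row = int(bad_len[0]) + 2
        raise ValueError(f"row {row}: stem_length_cm must be positive and finite")
    bad_status = df.index[~df["status"].isin(VALID_STATUS)]
    if len(bad_status):
        row = int(bad_status[0]) + 2
        raise ValueError(f"row {row}: status must be one of {sorted(VALID_STATUS)}")
    dup = df["plant_id"].duplicated()
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"row {row}: duplicate plant_id {df.loc[dup, 'plant_id'].iloc[0]!r}")
    for c in ("x", "y"):
        if not np.isfinite(df[c]).all():
            raise ValueError(f"column {c} contains non-finite coordinates")
    return df[CENSUS_COLUMNS]


def write_census(census: pd.DataFrame, path: str | Path) -> None:
    census[CENSUS_COLUMNS].to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis; defaults are the study protocol."""

    # synthetic landscape
    n_rows: int = 32
    n_cols: int = 32
    layer_names: tuple[str, ...] = ("bio03", "bio07", "bio15", "bio19")
    autocorr_range: float = 4.0
    gradient_layer: str = "bio03"
    gradient_amplitude: float = 2.0
    n_populations: int = 13
    plants_per_population: tuple[int, ...] = (11, 209, 109, 4, 77, 298, 22, 283, 181, 89, 251, 33, 48)
    # predictor selection
    r_max: float = 0.7
    vif_max: float = 10.0
    # ensemble protocol
    algorithms: tuple[str, ...] = ("glm",)
    n_pa_scenarios: int = 5
    n_repetitions: int = 15
    split_ratio: float = 0.7
    tss_min: float = 0.8
    n_pa: int | None = None
    # vulnerability index
    center_mode: str = "threshold"   # threshold | mean
    scenario_subset: str = "all"     # all | SSP1-RCP2.6 | SSP5-RCP8.5
    # demography
    alpha: float | None = None
    skewness_kind: str = "g1"
    distance_mode: str = "pairwise"
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for key in ("layer_names", "plants_per_population", "algorithms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
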