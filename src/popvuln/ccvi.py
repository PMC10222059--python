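"""Climate Change Vulnerability Index (CCVI).

The CCVI measures, per grid cell of the *present* distribution, how far a
future scenario's habitat suitability falls below the minimum suitability
the population needs to survive.  The construction:

1. overlay the present binary distribution on the future suitability map
   and take the future suitability values over the present footprint;
2. scale those values: subtract a center ``c`` (by default the ensemble's
   minimum-suitable-habitat threshold) and divide by the sample standard
   deviation ``sigma`` of the footprint values;
3. negate, so CCVI = -(s - c) / sigma:  CCVI <= 0 means the cell stays at
   or above the survival minimum (not vulnerable); positive CCVI means
   increasingly unsuitable future conditions;
4. extract the cell value for every censused plant (no interpolation);
5. average per population and per scenario (or across scenario subsets).

Because the index is standardized it is comparable across species and
suitability scales: any affine rescaling applied consistently to the
suitability values and the center leaves the CCVI unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rasters import Raster
from .sdm import SuitabilityMap


def footprint_overlay(present_binary: Raster, future: SuitabilityMap) -> tuple[np.ndarray, np.ndarray]:
    """Future suitability over the present-distribution footprint.

    Returns ``(values, cells)`` where ``cells`` is the (n, 2) array of
    (row, col) footprint cells in row-major order and ``values`` the future
    suitability at those cells.
    """
    if present_binary.geometry != future.raster.geometry:
        raise ValueError("present and future rasters must share geometry")
    fp = present_binary.values == 1
    if not fp.any():
        raise ValueError("empty footprint: present binary map has no occupied cells")
    rows, cols = np.nonzero(fp)  # np.nonzero is row-major
    cells = np.column_stack([rows, cols])
    return future.values[rows, cols], cells


@dataclass
class VulnerabilitySurface:
    """Per-cell CCVI over the present footprint for one scenario."""

    raster: Raster            # CCVI values; NaN outside the footprint
    scenario: str
    center: float
    sigma: float
    footprint_cells: int

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def ccvi_surface(
    values: np.ndarray,
    cells: np.ndarray,
    geometry,
    center: float,
    scenario: str = "",
) -> VulnerabilitySurface:
    """Build the CCVI surface: CCVI = -(s - center) / sigma.

    ``sigma`` is the sample standard deviation (n - 1 denominator) of the
    footprint suitability values.  Requires at least two footprint cells
    and non-zero variance.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two footprint cells")
    sigma = float(np.std(values, ddof=1))
    if sigma == 0:
        raise ValueError("footprint suitability has zero variance; CCVI undefined")
    ccvi = -(values - center) / sigma
    grid = np.full((geometry.n_rows, geometry.n_cols), np.nan)
    grid[cells[:, 0], cells[:, 1]] = ccvi
    return VulnerabilitySurface(
        raster=Raster(grid, geometry),
        scenario=scenario,
        center=float(center),
        sigma=sigma,
        footprint_cells=len(values),
    )


def vulnerability_surface(
    present_binary: Raster,
    future: SuitabilityMap,
    center: float | None = None,
    center_mode: str = "threshold",
    threshold: float | None = None,
) -> VulnerabilitySurface:
    """Overlay + scale in one step.

    ``center_mode='threshold'`` centers at ``threshold`` (the ensemble's
    minimum-suitable-habitat value, the survival minimum); ``'mean'``
    centers at the footprint mean (the generic scaling default).  An
    explicit ``center`` overrides both.
    """
    values, cells = footprint_overlay(present_binary, future)
    if center is None:
        if center_mode == "threshold":
            if threshold is None:
                raise ValueError("center_mode='threshold' requires a threshold")
            center = threshold
        elif center_mode == "mean":
            center = float(np.mean(values))
        else:
            raise ValueError(f"unknown center_mode {center_mode!r}")
    return ccvi_surface(values, cells, present_binary.geometry, center, future.scenario)


def extract_plant_ccvi(surface: VulnerabilitySurface, points: np.ndarray) -> np.ndarray:
    """CCVI of the cell containing each plant (no interpolation).

    Plants in cells outside the footprint get NaN with a warning; plants
    outside the grid raise.
    """
    vals = surface.raster.sample(np.asarray(points, dtype=float))
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} plant(s) fall outside the present-distribution footprint; "
            "their CCVI is missing"
        )
    return vals


@dataclass
class PopulationCCVI:
    """Per-population summary of plant-level CCVI for one scenario set."""

    population: str
    values: np.ndarray
    scenario: str

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample sd; NaN sentinel for a single plant."""
        return float(np.std(self.values, ddof=1)) if self.n > 1 else float("nan")


def population_ccvi(
    values: np.ndarray, populations: Sequence[str], scenario: str = ""
) -> list[PopulationCCVI]:
    """Group plant-level CCVI by population; mean +/- sample sd each."""
    values = np.asarray(values, dtype=float)
    populations = np.asarray(populations)
    if len(values) != len(populations):
        raise ValueError("values and population labels differ in length")
    out = []
    for pop in pd.unique(populations):
        v = values[populations == pop]
        v = v[np.isfinite(v)]
        if len(v) == 0:
            raise ValueError(f"population {pop!r} has no plants with a CCVI value")
        out.append(PopulationCCVI(population=str(pop), values=v, scenario=scenario))
    return out


def population_ccvi_table(groups: Mapping[str, list[PopulationCCVI]]) -> pd.DataFrame:
    """Census-table-style rendering: one row per population.

    ``groups`` maps a scenario-set label (e.g. ``"Mean CCVI"``,
    ``"Mean CCVI SSP5-RCP8.5"``) to its per-population summaries; columns
    render as ``mean ± sd``.
    """
    cols: dict[str, dict[str, str]] = {}
    for label, summaries in groups.items():
        cols[label] = {
            s.population: f"{s.mean:.3f} ± {s.sd:.3f}" if np.isfinite(s.sd) else f"{s.mean:.3f}"
            for s in summaries
        }
    return pd.DataFrame(cols)


def scenario_average(
    per_scenario: Mapping[str, np.ndarray], subset: Sequence[str] | None = None
) -> np.ndarray:
    """Plain per-plant arithmetic mean of CCVI across a scenario subset.

    Every plant must have a value in every scenario of the subset.
    """
    labels = list(subset) if subset is not None else list(per_scenario)
    missing = [s for s in labels if s not in per_scenario]
    if missing:
        raise KeyError(f"missing scenario value(s): {missing}")
    mat = np.stack([np.asarray(per_scenario[s], dtype=float) for s in labels])
    if np.isnan(mat).any():
        raise ValueError("a plant is missing a CCVI value in a scenario of the subset")
    return mat.mean(axis=0)
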