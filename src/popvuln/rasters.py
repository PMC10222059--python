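"""Planar rasters and multi-layer climate stacks.

All spatial computation in this package happens on regular cell lattices in
projected (planar, metric) coordinates.  Conventions:

* 0-based cell indexing, row 0 at the *southern* edge (y increases with row).
* Cell membership is half-open: a point with coordinates ``(x, y)`` belongs to
  column ``floor((x - x0) / cell_size)`` and row ``floor((y - y0) / cell_size)``.
* Cell-center registration: the center of cell ``(i, j)`` is at
  ``(x0 + (j + 0.5) h, y0 + (i + 0.5) h)``.
* Missing data is ``NaN`` in memory and ``-9999`` in ESRI ASCII grids on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular raster grid (planar meters)."""

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def x_max(self) -> float:
        return self.x0 + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y0 + self.n_rows * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) containing the point, half-open convention.

        Raises ``ValueError`` for points outside ``[x0, x_max) x [y0, y_max)``.
        """
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = int(np.floor((y - self.y0) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def cells_of(self, points: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`cell_of` for an (n, 2) array of (x, y) points."""
        pts = np.asarray(points, dtype=float)
        cols = np.floor((pts[:, 0] - self.x0) / self.cell_size).astype(int)
        rows = np.floor((pts[:, 1] - self.y0) / self.cell_size).astype(int)
        bad = (rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"point {tuple(pts[i])} falls outside the grid")
        return np.column_stack([rows, cols])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.cell_size,
            self.y0 + (row + 0.5) * self.cell_size,
        )

    def to_dict(self) -> dict:
        return {
            "x0": self.x0,
            "y0": self.y0,
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridGeometry":
        return cls(**d)


@dataclass
class Raster:
    """Single-band grid of floats; NaN marks missing cells."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"value array shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where data are present."""
        return np.isfinite(self.values)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Value of the containing cell for each (x, y) point (no interpolation)."""
        cells = self.geometry.cells_of(points)
        return self.values[cells[:, 0], cells[:, 1]]


class ClimateStack:
    """Named set of co-registered predictor layers on one grid.

    Layers are 2-D float arrays sharing a single :class:`GridGeometry`.
    Layer names are unique and no layer may be constant over its valid cells.
    """

    def __init__(
        self,
        layers: Mapping[str, np.ndarray],
        geometry: GridGeometry,
        validate: bool = True,
    ) -> None:
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.geometry = geometry
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (geometry.n_rows, geometry.n_cols):
                raise ValueError(f"layer {name!r} does not match the stack geometry")
            self.layers[name] = arr
        if validate:
            for name, arr in self.layers.items():
                finite = arr[np.isfinite(arr)]
                if finite.size and np.nanstd(finite) == 0:
                    raise ValueError(f"layer {name!r} is constant everywhere")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def raster(self, name: str) -> Raster:
        return Raster(self.layers[name], self.geometry)

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer has data."""
        m = np.ones((self.geometry.n_rows, self.geometry.n_cols), dtype=bool)
        for arr in self.layers.values():
            m &= np.isfinite(arr)
        return m

    def as_matrix(
        self, layer_names: Sequence[str] | None = None, cells: np.ndarray | None = None
    ) -> np.ndarray:
        """Stack layers into a (cells, predictors) matrix.

        ``cells`` is an (n, 2) array of (row, col); default is every cell,
        row-major.
        """
        names = list(layer_names) if layer_names is not None else self.layer_names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack is missing predictor layer(s): {missing}")
        if cells is None:
            return np.column_stack([self.layers[n].ravel() for n in names])
        cells = np.asarray(cells)
        return np.column_stack(
            [self.layers[n][cells[:, 0], cells[:, 1]] for n in names]
        )

    def sample(self, points: np.ndarray, layer_names: Sequence[str] | None = None) -> np.ndarray:
        return self.as_matrix(layer_names, self.geometry.cells_of(points))


@dataclass
class ScenarioSet:
    """A present-day stack plus its future projections.

    Each future is keyed by a general-circulation-model label and an
    SSP-RCP emissions pathway label; by default 5 GCMs x 2 pathways = 10
    futures sharing the present grid and layer names.
    """

    present: ClimateStack
    futures: list[tuple[str, str, ClimateStack]] = field(default_factory=list)

    def __post_init__(self) -> None:
        geo = self.present.geometry
        names = set(self.present.layer_names)
        for gcm, ssp, stack in self.futures:
            if stack.geometry != geo:
                raise ValueError(f"future ({gcm}, {ssp}) geometry differs from present")
            if set(stack.layer_names) != names:
                raise ValueError(f"future ({gcm}, {ssp}) layer names differ from present")
        ssps = {ssp for _, ssp, _ in self.futures}
        if self.futures and len(ssps) != 2:
            raise ValueError(f"expected exactly two emissions pathways, got {sorted(ssps)}")

    @property
    def scenario_labels(self) -> list[str]:
        return [f"{gcm}_{ssp}" for gcm, ssp, _ in self.futures]

    def subset(self, ssp: str) -> list[tuple[str, str, ClimateStack]]:
        return [f for f in self.futures if f[1] == ssp]


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO (dependency-free raster interchange format)
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (NODATA_value -9999).

    ASCII grids store the top (northern) row first, so the in-memory
    south-up array is flipped on write.
    """
    geo = raster.geometry
    vals = np.where(raster.mask, raster.values, NODATA)
    header = (
        f"ncols {geo.n_cols}\n"
        f"nrows {geo.n_rows}\n"
        f"xllcorner {float(geo.x0)!r}\n"
        f"yllcorner {float(geo.y0)!r}\n"
        f"cellsize {float(geo.cell_size)!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    # repr of a Python float is the shortest exactly round-tripping decimal
    body = "\n".join(
        " ".join(repr(float(v)) for v in row) for row in vals[::-1]
    )
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, crs: str = "local-meters") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            hdr[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in hdr:
            raise ValueError(f"ASCII grid {path} is missing header field {key!r}")
    nodata = hdr.get("nodata_value", NODATA)
    data = np.array(
        [[float(v) for v in line.split()] for line in lines[i:] if line.strip()]
    )
    geo = GridGeometry(
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
        cell_size=hdr["cellsize"],
        n_rows=int(hdr["nrows"]),
        n_cols=int(hdr["ncols"]),
        crs=crs,
    )
    if data.shape != (geo.n_rows, geo.n_cols):
        raise ValueError(f"ASCII grid {path} body does not match its header")
    vals = data[::-1].copy()  # back to south-up
    vals[vals == nodata] = np.nan
    return Raster(vals, geo)


def write_stack(stack: ClimateStack, directory: str | Path) -> None:
    """Write every layer as ``<name>.asc`` plus a ``stack.json`` manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in stack.layer_names:
        write_ascii_grid(stack.raster(name), directory / f"{name}.asc")
    manifest = {"layers": stack.layer_names, "geometry": stack.geometry.to_dict()}
    (directory / "stack.json").write_text(json.dumps(manifest, indent=2))


def read_stack(directory: str | Path) -> ClimateStack:
    directory = Path(directory)
    manifest = json.loads((directory / "stack.json").read_text())
    geo = GridGeometry.from_dict(manifest["geometry"])
    layers = {}
    for name in manifest["layers"]:
        r = read_ascii_grid(directory / f"{name}.asc", crs=geo.crs)
        if r.geometry != geo:
            raise ValueError(f"layer {name!r} geometry differs from the stack manifest")
        layers[name] = r.values
    return ClimateStack(layers, geo)


def assemble_stack(rasters: Mapping[str, Raster]) -> ClimateStack:
    """Combine single-layer rasters into a stack; geometries must agree."""
    geos = {r.geometry for r in rasters.values()}
    if len(geos) > 1:
        raise ValueError("cannot assemble a stack from rasters with differing geometry")
    geo = next(iter(geos))
    return ClimateStack({n: r.values for n, r in rasters.items()}, geo)
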