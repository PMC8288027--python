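"""Gridded raster container and plain-text (ESRI ASCII grid) I/O.

All layers of a :class:`RasterStack` share one :class:`GridSpec` (origin,
cell size, CRS) and one validity mask.  The grid follows the usual raster
convention: row 0 is the northern edge, column 0 the western edge, and a
point maps to the cell whose half-open interval contains it.  Cell size is
interpreted as kilometres throughout the pipeline (a 1-km analysis grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by all layers of a stack.

    ``x_origin``/``y_origin`` locate the north-west corner of cell (0, 0);
    x increases eastward, y increases northward, rows run north to south.
    """

    n_rows: int
    n_cols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError(
                f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_origin - self.n_rows * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        return (self.x_origin <= x <= self.x_max) and (self.y_min <= y <= self.y_origin)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell containing (x, y); half-open intervals, points on the far
        south/east extent edge are clamped into the last row/column."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        col = int(math.floor((x - self.x_origin) / self.cell_size))
        row = int(math.floor((self.y_origin - y) / self.cell_size))
        return (min(row, self.n_rows - 1), min(col, self.n_cols - 1))

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return (x, y)

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shape (n_rows, n_cols)."""
        cols = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)


@dataclass
class RasterStack:
    """Named 2-D layers on a common grid with a shared validity mask.

    ``mask`` is True on valid (data) cells.  Layers may additionally hold
    NaN for locally missing values; :meth:`values_at` treats both the same.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        for name in list(self.layers):
            self.layers[name] = self._check(self.layers[name])

    def _check(self, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer shape {arr.shape} does not match grid {self.grid.shape}"
            )
        return arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def add_layer(self, name: str, arr: np.ndarray) -> None:
        self.layers[name] = self._check(arr)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def masked(self, name: str) -> np.ndarray:
        """Layer values with invalid cells set to NaN."""
        out = self.layers[name].copy()
        out[~self.mask] = np.nan
        return out

    def values_at(self, name: str, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        vals = self.layers[name][rows, cols].astype(float)
        vals[~self.mask[rows, cols]] = np.nan
        return vals

    def copy(self) -> "RasterStack":
        return RasterStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            mask=self.mask.copy(),
        )

    # ------------------------------------------------------------------ I/O

    def write_dir(self, path: str | Path) -> None:
        """One ASCII grid per layer plus a small stack.yml with the CRS."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(path / f"{name}.asc", arr, self.grid, self.mask)
        meta = {"crs": self.grid.crs, "layers": self.layer_names}
        (path / "stack.yml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def read_dir(cls, path: str | Path) -> "RasterStack":
        path = Path(path)
        meta = yaml.safe_load((path / "stack.yml").read_text())
        stack: RasterStack | None = None
        for name in meta["layers"]:
            arr, grid, valid = read_ascii_grid(path / f"{name}.asc", crs=meta["crs"])
            if stack is None:
                stack = cls(grid=grid, mask=valid)
            stack.add_layer(name, arr)
        if stack is None:
            raise ValueError(f"no layers listed in {path / 'stack.yml'}")
        return stack


def write_ascii_grid(
    path: str | Path,
    arr: np.ndarray,
    grid: GridSpec,
    mask: np.ndarray | None = None,
) -> None:
    arr = np.asarray(arr, dtype=float)
    out = arr.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = np.nan
    out[~np.isfinite(out)] = NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_min!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(
    path: str | Path, crs: str = "EPSG:4326"
) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Returns (values-with-NaN, GridSpec, valid-mask)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    arr = arr.reshape(n_rows, n_cols)
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        crs=crs,
    )
    nodata = header.get("nodata_value", NODATA)
    valid = arr != nodata
    arr = arr.copy()
    arr[~valid] = np.nan
    return arr, grid, valid
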