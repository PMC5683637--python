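"""Planar raster grids, raster stacks, ESRI ASCII I/O and bilinear resampling.

Conventions
-----------
Grids are planar (no projection/geodesy), row-major and 0-based.  Row 0 is the
*northernmost* row, matching the line order of the ESRI ASCII grid format, and
``(origin_x, origin_y)`` is the lower-left corner of the grid.  All point
coordinates refer to cell centres: the centre of cell ``(row, col)`` is at
``x = origin_x + (col + 0.5) * cell_size`` and
``y = origin_y + (n_rows - row - 0.5) * cell_size``.

In memory, nodata cells are ``NaN``; the :class:`GridSpec` sentinel
(``nodata_value``) is used only when reading/writing ``.asc`` files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import ndimage

from .errors import ExtentError, GridError, ParameterError

__all__ = [
    "GridSpec",
    "Raster",
    "EnvStack",
    "bilinear_resample",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a planar raster grid (cell-centre convention)."""

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ParameterError("grid needs at least 2 rows and 2 columns")
        if not self.cell_size > 0:
            raise ParameterError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) outer bounds of the grid."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); raises outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise ExtentError("point outside grid extent")
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        # points exactly on the top/right edge belong to the last cell
        col = np.clip(col, 0, self.n_cols - 1)
        row_from_bottom = np.clip(row_from_bottom, 0, self.n_rows - 1)
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid covering the same extent with cells ``factor`` times larger."""
        if factor < 1 or self.n_rows % factor or self.n_cols % factor:
            raise ParameterError(
                "coarsening factor must divide both grid dimensions"
            )
        return replace(
            self,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            cell_size=self.cell_size * factor,
        )


@dataclass
class Raster:
    """A grid of real values; nodata cells are NaN."""

    spec: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise GridError(
                f"value array shape {self.values.shape} does not match "
                f"grid {self.spec.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy())

    def sample_points(self, x, y) -> np.ndarray:
        """Value of the cell containing each point (no interpolation)."""
        row, col = self.spec.cell_of(x, y)
        return self.values[row, col]


class EnvStack:
    """An ordered, named collection of rasters sharing one :class:`GridSpec`."""

    def __init__(self, layers: Mapping[str, Raster] | Iterable[tuple[str, Raster]]):
        items = list(layers.items()) if isinstance(layers, Mapping) else list(layers)
        if not items:
            raise ParameterError("stack needs at least one layer")
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ParameterError("layer names must be unique")
        spec = items[0][1].spec
        for name, raster in items:
            if raster.spec != spec:
                raise GridError(f"layer {name!r} is on a different grid")
        self._layers: dict[str, Raster] = dict(items)
        self.spec = spec

    # -- container protocol ----------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __getitem__(self, name: str) -> Raster:
        return self._layers[name]

    def items(self):
        return self._layers.items()

    def subset(self, names: Iterable[str]) -> "EnvStack":
        return EnvStack([(n, self._layers[n]) for n in names])

    # -- array views ------------------------------------------------------
    def to_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array view of the stack."""
        return np.stack([self._layers[n].values for n in self._layers])

    @property
    def joint_valid_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.to_array()), axis=0)

    def table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix over ``mask`` (default: joint valid)."""
        if mask is None:
            mask = self.joint_valid_mask
        return self.to_array()[:, mask].T


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def bilinear_resample(raster: Raster, target: GridSpec) -> Raster:
    """Resample a raster onto a new grid by bilinear interpolation.

    Each target cell centre is interpolated from the four surrounding source
    cell centres; nodata (NaN) propagates to any interpolated value that
    touches it.  Target centres must lie within the source extent; in the
    half-cell margin outside the outermost source centres the edge value is
    extended.  Resampling onto the identical grid returns an exact copy.
    """
    if target == raster.spec:
        return raster.copy()
    src = raster.spec
    tx, ty = target.cell_center(*np.meshgrid(
        np.arange(target.n_rows), np.arange(target.n_cols), indexing="ij"
    ))
    if not np.all(src.contains(tx, ty)):
        raise ExtentError("target grid extends outside the source extent")
    col_f = (tx - src.origin_x) / src.cell_size - 0.5
    top_y = src.origin_y + src.n_rows * src.cell_size
    row_f = (top_y - ty) / src.cell_size - 0.5
    out = ndimage.map_coordinates(
        raster.values, [row_f, col_f], order=1, mode="nearest"
    )
    return Raster(target, out)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    spec = raster.spec
    values = raster.values.copy()
    values[~np.isfinite(values)] = spec.nodata_value
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {spec.nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc) into a :class:`Raster`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        for key in _HEADER_KEYS:
            if key not in header:
                raise ParameterError(f"missing ASCII grid header field {key!r}")
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata_value=nodata,
    )
    if values.shape != spec.shape:
        raise GridError("ASCII grid body does not match its header")
    values[np.isclose(values, nodata)] = np.nan
    return Raster(spec, values)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
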