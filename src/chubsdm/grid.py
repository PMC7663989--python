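"""The 90-m spatial framework: habitat raster stacks, zonal units, and
assignment/aggregation of trawl samples.

Conventions (fixed throughout the package): row-major grids, 0-based
indices, origin at the upper-left corner, y increasing upward in world
coordinates. Cells are half-open intervals: a point on a shared edge
belongs to the cell on its lower-right in (row, col) order. Cell area is
``cell_size_m ** 2`` (8,100 m^2 at 90 m); no geodesic correction.

Rasters are read and written as ESRI ASCII grids (.asc), a plain-text
format with a 6-line header; nodata is honoured and the nodata mask is
shared across all variables of a stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HabitatStack",
    "ZoneMap",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "assign_to_cells",
    "aggregate_to_aha",
    "aha_habitat_means",
]


class AlignmentError(ValueError):
    """Grids that should share shape/georeference do not."""


@dataclass
class HabitatStack:
    """Aligned per-variable 2-D grids with a shared nodata mask.

    ``data`` has shape (n_variables, n_rows, n_cols); ``nodata_mask`` is
    True where a cell is nodata in *any* variable (the mask is shared).
    ``origin`` is the world coordinate of the upper-left corner of the
    upper-left cell.
    """

    data: np.ndarray
    names: list[str]
    cell_size_m: float = 90.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_variables, rows, cols)")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per variable required")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        nan_any = np.isnan(self.data).any(axis=0)
        if self.nodata_mask is None:
            self.nodata_mask = nan_any
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool) | nan_any
        # shared-mask contract: propagate to every band
        self.data[:, self.nodata_mask] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_variables(self) -> int:
        return self.data.shape[0]

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    def variable(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def subset(self, names: list[str]) -> "HabitatStack":
        """Stack restricted to ``names`` (order preserved as given)."""
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        idx = [self.names.index(n) for n in names]
        return HabitatStack(
            self.data[idx].copy(), list(names), self.cell_size_m, self.origin,
            self.nodata_mask.copy(),
        )

    def table(self) -> pd.DataFrame:
        """Valid cells as a DataFrame (one row per non-nodata cell)."""
        valid = ~self.nodata_mask
        rows, cols = np.nonzero(valid)
        out = pd.DataFrame({n: self.data[i, rows, cols] for i, n in enumerate(self.names)})
        out.insert(0, "row", rows)
        out.insert(1, "col", cols)
        return out

    def cell_of(self, x, y):
        """(row, col) of world points; half-open cell membership."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size_m).astype(int)
        row = np.floor((self.origin[1] - y) / self.cell_size_m).astype(int)
        # a point exactly on the top edge (y == origin_y - row*cell) belongs
        # to the row below it, which floor already gives; the x convention
        # (lower-right) likewise falls out of floor.
        return row, col

    def cell_center(self, row, col):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size_m
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size_m
        return x, y


@dataclass
class ZoneMap:
    """Integer grid of Aquatic Habitat Area ids plus a lake-unit id.

    Every non-nodata cell carries exactly one AHA id; the ALU (coarse lake
    unit) is a single id for the study extent.
    """

    aha: np.ndarray
    alu: int = 1
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.aha = np.asarray(self.aha)
        if self.nodata_mask is None:
            self.nodata_mask = self.aha < 0
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)

    @property
    def ids(self) -> np.ndarray:
        return np.unique(self.aha[~self.nodata_mask])


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(path, array, cell_size_m=90.0, origin=(0.0, 0.0),
                     nodata_value=-9999.0, fmt="%.8g"):
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes nodata."""
    array = np.asarray(array, dtype=float)
    nrows, ncols = array.shape
    xll = origin[0]
    yll = origin[1] - nrows * cell_size_m
    body = np.where(np.isnan(array), nodata_value, array)
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {xll!r}\nyllcorner {yll!r}\n"
        f"cellsize {cell_size_m!r}\nNODATA_value {nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=fmt)


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (array with NaN nodata, cell_size, origin)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        array = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    array = array.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        array = np.where(array == nodata, np.nan, array)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return array, cell, origin


def write_stack(stack: HabitatStack, directory) -> list[Path]:
    """One .asc file per variable; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(stack.names):
        p = directory / f"{name}.asc"
        write_ascii_grid(p, stack.data[i], stack.cell_size_m, stack.origin)
        paths.append(p)
    return paths


def read_stack(paths, variable_names=None) -> HabitatStack:
    """Read aligned ASCII grids into a stack; misaligned grids rejected."""
    paths = [Path(p) for p in paths]
    if variable_names is None:
        variable_names = [p.stem for p in paths]
    grids, ref = [], None
    for p in paths:
        array, cell, origin = read_ascii_grid(p)
        meta = (array.shape, cell, origin)
        if ref is None:
            ref = meta
        elif meta != ref:
            raise AlignmentError(
                f"grid {p} has shape/georeference {meta}, expected {ref}")
        grids.append(array)
    return HabitatStack(np.stack(grids), list(variable_names), ref[1], ref[2])


# ---------------------------------------------------------------------------
# Sample assignment and zonal aggregation
# ---------------------------------------------------------------------------

def assign_to_cells(samples: pd.DataFrame, stack: HabitatStack,
                    zones: ZoneMap | None = None) -> pd.DataFrame:
    """Attach (row, col) cell indices — and AHA ids if zones are given — to
    point samples with ``x``/``y`` columns.

    Points outside the grid extent (or on nodata cells) are excluded with
    a warning. Raises if no point lands inside.
    """
    out = samples.copy()
    row, col = stack.cell_of(out["x"].to_numpy(), out["y"].to_numpy())
    nrows, ncols = stack.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    valid = inside.copy()
    valid[inside] &= ~stack.nodata_mask[row[inside], col[inside]]
    if not valid.any():
        raise ValueError("all sample points fall outside the grid")
    if (~valid).any():
        warnings.warn(
            f"{(~valid).sum()} sample point(s) outside the grid or on nodata "
            "cells were excluded", stacklevel=2)
    out["row"], out["col"] = row, col
    out = out.loc[valid].reset_index(drop=True)
    if zones is not None:
        out["aha_id"] = zones.aha[out["row"].to_numpy(), out["col"].to_numpy()]
    return out


def aggregate_to_aha(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-AHA unweighted mean CPUE, sample count, and presence flag.

    ``samples`` needs ``aha_id`` and ``cpue`` columns (and optionally
    ``count``). AHAs with no samples do not appear.
    """
    if "aha_id" not in samples or "cpue" not in samples:
        raise KeyError("samples must carry 'aha_id' and 'cpue' columns")
    grouped = samples.groupby("aha_id")
    out = grouped.agg(mean_cpue=("cpue", "mean"), n_samples=("cpue", "size"))
    presence_col = "count" if "count" in samples else "cpue"
    out["any_presence"] = grouped[presence_col].apply(lambda s: bool((s > 0).any()))
    return out


def aha_habitat_means(stack: HabitatStack, zones: ZoneMap) -> pd.DataFrame:
    """Mean of each habitat variable over the non-nodata cells of each AHA.

    AHAs whose cells are entirely nodata are excluded with a warning.
    """
    if zones.aha.shape != stack.shape:
        raise AlignmentError("zone map and stack shapes differ")
    valid = ~(stack.nodata_mask | zones.nodata_mask)
    ids = zones.aha[valid]
    flat = stack.data[:, valid]  # (n_vars, n_valid)
    frame = pd.DataFrame(flat.T, columns=stack.names)
    frame["aha_id"] = ids
    means = frame.groupby("aha_id").mean()
    all_ids = np.unique(zones.aha[~zones.nodata_mask])
    dropped = set(all_ids) - set(means.index)
    if dropped:
        warnings.warn(f"AHA(s) {sorted(dropped)} are fully nodata and were "
                      "excluded", stacklevel=2)
    return means
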