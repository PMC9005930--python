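"""Grid model, covariate raster stacks, I/O and derived-covariate helpers.

Conventions used throughout the package:

* coordinates are projected, in kilometres;
* row 0 is the northern edge of the grid and ``origin_x``/``origin_y`` is
  the *top-left corner* of the raster;
* cell centres define the coordinate of a cell;
* indices are 0-based and coordinate-to-index intervals are half-open.

A :class:`CovariateStack` is a named collection of float64 layers sharing
one :class:`GridSpec`.  Masked (invalid) cells carry ``NaN`` and are
additionally recorded in a boolean validity mask.  Stacks round-trip
through multi-band TIFF files bit-exactly (band layout + a JSON metadata
tag + a plain-text sidecar legend).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Covariate codes recognised by the stack, in canonical order: summer /
#: winter precipitation, temperature extremes and range, annual
#: heat:moisture index, climatic moisture deficit, NDVI amplitude and
#: maximum, soil water stress, surface texture (apparent thermal
#: inertia), heat load index, slope and topographic position index.
COVARIATE_CODES = (
    "SP", "WP", "Tmax", "Tmin", "Trange", "AHM", "CMD",
    "AMP", "MAXN", "SWS", "ATI", "HLI", "Slope", "TPI",
)

#: Codes describing temperature and precipitation, used by summary tools.
TEMPERATURE_CODES = ("Tmax", "Tmin", "Trange")
PRECIPITATION_CODES = ("WP", "SP")


@dataclass(frozen=True)
class GridSpec:
    """Regular grid in projected kilometre coordinates."""

    nrows: int
    ncols: int
    cell_km: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "local-km"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    # --- cell index <-> coordinate mapping -------------------------------
    def cell_center(self, row, col):
        """Projected (x, y) of cell centres; row 0 is the northern edge."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_km
        y = self.origin_y - (row + 0.5) * self.cell_km
        return x, y

    def xy_to_rowcol(self, x, y):
        """Map coordinates to (row, col); half-open cell intervals."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_km).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.cell_km).astype(np.int64)
        return row, col

    def contains_xy(self, x, y):
        row, col = self.xy_to_rowcol(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def flat_index(self, row, col):
        return np.asarray(row) * self.ncols + np.asarray(col)

    def rowcol_from_flat(self, idx):
        idx = np.asarray(idx)
        return idx // self.ncols, idx % self.ncols


class CovariateStack:
    """Named covariate layers on a shared grid.

    Parameters
    ----------
    grid:
        The shared :class:`GridSpec`.
    layers:
        Mapping of covariate code to a float array of shape
        ``(nrows, ncols)``.  NaN marks masked cells.
    mask:
        Optional boolean validity raster (True = valid).  Defaults to the
        cells that are finite in every layer.
    """

    def __init__(self, grid: GridSpec, layers: dict[str, np.ndarray],
                 mask: np.ndarray | None = None):
        if len(layers) == 0:
            raise ValueError("stack needs at least one layer")
        codes = list(layers)
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate covariate codes")
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}
        for code, arr in layers.items():
            arr = np.array(arr, dtype=np.float64, copy=True)
            if arr.shape != grid.shape:
                raise ValueError(
                    f"layer {code!r} has shape {arr.shape}, grid is {grid.shape}")
            self.layers[code] = arr
        if mask is None:
            mask = np.ones(grid.shape, dtype=bool)
            for arr in self.layers.values():
                mask &= np.isfinite(arr)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != grid.shape:
                raise ValueError("mask shape does not match grid")
        self.mask = mask
        for arr in self.layers.values():
            arr[~self.mask] = np.nan

    # --- basic accessors --------------------------------------------------
    @property
    def codes(self) -> list[str]:
        return list(self.layers)

    def __contains__(self, code: str) -> bool:
        return code in self.layers

    def __getitem__(self, code: str) -> np.ndarray:
        return self.layers[code]

    @property
    def valid_cells(self) -> np.ndarray:
        """Flat indices of non-masked cells."""
        return np.flatnonzero(self.mask.ravel())

    def table(self, cells=None, codes=None) -> pd.DataFrame:
        """Covariate values at the given flat cell indices as a DataFrame."""
        if cells is None:
            cells = self.valid_cells
        cells = np.asarray(cells)
        if codes is None:
            codes = self.codes
        data = {c: self.layers[c].ravel()[cells] for c in codes}
        return pd.DataFrame(data, index=cells)

    def layer_csv(self, code: str, path) -> None:
        """Export one layer as CSV with row, col, x, y, value columns."""
        rows, cols = np.nonzero(np.ones(self.grid.shape, dtype=bool))
        x, y = self.grid.cell_center(rows, cols)
        pd.DataFrame({
            "row": rows, "col": cols, "x": x, "y": y,
            "value": self.layers[code].ravel(),
        }).to_csv(path, index=False)


# --- derived covariates ----------------------------------------------------

def annual_heat_moisture(mat_c, map_mm):
    """Annual heat:moisture index, (MAT + 10) / (MAP / 1000).

    ``mat_c`` is mean annual temperature in deg C and ``map_mm`` mean
    annual precipitation in millimetres; higher values indicate hotter,
    drier sites.
    """
    mat_c = np.asarray(mat_c, dtype=float)
    map_mm = np.asarray(map_mm, dtype=float)
    if np.any(map_mm <= 0):
        raise ValueError("mean annual precipitation must be positive")
    out = (mat_c + 10.0) / (map_mm / 1000.0)
    return float(out) if out.ndim == 0 else out


# --- correlation -----------------------------------------------------------

def correlation_matrix(stack: CovariateStack) -> pd.DataFrame:
    """Pearson correlation between layers over jointly valid cells.

    A constant layer has undefined correlation with everything else; those
    entries are reported as NaN (not 0) so that downstream screening can
    treat them explicitly.  The diagonal is 1 even for constant layers.
    """
    cells = stack.valid_cells
    if cells.size < 3:
        raise ValueError("need at least 3 jointly valid cells")
    codes = stack.codes
    X = np.column_stack([stack.layers[c].ravel()[cells] for c in codes])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    denom = np.outer(sd, sd) * X.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Xc) / denom
    r[(sd == 0), :] = np.nan
    r[:, (sd == 0)] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=codes, columns=codes)


# --- TIFF round-trip I/O ---------------------------------------------------

_META_KEY = "seedmenus_stack"


def write_stack(stack: CovariateStack, path) -> None:
    """Write a stack as a multi-band float64 TIFF plus a text legend.

    Band order follows ``stack.codes``; grid metadata and band names are
    embedded as JSON in the TIFF description tag, and a human-readable
    ``<path>.legend.txt`` sidecar lists bands and grid parameters.
    """
    path = Path(path)
    data = np.stack([stack.layers[c] for c in stack.codes])
    g = stack.grid
    meta = {
        _META_KEY: 1,
        "codes": stack.codes,
        "grid": {"nrows": g.nrows, "ncols": g.ncols, "cell_km": g.cell_km,
                 "origin_x": g.origin_x, "origin_y": g.origin_y,
                 "crs_tag": g.crs_tag},
    }
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))
    legend = [f"covariate stack: {path.name}",
              f"grid: {g.nrows} rows x {g.ncols} cols, cell {g.cell_km} km, "
              f"origin ({g.origin_x}, {g.origin_y}), crs {g.crs_tag}",
              "bands:"]
    legend += [f"  {i + 1}: {c}" for i, c in enumerate(stack.codes)]
    Path(str(path) + ".legend.txt").write_text("\n".join(legend) + "\n")


def read_stack(path) -> CovariateStack:
    """Read a stack written by :func:`write_stack` (bit-exact round trip)."""
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
        data = tif.asarray()
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise ValueError("file lacks stack metadata (band names)") from exc
    if _META_KEY not in meta:
        raise ValueError("file lacks stack metadata (band names)")
    codes = meta["codes"]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate band names in file")
    if data.ndim == 2:
        data = data[None, :, :]
    if data.shape[0] != len(codes):
        raise ValueError("band count does not match band-name metadata")
    g = meta["grid"]
    grid = GridSpec(nrows=g["nrows"], ncols=g["ncols"], cell_km=g["cell_km"],
                    origin_x=g["origin_x"], origin_y=g["origin_y"],
                    crs_tag=g["crs_tag"])
    if data.shape[1:] != grid.shape:
        raise ValueError("raster shape does not match grid metadata")
    layers = {c: np.array(data[i], dtype=np.float64) for i, c in enumerate(codes)}
    return CovariateStack(grid, layers)


def write_probability_raster(grid: GridSpec, array: np.ndarray, path,
                             name: str = "probability") -> None:
    """Write a single layer (probability / SE / count) as a 1-band TIFF."""
    stack = CovariateStack(grid, {name: np.asarray(array, dtype=np.float64)})
    write_stack(stack, path)
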