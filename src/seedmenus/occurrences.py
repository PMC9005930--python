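"""Occurrence QC, rasterisation, spatial thinning and pseudo-absences.

Presence-only occurrence records go through four steps before fitting:

1. :func:`qc_filter` drops records with large positional uncertainty,
   records on water/masked cells and records outside the grid;
2. :func:`rasterize_presences` collapses records to unique presence
   cells at the modelling resolution;
3. :func:`thin_presences` caps the number of presence cells retained in
   any one thinning block, damping unequal sampling effort;
4. :func:`sample_pseudo_absences` draws background/pseudo-absence cells
   with per-algorithm-family defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CovariateStack, GridSpec

OCCURRENCE_COLUMNS = ("species_id", "x", "y", "uncertainty_km", "source")

#: Default pseudo-absence counts per algorithm family.  Regression-style
#: learners (smooth additive, maxent-like) use a large background of
#: 10,000 cells; the tree ensemble uses as many absences as presences.
PSEUDO_ABSENCE_DEFAULTS = {
    "smooth_additive": 10_000,
    "maxent_like": 10_000,
    "tree_ensemble": None,  # = number of presences
}

ALGORITHM_FAMILIES = tuple(PSEUDO_ABSENCE_DEFAULTS)


@dataclass
class OccurrenceSet:
    """Occurrence records for one species.

    ``records`` is a DataFrame with columns x, y (projected km),
    uncertainty_km (may be NaN = not reported) and source.
    """

    species_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        rec = self.records
        for col in ("x", "y"):
            if col not in rec.columns:
                raise ValueError(f"records missing column {col!r}")
        if "uncertainty_km" not in rec.columns:
            rec = rec.assign(uncertainty_km=np.nan)
        if "source" not in rec.columns:
            rec = rec.assign(source="unknown")
        if not np.isfinite(rec[["x", "y"]].to_numpy()).all():
            raise ValueError("coordinates must be finite")
        unc = rec["uncertainty_km"].to_numpy(dtype=float)
        if np.any(unc[np.isfinite(unc)] < 0):
            raise ValueError("uncertainty must be non-negative")
        self.records = rec.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path, species_id: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        if species_id is None:
            species_id = str(df["species_id"].iloc[0])
        else:
            df = df[df["species_id"] == species_id]
        return cls(species_id=species_id, records=df)

    def to_csv(self, path) -> None:
        cols = [c for c in OCCURRENCE_COLUMNS if c in self.records.columns]
        self.records[cols].to_csv(path, index=False)


@dataclass
class PresenceBackground:
    """One cross-validation replicate's presence and absence cells."""

    presence_cells: np.ndarray
    absence_cells: np.ndarray
    run_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.presence_cells = np.asarray(self.presence_cells, dtype=np.int64)
        self.absence_cells = np.asarray(self.absence_cells, dtype=np.int64)


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

def qc_filter(occ: OccurrenceSet, stack: CovariateStack,
              max_uncertainty_km: float = 1.0,
              water_mask: np.ndarray | None = None,
              ) -> tuple[OccurrenceSet, dict[str, int]]:
    """Quality-control occurrence records against a covariate stack.

    Removes, in order: records outside the grid; records whose reported
    positional uncertainty exceeds ``max_uncertainty_km`` (records with
    *missing* uncertainty are kept); records falling on water or masked
    cells.  Returns the filtered set and a per-rule removal count report.
    """
    rec = occ.records
    grid = stack.grid
    report = {"outside_grid": 0, "uncertain": 0, "water_or_masked": 0,
              "n_in": len(rec), "n_out": 0}

    inside = grid.contains_xy(rec["x"].to_numpy(), rec["y"].to_numpy())
    report["outside_grid"] = int((~inside).sum())
    rec = rec[inside]

    unc = rec["uncertainty_km"].to_numpy(dtype=float)
    keep_unc = ~(np.isfinite(unc) & (unc > max_uncertainty_km))
    report["uncertain"] = int((~keep_unc).sum())
    rec = rec[keep_unc]

    row, col = grid.xy_to_rowcol(rec["x"].to_numpy(), rec["y"].to_numpy())
    bad = ~stack.mask[row, col]
    if water_mask is not None:
        bad |= np.asarray(water_mask, dtype=bool)[row, col]
    report["water_or_masked"] = int(bad.sum())
    rec = rec[~bad]

    report["n_out"] = len(rec)
    return OccurrenceSet(occ.species_id, rec.reset_index(drop=True)), report


def rasterize_presences(occ: OccurrenceSet, grid: GridSpec) -> np.ndarray:
    """Unique presence cells (sorted flat indices) at grid resolution."""
    if len(occ) == 0:
        return np.empty(0, dtype=np.int64)
    row, col = grid.xy_to_rowcol(occ.records["x"].to_numpy(),
                                 occ.records["y"].to_numpy())
    if np.any((row < 0) | (row >= grid.nrows) | (col < 0) | (col >= grid.ncols)):
        raise ValueError("occurrences fall outside the grid; run qc_filter first")
    return np.unique(grid.flat_index(row, col))


def thin_presences(cells, grid: GridSpec, block_km: float = 10.0,
                   max_per_block: int = 3, seed: int = 0) -> np.ndarray:
    """Spatially thin presence cells by block subsampling.

    The grid is partitioned into ``block_km`` x ``block_km`` blocks
    anchored at the grid origin; within each block at most
    ``max_per_block`` cells are retained, chosen uniformly at random.
    Output is sorted and deterministic under ``seed``.
    """
    cells = np.asarray(cells, dtype=np.int64)
    if block_km < grid.cell_km:
        raise ValueError("block_km must be at least one cell")
    if cells.size == 0:
        return cells
    rng = np.random.default_rng(seed)
    row, col = grid.rowcol_from_flat(cells)
    cells_per_block = max(int(round(block_km / grid.cell_km)), 1)
    block_id = (row // cells_per_block) * (grid.ncols // cells_per_block + 1) \
        + (col // cells_per_block)
    keep = []
    for b in np.unique(block_id):
        members = cells[block_id == b]
        if members.size <= max_per_block:
            keep.append(members)
        else:
            keep.append(rng.choice(members, size=max_per_block, replace=False))
    return np.sort(np.concatenate(keep))


def sample_pseudo_absences(stack: CovariateStack, presence_cells,
                           algorithm_family: str,
                           n_override: int | None = None,
                           exclude_presence: bool | None = None,
                           seed: int = 0) -> np.ndarray:
    """Draw pseudo-absence / background cells for one algorithm family.

    Defaults follow common presence-only recommendations: 10,000 cells
    for the smooth additive and maxent-like families (the maxent-like
    background does *not* exclude presence cells), and one absence per
    presence for the tree ensemble (presences excluded).  Requests larger
    than the candidate pool are capped with a warning.  Sampling is
    uniform without replacement and deterministic under ``seed``.
    """
    if algorithm_family not in PSEUDO_ABSENCE_DEFAULTS:
        raise ValueError(f"unknown algorithm family {algorithm_family!r}")
    presence_cells = np.asarray(presence_cells, dtype=np.int64)
    if exclude_presence is None:
        exclude_presence = algorithm_family != "maxent_like"
    n = n_override
    if n is None:
        n = PSEUDO_ABSENCE_DEFAULTS[algorithm_family]
        if n is None:
            n = presence_cells.size
    if n < 1:
        raise ValueError("need at least one pseudo-absence")

    candidates = stack.valid_cells
    if exclude_presence:
        candidates = np.setdiff1d(candidates, presence_cells, assume_unique=False)
    if candidates.size == 0:
        raise ValueError("no candidate cells available for pseudo-absences")
    if n > candidates.size:
        warnings.warn(
            f"requested {n} pseudo-absences but only {candidates.size} "
            f"candidate cells; capping", stacklevel=2)
        n = candidates.size
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(candidates, size=n, replace=False))
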