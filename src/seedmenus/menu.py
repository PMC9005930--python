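"""Seed-menu decision support: extract, threshold, join traits, count.

Given stacked per-species habitat-probability rasters and one or more
restoration sites, the engine extracts per-site probabilities, includes
a species when its probability meets the threshold at *all* sites (an
AND rule with inclusive >= comparison), joins the selected trait
columns, and can also count, cell by cell, how many species clear their
thresholds (the coverage map).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .grids import GridSpec


@dataclass
class Site:
    site_id: str
    geometry: BaseGeometry
    source: str = "coordinates"


@dataclass
class SiteSet:
    """Restoration sites as points or (single-part) polygons."""

    sites: list[Site]

    def __post_init__(self) -> None:
        for s in self.sites:
            if s.geometry.geom_type in ("MultiPolygon", "MultiPoint",
                                        "MultiLineString", "GeometryCollection"):
                raise ValueError(
                    f"site {s.site_id!r} is a multipart geometry; split it "
                    "into one feature per part before loading")

    @classmethod
    def from_coordinates(cls, table: pd.DataFrame) -> "SiteSet":
        """Build from a table with site_id, x, y columns (km coordinates)."""
        sites = [Site(str(r.site_id), Point(float(r.x), float(r.y)),
                      source="coordinates")
                 for r in table.itertuples()]
        return cls(sites)

    @classmethod
    def from_csv(cls, path) -> "SiteSet":
        return cls.from_coordinates(pd.read_csv(path))

    @classmethod
    def from_geojson(cls, path) -> "SiteSet":
        """Load sites from a GeoJSON FeatureCollection (points/polygons)."""
        gj = json.loads(open(path).read())
        sites = []
        for i, feat in enumerate(gj["features"]):
            props = feat.get("properties") or {}
            sid = str(props.get("site_id", f"site{i + 1}"))
            sites.append(Site(sid, shape(feat["geometry"]), source="vector-file"))
        return cls(sites)


@dataclass
class ThresholdRule:
    """How to resolve the per-species inclusion threshold.

    ``kind='fixed'`` uses one value for every species; ``kind='max_sss'``
    and ``kind='sens_eq_spec'`` use species-specific thresholds supplied
    in ``per_species`` (typically derived from each model's sensitivity /
    specificity profile).
    """

    kind: str = "fixed"
    fixed_value: float = 0.0
    per_species: dict[str, float] = field(default_factory=dict)

    def resolve(self, species_id: str) -> float:
        if self.kind == "fixed":
            t = self.fixed_value
        elif self.kind in ("max_sss", "sens_eq_spec"):
            if species_id not in self.per_species:
                raise ValueError(
                    f"no resolved threshold for species {species_id!r}")
            t = self.per_species[species_id]
        else:
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold for {species_id!r} outside [0, 1]")
        return float(t)


def extract_at_sites(rasters: dict[str, np.ndarray], grid: GridSpec,
                     sites: SiteSet, polygon_rule: str = "mean") -> pd.DataFrame:
    """Per-site habitat probability for each species raster.

    Points take the containing cell's value; polygons summarise the
    valid cells whose centres fall inside with ``polygon_rule`` (mean,
    min or max).  Sites outside the grid or covering no valid cell raise.
    Returns a DataFrame indexed by species with one column per site.
    """
    if polygon_rule not in ("mean", "min", "max"):
        raise ValueError("polygon_rule must be mean, min or max")
    agg = {"mean": np.nanmean, "min": np.nanmin, "max": np.nanmax}[polygon_rule]
    cols = {}
    for site in sites.sites:
        geom = site.geometry
        if geom.geom_type == "Point":
            if not grid.contains_xy(geom.x, geom.y):
                raise ValueError(f"site {site.site_id!r} lies outside the grid")
            r, c = grid.xy_to_rowcol(geom.x, geom.y)
            vals = {}
            for sp, ras in rasters.items():
                v = ras[int(r), int(c)]
                vals[sp] = float(v)
            cols[site.site_id] = vals
        elif geom.geom_type == "Polygon":
            minx, miny, maxx, maxy = geom.bounds
            rows_all, cols_all = np.meshgrid(np.arange(grid.nrows),
                                             np.arange(grid.ncols),
                                             indexing="ij")
            x, y = grid.cell_center(rows_all.ravel(), cols_all.ravel())
            inbox = (x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy)
            idx = np.flatnonzero(inbox)
            inside = [i for i in idx
                      if geom.covers(Point(float(x[i]), float(y[i])))]
            if not inside:
                raise ValueError(
                    f"polygon site {site.site_id!r} contains no cell centre")
            rr = rows_all.ravel()[inside]
            cc = cols_all.ravel()[inside]
            vals = {}
            for sp, ras in rasters.items():
                cell_vals = ras[rr, cc]
                if np.all(np.isnan(cell_vals)):
                    raise ValueError(
                        f"polygon site {site.site_id!r} intersects no valid "
                        f"cell for species {sp!r}")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    vals[sp] = float(agg(cell_vals))
            cols[site.site_id] = vals
        else:
            raise ValueError(
                f"unsupported geometry {geom.geom_type!r} for site "
                f"{site.site_id!r}")
    out = pd.DataFrame(cols)
    out.index.name = "species_id"
    return out


def apply_threshold(prob_table: pd.DataFrame, rule: ThresholdRule) -> pd.DataFrame:
    """Inclusion decisions: probability >= threshold at EVERY site.

    NaN probabilities (masked-only sites) never satisfy the comparison.
    Returns the probability table plus ``threshold``, ``min_probability``
    and boolean ``included`` columns.
    """
    site_cols = list(prob_table.columns)
    out = prob_table.copy()
    thresholds = pd.Series({sp: rule.resolve(sp) for sp in out.index})
    probs = out[site_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        meets = probs >= thresholds.to_numpy()[:, None]
    meets[np.isnan(probs)] = False
    out["threshold"] = thresholds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        out["min_probability"] = (np.nanmin(probs, axis=1) if probs.size
                                  else np.nan)
    out["included"] = meets.all(axis=1)
    return out


def build_menu(inclusion: pd.DataFrame, traits: pd.DataFrame,
               selected_traits: list[str] | None = None,
               include_all: bool = False) -> pd.DataFrame:
    """Join trait columns onto the included species.

    ``selected_traits`` must name columns of ``traits``; unknown names
    raise with the available columns listed.  Species missing from the
    trait table are kept with NaN traits and a warning.  With
    ``include_all`` every species is kept with its inclusion flag.
    """
    traits = traits.set_index("species_id") if "species_id" in traits.columns \
        else traits
    if selected_traits is None:
        selected_traits = []
    unknown = [t for t in selected_traits if t not in traits.columns]
    if unknown:
        raise ValueError(
            f"unknown trait column(s) {unknown}; available: "
            f"{sorted(traits.columns)}")
    rows = inclusion if include_all else inclusion[inclusion["included"]]
    missing = [sp for sp in rows.index if sp not in traits.index]
    if missing:
        warnings.warn(f"species missing from trait table: {missing}",
                      stacklevel=2)
    joined = rows.join(traits[selected_traits], how="left")
    joined.index.name = "species_id"
    return joined.reset_index()


def menu_to_csv(menu: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a menu CSV with ``# key: value`` metadata header comments."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        menu.to_csv(fh, index=False)


def coverage_map(rasters: dict[str, np.ndarray], rule: ThresholdRule
                 ) -> np.ndarray:
    """Per-cell count of species whose probability meets their threshold."""
    if len(rasters) == 0:
        raise ValueError("need at least one species raster")
    shapes = {r.shape for r in rasters.values()}
    if len(shapes) != 1:
        raise ValueError("species rasters disagree on grid shape")
    count = np.zeros(next(iter(shapes)), dtype=np.int32)
    for sp, ras in rasters.items():
        t = rule.resolve(sp)
        with np.errstate(invalid="ignore"):
            count += (np.nan_to_num(ras, nan=-1.0) >= t).astype(np.int32)
    return count
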