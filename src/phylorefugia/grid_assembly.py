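"""Sampling grids, presence-absence matrices, and per-cell metric surfaces.

Species occurrences are sampled on a regular lattice of cell-center points
(emulating 0.1-degree point sampling of range polygons): a species is present
in a cell iff the cell's center point lies inside or on the boundary of its
range polygon.  Coordinates are abstract planar "degrees"; no geodesy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape


@dataclass(frozen=True)
class GridSpec:
    """Regular rectangular sampling grid.

    Cells are squares of edge ``resolution``; cell centers form the lattice of
    midpoints.  Cell indexing is row-major from the (x_min, y_min) corner,
    0-based: ``index = iy * nx + ix``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    resolution: float = 0.1

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("grid extents must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must contain at least one cell per axis")

    @property
    def nx(self) -> int:
        return int(np.floor((self.x_max - self.x_min) / self.resolution + 1e-9))

    @property
    def ny(self) -> int:
        return int(np.floor((self.y_max - self.y_min) / self.resolution + 1e-9))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, row-major order."""
        xs = self.x_min + (np.arange(self.nx) + 0.5) * self.resolution
        ys = self.y_min + (np.arange(self.ny) + 0.5) * self.resolution
        xx, yy = np.meshgrid(xs, ys)  # rows = y, cols = x -> row-major flatten
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_xy(self) -> tuple[np.ndarray, np.ndarray]:
        c = self.cell_centers()
        return c[:, 0], c[:, 1]

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "y_min": self.y_min,
            "x_max": self.x_max,
            "y_max": self.y_max,
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(**{k: float(d[k]) for k in ("x_min", "y_min", "x_max", "y_max", "resolution")})


@dataclass
class CommunityMatrix:
    """Binary site-by-species table on a :class:`GridSpec`.

    ``matrix`` has shape (n_cells, n_species) with entries in {0, 1}.
    """

    grid: GridSpec
    species: tuple[str, ...]
    matrix: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (self.grid.n_cells, len(self.species)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"({self.grid.n_cells}, {len(self.species)})"
            )
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("community matrix entries must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        x, y = self.grid.cell_xy()
        df = pd.DataFrame(self.matrix, columns=list(self.species))
        df.insert(0, "y", y)
        df.insert(0, "x", x)
        df.insert(0, "cell_index", np.arange(self.grid.n_cells))
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


@dataclass
class MetricSurface:
    """Per-cell values of one metric (NaN marks missing cells).

    When summarised over a tree set, ``values`` holds the across-tree mean and
    ``vmin``/``vmax`` the per-cell range.
    """

    grid: GridSpec
    values: np.ndarray
    name: str = ""
    group: str = ""
    n_trees: int = 1
    vmin: np.ndarray | None = None
    vmax: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError("surface length must equal grid cell count")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValueError("surface values must be finite or NaN")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array: True where the value is present (non-missing)."""
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        x, y = self.grid.cell_xy()
        df = pd.DataFrame(
            {
                "cell_index": np.arange(self.grid.n_cells),
                "x": x,
                "y": y,
                "mean": self.values,
            }
        )
        if self.vmin is not None:
            df["min"] = self.vmin
            df["max"] = self.vmax
        return df

    def write_csv(self, path) -> None:
        # missing values serialize as empty fields, never sentinel numbers
        self.to_frame().to_csv(path, index=False, na_rep="")

    @classmethod
    def read_csv(cls, path, grid: GridSpec | None = None, name: str = "") -> "MetricSurface":
        df = pd.read_csv(path)
        if grid is None:
            res = float(np.round(np.diff(np.unique(df["x"]).round(12)).min(), 12))
            grid = GridSpec(
                x_min=float(df["x"].min() - res / 2),
                y_min=float(df["y"].min() - res / 2),
                x_max=float(df["x"].max() + res / 2),
                y_max=float(df["y"].max() + res / 2),
                resolution=res,
            )
        values = np.full(grid.n_cells, np.nan)
        values[df["cell_index"].to_numpy()] = df["mean"].to_numpy()
        surf = cls(grid=grid, values=values, name=name)
        if "min" in df.columns:
            vmin = np.full(grid.n_cells, np.nan)
            vmax = np.full(grid.n_cells, np.nan)
            vmin[df["cell_index"].to_numpy()] = df["min"].to_numpy()
            vmax[df["cell_index"].to_numpy()] = df["max"].to_numpy()
            surf.vmin, surf.vmax = vmin, vmax
        return surf


def rasterize_presence(
    ranges: Mapping[str, shapely.Geometry], grid: GridSpec, group: str = ""
) -> CommunityMatrix:
    """Point-sample range polygons at cell centers into a presence-absence matrix.

    A species is present in a cell iff the cell center lies inside or on the
    boundary of its polygon (``shapely.covers`` semantics).
    """
    centers = grid.cell_centers()
    points = shapely.points(centers[:, 0], centers[:, 1])
    species = tuple(ranges.keys())
    mat = np.zeros((grid.n_cells, len(species)), dtype=np.int8)
    for j, sp in enumerate(species):
        poly = ranges[sp]
        if poly.area == 0:
            warnings.warn(f"range polygon for {sp!r} has zero area; species absent everywhere")
            continue
        mat[:, j] = shapely.covers(poly, points)
    return CommunityMatrix(grid=grid, species=species, matrix=mat, group=group)


def richness(matrix: CommunityMatrix) -> MetricSurface:
    """Alpha diversity: number of species present at each cell."""
    return MetricSurface(
        grid=matrix.grid,
        values=matrix.matrix.sum(axis=1).astype(float),
        name="richness",
        group=matrix.group,
    )


def normalize_surface(surface: MetricSurface) -> MetricSurface:
    """Min-max rescale non-missing values to [0, 1]; missing stays missing.

    A constant surface maps to all zeros (with a warning); an all-missing
    surface is an error.
    """
    m = surface.mask
    if not m.any():
        raise ValueError("cannot normalize an all-missing surface")
    vals = surface.values.copy()
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi == lo:
        warnings.warn("constant surface normalized to all zeros")
        vals[m] = 0.0
    else:
        vals[m] = (vals[m] - lo) / (hi - lo)
    return MetricSurface(
        grid=surface.grid,
        values=vals,
        name=f"{surface.name}_norm" if surface.name else "norm",
        group=surface.group,
        n_trees=surface.n_trees,
    )


def write_ranges_geojson(ranges: Mapping[str, shapely.Geometry], path) -> None:
    """Write ranges as a GeoJSON FeatureCollection keyed by property 'species_id'."""
    features = [
        {
            "type": "Feature",
            "properties": {"species_id": sp},
            "geometry": geom_mapping(poly),
        }
        for sp, poly in ranges.items()
    ]
    with open(path, "w") as fh:
        json.dump(
            {"type": "FeatureCollection", "features": features},
            fh,
            sort_keys=True,
            separators=(",", ":"),
        )


def read_ranges_geojson(path) -> dict[str, shapely.Geometry]:
    with open(path) as fh:
        fc = json.load(fh)
    out: dict[str, shapely.Geometry] = {}
    for feat in fc["features"]:
        out[feat["properties"]["species_id"]] = geom_shape(feat["geometry"])
    return out
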