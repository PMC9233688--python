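"""Raster lattice, polygon geometry and sampling shared by every pipeline stage.

All rasters in one analysis live on a single regular lattice (:class:`GridSpec`).
Coordinates are geographic degrees treated as planar; at the 0.5-degree scale of
the analysis this is adequate and keeps geometry tests exact.

Conventions used everywhere in the package:

* row 0 is the northernmost row;
* a cell is half-open, ``[x, x + cs) x (y - cs, y]`` — a point on a vertical
  seam belongs to the cell to its east, a point on a horizontal seam to the
  cell below whose top edge it touches;
* a cell belongs to a polygon iff its *center* is inside the polygon or on its
  boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

__all__ = [
    "GridSpec",
    "ClimateStack",
    "RangePolygons",
    "read_ascii_raster",
    "write_ascii_raster",
    "read_raster_stack",
    "write_raster_stack",
    "cells_in_polygons",
    "sample_occurrences",
    "extract_at_points",
    "read_range_polygons",
    "write_range_polygons",
    "read_occurrences",
    "write_occurrences",
]

PHENOLOGY_LABELS = ("annual", "breeding", "wintering", "breeding+wintering")


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice of square cells in geographic degrees.

    ``(x_min, y_min)`` is the lower-left corner of the lattice; row 0 is the
    northernmost row, so the center of cell ``(r, c)`` is
    ``(x_min + (c + 0.5) * cell_size, y_max - (r + 0.5) * cell_size)``.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float
    crs_label: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """Center coordinates ``(x, y)`` of cell ``(row, col)``."""
        x = self.x_min + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_max - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def all_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of every cell as two ``(n_rows, n_cols)`` arrays."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell ``(row, col)`` containing a point under the half-open rule.

        Raises ``ValueError`` for a point outside the lattice.  The north and
        west outer edges are inside; the south and east outer edges are not.
        """
        col = int(np.floor((x - self.x_min) / self.cell_size))
        # cell r spans y in (y_max-(r+1)cs, y_max-r*cs]: y on a seam maps to
        # the cell whose top edge it is, which floor() delivers directly
        row = int(np.floor((self.y_max - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"point ({x}, {y}) outside grid bounds "
                f"x [{self.x_min}, {self.x_max}), y ({self.y_min}, {self.y_max}]"
            )
        return row, col

    def matches(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.x_min, other.x_min)
            and np.isclose(self.y_min, other.y_min)
            and np.isclose(self.cell_size, other.cell_size)
        )


@dataclass
class ClimateStack:
    """A multi-variable gridded climate scenario on one lattice.

    ``values`` maps variable name -> ``(n_rows, n_cols)`` float array.  The
    nodata mask is shared across variables: a cell masked in any input layer
    is masked in all of them.
    """

    grid: GridSpec
    variables: list[str]
    values: dict[str, np.ndarray]
    nodata_mask: np.ndarray
    scenario_id: str = "present"

    def __post_init__(self) -> None:
        for name in self.variables:
            if name not in self.values:
                raise ValueError(f"variable {name!r} missing from values")
            if self.values[name].shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {self.values[name].shape} does not "
                    f"conform to grid {self.grid.shape}"
                )
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError("nodata_mask does not conform to grid")

    def layer(self, variable: str) -> np.ndarray:
        if variable not in self.values:
            raise KeyError(f"variable {variable!r} not in stack {self.scenario_id!r}")
        return self.values[variable]

    def covariate_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Covariates at cells ``(rows, cols)`` as an ``(n, n_vars)`` matrix."""
        return np.column_stack([self.values[v][rows, cols] for v in self.variables])


@dataclass
class RangePolygons:
    """Presence and absence polygon sets for one species.

    Each polygon carries a phenology label (annual / breeding / wintering);
    ``phenology`` summarises the presence set as a whole, e.g.
    ``"breeding+wintering"`` when both seasonal ranges are present.
    """

    species: str
    presence: list[BaseGeometry]
    absence: list[BaseGeometry]
    phenology: str = "annual"
    presence_phenology: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phenology not in PHENOLOGY_LABELS:
            raise ValueError(f"unknown phenology {self.phenology!r}")
        self.presence = [make_valid(g) for g in self.presence]
        self.absence = [make_valid(g) for g in self.absence]
        if not self.presence_phenology:
            lab = "breeding" if self.phenology == "breeding+wintering" else self.phenology
            self.presence_phenology = [lab] * len(self.presence)
        if len(self.presence_phenology) != len(self.presence):
            raise ValueError("presence_phenology length mismatch")

    def presence_for_scope(self, scope: str) -> list[BaseGeometry]:
        """Presence polygons restricted to a phenology scope."""
        if scope == "breeding+wintering":
            wanted = {"breeding", "wintering"}
        else:
            wanted = {scope}
        polys = [g for g, p in zip(self.presence, self.presence_phenology) if p in wanted]
        if not polys:
            raise ValueError(
                f"species {self.species!r} has no presence polygons with "
                f"phenology {scope!r} (available: {sorted(set(self.presence_phenology))})"
            )
        return polys


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)

def write_ascii_raster(
    path: str | Path,
    grid: GridSpec,
    layer: np.ndarray,
    nodata_mask: np.ndarray | None = None,
    nodata_value: float = -9999.0,
) -> None:
    """Write one layer as an ESRI ASCII grid with full float precision."""
    layer = np.asarray(layer, dtype=float)
    if layer.shape != grid.shape:
        raise ValueError("layer does not conform to grid")
    out = layer.copy()
    if nodata_mask is not None:
        out[nodata_mask] = nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min!r}\n")
        fh.write(f"yllcorner {grid.y_min!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_raster(path: str | Path) -> tuple[GridSpec, np.ndarray, np.ndarray]:
    """Read an ESRI ASCII grid; returns (grid, layer, nodata_mask)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {req!r}")
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
    )
    layer = np.array(rows, dtype=float)
    if layer.shape != grid.shape:
        raise ValueError(f"{path}: data shape {layer.shape} does not match header {grid.shape}")
    nodata = header.get("nodata_value", -9999.0)
    mask = layer == nodata
    layer = layer.copy()
    layer[mask] = np.nan
    return grid, layer, mask


def read_raster_stack(
    paths: Sequence[str | Path],
    variable_names: Sequence[str],
    scenario_id: str = "present",
) -> ClimateStack:
    """Read one ASCII grid per variable into a :class:`ClimateStack`.

    All files must share one lattice; nodata is unified across layers (a cell
    masked anywhere is masked everywhere).
    """
    if len(paths) != len(variable_names):
        raise ValueError("paths and variable_names must have equal length")
    grid: GridSpec | None = None
    values: dict[str, np.ndarray] = {}
    mask: np.ndarray | None = None
    for path, name in zip(paths, variable_names):
        g, layer, m = read_ascii_raster(path)
        if grid is None:
            grid, mask = g, m
        else:
            if not grid.matches(g):
                raise ValueError(
                    f"lattice mismatch: {paths[0]} has {grid}, {path} has {g}"
                )
            mask = mask | m
        values[name] = layer
    assert grid is not None and mask is not None
    for name in values:  # unify nodata across layers
        values[name][mask] = np.nan
    return ClimateStack(
        grid=grid,
        variables=list(variable_names),
        values=values,
        nodata_mask=mask,
        scenario_id=scenario_id,
    )


def write_raster_stack(directory: str | Path, stack: ClimateStack) -> list[Path]:
    """Write each variable of a stack as ``<directory>/<variable>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in stack.variables:
        p = directory / f"{name}.asc"
        write_ascii_raster(p, stack.grid, stack.values[name], stack.nodata_mask)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# polygon <-> cell association

def cells_in_polygons(grid: GridSpec, polys: Iterable[BaseGeometry]) -> np.ndarray:
    """Boolean ``(n_rows, n_cols)`` grid of cells whose center lies in any polygon.

    A center on a polygon boundary counts as inside (covers semantics).  An
    empty polygon set yields an all-false grid.
    """
    polys = [make_valid(p) for p in polys]
    inside = np.zeros(grid.shape, dtype=bool)
    if not polys:
        return inside
    xs, ys = grid.all_centers()
    points = shapely.points(xs.ravel(), ys.ravel())
    for poly in polys:
        # restrict the test to cells inside the polygon bounding box
        bx0, by0, bx1, by1 = poly.bounds
        sel = (
            (xs.ravel() >= bx0 - grid.cell_size)
            & (xs.ravel() <= bx1 + grid.cell_size)
            & (ys.ravel() >= by0 - grid.cell_size)
            & (ys.ravel() <= by1 + grid.cell_size)
        )
        if not sel.any():
            continue
        hit = shapely.covers(poly, points[sel])
        flat = inside.ravel()
        idx = np.flatnonzero(sel)[hit]
        flat[idx] = True
        inside = flat.reshape(grid.shape)
    return inside


def _eligible_cells(
    stack: ClimateStack, polys: Iterable[BaseGeometry]
) -> tuple[np.ndarray, np.ndarray]:
    member = cells_in_polygons(stack.grid, polys) & ~stack.nodata_mask
    rows, cols = np.nonzero(member)
    return rows, cols


def sample_occurrences(
    stack: ClimateStack,
    polys: RangePolygons,
    n_presence: int,
    n_absence: int,
    seed: int,
    with_replacement: bool = False,
) -> pd.DataFrame:
    """Sample presence (label 1) and absence (label 0) records with covariates.

    Default mode draws cell centers uniformly *without replacement* from the
    eligible (non-nodata) cells of each polygon set, one record per cell.
    ``with_replacement=True`` instead draws cells uniformly with replacement,
    allowing duplicate records.  Cells claimed by both polygon sets are
    assigned to presence and removed from the absence pool: the absence
    polygons closely surround the presence ones, so seam cells are ambiguous
    and presence is the conservative label.
    """
    rng = np.random.default_rng(seed)
    pres_member = cells_in_polygons(stack.grid, polys.presence) & ~stack.nodata_mask
    abs_member = cells_in_polygons(stack.grid, polys.absence) & ~stack.nodata_mask
    abs_member &= ~pres_member  # overlap resolved in favour of presence

    frames = []
    for member, n, label in ((pres_member, n_presence, 1), (abs_member, n_absence, 0)):
        rows, cols = np.nonzero(member)
        if len(rows) == 0 or (not with_replacement and len(rows) < n):
            role = "presence" if label == 1 else "absence"
            raise ValueError(
                f"species {polys.species!r}: {role} polygons contain "
                f"{len(rows)} eligible cells, {n} requested"
            )
        pick = rng.choice(len(rows), size=n, replace=with_replacement)
        r, c = rows[pick], cols[pick]
        x, y = stack.grid.cell_center(r, c)
        frame = pd.DataFrame({"species": polys.species, "x": x, "y": y, "label": label})
        cov = stack.covariate_matrix(r, c)
        for j, name in enumerate(stack.variables):
            frame[name] = cov[:, j]
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if not np.isfinite(table[stack.variables].to_numpy()).all():
        raise AssertionError("sampled covariates contain non-finite values")
    return table


def extract_at_points(
    layer: np.ndarray,
    grid: GridSpec,
    points: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Value of the cell containing each point; nodata cells yield NaN.

    Points outside the grid raise ``ValueError`` naming the point index.
    """
    layer = np.asarray(layer, dtype=float)
    if layer.shape != grid.shape:
        raise ValueError("layer does not conform to grid")
    out = np.empty(len(points), dtype=float)
    for i, (x, y) in enumerate(points):
        try:
            r, c = grid.cell_of(x, y)
        except ValueError as exc:
            raise ValueError(f"point {i} at ({x}, {y}) is outside the grid") from exc
        out[i] = layer[r, c]
    return out


# ---------------------------------------------------------------------------
# vector and tabular I/O

def write_range_polygons(path: str | Path, polys: RangePolygons) -> None:
    """Write presence/absence polygons as a GeoJSON FeatureCollection."""
    features = []
    for geom, phen in zip(polys.presence, polys.presence_phenology):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "species": polys.species,
                    "role": "presence",
                    "phenology": phen,
                },
            }
        )
    for geom in polys.absence:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "species": polys.species,
                    "role": "absence",
                    "phenology": polys.phenology,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_range_polygons(path: str | Path) -> RangePolygons:
    """Read a GeoJSON FeatureCollection written by :func:`write_range_polygons`."""
    with open(path) as fh:
        collection = json.load(fh)
    species = None
    presence: list[BaseGeometry] = []
    presence_phen: list[str] = []
    absence: list[BaseGeometry] = []
    phen_labels: set[str] = set()
    for feat in collection.get("features", []):
        props = feat.get("properties", {})
        role = props.get("role")
        species = species or props.get("species")
        geom = shape(feat["geometry"])
        if role == "presence":
            presence.append(geom)
            presence_phen.append(props.get("phenology", "annual"))
            phen_labels.add(props.get("phenology", "annual"))
        elif role == "absence":
            absence.append(geom)
        else:
            raise ValueError(f"{path}: feature with unknown role {role!r}")
    if species is None or not presence:
        raise ValueError(f"{path}: no presence features found")
    if phen_labels == {"breeding", "wintering"}:
        phenology = "breeding+wintering"
    else:
        phenology = next(iter(phen_labels)) if phen_labels else "annual"
    return RangePolygons(
        species=species,
        presence=presence,
        absence=absence,
        phenology=phenology,
        presence_phenology=presence_phen,
    )


def write_occurrences(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("species", "x", "y", "label"):
        if col not in table.columns:
            raise ValueError(f"{path}: occurrences CSV missing column {col!r}")
    return table


def covariate_columns(table: pd.DataFrame) -> list[str]:
    """Names of the covariate columns of an occurrence table."""
    return [c for c in table.columns if c not in ("species", "x", "y", "label")]
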