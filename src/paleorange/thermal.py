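"""Species Thermal Index (STI) and thermal-niche summaries.

The STI of a species is the mean temperature it experiences across its
distribution: temperature values are read at every grid cell whose center
falls inside the species' presence polygons and summarized (min, max, mean,
median, sd).  Niche breadth ("Range") is max - min by definition.

Variable selection follows the phenology of the range data: resident species
use mean annual temperature (bio01) over their full (annual or
breeding + wintering) range; long-distance Afro-Palearctic migrants use the
mean temperature of the warmest quarter (bio10) over the breeding range only,
because their wintering climate is experienced in a different season and
hemisphere.

Statistics are unweighted per-cell values (the range is a census of cells,
not a sample, hence the population sd); a cosine-latitude-weighted mean is
reported alongside as a secondary column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ClimateStack, RangePolygons, cells_in_polygons

__all__ = [
    "ThermalNicheSummary",
    "select_thermal_variable",
    "compute_sti",
    "classify_tolerance",
    "niche_breadth",
    "summaries_to_frame",
]

DEFAULT_COLD_CUTOFF = 6.0  # degrees C on the STI scale


@dataclass
class ThermalNicheSummary:
    """Per-species thermal-niche statistics in degrees C."""

    species: str
    variable_used: str
    polygon_scope: str
    min_temp: float
    max_temp: float
    mean_temp: float  # the STI
    median_temp: float
    range_breadth: float
    sd_temp: float
    weighted_mean_temp: float = float("nan")
    n_cells: int = 0
    tolerance_label: str | None = None
    cold_cutoff: float | None = None

    @property
    def sti(self) -> float:
        return self.mean_temp


def niche_breadth(min_temp: float, max_temp: float) -> float:
    """Thermal niche breadth: max - min (the Table-style "Range" column)."""
    return max_temp - min_temp


def select_thermal_variable(phenology: str, migrant: bool) -> tuple[str, str]:
    """Pick the thermal variable and polygon scope for a species.

    Migrants -> (bio10, breeding polygons only); residents -> (bio01, the
    species' own phenology scope).
    """
    if migrant:
        return "bio10", "breeding"
    return "bio01", phenology


def compute_sti(
    polys: RangePolygons,
    stack: ClimateStack,
    variable: str,
    scope: str | None = None,
) -> ThermalNicheSummary:
    """Thermal-niche summary of one species over its scoped presence polygons.

    Values are taken at every non-nodata cell whose center lies in the scoped
    presence polygons; statistics are unweighted, with the population sd.
    """
    scope = scope or polys.phenology
    presence = polys.presence_for_scope(scope)
    member = cells_in_polygons(stack.grid, presence) & ~stack.nodata_mask
    rows, cols = np.nonzero(member)
    if rows.size == 0:
        raise ValueError(
            f"species {polys.species!r}: no eligible cells in scope {scope!r}"
        )
    vals = stack.layer(variable)[rows, cols]
    lat = stack.grid.cell_center(rows, cols)[1]
    w = np.cos(np.deg2rad(lat))
    vmin, vmax = float(vals.min()), float(vals.max())
    return ThermalNicheSummary(
        species=polys.species,
        variable_used=variable,
        polygon_scope=scope,
        min_temp=vmin,
        max_temp=vmax,
        mean_temp=float(vals.mean()),
        median_temp=float(np.median(vals)),
        range_breadth=niche_breadth(vmin, vmax),
        sd_temp=float(vals.std(ddof=0)),
        weighted_mean_temp=float(np.average(vals, weights=w)),
        n_cells=int(rows.size),
    )


def classify_tolerance(
    summaries: list[ThermalNicheSummary],
    cold_cutoff: float = DEFAULT_COLD_CUTOFF,
) -> list[ThermalNicheSummary]:
    """Label each species cold-dwelling (STI strictly below cutoff) or temperate.

    The cutoff is recorded on every summary; a species exactly at the cutoff
    is temperate (strict inequality).
    """
    if not summaries:
        raise ValueError("at least one summary required")
    for s in summaries:
        s.tolerance_label = "cold-dwelling" if s.sti < cold_cutoff else "temperate"
        s.cold_cutoff = cold_cutoff
    return summaries


def summaries_to_frame(summaries: list[ThermalNicheSummary]) -> pd.DataFrame:
    """Tabulate summaries with the standard output columns."""
    return pd.DataFrame(
        {
            "species": [s.species for s in summaries],
            "scope": [s.polygon_scope for s in summaries],
            "variable": [s.variable_used for s in summaries],
            "min": [s.min_temp for s in summaries],
            "max": [s.max_temp for s in summaries],
            "range": [s.range_breadth for s in summaries],
            "mean": [s.mean_temp for s in summaries],
            "median": [s.median_temp for s in summaries],
            "sd": [s.sd_temp for s in summaries],
            "weighted_mean": [s.weighted_mean_temp for s in summaries],
            "n_cells": [s.n_cells for s in summaries],
            "label": [s.tolerance_label for s in summaries],
        }
    )
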