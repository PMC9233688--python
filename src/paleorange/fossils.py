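"""Fossil-occurrence filtering and hindcast validation.

Georeferenced fossil occurrences with calibrated age intervals (ka BP) are
filtered to a glacial age window — by default strict containment in the
Marine Isotope Stage 2 interval, 29-14 ka BP — and then scored against a
vote-ensemble hindcast: the ensemble vote is read at each fossil's cell, and
a fossil counts as supported when the vote reaches a cutoff.  The supported
fraction is an explicit operationalization of "the fossil record supports
the hindcast", which map-based studies usually judge visually.

Input ages must already be calibrated (the ``calibrated`` CSV column must be
true); radiocarbon calibration itself is outside the package's scope.
Multiple fossils of one species in one grid cell count once by default —
stratigraphic units of a single site are not independent spatial evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import extract_at_points
from .hindcast import EnsembleMap

__all__ = [
    "FossilOccurrence",
    "FossilSupportReport",
    "read_fossils",
    "write_fossils",
    "filter_age_window",
    "score_fossil_support",
    "MIS2_WINDOW_KA",
]

MIS2_WINDOW_KA = (29.0, 14.0)  # (old, young) bounds in ka BP


@dataclass(frozen=True)
class FossilOccurrence:
    """One georeferenced fossil record with a calibrated age interval."""

    site_name: str
    species: str
    x: float
    y: float
    age_min_ka: float
    age_max_ka: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.age_min_ka > self.age_max_ka:
            raise ValueError(
                f"{self.site_name}: age_min {self.age_min_ka} > age_max {self.age_max_ka}"
            )


@dataclass
class FossilSupportReport:
    """Per-fossil ensemble votes and per-species support summary."""

    records: pd.DataFrame  # site_name, species, x, y, vote, status
    summary: pd.DataFrame  # species, n_fossils, n_scored, median_vote, fraction_supported
    vote_cutoff: int
    n_input: int
    n_nodata: int
    n_out_of_grid: int


def read_fossils(path: str | Path) -> list[FossilOccurrence]:
    """Read the fossil CSV schema; rejects uncalibrated ages."""
    table = pd.read_csv(path)
    required = {"site_name", "species", "x", "y", "age_min_ka", "age_max_ka", "calibrated"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: fossil CSV missing columns {sorted(missing)}")
    bad = table[~table["calibrated"].astype(bool)]
    if len(bad):
        raise ValueError(
            f"{path}: {len(bad)} fossil record(s) flagged as uncalibrated; "
            "ages must be calibrated ka BP"
        )
    return [
        FossilOccurrence(
            site_name=str(r.site_name),
            species=str(r.species),
            x=float(r.x),
            y=float(r.y),
            age_min_ka=float(r.age_min_ka),
            age_max_ka=float(r.age_max_ka),
            source=str(getattr(r, "source", "")),
        )
        for r in table.itertuples()
    ]


def write_fossils(path: str | Path, fossils: list[FossilOccurrence]) -> None:
    pd.DataFrame(
        {
            "site_name": [f.site_name for f in fossils],
            "species": [f.species for f in fossils],
            "x": [f.x for f in fossils],
            "y": [f.y for f in fossils],
            "age_min_ka": [f.age_min_ka for f in fossils],
            "age_max_ka": [f.age_max_ka for f in fossils],
            "calibrated": True,
            "source": [f.source for f in fossils],
        }
    ).to_csv(path, index=False)


def filter_age_window(
    fossils: list[FossilOccurrence],
    window: tuple[float, float] = MIS2_WINDOW_KA,
    containment: bool = True,
) -> list[FossilOccurrence]:
    """Keep fossils reliably dated inside an (old, young) ka window.

    The default rule requires the whole age interval to lie within the
    window; ``containment=False`` relaxes to interval overlap.
    """
    old, young = window
    if old <= young:
        raise ValueError(f"window must be (old, young) with old > young, got {window}")
    if containment:
        return [f for f in fossils if young <= f.age_min_ka and f.age_max_ka <= old]
    return [f for f in fossils if f.age_min_ka <= old and f.age_max_ka >= young]


def score_fossil_support(
    ensemble: EnsembleMap,
    fossils: list[FossilOccurrence],
    vote_cutoff: int,
    dedupe_cells: bool = True,
) -> FossilSupportReport:
    """Score fossils against an ensemble hindcast.

    Reads the vote at each fossil's cell; a fossil is supported when the vote
    reaches ``vote_cutoff``.  Fossils outside the grid or on nodata cells are
    flagged, excluded from fractions and counted separately.  With
    ``dedupe_cells`` (default), multiple fossils of one species in one cell
    count once toward the supported fraction.
    """
    if not 1 <= vote_cutoff <= ensemble.K:
        raise ValueError(f"vote_cutoff must lie in [1, {ensemble.K}]")
    if not fossils:
        warnings.warn("empty fossil list: nothing to score", stacklevel=2)
        empty = pd.DataFrame(
            columns=["site_name", "species", "x", "y", "cell", "vote", "status"]
        )
        summary = pd.DataFrame(
            columns=["species", "n_fossils", "n_scored", "median_vote", "fraction_supported"]
        )
        return FossilSupportReport(empty, summary, vote_cutoff, 0, 0, 0)

    votes_layer = np.where(
        ensemble.valid_mask, ensemble.votes.astype(float), np.nan
    )
    rows = []
    for f in fossils:
        try:
            r, c = ensemble.grid.cell_of(f.x, f.y)
        except ValueError:
            rows.append((f.site_name, f.species, f.x, f.y, None, np.nan, "out_of_grid"))
            continue
        vote = extract_at_points(votes_layer, ensemble.grid, [(f.x, f.y)])[0]
        status = "nodata" if np.isnan(vote) else "scored"
        rows.append((f.site_name, f.species, f.x, f.y, (r, c), vote, status))
    records = pd.DataFrame(
        rows, columns=["site_name", "species", "x", "y", "cell", "vote", "status"]
    )

    summaries = []
    for species, grp in records.groupby("species", sort=True):
        scored = grp[grp["status"] == "scored"]
        if dedupe_cells:
            scored = scored.drop_duplicates(subset=["cell"])
        n_scored = len(scored)
        supported = (scored["vote"] >= vote_cutoff).sum()
        summaries.append(
            {
                "species": species,
                "n_fossils": len(grp),
                "n_scored": n_scored,
                "median_vote": float(scored["vote"].median()) if n_scored else np.nan,
                "fraction_supported": supported / n_scored if n_scored else np.nan,
            }
        )
    summary = pd.DataFrame(summaries)
    return FossilSupportReport(
        records=records,
        summary=summary,
        vote_cutoff=vote_cutoff,
        n_input=len(fossils),
        n_nodata=int((records["status"] == "nodata").sum()),
        n_out_of_grid=int((records["status"] == "out_of_grid").sum()),
    )
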