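"""Scenario projection, vote-ensemble maps, range size and range change.

A fitted suitability model is projected onto the present scenario and onto K
alternative past scenarios (one per general circulation model).  Each
continuous suitability map is binarized at a threshold tau and the K binary
maps are summed cell-wise into a vote ensemble: the value of a cell counts
how many of the K members predict presence there (0..K).  Range size is then
the number (or cosine-latitude-weighted area) of cells whose vote reaches a
cutoff, and net range change compares past against present range at the same
cutoff.

The binarization threshold is not dictated by the vote-map construction, so
it is always recorded in the ensemble; the default is tau = 0.5, the natural
decision point on the Bernoulli probability scale, with a max-TSS alternative
(threshold maximizing sensitivity + specificity on the calibration data) for
prevalence-skewed cases.  Because no single vote cutoff is privileged either,
a sweep over all cutoffs 1..K is the primary range-size product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSpec

__all__ = [
    "EnsembleMap",
    "RangeMetrics",
    "binarize",
    "ensemble_vote",
    "mean_suitability",
    "range_metrics",
    "net_range_change",
    "range_sweep",
    "max_tss_threshold",
    "KM_PER_DEGREE",
]

KM_PER_DEGREE = 111.32  # spherical approximation at the equator


@dataclass
class EnsembleMap:
    """Integer vote map: how many of K member scenarios predict presence."""

    grid: GridSpec
    votes: np.ndarray  # int grid, -1 on nodata
    K: int
    member_ids: list[str]
    threshold: float

    NODATA = -1

    def __post_init__(self) -> None:
        v = self.votes[self.votes != self.NODATA]
        if v.size and (v.min() < 0 or v.max() > self.K):
            raise ValueError("votes must lie in [0, K]")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.votes != self.NODATA


@dataclass
class RangeMetrics:
    """Range size of one ensemble at one vote cutoff."""

    range_cells: int
    range_km2: float
    vote_cutoff: int
    K: int
    scenario_id: str = ""


def binarize(suitability: np.ndarray, tau: float) -> np.ndarray:
    """Binary presence map: cell predicted present iff suitability >= tau.

    Nodata (NaN) propagates as NaN in a float array so ensemble summation can
    keep masking consistent.  tau must lie strictly inside (0, 1).
    """
    if not 0 < tau < 1:
        raise ValueError(f"binarization threshold must lie in (0, 1), got {tau}")
    s = np.asarray(suitability, dtype=float)
    if np.nanmin(s) < 0 or np.nanmax(s) > 1:
        raise ValueError("suitability values must lie in [0, 1]")
    out = np.where(np.isnan(s), np.nan, (s >= tau).astype(float))
    return out


def ensemble_vote(
    member_binaries: list[np.ndarray],
    grid: GridSpec,
    member_ids: list[str] | None = None,
    threshold: float = 0.5,
) -> EnsembleMap:
    """Sum K binary member maps into an integer vote map.

    Cells that are nodata in any member are nodata in the ensemble.
    """
    if not member_binaries:
        raise ValueError("at least one ensemble member required")
    shapes = {m.shape for m in member_binaries}
    if shapes != {grid.shape}:
        raise ValueError(f"member lattice mismatch: shapes {shapes} vs grid {grid.shape}")
    stackarr = np.stack([np.asarray(m, dtype=float) for m in member_binaries])
    nodata = np.isnan(stackarr).any(axis=0)
    votes = np.where(nodata, EnsembleMap.NODATA, np.nansum(stackarr, axis=0)).astype(int)
    K = len(member_binaries)
    ids = member_ids if member_ids is not None else [f"member{i + 1}" for i in range(K)]
    return EnsembleMap(grid=grid, votes=votes, K=K, member_ids=list(ids), threshold=threshold)


def mean_suitability(member_suitabilities: list[np.ndarray]) -> np.ndarray:
    """Secondary continuous ensemble: cell-wise mean suitability across members."""
    return np.mean(np.stack(member_suitabilities), axis=0)


def _cell_areas_km2(grid: GridSpec) -> np.ndarray:
    """Cosine-latitude-weighted cell areas, one value per row."""
    rows = np.arange(grid.n_rows)
    _, lat = grid.cell_center(rows, np.zeros_like(rows))
    return (grid.cell_size * KM_PER_DEGREE) ** 2 * np.cos(np.deg2rad(lat))


def range_metrics(ensemble: EnsembleMap, vote_cutoff: int) -> RangeMetrics:
    """Cells (and km^2) whose vote count reaches the cutoff."""
    if not 1 <= vote_cutoff <= ensemble.K:
        raise ValueError(
            f"vote_cutoff must lie in [1, {ensemble.K}], got {vote_cutoff}"
        )
    member = (ensemble.votes >= vote_cutoff) & ensemble.valid_mask
    areas = _cell_areas_km2(ensemble.grid)
    km2 = float((member.sum(axis=1) * areas).sum())
    return RangeMetrics(
        range_cells=int(member.sum()),
        range_km2=km2,
        vote_cutoff=vote_cutoff,
        K=ensemble.K,
    )


def net_range_change(present: RangeMetrics, past: RangeMetrics) -> dict[str, float]:
    """Signed fractional change (past - present) / present in area and cells."""
    if present.vote_cutoff != past.vote_cutoff:
        raise ValueError("range metrics must use the same vote cutoff")
    if present.range_cells == 0:
        raise ZeroDivisionError(
            "present range is empty: net range change is undefined"
        )
    return {
        "net_change_area": (past.range_km2 - present.range_km2) / present.range_km2,
        "net_change_cells": (past.range_cells - present.range_cells)
        / present.range_cells,
    }


def range_sweep(
    present: EnsembleMap, past: EnsembleMap, species: str = ""
) -> pd.DataFrame:
    """Range size and net change at every vote cutoff 1..K (the primary table)."""
    if present.K != past.K:
        raise ValueError("ensembles must have the same number of members")
    rows = []
    for cutoff in range(1, present.K + 1):
        m_now = range_metrics(present, cutoff)
        m_past = range_metrics(past, cutoff)
        change = (
            net_range_change(m_now, m_past)
            if m_now.range_cells > 0
            else {"net_change_area": np.nan, "net_change_cells": np.nan}
        )
        rows.append(
            {
                "species": species,
                "vote_cutoff": cutoff,
                "present_cells": m_now.range_cells,
                "present_km2": m_now.range_km2,
                "past_cells": m_past.range_cells,
                "past_km2": m_past.range_km2,
                **change,
            }
        )
    return pd.DataFrame(rows)


def max_tss_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """Threshold maximizing the true skill statistic (sensitivity + specificity - 1).

    Candidates are midpoints between consecutive distinct sorted scores; ties
    resolve to the lowest threshold.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(s, kind="stable")
    ss, ys = s[order], y[order]
    n1, n0 = ys.sum(), (1 - ys).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    distinct = np.nonzero(np.diff(ss) > 0)[0]
    best_tau, best_tss = 0.5, -np.inf
    for k in distinct:
        tau = 0.5 * (ss[k] + ss[k + 1])
        pred = s >= tau
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_tau = tss, float(tau)
    return best_tau
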