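"""Synthetic climate scenarios, virtual species, range polygons and fossils.

The generator reproduces the statistical structure the hindcasting analysis
assumes, so every downstream stage can be exercised end to end without any
external download:

* spatially autocorrelated multi-variable climate fields with a north-south
  temperature gradient (row 0 is the cold, northern edge);
* K alternative past scenarios that share a coherent cooling offset on the
  temperature-like variables plus independent per-scenario noise, emulating
  the spread among general circulation models;
* virtual species whose occupancy is a thresholded Gaussian (unimodal)
  response to one or two climate variables;
* presence polygons dissolved from true occupancy and absence polygons as a
  surrounding buffer ring, mirroring how hand-drawn pseudo-absence polygons
  closely surround a published range map;
* fossil points drawn from past-scenario true occupancy with a configurable
  false-location rate standing in for taphonomic and georeferencing noise.

No attempt is made to imitate real GCM physics, the covariance structure of
real bioclim variables, or continental geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import unary_union
from shapely.geometry import box

from .grids import ClimateStack, GridSpec, RangePolygons

__all__ = [
    "NicheTruth",
    "WorldConfig",
    "generate_climate",
    "gcm_realizations",
    "realize_species",
    "polygons_from_occupancy",
    "sample_fossils",
]


@dataclass(frozen=True)
class NicheTruth:
    """True climatic niche of a virtual species.

    Suitability is a product of Gaussian responses over the driver variables,
    ``s(x) = exp(-sum_v (x_v - mu_v)^2 / (2 sigma_v^2))``; the species
    occupies the cells whose suitability exceeds the ``1 - q`` quantile, so a
    fraction ``q`` of the (non-nodata) world is occupied.
    """

    species: str
    driver_variables: tuple[str, ...]
    optimum: tuple[float, ...]  # degrees C per driver
    breadth: tuple[float, ...]  # sigma, degrees C per driver
    occupancy_quantile: float = 0.1

    def __post_init__(self) -> None:
        if not 1 <= len(self.driver_variables) <= 2:
            raise ValueError("1 or 2 driver variables required")
        if len(self.optimum) != len(self.driver_variables) or len(self.breadth) != len(
            self.driver_variables
        ):
            raise ValueError("optimum/breadth must match driver_variables in length")
        if any(s <= 0 for s in self.breadth):
            raise ValueError("breadth sigma must be positive")
        if not 0 < self.occupancy_quantile < 1:
            raise ValueError("occupancy_quantile must lie in (0, 1)")

    def suitability(self, stack: ClimateStack) -> np.ndarray:
        """True suitability s(x) on the stack's lattice (NaN on nodata)."""
        s = np.zeros(stack.grid.shape)
        for var, mu, sigma in zip(self.driver_variables, self.optimum, self.breadth):
            s += (stack.layer(var) - mu) ** 2 / (2.0 * sigma**2)
        out = np.exp(-s)
        out[stack.nodata_mask] = np.nan
        return out


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    Defaults mirror the study conditions the pipeline targets: 19 bioclim-like
    variables, 8 past-scenario realizations, a 6 degree mean cooling from the
    present to the past on the temperature-like variables (variables 1-11 by
    bioclim convention), and mild per-scenario noise standing in for GCM
    disagreement.
    """

    grid: GridSpec
    n_variables: int = 19
    n_scenarios: int = 8
    cooling_offset: float = -6.0  # degrees C applied to temperature-like vars
    scenario_noise_sd: float = 1.0  # degrees C, per past scenario
    gradient_amplitude: float = 30.0  # degrees C north-south contrast
    field_noise_sd: float = 3.0  # degrees C, spatial texture of each field
    autocorrelation_length: float = 5.0  # cells
    temperature_like: tuple[int, ...] = tuple(range(11))  # indices into variables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scenarios < 1:
            raise ValueError("need at least one past scenario")
        if self.scenario_noise_sd < 0 or self.field_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.autocorrelation_length < 1:
            raise ValueError("autocorrelation_length must be >= 1 cell")

    @property
    def variable_names(self) -> list[str]:
        return [f"bio{i + 1:02d}" for i in range(self.n_variables)]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], length: float, sd: float) -> np.ndarray:
    """Gaussian-correlated random field with (approximately) the given sd.

    White noise is convolved with a Gaussian kernel truncated at three
    correlation lengths, then rescaled to restore the target marginal sd.
    """
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=length, truncate=3.0, mode="reflect")
    s = smooth.std()
    if s == 0:  # degenerate 1x1 grid
        return np.zeros(shape)
    return smooth * (sd / s)


def generate_climate(config: WorldConfig) -> tuple[ClimateStack, list[ClimateStack]]:
    """Generate the present stack and K past-scenario stacks.

    Every variable is a latitudinal gradient plus an autocorrelated noise
    field; each past scenario adds the cooling offset on temperature-like
    variables and an independent autocorrelated perturbation of sd
    ``scenario_noise_sd`` on every variable.  Fully deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    names = config.variable_names
    temp_vars = {names[i] for i in config.temperature_like if i < len(names)}

    # north-south gradient: row 0 (north) coldest, bottom row warmest
    rows = np.arange(grid.n_rows, dtype=float)
    if grid.n_rows > 1:
        ramp = rows / (grid.n_rows - 1)
    else:
        ramp = np.full(1, 0.5)
    gradient = np.tile((ramp * config.gradient_amplitude)[:, None], (1, grid.n_cols))

    present_values: dict[str, np.ndarray] = {}
    for name in names:
        noise = _smooth_field(rng, grid.shape, config.autocorrelation_length, config.field_noise_sd)
        present_values[name] = gradient + noise
    mask = np.zeros(grid.shape, dtype=bool)
    present = ClimateStack(
        grid=grid, variables=list(names), values=present_values, nodata_mask=mask,
        scenario_id="present",
    )

    past: list[ClimateStack] = []
    for k in range(config.n_scenarios):
        values = {}
        for name in names:
            layer = present_values[name].copy()
            if name in temp_vars:
                layer = layer + config.cooling_offset
            layer = layer + _smooth_field(
                rng, grid.shape, config.autocorrelation_length, config.scenario_noise_sd
            )
            values[name] = layer
        past.append(
            ClimateStack(
                grid=grid, variables=list(names), values=values,
                nodata_mask=mask.copy(), scenario_id=f"past/gcm{k + 1:02d}",
            )
        )
    return present, past


def gcm_realizations(
    stack: ClimateStack, config: WorldConfig, seed: int
) -> list[ClimateStack]:
    """K same-epoch realizations of one scenario (inter-GCM spread, no offset).

    Each member is the input stack plus an independent autocorrelated
    perturbation of sd ``scenario_noise_sd`` on every variable — the
    present-day counterpart of the past-scenario spread, mirroring how a GCM
    ensemble also disagrees about the present climate.  With
    ``scenario_noise_sd=0`` all members equal the input.
    """
    rng = np.random.default_rng(seed)
    members = []
    for k in range(config.n_scenarios):
        values = {
            name: stack.values[name]
            + _smooth_field(
                rng, config.grid.shape, config.autocorrelation_length, config.scenario_noise_sd
            )
            for name in stack.variables
        }
        members.append(
            ClimateStack(
                grid=config.grid, variables=list(stack.variables), values=values,
                nodata_mask=stack.nodata_mask.copy(),
                scenario_id=f"{stack.scenario_id}/gcm{k + 1:02d}",
            )
        )
    return members


def realize_species(truth: NicheTruth, stack: ClimateStack) -> np.ndarray:
    """True occupancy: suitability above its ``1 - q`` quantile.

    Returns a boolean grid; nodata cells are never occupied.  Raises on a
    degenerate (constant) suitability surface, for which the quantile rule
    is meaningless.
    """
    s = truth.suitability(stack)
    valid = ~stack.nodata_mask
    sv = s[valid]
    if np.nanmax(sv) == np.nanmin(sv):
        raise ValueError("degenerate suitability surface: all cells equal")
    threshold = np.quantile(sv, 1.0 - truth.occupancy_quantile)
    occ = np.zeros(stack.grid.shape, dtype=bool)
    occ[valid] = s[valid] >= threshold
    return occ


def polygons_from_occupancy(
    occupancy: np.ndarray,
    grid: GridSpec,
    buffer_cells: int = 2,
    species: str = "virtual",
    phenology: str = "annual",
) -> RangePolygons:
    """Dissolve occupied cells into presence polygons; ring buffer = absence.

    The absence set is the morphological dilation of the occupancy (square
    8-neighbour structuring element, ``buffer_cells`` iterations) minus the
    occupancy itself — a ring of pseudo-absence cells closely surrounding the
    range, as hand-drawn absence polygons would.  ``buffer_cells=0`` yields an
    empty absence set with a warning.
    """
    occupancy = np.asarray(occupancy, dtype=bool)
    if occupancy.shape != grid.shape:
        raise ValueError("occupancy does not conform to grid")
    if not occupancy.any():
        raise ValueError("no occupied cells: cannot build presence polygons")

    def cells_to_polys(member: np.ndarray):
        rows, cols = np.nonzero(member)
        cs = grid.cell_size
        boxes = [
            box(
                grid.x_min + c * cs,
                grid.y_max - (r + 1) * cs,
                grid.x_min + (c + 1) * cs,
                grid.y_max - r * cs,
            )
            for r, c in zip(rows, cols)
        ]
        merged = unary_union(boxes)
        if merged.geom_type == "Polygon":
            return [merged]
        return list(merged.geoms)

    presence = cells_to_polys(occupancy)
    if buffer_cells == 0:
        warnings.warn("buffer_cells=0: absence polygon set is empty", stacklevel=2)
        absence = []
    else:
        ring = ndimage.binary_dilation(
            occupancy, structure=np.ones((3, 3), dtype=bool), iterations=buffer_cells
        ) & ~occupancy
        absence = cells_to_polys(ring) if ring.any() else []
    return RangePolygons(
        species=species, presence=presence, absence=absence, phenology=phenology
    )


def sample_fossils(
    occupancy_past: np.ndarray,
    grid: GridSpec,
    n: int,
    misplacement_rate: float,
    seed: int,
    species: str = "virtual",
    age_window_ka: tuple[float, float] = (29.0, 14.0),
) -> pd.DataFrame:
    """Draw synthetic fossil localities from past true occupancy.

    Each fossil sits at the center of a uniformly chosen occupied cell with
    probability ``1 - misplacement_rate``, otherwise at a uniformly chosen
    unoccupied cell (taphonomic / georeferencing noise).  Cells are drawn
    without replacement within each group, mirroring distinct localities.
    Calibrated age intervals are drawn uniformly inside the ka window.
    Returns the fossil CSV schema used throughout the package.
    """
    if not 0 <= misplacement_rate <= 1:
        raise ValueError("misplacement_rate must lie in [0, 1]")
    occupancy_past = np.asarray(occupancy_past, dtype=bool)
    rng = np.random.default_rng(seed)
    occ_rows, occ_cols = np.nonzero(occupancy_past)
    un_rows, un_cols = np.nonzero(~occupancy_past)
    misplaced = rng.random(n) < misplacement_rate
    n_true, n_false = int((~misplaced).sum()), int(misplaced.sum())
    if n_true > len(occ_rows):
        raise ValueError(
            f"requested {n_true} on-range fossils but only {len(occ_rows)} occupied cells"
        )
    if n_false > len(un_rows):
        raise ValueError(
            f"requested {n_false} off-range fossils but only {len(un_rows)} unoccupied cells"
        )
    pick_true = rng.choice(len(occ_rows), size=n_true, replace=False)
    pick_false = rng.choice(len(un_rows), size=n_false, replace=False)
    rows = np.concatenate([occ_rows[pick_true], un_rows[pick_false]])
    cols = np.concatenate([occ_cols[pick_true], un_cols[pick_false]])
    on_truth = np.concatenate([np.ones(n_true, bool), np.zeros(n_false, bool)])
    order = rng.permutation(n)
    rows, cols, on_truth = rows[order], cols[order], on_truth[order]
    x, y = grid.cell_center(rows, cols)

    old, young = age_window_ka
    if old <= young:
        raise ValueError("age window must be (old, young) with old > young")
    # keep the interval strictly inside the window so the age filter retains it
    mid = rng.uniform(young + 1.0, old - 1.0, size=n)
    half = rng.uniform(0.0, 1.0, size=n)
    return pd.DataFrame(
        {
            "site_name": [f"synthetic_site_{i + 1:03d}" for i in range(n)],
            "species": species,
            "x": x,
            "y": y,
            "age_min_ka": mid - half,
            "age_max_ka": mid + half,
            "calibrated": True,
            "source": "synthetic",
            "on_truth": on_truth,
        }
    )
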