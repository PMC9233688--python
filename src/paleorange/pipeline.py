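"""End-to-end pipeline: world -> samples -> model -> hindcast -> reports.

One declarative config drives the whole analysis.  In *synthetic* mode the
pipeline generates its own world (climate scenarios, virtual species, range
polygons, fossils); in *data* mode it reads ASCII-grid rasters, GeoJSON
polygons and fossil CSVs from disk.  A single seed in the config is expanded
into per-stage seeds (seed + CRC32 of the stage tag, kept below 2^31) so
every stage is independently reproducible.

Per species the pipeline emits: the sampled occurrence table, the fitted
model (JSON), a fit report, present and past vote-ensemble maps, the
range-size sweep over all vote cutoffs, a thermal-niche summary and a
fossil-support report, plus a run manifest (config hash, seed, versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brt import fit_brt, predict_suitability, save_model, variable_importance
from .fossils import MIS2_WINDOW_KA, filter_age_window, read_fossils, score_fossil_support
from .grids import (
    ClimateStack,
    GridSpec,
    read_range_polygons,
    read_raster_stack,
    write_ascii_raster,
    write_occurrences,
    write_range_polygons,
    write_raster_stack,
)
from .hindcast import binarize, ensemble_vote, mean_suitability, range_sweep
from .synthetic import (
    NicheTruth,
    WorldConfig,
    gcm_realizations,
    generate_climate,
    polygons_from_occupancy,
    realize_species,
    sample_fossils,
)
from .thermal import classify_tolerance, compute_sti, select_thermal_variable, summaries_to_frame

logger = logging.getLogger("paleorange")

__all__ = ["SpeciesConfig", "PipelineConfig", "run_pipeline", "default_synthetic_config"]


def stage_seed(seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (seed + zlib.crc32(tag.encode())) % (2**31 - 1)


@dataclass
class SpeciesConfig:
    """One species in the run: either a synthetic truth or file paths."""

    name: str
    migrant: bool = False
    phenology: str = "annual"
    # synthetic mode
    driver_variables: tuple[str, ...] = ("bio01",)
    optimum: tuple[float, ...] = (10.0,)
    breadth: tuple[float, ...] = (2.0,)
    occupancy_quantile: float = 0.08
    buffer_cells: int = 3
    n_fossils: int = 40
    misplacement_rate: float = 0.1
    # data mode
    polygons_path: str | None = None
    fossils_path: str | None = None

    def truth(self) -> NicheTruth:
        return NicheTruth(
            species=self.name,
            driver_variables=tuple(self.driver_variables),
            optimum=tuple(self.optimum),
            breadth=tuple(self.breadth),
            occupancy_quantile=self.occupancy_quantile,
        )


@dataclass
class PipelineConfig:
    """Declarative description of a full run."""

    mode: str = "synthetic"  # "synthetic" | "data"
    world: WorldConfig | None = None
    species: list[SpeciesConfig] = field(default_factory=list)
    # data-mode inputs: {scenario_id: [raster paths]} plus shared variable names
    raster_paths: dict[str, list[str]] = field(default_factory=dict)
    variable_names: list[str] = field(default_factory=list)
    # hyperparameters (reference settings: lr 0.1, tc 1, bag 0.5)
    lr: float = 0.1
    tree_complexity: int = 1
    bag_fraction: float = 0.5
    max_trees: int = 1000
    n_presence: int = 300
    n_absence: int = 300
    tau: float = 0.5
    vote_cutoff: int | None = None  # default: majority of K
    cold_cutoff: float = 6.0
    age_window: tuple[float, float] = MIS2_WINDOW_KA
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.tau < 1:
            raise ValueError(f"binarization threshold tau={self.tau} outside (0, 1)")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction outside (0, 1]")
        if not 0 <= self.lr <= 1:
            raise ValueError("learning rate outside [0, 1]")
        if self.max_trees < 1 or self.n_presence < 1 or self.n_absence < 1:
            raise ValueError("max_trees and sample sizes must be positive")
        if not self.species:
            raise ValueError("at least one species required")
        if self.mode == "synthetic" and self.world is None:
            raise ValueError("synthetic mode requires a world config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        world = None
        if "world" in doc:
            w = dict(doc.pop("world"))
            grid = GridSpec(**w.pop("grid"))
            for key in ("temperature_like",):
                if key in w:
                    w[key] = tuple(w[key])
            world = WorldConfig(grid=grid, **w)
        species = [
            SpeciesConfig(
                **{
                    k: tuple(v) if k in ("driver_variables", "optimum", "breadth") else v
                    for k, v in sp.items()
                }
            )
            for sp in doc.pop("species", [])
        ]
        if "age_window" in doc:
            doc["age_window"] = tuple(doc["age_window"])
        cfg = cls(world=world, species=species, **doc)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_synthetic_config(seed: int = 0) -> PipelineConfig:
    """The packaged synthetic experiment: one cold-dwelling, one temperate species.

    A 90x90 half-degree world spanning 20-65 degrees latitude with a 30 degree
    north-south temperature contrast, K = 8 past realizations cooled by 6
    degrees with 1 degree per-scenario noise.  The cold species' optimum sits
    near the cold (northern) edge of the present climate; the temperate
    species' optimum sits mid-gradient.
    """
    grid = GridSpec(n_rows=90, n_cols=90, x_min=0.0, y_min=20.0, cell_size=0.5)
    world = WorldConfig(grid=grid, seed=stage_seed(seed, "world"))
    # the cold-dwelling default is a glacial relict: its thermal optimum lies
    # below the present climate minimum, so its present range is the coldest
    # sliver of the landscape and cooling opens new habitat
    species = [
        SpeciesConfig(
            name="cold_dwelling",
            driver_variables=("bio01",),
            optimum=(-8.0,),
            breadth=(3.0,),
            occupancy_quantile=0.08,
        ),
        SpeciesConfig(
            name="temperate",
            driver_variables=("bio01",),
            optimum=(16.0,),
            breadth=(2.0,),
            occupancy_quantile=0.08,
        ),
    ]
    return PipelineConfig(mode="synthetic", world=world, species=species, seed=seed)


def _load_data_stacks(config: PipelineConfig) -> tuple[ClimateStack, list[ClimateStack]]:
    if "present" not in config.raster_paths:
        raise ValueError("data mode requires a 'present' raster scenario")
    present = read_raster_stack(
        config.raster_paths["present"], config.variable_names, scenario_id="present"
    )
    past = [
        read_raster_stack(paths, config.variable_names, scenario_id=sid)
        for sid, paths in config.raster_paths.items()
        if sid != "present"
    ]
    if not past:
        raise ValueError("data mode requires at least one past scenario")
    return present, past


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full analysis; returns the output directory.

    Outputs are deterministic under (config, seed): rerunning with the same
    config writes byte-identical CSVs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        present, past = generate_climate(config.world)
        # the GCM ensemble also spreads about the present climate, so the
        # present-day ensemble gets K realizations of its own
        present_members = gcm_realizations(
            present, config.world, stage_seed(config.seed, "present-members")
        )
        write_raster_stack(outdir / "climate" / "present", present)
    else:
        present, past = _load_data_stacks(config)
        present_members = [present] * len(past)
    K = len(past)
    vote_cutoff = config.vote_cutoff or (K // 2 + 1)  # majority of K
    logger.info("world ready: grid=%s K=%d vote_cutoff=%d", present.grid.shape, K, vote_cutoff)

    sweep_frames, summaries, fossil_frames = [], [], []
    manifest_outputs: list[str] = []
    for sp in config.species:
        spdir = outdir / sp.name
        spdir.mkdir(parents=True, exist_ok=True)
        try:
            result = _run_species(
                sp, config, present, present_members, past, K, vote_cutoff, spdir
            )
        except Exception as exc:
            (spdir / "INCOMPLETE").write_text(f"stage failure: {exc}\n")
            raise RuntimeError(f"species {sp.name!r}: {exc}") from exc
        sweep_frames.append(result["sweep"])
        summaries.append(result["thermal"])
        if result["fossil_summary"] is not None:
            fossil_frames.append(result["fossil_summary"])
        manifest_outputs.extend(result["outputs"])

    classify_tolerance(summaries, config.cold_cutoff)
    thermal_table = summaries_to_frame(summaries)
    thermal_table.to_csv(outdir / "thermal_niche.csv", index=False)
    pd.concat(sweep_frames, ignore_index=True).to_csv(
        outdir / "range_sweep.csv", index=False
    )
    if fossil_frames:
        pd.concat(fossil_frames, ignore_index=True).to_csv(
            outdir / "fossil_support.csv", index=False
        )

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "n_scenarios": K,
        "vote_cutoff": vote_cutoff,
        "tau": config.tau,
        "species": [sp.name for sp in config.species],
        "outputs": sorted(manifest_outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def _run_species(
    sp: SpeciesConfig,
    config: PipelineConfig,
    present: ClimateStack,
    present_members: list[ClimateStack],
    past: list[ClimateStack],
    K: int,
    vote_cutoff: int,
    spdir: Path,
) -> dict:
    from .grids import sample_occurrences  # local to avoid cycle at import time

    outputs = []
    grid = present.grid

    # --- range polygons (truth-derived in synthetic mode) -------------------
    if config.mode == "synthetic":
        truth = sp.truth()
        occ_present = realize_species(truth, present)
        polys = polygons_from_occupancy(
            occ_present, grid, buffer_cells=sp.buffer_cells,
            species=sp.name, phenology=sp.phenology,
        )
        write_range_polygons(spdir / "range_polygons.geojson", polys)
        outputs.append(f"{sp.name}/range_polygons.geojson")
    else:
        if sp.polygons_path is None:
            raise ValueError("data mode requires polygons_path per species")
        polys = read_range_polygons(sp.polygons_path)

    # --- sample and fit ------------------------------------------------------
    table = sample_occurrences(
        present, polys, config.n_presence, config.n_absence,
        seed=stage_seed(config.seed, f"sample/{sp.name}"),
    )
    write_occurrences(spdir / "occurrences.csv", table)
    model, report = fit_brt(
        table,
        lr=config.lr,
        tree_complexity=config.tree_complexity,
        bag_fraction=config.bag_fraction,
        max_trees=config.max_trees,
        seed=stage_seed(config.seed, f"fit/{sp.name}"),
    )
    save_model(spdir / "model.json", model)
    fit_doc = {
        "auc_train": report.auc_train,
        "auc_test": report.auc_test,
        "n_trees_used": report.n_trees_used,
        "still_improving": report.still_improving,
        "variable_importance": variable_importance(model),
    }
    (spdir / "fit_report.json").write_text(json.dumps(fit_doc, indent=2) + "\n")
    outputs += [f"{sp.name}/occurrences.csv", f"{sp.name}/model.json", f"{sp.name}/fit_report.json"]
    logger.info(
        "%s: fitted %d trees, AUC train %.3f test %.3f",
        sp.name, report.n_trees_used, report.auc_train, report.auc_test,
    )

    # --- project and ensemble ------------------------------------------------
    present_suits = [predict_suitability(model, m) for m in present_members]
    present_bins = [binarize(s, config.tau) for s in present_suits]
    present_ens = ensemble_vote(
        present_bins, grid, [m.scenario_id for m in present_members], config.tau
    )
    member_suits = [predict_suitability(model, pst) for pst in past]
    member_bins = [binarize(s, config.tau) for s in member_suits]
    past_ens = ensemble_vote(member_bins, grid, [p.scenario_id for p in past], config.tau)
    votes = past_ens.votes.astype(float)
    votes[~past_ens.valid_mask] = np.nan
    write_ascii_raster(spdir / "ensemble_past.asc", grid, votes, np.isnan(votes))
    write_ascii_raster(
        spdir / "ensemble_present.asc", grid,
        np.where(present_ens.valid_mask, present_ens.votes, np.nan),
        ~present_ens.valid_mask,
    )
    write_ascii_raster(
        spdir / "mean_suitability_past.asc", grid, mean_suitability(member_suits)
    )
    outputs += [
        f"{sp.name}/ensemble_past.asc",
        f"{sp.name}/ensemble_present.asc",
        f"{sp.name}/mean_suitability_past.asc",
    ]

    sweep = range_sweep(present_ens, past_ens, species=sp.name)
    logger.info(
        "%s: range %d -> %d cells at cutoff %d (net change %+.2f)",
        sp.name,
        sweep.loc[sweep.vote_cutoff == vote_cutoff, "present_cells"].iat[0],
        sweep.loc[sweep.vote_cutoff == vote_cutoff, "past_cells"].iat[0],
        vote_cutoff,
        sweep.loc[sweep.vote_cutoff == vote_cutoff, "net_change_cells"].iat[0],
    )

    # --- thermal niche --------------------------------------------------------
    variable, scope = select_thermal_variable(sp.phenology, sp.migrant)
    thermal = compute_sti(polys, present, variable, scope)

    # --- fossils --------------------------------------------------------------
    fossil_summary = None
    if config.mode == "synthetic":
        # true past occupancy from the ensemble-mean past climate
        mean_past_values = {
            v: np.mean([p.values[v] for p in past], axis=0) for v in present.variables
        }
        mean_past = ClimateStack(
            grid=grid, variables=list(present.variables), values=mean_past_values,
            nodata_mask=present.nodata_mask.copy(), scenario_id="past/mean",
        )
        occ_past = realize_species(sp.truth(), mean_past)
        fossil_table = sample_fossils(
            occ_past, grid, sp.n_fossils, sp.misplacement_rate,
            seed=stage_seed(config.seed, f"fossils/{sp.name}"), species=sp.name,
        )
        fossil_table.drop(columns=["on_truth"]).to_csv(
            spdir / "fossils.csv", index=False
        )
        outputs.append(f"{sp.name}/fossils.csv")
        fossils = read_fossils(spdir / "fossils.csv")
    elif sp.fossils_path:
        fossils = read_fossils(sp.fossils_path)
    else:
        fossils = []
    if fossils:
        kept = filter_age_window(fossils, config.age_window)
        support = score_fossil_support(past_ens, kept, vote_cutoff)
        support.records.to_csv(spdir / "fossil_votes.csv", index=False)
        outputs.append(f"{sp.name}/fossil_votes.csv")
        fossil_summary = support.summary

    return {
        "sweep": sweep,
        "thermal": thermal,
        "fossil_summary": fossil_summary,
        "outputs": outputs,
    }
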