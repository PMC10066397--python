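"""Configuration handling and the end-to-end pipeline driver.

``run_pipeline`` ties the stages together on a synthetic sample:

    phantom -> simulate (forward projection) -> reconstruct (FBP)
            -> unfold -> quantify (villi, follicles) -> revopt

Stages are individually toggleable; disabled upstream stages make downstream
ones fall back to the phantom data directly (e.g. unfolding the rendered
phantom instead of its reconstruction).  Every run writes its artifacts
(TIFF volumes, CSV tables) plus a machine-readable JSON report with stage
timings, parameters, counts and the seed, so any run is reproducible from
config + seed alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as gio
from .errors import ParameterError
from .opt_core import VoxelGrid, forward_project, reconstruct_fbp
from .phantom import (
    CellSpec,
    FollicleSpec,
    PhantomSpec,
    make_gut_phantom,
    regular_follicle_specs,
)
from .quantify import follicle_stats, segment_follicles, villous_density
from .revopt import RoiRecord, SectionPlan, match_sections, section_indices
from .unfold import unfold_volume

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "DEFAULT_CONFIG"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (nested by stage)."""

    seed: int = 0
    phantom: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    reconstruct: dict[str, Any] = field(default_factory=dict)
    unfold: dict[str, Any] = field(default_factory=dict)
    quantify: dict[str, Any] = field(default_factory=dict)
    revopt: dict[str, Any] = field(default_factory=dict)


# admissible keys per stage; unknown keys are rejected before any work runs
_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "phantom", "simulate", "reconstruct", "unfold", "quantify", "revopt"},
    "phantom": {
        "enabled", "grid_shape", "voxel_size_um", "lumen_radius_um",
        "mucosa_outer_radius_um", "submucosa_outer_radius_um",
        "muscularis_outer_radius_um", "villus_count_per_ring", "villus_length_um",
        "villus_width_um", "villus_ring_spacing_um", "noise_sigma",
        "follicles", "cells",
    },
    "phantom.follicles": {
        "count", "axial_spacing_um", "radius_from_axis_um", "semi_axes_um", "peak",
    },
    "simulate": {"enabled", "n_angles", "channels"},
    "reconstruct": {"enabled", "window"},
    "unfold": {"enabled", "angle_deg", "band_inner_um", "band_outer_um", "step_um"},
    "quantify": {"villi", "follicles"},
    "quantify.villi": {
        "enabled", "layer_depth_um", "sector_size_um", "min_prominence",
        "villus_width_um",
    },
    "quantify.follicles": {
        "enabled", "intensity_threshold", "smoothing_sigma_um", "min_voxels",
    },
    "revopt": {"enabled", "section_thickness_um", "origin_end", "density_threshold"},
}


def _check_keys(mapping: dict, scope: str) -> None:
    allowed = _SCHEMA[scope]
    unknown = set(mapping) - allowed
    if unknown:
        where = scope or "top level"
        raise ParameterError(f"unknown config key(s) {sorted(unknown)} at {where}")
    for key, sub in mapping.items():
        child = f"{scope}.{key}" if scope else key
        if child in _SCHEMA and isinstance(sub, dict):
            _check_keys(sub, child)


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "phantom": {
        "enabled": True,
        "grid_shape": [96, 96, 96],
        "voxel_size_um": 5.0,
        "lumen_radius_um": 110.0,
        "mucosa_outer_radius_um": 175.0,
        "submucosa_outer_radius_um": 205.0,
        "muscularis_outer_radius_um": 230.0,
        "villus_count_per_ring": 8,
        "villus_length_um": 55.0,
        "villus_width_um": 40.0,
        "noise_sigma": 0.0,
        "follicles": {
            "count": 3,
            "axial_spacing_um": 150.0,
            "radius_from_axis_um": 190.0,
            "semi_axes_um": [30.0, 20.0, 20.0],
            "peak": 1.0,
        },
        "cells": {},
    },
    "simulate": {"enabled": True, "n_angles": 400, "channels": ["marker"]},
    "reconstruct": {"enabled": True, "window": "ramlak"},
    "unfold": {
        "enabled": True,
        "angle_deg": 45.0,
        "band_inner_um": 200.0,
        "band_outer_um": 10.0,
    },
    "quantify": {
        "villi": {
            "enabled": True,
            "layer_depth_um": 155.0,
            "sector_size_um": 250.0,
            "min_prominence": 0.05,
            "villus_width_um": 40.0,
        },
        "follicles": {
            "enabled": True,
            "intensity_threshold": 0.5,
            "smoothing_sigma_um": 2.0,
            "min_voxels": 20,
        },
    },
    "revopt": {
        "enabled": True,
        "section_thickness_um": 25.0,
        "origin_end": "proximal",
        "density_threshold": 400.0,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, merge over the defaults, and validate keys."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw = _merge(raw, overrides)
    _check_keys(raw, "")
    merged = _merge(DEFAULT_CONFIG, raw)
    return PipelineConfig(
        seed=merged["seed"],
        phantom=merged["phantom"],
        simulate=merged["simulate"],
        reconstruct=merged["reconstruct"],
        unfold=merged["unfold"],
        quantify=merged["quantify"],
        revopt=merged["revopt"],
    )


def _build_phantom_spec(cfg: dict, seed: int) -> PhantomSpec:
    grid_shape = tuple(cfg["grid_shape"])
    foll_cfg = cfg.get("follicles") or {}
    follicles: list[FollicleSpec] = []
    if foll_cfg.get("count"):
        follicles = regular_follicle_specs(
            n=foll_cfg["count"],
            axial_spacing_um=foll_cfg["axial_spacing_um"],
            radius_from_axis_um=foll_cfg["radius_from_axis_um"],
            grid_shape=grid_shape,
            voxel_size_um=cfg["voxel_size_um"],
            semi_axes_um=tuple(foll_cfg.get("semi_axes_um", (30.0, 20.0, 20.0))),
            peak=foll_cfg.get("peak", 1.0),
        )
    cells = [CellSpec(region=k, count=v) for k, v in (cfg.get("cells") or {}).items()]
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_um=cfg["voxel_size_um"],
        lumen_radius_um=cfg["lumen_radius_um"],
        mucosa_outer_radius_um=cfg["mucosa_outer_radius_um"],
        submucosa_outer_radius_um=cfg["submucosa_outer_radius_um"],
        muscularis_outer_radius_um=cfg["muscularis_outer_radius_um"],
        villus_count_per_ring=cfg.get("villus_count_per_ring", 0),
        villus_length_um=cfg.get("villus_length_um", 0.0),
        villus_width_um=cfg.get("villus_width_um", 0.0),
        villus_ring_spacing_um=cfg.get("villus_ring_spacing_um"),
        follicle_specs=follicles,
        cell_specs=cells,
        noise_sigma=cfg.get("noise_sigma", 0.0),
        rng_seed=seed,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the enabled stages in order; return (and write) the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "config": asdict(config), "stages": {}}

    def record(stage: str, t0: float, **info: Any) -> None:
        report["stages"][stage] = {"elapsed_s": round(time.perf_counter() - t0, 3), **info}

    if not config.phantom.get("enabled", True):
        raise ParameterError("the pipeline driver operates on a generated phantom")
    t0 = time.perf_counter()
    spec = _build_phantom_spec(config.phantom, config.seed)
    autofluo, marker, truth = make_gut_phantom(spec)
    gio.write_volume(autofluo, out / "autofluorescence.tif", as_uint16=True)
    gio.write_volume(marker, out / "marker.tif", as_uint16=True)
    gio.write_truth(truth, out / "truth")
    record(
        "phantom", t0,
        true_follicles=len(truth.follicles),
        true_villi=len(truth.villus_apexes),
        true_cells=int(truth.cells.shape[0]),
    )

    channels = {"autofluorescence": autofluo, "marker": marker}
    recon = dict(channels)  # downstream uses phantom directly unless reconstructed
    if config.simulate.get("enabled", True):
        t0 = time.perf_counter()
        n_angles = config.simulate.get("n_angles", 400)
        wanted = config.simulate.get("channels", ["marker"])
        projections = {name: forward_project(channels[name], n_angles) for name in wanted}
        for name, ps in projections.items():
            gio.write_projections(ps, out / f"projections_{name}.tif")
        record("simulate", t0, n_angles=n_angles, channels=list(projections))

        if config.reconstruct.get("enabled", True):
            t0 = time.perf_counter()
            window = config.reconstruct.get("window", "ramlak")
            for name, ps in projections.items():
                recon[name] = reconstruct_fbp(ps, window=window)
                gio.write_volume(recon[name], out / f"recon_{name}.tif", as_uint16=True)
            record("reconstruct", t0, window=window, channels=list(projections))

    unfolded = None
    if config.unfold.get("enabled", True):
        t0 = time.perf_counter()
        ucfg = config.unfold
        unfolded = unfold_volume(
            recon["autofluorescence"],
            angle_deg=ucfg.get("angle_deg", 45.0),
            band_inner_um=ucfg.get("band_inner_um", 0.0),
            band_outer_um=ucfg.get("band_outer_um", 0.0),
            step_um=ucfg.get("step_um"),
        )
        gio.write_volume(
            VoxelGrid(unfolded.unfolded_volume, unfolded.step_um, "unfolded"),
            out / "unfolded.tif",
            as_uint16=True,
        )
        record(
            "unfold", t0,
            n_slices=int(unfolded.straightened_stack.shape[0]),
            n_layers=int(unfolded.unfolded_volume.shape[0]),
            failed_slices=unfolded.failed_slices,
        )

    villi_count = None
    vcfg = config.quantify.get("villi", {})
    if vcfg.get("enabled", True) and unfolded is not None:
        t0 = time.perf_counter()
        layer_idx = int(round(
            (vcfg["layer_depth_um"] + unfolded.band_outer_um) / unfolded.step_um
        ))
        layer_idx = min(layer_idx, unfolded.unfolded_volume.shape[0] - 1)
        dmap = villous_density(
            unfolded.unfolded_volume[layer_idx],
            pixel_size_um=unfolded.step_um,
            sector_size_um=vcfg["sector_size_um"],
            min_prominence=vcfg["min_prominence"],
            villus_width_um=vcfg["villus_width_um"],
        )
        np.savetxt(out / "villous_sector_counts.csv", dmap.sector_counts,
                   fmt="%d", delimiter=",")
        villi_count = dmap.total_count
        record("quantify_villi", t0, layer_index=layer_idx,
               villi_detected=villi_count, true_villi=len(truth.villus_apexes))

    table = None
    fcfg = config.quantify.get("follicles", {})
    if fcfg.get("enabled", True):
        t0 = time.perf_counter()
        table = segment_follicles(
            recon["marker"],
            intensity_threshold=fcfg["intensity_threshold"],
            smoothing_sigma_um=fcfg.get("smoothing_sigma_um", 2.0),
            min_voxels=fcfg.get("min_voxels", 1),
        )
        table.table.to_csv(out / "follicles.csv", index=False)
        info = {"follicles_detected": len(table), "true_follicles": len(truth.follicles)}
        if len(table) >= 2:
            stats = follicle_stats(table)
            stats.table.to_csv(out / "follicle_distances.csv", index=False)
            info["mean_nn_distance_um"] = stats.mean_nearest_neighbour_um
        record("quantify_follicles", t0, **info)

    if config.revopt.get("enabled", True) and table is not None and len(table):
        t0 = time.perf_counter()
        rcfg = config.revopt
        v = spec.voxel_size_um
        plan = SectionPlan(
            section_thickness_um=rcfg.get("section_thickness_um", 25.0),
            sample_length_um=spec.grid_shape[0] * v,
            origin_end=rcfg.get("origin_end", "proximal"),
        )
        rois, windows, contained = [], {}, 0
        for _, row in table.table.iterrows():
            roi = RoiRecord(
                roi_id=f"follicle_{int(row['label'])}",
                axial_start_um=row["bbox_zmin_index"] * v,
                axial_end_um=(row["bbox_zmax_index"] + 1) * v,
            )
            rois.append(roi)
            windows[roi.roi_id] = section_indices(roi, plan)
        # ground-truth check: does each true follicle fall in a predicted window?
        thickness = plan.section_thickness_um
        for centroid, _vol in truth.follicles:
            true_section = int(centroid[0] // thickness)
            if any(true_section in w for w in windows.values()):
                contained += 1
        hits = [(k, 2 * rcfg.get("density_threshold", 400.0))
                for w in windows.values() for k in w]
        match = match_sections(rois, hits, plan,
                               density_threshold=rcfg.get("density_threshold", 400.0))
        with open(out / "section_windows.json", "w") as fh:
            json.dump({k: list(v) for k, v in windows.items()}, fh, indent=2)
        record("revopt", t0, n_rois=len(rois),
               true_follicles_in_windows=contained,
               unexplained_sections=match.unexplained_sections,
               empty_rois=match.empty_rois)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    return report
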