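"""File I/O: multi-page TIFF volumes with JSON sidecars, CSV tables, configs.

Volumes and projection sets are stored as multi-page TIFF (one page per
slice / projection, page index = axis 0) with a ``<name>.json`` sidecar
carrying the metadata that TIFF does not: voxel size, channel label and, for
projection sets, the rotation angles.  Round trips are lossless for integer
data; phantom floats are exported as 16-bit by :func:`write_volume` with
``as_uint16=True``.

CSV dialect everywhere: comma-separated, UTF-8, header row, '.' decimal,
units embedded in column names (e.g. ``volume_um3``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import MetadataError
from .opt_core import ProjectionSet, VoxelGrid
from .phantom import PhantomTruth

__all__ = [
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "write_truth",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_volume(grid: VoxelGrid, path: str | Path, as_uint16: bool = False) -> Path:
    """Write a volume as a multi-page TIFF plus JSON sidecar.

    ``as_uint16`` rescales float data to the full 16-bit range (the sidecar
    records the scale so reading restores intensities approximately); integer
    data round-trips bit-identically.
    """
    path = Path(path)
    data = grid.data
    scale = None
    if as_uint16 and not np.issubdtype(data.dtype, np.integer):
        lo, hi = float(data.min()), float(data.max())
        scale = {"min": lo, "max": hi}
        span = (hi - lo) or 1.0
        data = np.round((data - lo) / span * 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "voxel_size_um": grid.voxel_size_um,
        "channel_label": grid.channel_label,
        "kind": "volume",
    }
    if scale:
        meta["uint16_scale"] = scale
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> VoxelGrid:
    """Read a multi-page TIFF volume; voxel size from sidecar or argument."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MetadataError(f"{path}: expected a 2D/3D TIFF, got ndim={data.ndim}")
    label = ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("channel_label", "")
        if voxel_size_um is None:
            voxel_size_um = meta.get("voxel_size_um")
        if "uint16_scale" in meta:
            s = meta["uint16_scale"]
            data = data.astype(float) / 65535.0 * (s["max"] - s["min"]) + s["min"]
    if voxel_size_um is None:
        raise MetadataError(
            f"{path}: no voxel size; provide a sidecar or pass voxel_size_um"
        )
    return VoxelGrid(data, voxel_size_um, label)


def write_projections(ps: ProjectionSet, path: str | Path) -> Path:
    """Write a projection set as TIFF pages (one per angle) plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, ps.projections.astype(np.float32))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "angles_deg": ps.angles_deg.tolist(),
                "detector_pixel_size_um": ps.detector_pixel_size_um,
                "channel_label": ps.channel_label,
                "kind": "projections",
            },
            indent=2,
        )
    )
    return path


def read_projections(path: str | Path) -> ProjectionSet:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"{path}: projection sets require a JSON sidecar")
    meta = json.loads(sidecar.read_text())
    return ProjectionSet(
        projections=tifffile.imread(path),
        angles_deg=np.array(meta["angles_deg"]),
        detector_pixel_size_um=meta["detector_pixel_size_um"],
        channel_label=meta.get("channel_label", ""),
    )


def write_truth(truth: PhantomTruth, out_dir: str | Path) -> dict[str, Path]:
    """Export phantom ground truth as one CSV per object class + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    apex = pd.DataFrame(
        truth.villus_apexes, columns=["slice_index", "angle_rad", "radius_um"]
    )
    paths["villus_apexes"] = out_dir / "villus_apexes.csv"
    apex.to_csv(paths["villus_apexes"], index=False)

    foll = pd.DataFrame(
        [
            {
                "centroid_z_um": c[0],
                "centroid_y_um": c[1],
                "centroid_x_um": c[2],
                "volume_um3": v,
            }
            for c, v in truth.follicles
        ]
    )
    paths["follicles"] = out_dir / "follicles.csv"
    foll.to_csv(paths["follicles"], index=False)

    cells = pd.DataFrame(truth.cells, columns=["z_um", "y_um", "x_um"])
    paths["cells"] = out_dir / "cells.csv"
    cells.to_csv(paths["cells"], index=False)

    paths["layers"] = out_dir / "layer_radii.json"
    paths["layers"].write_text(json.dumps(truth.layer_radii_um, indent=2))
    return paths
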