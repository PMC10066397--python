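"""Quantification of gut structures: villi, lymphoid follicles, immune cells.

Three measurements from the imaging pipeline:

* **Villous density** — villus apexes appear as bright blobs in unfolded
  surface layers; they are detected as local maxima of a
  Laplacian-of-Gaussian (blob) response at the villus scale and binned into
  square sectors, yielding counts per mm^2 both per sector and overall.
* **Follicle segmentation** — isolated lymphoid follicles (ILFs) in the
  immune-marker channel are segmented by Gaussian smoothing (default 2 um),
  absolute-intensity thresholding and 26-connected component labelling,
  with a minimum voxel-count filter; per-object volume (um^3) and centroid
  are tabulated, and centroid-to-centroid distance statistics summarise
  their spatial distribution.
* **Cell density** — in cryosection images, point-cell counts are
  normalised by the nuclei-mask (DAPI) area to cells per mm^2; a structure
  is considered visible in an OPT reconstruction when that density reaches
  a configurable threshold (default 400 cells/mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import pdist, squareform
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops

from .errors import InsufficientObjectsError, ParameterError
from .opt_core import VoxelGrid

__all__ = [
    "DensityMap",
    "FollicleTable",
    "FollicleStats",
    "villous_density",
    "segment_follicles",
    "follicle_stats",
    "nearest_neighbour_distances",
    "cell_density",
    "opt_visible",
]


@dataclass
class DensityMap:
    """Detected maxima binned into square sectors.

    ``sector_counts[i, j]`` is the number of maxima in sector (i, j);
    ``density`` is counts per mm^2 of sector area.  Sector counts always
    partition the total: ``sector_counts.sum() == total_count``.
    """

    sector_counts: np.ndarray
    sector_size_um: float
    density_per_mm2: np.ndarray
    total_count: int
    maxima_px: np.ndarray  # (n, 2) detected apex positions (row, col)

    @property
    def mean_density_per_mm2(self) -> float:
        return float(self.density_per_mm2.mean()) if self.density_per_mm2.size else 0.0


def villous_density(
    unfolded_layer: np.ndarray,
    pixel_size_um: float,
    sector_size_um: float,
    min_prominence: float,
    villus_width_um: float = 60.0,
) -> DensityMap:
    """Count villus apexes in an unfolded surface layer, per sector.

    The layer is filtered with a Laplacian of Gaussian at the villus scale
    (sigma = villus_width / (2*sqrt(2)), the LoG optimum for a blob of that
    diameter); local maxima of the (sign-flipped, scale-normalised) response
    with height >= ``min_prominence`` and mutual separation >= one villus
    width are taken as apexes and binned into square sectors of side
    ``sector_size_um``.  A constant layer yields zero maxima.
    """
    layer = np.asarray(unfolded_layer, dtype=float)
    if layer.ndim != 2 or layer.size == 0:
        raise ParameterError("unfolded layer must be a non-empty 2D image")
    if pixel_size_um <= 0 or villus_width_um <= 0:
        raise ParameterError("pixel size and villus width must be positive")
    if sector_size_um < 2 * pixel_size_um:
        raise ParameterError("sector_size_um must be at least 2 pixels wide")
    if min_prominence <= 0:
        raise ParameterError("min_prominence must be positive")

    sigma_px = villus_width_um / (2.0 * np.sqrt(2.0)) / pixel_size_um
    response = -(sigma_px**2) * ndi.gaussian_laplace(layer, sigma_px)
    min_sep_px = max(1, int(round(villus_width_um / pixel_size_um)))
    maxima = peak_local_max(
        response,
        min_distance=min_sep_px,
        threshold_abs=min_prominence,
        exclude_border=False,
    )

    n_i = int(np.ceil(layer.shape[0] * pixel_size_um / sector_size_um))
    n_j = int(np.ceil(layer.shape[1] * pixel_size_um / sector_size_um))
    counts = np.zeros((n_i, n_j), dtype=int)
    if maxima.size:
        si = (maxima[:, 0] * pixel_size_um / sector_size_um).astype(int)
        sj = (maxima[:, 1] * pixel_size_um / sector_size_um).astype(int)
        np.add.at(counts, (si, sj), 1)
    sector_area_mm2 = (sector_size_um**2) * 1e-6
    return DensityMap(
        sector_counts=counts,
        sector_size_um=sector_size_um,
        density_per_mm2=counts / sector_area_mm2,
        total_count=int(len(maxima)),
        maxima_px=maxima,
    )


@dataclass
class FollicleTable:
    """Per-follicle measurements plus the segmentation parameters used."""

    table: pd.DataFrame  # columns: label, voxel_count, volume_um3, centroid z/y/x
    threshold: float
    smoothing_sigma_um: float
    min_voxels: int
    voxel_size_um: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids_um(self) -> np.ndarray:
        return self.table[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()

    @property
    def volumes_um3(self) -> np.ndarray:
        return self.table["volume_um3"].to_numpy()


def segment_follicles(
    marker: VoxelGrid,
    intensity_threshold: float,
    smoothing_sigma_um: float = 2.0,
    min_voxels: int = 1,
) -> FollicleTable:
    """Segment bright follicle clusters in the marker channel.

    Gaussian smoothing at ``smoothing_sigma_um`` (converted to voxels),
    absolute-intensity thresholding, 26-connected labelling and removal of
    objects smaller than ``min_voxels``.  Volumes are
    ``voxel_count * voxel_size^3`` and centroids are intensity-free
    (geometric) centroids in micrometres of voxel centres.
    """
    data = np.asarray(marker.data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if not (lo <= intensity_threshold <= hi):
        raise ParameterError(
            f"threshold {intensity_threshold} outside intensity range [{lo}, {hi}]"
        )
    if smoothing_sigma_um < 0:
        raise ParameterError("smoothing_sigma_um must be >= 0")
    if min_voxels < 1:
        raise ParameterError("min_voxels must be >= 1")

    v = marker.voxel_size_um
    smoothed = (
        ndi.gaussian_filter(data, smoothing_sigma_um / v) if smoothing_sigma_um else data
    )
    labels = label(smoothed > intensity_threshold, connectivity=3)
    rows = []
    for rp in regionprops(labels):
        if rp.num_pixels < min_voxels:
            continue
        cz, cy, cx = rp.centroid
        rows.append(
            {
                "label": rp.label,
                "voxel_count": int(rp.num_pixels),
                "volume_um3": rp.num_pixels * v**3,
                "centroid_z_um": (cz + 0.5) * v,
                "centroid_y_um": (cy + 0.5) * v,
                "centroid_x_um": (cx + 0.5) * v,
                "bbox_zmin_index": int(rp.bbox[0]),
                "bbox_zmax_index": int(rp.bbox[3]) - 1,
            }
        )
    columns = [
        "label", "voxel_count", "volume_um3",
        "centroid_z_um", "centroid_y_um", "centroid_x_um",
        "bbox_zmin_index", "bbox_zmax_index",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return FollicleTable(
        table=table,
        threshold=intensity_threshold,
        smoothing_sigma_um=smoothing_sigma_um,
        min_voxels=min_voxels,
        voxel_size_um=v,
    )


@dataclass
class FollicleStats:
    """Min / mean / max centroid distance from each follicle to the others."""

    table: pd.DataFrame  # columns: label, min_distance_um, mean_distance_um, max_distance_um
    mode: str  # "all_pairs" or "axial_nn"

    @property
    def mean_nearest_neighbour_um(self) -> float:
        return float(self.table["min_distance_um"].mean())


def follicle_stats(follicles: FollicleTable, mode: str = "all_pairs") -> FollicleStats:
    """Inter-follicle distance statistics (centroid-to-centroid, Euclidean).

    ``all_pairs`` (default): for each follicle, the min / mean / max distance
    to every other follicle; the per-follicle minimum is its
    nearest-neighbour distance.  ``axial_nn``: distances to the two axially
    adjacent follicles only (useful for samples mounted along the axis).
    """
    n = len(follicles)
    if n < 2:
        raise InsufficientObjectsError(f"need >= 2 follicles for distances, got {n}")
    cents = follicles.centroids_um
    labels = follicles.table["label"].to_numpy()
    if mode == "all_pairs":
        dm = squareform(pdist(cents))
        np.fill_diagonal(dm, np.inf)
        mins = dm.min(axis=1)
        finite = np.where(np.isinf(dm), np.nan, dm)
        means = np.nanmean(finite, axis=1)
        np.fill_diagonal(dm, -np.inf)
        maxs = dm.max(axis=1)
    elif mode == "axial_nn":
        order = np.argsort(cents[:, 0])
        mins = np.empty(n)
        means = np.empty(n)
        maxs = np.empty(n)
        for rank, i in enumerate(order):
            neigh = [order[rank - 1]] if rank > 0 else []
            if rank < n - 1:
                neigh.append(order[rank + 1])
            d = np.linalg.norm(cents[neigh] - cents[i], axis=1)
            mins[i], means[i], maxs[i] = d.min(), d.mean(), d.max()
    else:
        raise ParameterError(f"unknown mode {mode!r}; use 'all_pairs' or 'axial_nn'")
    table = pd.DataFrame(
        {
            "label": labels,
            "min_distance_um": mins,
            "mean_distance_um": means,
            "max_distance_um": maxs,
        }
    )
    return FollicleStats(table=table, mode=mode)


def nearest_neighbour_distances(follicles: FollicleTable) -> np.ndarray:
    """Nearest-neighbour centroid distance for every follicle (um)."""
    return follicle_stats(follicles).table["min_distance_um"].to_numpy()


def cell_density(
    cell_coords_um: np.ndarray,
    nuclei_mask: np.ndarray,
    pixel_size_um: float,
) -> float:
    """Cells per mm^2 of nuclei-mask area.

    ``cell_coords_um`` are (row, col) positions in micrometres; only points
    falling on mask pixels are counted.  Mask area is
    ``pixel_count * pixel_size^2 * 1e-6`` mm^2.
    """
    mask = np.asarray(nuclei_mask, dtype=bool)
    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be positive")
    n_px = int(mask.sum())
    if n_px == 0:
        raise ParameterError("empty nuclei mask: density undefined")
    coords = np.asarray(cell_coords_um, dtype=float).reshape(-1, 2)
    inside = 0
    for r_um, c_um in coords:
        i, j = int(r_um / pixel_size_um), int(c_um / pixel_size_um)
        if 0 <= i < mask.shape[0] and 0 <= j < mask.shape[1] and mask[i, j]:
            inside += 1
    area_mm2 = n_px * (pixel_size_um**2) * 1e-6
    return inside / area_mm2


def opt_visible(density_per_mm2: float, threshold: float = 400.0) -> bool:
    """Whether a cell cluster of this density is expected to show up in OPT.

    The visibility threshold defaults to 400 cells/mm^2 of nuclei signal and
    the comparison is inclusive (a density exactly at the threshold counts
    as visible); the threshold is configurable because it is an approximate,
    setup-dependent figure.
    """
    if density_per_mm2 < 0:
        raise ParameterError("density must be >= 0")
    return density_per_mm2 >= threshold
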