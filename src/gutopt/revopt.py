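"""Reverse-OPT region-of-interest tracking into physical cryosections.

After tomographic imaging the sample can be reverted, frozen and cut into
sections of known thickness (25 um by default).  A region of interest (ROI)
selected in the 3D reconstruction is located in the physical sections purely
by axial arithmetic: its distance from the end of the tissue fixes the range
of section indices that contain it.  Conversely, sections found to contain
high-density signal can be matched back to the OPT ROIs whose windows cover
them.

Sections are indexed zero-based from the cutting face at the configured
origin end and occupy half-open intervals ``[k*t, (k+1)*t)`` so that the
axis is partitioned without double assignment.  No shrinkage or rehydration
scale correction is applied by default (an optional linear factor is
available); distances are measured along the straight grid axis, so curved
samples must be mounted straight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "SectionPlan",
    "RoiRecord",
    "MatchReport",
    "roi_axial_distance",
    "section_indices",
    "match_sections",
]


@dataclass(frozen=True)
class SectionPlan:
    """Cryosectioning parameters: thickness, sample length, cutting origin."""

    section_thickness_um: float = 25.0
    sample_length_um: float = 0.0
    origin_end: str = "proximal"
    scale_factor: float = 1.0  # optional OPT-to-section linear scaling

    def __post_init__(self) -> None:
        if self.section_thickness_um <= 0:
            raise ParameterError("section thickness must be positive")
        if self.sample_length_um < self.section_thickness_um:
            raise ParameterError("sample length must be at least one section")
        if self.origin_end not in ("proximal", "distal"):
            raise ParameterError("origin_end must be 'proximal' or 'distal'")
        if self.scale_factor <= 0:
            raise ParameterError("scale_factor must be positive")


@dataclass
class RoiRecord:
    """One ROI with its axial extent measured from the origin end (um)."""

    roi_id: str
    axial_start_um: float
    axial_end_um: float
    centroid_um: tuple[float, float, float] | None = None
    source: str = "opt"

    def __post_init__(self) -> None:
        if not 0 <= self.axial_start_um < self.axial_end_um:
            raise ParameterError(
                f"ROI {self.roi_id}: need 0 <= start < end, got "
                f"({self.axial_start_um}, {self.axial_end_um})"
            )


def roi_axial_distance(
    volume_shape: tuple[int, int, int],
    voxel_size_um: float,
    roi_voxels: np.ndarray,
    origin_end: str = "proximal",
    roi_id: str = "roi",
) -> RoiRecord:
    """Axial extent of an ROI, measured from the chosen end of the tissue.

    ``roi_voxels`` is either an (n, 3) array of voxel indices or a boolean
    mask of the volume.  The extent covers the occupied slices:
    ``[min_slice * v, (max_slice + 1) * v)`` from the proximal end; from the
    distal end the interval is mirrored about the sample length, so extents
    measured from both ends sum to the sample length.
    """
    if origin_end not in ("proximal", "distal"):
        raise ParameterError("origin_end must be 'proximal' or 'distal'")
    roi_voxels = np.asarray(roi_voxels)
    if roi_voxels.dtype == bool:
        if roi_voxels.shape != tuple(volume_shape):
            raise ParameterError("boolean ROI mask must match the volume shape")
        idx = np.argwhere(roi_voxels)
    else:
        idx = roi_voxels.reshape(-1, 3)
    if idx.size == 0:
        raise ParameterError("ROI is empty")
    nz = volume_shape[0]
    if idx[:, 0].min() < 0 or idx[:, 0].max() >= nz:
        raise ParameterError("ROI voxels fall outside the volume")
    zmin, zmax = int(idx[:, 0].min()), int(idx[:, 0].max())
    start, end = zmin * voxel_size_um, (zmax + 1) * voxel_size_um
    if origin_end == "distal":
        length = nz * voxel_size_um
        start, end = length - end, length - start
    centroid = tuple((idx.mean(axis=0) + 0.5) * voxel_size_um)
    return RoiRecord(
        roi_id=roi_id,
        axial_start_um=start,
        axial_end_um=end,
        centroid_um=centroid,
        source="opt",
    )


def section_indices(roi: RoiRecord, plan: SectionPlan) -> list[int]:
    """Zero-based indices of the sections intersecting an ROI's extent.

    Section k occupies ``[k*t, (k+1)*t)``; indices are those whose interval
    overlaps ``[start, end)`` after the plan's optional scale factor.
    """
    t = plan.section_thickness_um
    start = roi.axial_start_um * plan.scale_factor
    end = roi.axial_end_um * plan.scale_factor
    if end > plan.sample_length_um + 1e-9:
        raise ParameterError(
            f"ROI {roi.roi_id} extent ({start}, {end}) um exceeds sample length "
            f"{plan.sample_length_um} um"
        )
    first = int(np.floor(start / t))
    last = int(np.ceil(end / t)) - 1
    last = max(last, first)  # sub-section ROI still hits one section
    return list(range(first, last + 1))


@dataclass
class MatchReport:
    """Outcome of matching observed high-density sections to OPT ROIs."""

    assignments: dict[int, str]  # section index -> roi_id
    unexplained_sections: list[int] = field(default_factory=list)
    empty_rois: list[str] = field(default_factory=list)


def match_sections(
    opt_rois: list[RoiRecord],
    section_hits: list[tuple[int, float]],
    plan: SectionPlan,
    density_threshold: float = 400.0,
) -> MatchReport:
    """Match high-density sections back to the OPT ROIs predicting them.

    ``section_hits`` are (section index, cell density per mm^2) pairs.  A
    section is "high-density" when its density reaches ``density_threshold``.
    Each high-density section is assigned to the ROI whose section window
    contains it (first matching ROI in argument order); high-density sections
    with no covering ROI are reported as unexplained, and ROIs whose window
    received no high-density section are reported as empty.  Report-only:
    no error is raised for mismatches.
    """
    windows = {roi.roi_id: set(section_indices(roi, plan)) for roi in opt_rois}
    assignments: dict[int, str] = {}
    unexplained: list[int] = []
    for k, density in section_hits:
        if density < density_threshold:
            continue
        for roi in opt_rois:
            if k in windows[roi.roi_id]:
                assignments[k] = roi.roi_id
                break
        else:
            unexplained.append(k)
    hit_rois = set(assignments.values())
    empty = [roi.roi_id for roi in opt_rois if roi.roi_id not in hit_rois]
    return MatchReport(
        assignments=assignments,
        unexplained_sections=unexplained,
        empty_rois=empty,
    )
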