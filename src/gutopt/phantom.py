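"""Synthetic two-channel gut phantoms with exported ground truth.

Every downstream stage (projection simulation, reconstruction, unfolding,
quantification, section tracking) is validated against phantoms whose
anatomy is known analytically:

* an **autofluorescence** channel with the concentric wall layers of the
  small intestine — lumen, mucosa, submucosa, muscularis, from the centre
  outward — and finger-like villi protruding from the mucosal inner surface
  into the lumen;
* a **marker** channel (emulating an immune-cell stain such as CD45) with
  bright ellipsoidal follicle clusters in the submucosa and sparse
  point-like single cells.

Villi are modelled as smooth cosine-squared radial bumps arranged on a
regular (ring x angle) lattice, so the apex count per slice and per volume
is known exactly.  Follicles use a super-Gaussian radial profile
``peak * exp(-ln2 * rho^4)`` (rho = 1 on the ellipsoid boundary), i.e. the
half-maximum isosurface coincides with the analytic ellipsoid, so
half-peak thresholding recovers the analytic volume (4/3)*pi*a*b*c.

Intensities are dimensionless floats in [0, 1] before noise; TIFF export
converts to 16-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError
from .opt_core import VoxelGrid

__all__ = [
    "FollicleSpec",
    "CellSpec",
    "PhantomSpec",
    "PhantomTruth",
    "SectionTruth",
    "make_gut_phantom",
    "make_annulus_phantom",
    "make_section_image",
    "regular_follicle_specs",
]

REGIONS = ("lumen", "mucosa", "submucosa", "muscularis")

# layer intensities of the autofluorescence channel (arbitrary units in [0,1])
LAYER_INTENSITY = {"lumen": 0.0, "mucosa": 0.8, "submucosa": 0.4, "muscularis": 0.6}


@dataclass(frozen=True)
class FollicleSpec:
    """One ellipsoidal follicle: centroid (z, y, x) in um, semi-axes in um, peak."""

    centroid_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    peak: float = 1.0

    @property
    def analytic_volume_um3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class CellSpec:
    """Point-like cells: how many to scatter uniformly in which wall region."""

    region: str
    count: int


@dataclass
class PhantomSpec:
    """Full description of a synthetic gut segment.

    All radii are measured from the tube axis (the grid centre in each
    slice); the ordering lumen < mucosa < submucosa < muscularis must hold
    and the outermost radius must fit inside the slice plane.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_um: float
    lumen_radius_um: float
    mucosa_outer_radius_um: float
    submucosa_outer_radius_um: float
    muscularis_outer_radius_um: float
    villus_count_per_ring: int = 0
    villus_length_um: float = 0.0
    villus_width_um: float = 0.0
    villus_ring_spacing_um: float | None = None  # default: 2 * villus_width
    follicle_specs: list[FollicleSpec] = field(default_factory=list)
    cell_specs: list[CellSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.grid_shape
        if min(nz, ny, nx) < 1:
            raise GeometryError(f"grid_shape must be positive, got {self.grid_shape}")
        if not self.voxel_size_um > 0:
            raise GeometryError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        radii = (
            self.lumen_radius_um,
            self.mucosa_outer_radius_um,
            self.submucosa_outer_radius_um,
            self.muscularis_outer_radius_um,
        )
        if not (0 <= radii[0] < radii[1] < radii[2] < radii[3]):
            raise GeometryError(
                "layer radii must satisfy lumen < mucosa < submucosa < muscularis, "
                f"got {radii}"
            )
        half_extent = min(ny, nx) / 2.0 * self.voxel_size_um
        if radii[3] > half_extent:
            raise GeometryError(
                f"muscularis radius {radii[3]} um exceeds half slice extent {half_extent} um"
            )
        if self.villus_count_per_ring:
            if self.villus_length_um <= 0 or self.villus_width_um <= 0:
                raise GeometryError("villus length and width must be positive")
            if self.villus_length_um >= self.lumen_radius_um:
                raise GeometryError("villus length must be smaller than the lumen radius")
        if self.noise_sigma < 0:
            raise GeometryError("noise_sigma must be >= 0")
        for f in self.follicle_specs:
            if min(f.semi_axes_um) < 2 * self.voxel_size_um:
                raise GeometryError(
                    f"follicle semi-axes {f.semi_axes_um} not resolvable at "
                    f"{self.voxel_size_um} um voxels (need >= 2 voxels)"
                )
            for axis, (c, ax, n) in enumerate(
                zip(f.centroid_um, f.semi_axes_um, self.grid_shape)
            ):
                if c - ax < 0 or c + ax > n * self.voxel_size_um:
                    raise GeometryError(
                        f"follicle at {f.centroid_um} um exceeds the grid along axis {axis}"
                    )
        for c in self.cell_specs:
            if c.region not in REGIONS:
                raise GeometryError(f"unknown region {c.region!r}; choose from {REGIONS}")
            if c.count < 0:
                raise GeometryError("cell count must be >= 0")

    @property
    def layer_radii_um(self) -> dict[str, float]:
        return {
            "lumen": self.lumen_radius_um,
            "mucosa": self.mucosa_outer_radius_um,
            "submucosa": self.submucosa_outer_radius_um,
            "muscularis": self.muscularis_outer_radius_um,
        }


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom.

    villus_apexes : list of (slice_index, angle_rad, radius_um)
    follicles     : list of (centroid_um (z, y, x), analytic_volume_um3)
    cells         : (n, 3) array of cell coordinates in um (z, y, x)
    layer_radii_um: radii of the four wall layers
    """

    villus_apexes: list[tuple[int, float, float]]
    follicles: list[tuple[tuple[float, float, float], float]]
    cells: np.ndarray
    layer_radii_um: dict[str, float]


def _cylindrical_coords(spec: PhantomSpec):
    """Radius (um) and azimuth grids over one slice plane, plus z centres (um)."""
    nz, ny, nx = spec.grid_shape
    v = spec.voxel_size_um
    # tube axis at (ny//2, nx//2): the rotation-axis convention of the
    # projection simulator, so phantoms sit on the tomographic axis
    cy, cx = ny // 2, nx // 2
    yy, xx = np.meshgrid(
        (np.arange(ny) - cy) * v, (np.arange(nx) - cx) * v, indexing="ij"
    )
    r = np.hypot(yy, xx)
    theta = np.mod(np.arctan2(yy, xx), 2 * np.pi)
    z = (np.arange(nz) + 0.5) * v
    return r, theta, z


def _villus_field(spec: PhantomSpec, r, theta, z):
    """Radial bump amplitude in [0, 1] over (z, y, x), plus apex ground truth.

    Bumps sit on a regular lattice: ``villus_count_per_ring`` azimuthal
    positions per ring, rings spaced ``villus_ring_spacing_um`` along the
    axis.  Each bump is cos^2-shaped in both azimuth and z, so apexes are
    isolated smooth maxima.
    """
    n = spec.villus_count_per_ring
    spacing = spec.villus_ring_spacing_um or 2 * spec.villus_width_um
    w_theta = spec.villus_width_um / spec.lumen_radius_um  # angular full width
    w_z = spec.villus_width_um
    period = 2 * np.pi / n

    # villus centres at (k + 1/2) * period: offset half a period so that no
    # villus straddles azimuth 0 or the cardinal angles used as seams
    d_theta = np.mod(theta, period) - period / 2
    bump_t = np.where(
        np.abs(d_theta) < w_theta / 2, np.cos(np.pi * d_theta / w_theta) ** 2, 0.0
    )

    length_z = spec.grid_shape[0] * spec.voxel_size_um
    centres = np.arange(spacing / 2, length_z, spacing)
    centres = centres[(centres - w_z / 2 >= 0) & (centres + w_z / 2 <= length_z)]
    d_z = z[:, None] - centres[None, :]
    bump_z = np.where(np.abs(d_z) < w_z / 2, np.cos(np.pi * d_z / w_z) ** 2, 0.0)
    bump_z = bump_z.max(axis=1)  # rings never overlap for spacing > width

    apex_r = spec.lumen_radius_um - spec.villus_length_um
    apexes = [
        (int(round(zc / spec.voxel_size_um - 0.5)), float((k + 0.5) * period), apex_r)
        for zc in centres
        for k in range(n)
    ]
    return bump_t[None, :, :] * bump_z[:, None, None], apexes


def _region_masks(spec: PhantomSpec, r, villus_bump):
    """Boolean masks of the four wall regions over the full (z, y, x) grid."""
    lum, muc, sub, mus = (
        spec.lumen_radius_um,
        spec.mucosa_outer_radius_um,
        spec.submucosa_outer_radius_um,
        spec.muscularis_outer_radius_um,
    )
    r3 = np.broadcast_to(r, (spec.grid_shape[0],) + r.shape)
    if villus_bump is not None:
        inner_surface = lum - spec.villus_length_um * villus_bump
    else:
        inner_surface = np.full_like(r3, lum)
    mucosa = (r3 >= inner_surface) & (r3 < muc)
    return {
        "lumen": r3 < inner_surface,
        "mucosa": mucosa,
        "submucosa": (r3 >= muc) & (r3 < sub),
        "muscularis": (r3 >= sub) & (r3 < mus),
    }


def _render_follicle(marker: np.ndarray, spec: PhantomSpec, f: FollicleSpec) -> None:
    """Add one super-Gaussian ellipsoid to the marker channel, in place."""
    v = spec.voxel_size_um
    nz, ny, nx = spec.grid_shape
    cz, cy, cx = f.centroid_um
    a, b, c = f.semi_axes_um  # along z, y, x respectively
    # bounding box at 2x the semi-axes (profile is ~6e-5 of peak at rho = 2)
    lo = [max(0, int((cc - 2 * ax) / v)) for cc, ax in zip(f.centroid_um, (a, b, c))]
    hi = [
        min(n, int(np.ceil((cc + 2 * ax) / v)) + 1)
        for cc, ax, n in zip(f.centroid_um, (a, b, c), (nz, ny, nx))
    ]
    zz = (np.arange(lo[0], hi[0]) + 0.5) * v - cz
    yy = (np.arange(lo[1], hi[1]) + 0.5) * v - cy
    xx = (np.arange(lo[2], hi[2]) + 0.5) * v - cx
    rho2 = (
        (zz[:, None, None] / a) ** 2
        + (yy[None, :, None] / b) ** 2
        + (xx[None, None, :] / c) ** 2
    )
    marker[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += f.peak * np.exp(
        -math.log(2) * rho2**2
    )


def make_gut_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, VoxelGrid, PhantomTruth]:
    """Render a two-channel gut phantom and its ground truth.

    Returns the autofluorescence channel (wall layers + villi), the marker
    channel (follicles + point cells) and a :class:`PhantomTruth` record.
    Output is deterministic for a fixed ``rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    r, theta, z = _cylindrical_coords(spec)

    apexes: list[tuple[int, float, float]] = []
    villus_bump = None
    if spec.villus_count_per_ring:
        villus_bump, apexes = _villus_field(spec, r, theta, z)

    masks = _region_masks(spec, r, villus_bump)
    autofluo = np.zeros(spec.grid_shape, dtype=float)
    for name, mask in masks.items():
        autofluo[mask] = LAYER_INTENSITY[name]

    marker = np.zeros(spec.grid_shape, dtype=float)
    for f in spec.follicle_specs:
        _render_follicle(marker, spec, f)

    cell_coords = []
    for c in spec.cell_specs:
        flat = np.flatnonzero(masks[c.region])
        if c.count > flat.size:
            raise GeometryError(
                f"cannot place {c.count} cells in region {c.region!r} "
                f"({flat.size} voxels available)"
            )
        chosen = rng.choice(flat, size=c.count, replace=False)
        idx = np.unravel_index(chosen, spec.grid_shape)
        marker[idx] = np.maximum(marker[idx], 1.0)
        coords = (np.stack(idx, axis=1) + 0.5) * spec.voxel_size_um
        cell_coords.append(coords)
    cells = (
        np.concatenate(cell_coords, axis=0) if cell_coords else np.empty((0, 3))
    )

    if spec.noise_sigma > 0:
        autofluo = autofluo + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
        marker = marker + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)

    truth = PhantomTruth(
        villus_apexes=apexes,
        follicles=[(f.centroid_um, f.analytic_volume_um3) for f in spec.follicle_specs],
        cells=cells,
        layer_radii_um=spec.layer_radii_um,
    )
    return (
        VoxelGrid(autofluo, spec.voxel_size_um, "autofluorescence"),
        VoxelGrid(marker, spec.voxel_size_um, "marker"),
        truth,
    )


def regular_follicle_specs(
    n: int,
    axial_spacing_um: float,
    radius_from_axis_um: float,
    grid_shape: tuple[int, int, int],
    voxel_size_um: float,
    semi_axes_um: tuple[float, float, float] = (60.0, 60.0, 60.0),
    peak: float = 1.0,
    start_um: float | None = None,
) -> list[FollicleSpec]:
    """Place ``n`` identical follicles on a straight axial line.

    Centroids sit at ``radius_from_axis_um`` from the tube axis (along +x)
    with regular spacing along the sample axis — the layout used for the
    spacing-statistics validation.
    """
    _, ny, nx = grid_shape
    cy = ny / 2.0 * voxel_size_um
    cx = nx / 2.0 * voxel_size_um + radius_from_axis_um
    length = grid_shape[0] * voxel_size_um
    if start_um is None:
        start_um = (length - (n - 1) * axial_spacing_um) / 2.0
    return [
        FollicleSpec(
            centroid_um=(start_um + k * axial_spacing_um, cy, cx),
            semi_axes_um=semi_axes_um,
            peak=peak,
        )
        for k in range(n)
    ]


def make_annulus_phantom(
    inner_radius_um: float,
    outer_radius_um: float,
    grid_shape: tuple[int, int, int],
    voxel_size_um: float,
) -> VoxelGrid:
    """A volume whose every slice is the same filled annulus (unit intensity).

    The analytic oracle for unfolding tests: perimeter, band geometry and
    symmetry are all known in closed form.  ``inner_radius_um = 0`` gives a
    filled disk.
    """
    if inner_radius_um < 0 or outer_radius_um <= inner_radius_um:
        raise GeometryError(
            f"need 0 <= inner < outer, got ({inner_radius_um}, {outer_radius_um})"
        )
    nz, ny, nx = grid_shape
    if not voxel_size_um > 0:
        raise GeometryError("voxel_size_um must be > 0")
    if outer_radius_um > min(ny, nx) / 2.0 * voxel_size_um:
        raise GeometryError("outer radius does not fit inside the slice plane")
    cy, cx = ny // 2, nx // 2
    yy, xx = np.meshgrid(
        (np.arange(ny) - cy) * voxel_size_um,
        (np.arange(nx) - cx) * voxel_size_um,
        indexing="ij",
    )
    r = np.hypot(yy, xx)
    slice_mask = ((r >= inner_radius_um) & (r < outer_radius_um)).astype(float)
    return VoxelGrid(
        np.broadcast_to(slice_mask, (nz, ny, nx)).copy(), voxel_size_um, "annulus"
    )


@dataclass
class SectionTruth:
    """Ground truth for one synthetic cryosection image."""

    cell_coords_um: np.ndarray  # (n, 2) as (row_um, col_um)
    density_cells_per_mm2: float
    mask_area_mm2: float


# refuse cell layouts denser than one cell per 4 mask pixels: beyond that,
# "point-like" cells would routinely touch and counts become ill-defined
_PACKING_LIMIT = 0.25


def make_section_image(
    cell_count: int,
    tissue_mask_area_mm2: float,
    pixel_size_um: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SectionTruth]:
    """Simulate a confocal cryosection: point cells inside a nuclei mask.

    The nuclei (DAPI) mask is a synthetic compact region containing exactly
    ``round(area / pixel_area)`` pixels, so the true density
    ``cell_count / mask_area`` is exact.  Cells occupy distinct pixels drawn
    uniformly from the mask.

    Returns (cell channel, nuclei mask, truth).
    """
    if cell_count < 0:
        raise ParameterError("cell_count must be >= 0")
    if tissue_mask_area_mm2 <= 0 or pixel_size_um <= 0:
        raise ParameterError("mask area and pixel size must be positive")
    px_area_mm2 = (pixel_size_um**2) * 1e-6
    n_px = int(round(tissue_mask_area_mm2 / px_area_mm2))
    if n_px < 1:
        raise GeometryError("mask area smaller than one pixel")
    if cell_count > _PACKING_LIMIT * n_px:
        raise GeometryError(
            f"{cell_count} cells exceed the packing limit "
            f"({_PACKING_LIMIT:.0%} of {n_px} mask pixels)"
        )

    # compact block mask: full rows of width `side` plus one partial row
    side = int(math.floor(math.sqrt(n_px)))
    full_rows, rem = divmod(n_px, side)
    n_rows = full_rows + (1 if rem else 0)
    margin = 2
    img_shape = (n_rows + 2 * margin, side + 2 * margin)
    mask = np.zeros(img_shape, dtype=bool)
    mask[margin : margin + full_rows, margin : margin + side] = True
    if rem:
        mask[margin + full_rows, margin : margin + rem] = True

    rng = np.random.default_rng(seed)
    flat = np.flatnonzero(mask)
    chosen = rng.choice(flat, size=cell_count, replace=False)
    cells = np.zeros(img_shape, dtype=float)
    cells.flat[chosen] = 1.0
    rows, cols = np.unravel_index(chosen, img_shape)
    coords = (np.stack([rows, cols], axis=1) + 0.5) * pixel_size_um

    area = n_px * px_area_mm2
    truth = SectionTruth(
        cell_coords_um=coords,
        density_cells_per_mm2=cell_count / area,
        mask_area_mm2=area,
    )
    return cells, mask, truth
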