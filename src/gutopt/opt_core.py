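"""Parallel-beam OPT simulation and filtered back-projection reconstruction.

Optical projection tomography (OPT) acquires fluorescence or transmission
projections while the cleared sample rotates through 360 degrees.  With a
high-depth-of-field telecentric setup the acquisition is well approximated
by a parallel-beam Radon transform applied independently to every
cross-sectional slice along the rotation axis.  Reconstruction is classic
filtered back-projection (FBP): each projection profile is ramp-filtered in
the frequency domain and smeared back across the slice grid, with the result
scaled by pi / (2 * n_angles).

Conventions
-----------
* Axis 0 of every volume is the sample long axis (= rotation axis); slices
  are taken perpendicular to it.
* Projection angles are sampled on [0, 360) endpoint-exclusive; the
  redundancy of opposing views is kept rather than folded to 180 degrees,
  matching a full-rotation acquisition.
* The rotation axis projects onto the detector-column centre; voxels outside
  the inscribed reconstruction circle are set to zero (unmeasured region).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import radon as _sk_radon

from .errors import ParameterError

__all__ = [
    "VoxelGrid",
    "ProjectionSet",
    "MultiChannelVolume",
    "forward_project",
    "ramp_filter",
    "reconstruct_fbp",
    "overlay_channels",
]


@dataclass
class VoxelGrid:
    """A 3D single-channel intensity grid with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensities. Axis 0 is the sample long axis.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    channel_label : str
        Free-text channel name (e.g. ``"autofluorescence"``).
    """

    data: np.ndarray
    voxel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"volume must be 3D, got ndim={self.data.ndim}")
        if not self.voxel_size_um > 0:
            raise ParameterError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VoxelGrid":
        return replace(self, data=self.data.copy())


@dataclass
class ProjectionSet:
    """An ordered stack of parallel-beam projections.

    ``projections`` has shape (n_angles, n_rows, n_detector): each page is
    the 2D projection image at one rotation angle, with rows indexing
    position along the rotation axis and columns indexing detector bins.
    """

    projections: np.ndarray
    angles_deg: np.ndarray
    detector_pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.projections.ndim != 3:
            raise ParameterError("projections must be a 3D stack (angle, row, detector)")
        if len(self.angles_deg) != self.projections.shape[0]:
            raise ParameterError(
                f"{len(self.angles_deg)} angles for {self.projections.shape[0]} projections"
            )
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ParameterError("angles must be strictly increasing")
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg >= 360):
            raise ParameterError("angles must lie in [0, 360)")

    @property
    def n_angles(self) -> int:
        return self.projections.shape[0]


@dataclass
class MultiChannelVolume:
    """Lossless stack of co-registered single-channel volumes."""

    data: np.ndarray  # (n_channels, nz, ny, nx)
    voxel_size_um: float
    channel_labels: tuple[str, ...] = field(default_factory=tuple)

    def channel(self, i: int) -> VoxelGrid:
        return VoxelGrid(self.data[i], self.voxel_size_um, self.channel_labels[i])


def forward_project(volume: VoxelGrid, n_angles: int) -> ProjectionSet:
    """Simulate parallel-beam OPT acquisition over a full rotation.

    For every slice along axis 0 the parallel-beam Radon transform is
    evaluated at angles k * 360 / n_angles, k = 0 .. n_angles-1.  Each
    projection bin is a line integral through the slice, so the sum over
    detector bins at any angle conserves the slice mass (up to bilinear
    interpolation error, < 0.5 % relative for signal inside the inscribed
    circle).

    Parameters
    ----------
    volume : VoxelGrid
        Input volume; slice planes must be square and all signal should lie
        inside the inscribed circle of the slice.
    n_angles : int
        Number of projection angles (typical acquisitions use 400 or 1200).
    """
    if n_angles < 2:
        raise ParameterError(f"n_angles must be >= 2, got {n_angles}")
    data = np.asarray(volume.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ParameterError("volume contains non-finite voxels")
    nz, ny, nx = data.shape
    if ny != nx:
        raise ParameterError(f"slice planes must be square for rotation, got {ny}x{nx}")
    angles = np.arange(n_angles) * (360.0 / n_angles)

    # skimage.radon returns a sinogram (detector, angle) per slice.
    projections = np.empty((n_angles, nz, nx), dtype=float)
    for z in range(nz):
        sino = _sk_radon(data[z], theta=angles, circle=True)
        projections[:, z, :] = sino.T
    return ProjectionSet(
        projections=projections,
        angles_deg=angles,
        detector_pixel_size_um=volume.voxel_size_um,
        channel_label=volume.channel_label,
    )


_WINDOWS = ("ramlak", "hann")


def _fourier_ramp(n_pad: int, window: str) -> np.ndarray:
    """Frequency response |f| (optionally Hann-apodised) on an FFT grid."""
    freqs = np.fft.fftfreq(n_pad)
    filt = 2.0 * np.abs(freqs)
    if window == "hann":
        # raised cosine falling to zero at the Nyquist frequency
        filt = filt * 0.5 * (1.0 + np.cos(2.0 * np.pi * freqs))
    elif window != "ramlak":
        raise ParameterError(f"unknown window {window!r}; choose from {_WINDOWS}")
    return filt


def _pad_size(n: int) -> int:
    # pad to >= 2n and a power of two to suppress circular-convolution wrap-around
    return int(max(64, 2 ** int(np.ceil(np.log2(2 * n)))))


def ramp_filter(profile: np.ndarray, window: str = "ramlak") -> np.ndarray:
    """Apply the FBP ramp filter to a 1D projection profile.

    The profile is zero-padded to a power of two, multiplied by |f| in the
    frequency domain (Hann apodisation optional) and cropped back.  The DC
    component of the Ram-Lak output is exactly zero.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 2:
        raise ParameterError("profile must be 1D with length >= 2")
    n = profile.size
    n_pad = _pad_size(n)
    filt = _fourier_ramp(n_pad, window)
    spectrum = np.fft.fft(profile, n_pad) * filt
    return np.real(np.fft.ifft(spectrum))[:n]


def _filter_sinogram(sino: np.ndarray, window: str) -> np.ndarray:
    """Ramp-filter all columns of a (detector, angle) sinogram at once."""
    n = sino.shape[0]
    n_pad = _pad_size(n)
    filt = _fourier_ramp(n_pad, window)[:, None]
    spectrum = np.fft.fft(sino, n_pad, axis=0) * filt
    return np.real(np.fft.ifft(spectrum, axis=0))[:n]


def reconstruct_fbp(ps: ProjectionSet, window: str = "ramlak") -> VoxelGrid:
    """Reconstruct a volume from projections by filtered back-projection.

    Each slice is reconstructed independently: projection profiles are
    ramp-filtered, then smeared back across an n x n grid (n = detector
    width) with linear interpolation, and the accumulated image is scaled by
    pi / (2 * n_angles).  Voxels outside the inscribed circle are zeroed.
    """
    if ps.n_angles < 2:
        raise ParameterError("need at least 2 projection angles")
    if window not in _WINDOWS:
        raise ParameterError(f"unknown window {window!r}; choose from {_WINDOWS}")
    n_angles, nz, n_det = ps.projections.shape
    center = n_det // 2  # rotation-axis convention of the forward transform
    xpr, ypr = np.meshgrid(
        np.arange(n_det) - center, np.arange(n_det) - center, indexing="xy"
    )
    radians = np.deg2rad(ps.angles_deg)
    inside = xpr**2 + ypr**2 <= (n_det / 2.0) ** 2
    det_coords = np.arange(n_det, dtype=float)

    out = np.zeros((nz, n_det, n_det), dtype=float)
    for z in range(nz):
        filtered = _filter_sinogram(ps.projections[:, z, :].T, window)
        recon = np.zeros((n_det, n_det), dtype=float)
        for col, angle in zip(filtered.T, radians):
            t = ypr * np.cos(angle) - xpr * np.sin(angle) + center
            recon += np.interp(t, det_coords, col, left=0.0, right=0.0)
        recon *= np.pi / (2.0 * n_angles)
        recon[~inside] = 0.0
        out[z] = recon
    return VoxelGrid(out, ps.detector_pixel_size_um, ps.channel_label)


def overlay_channels(a: VoxelGrid, b: VoxelGrid) -> MultiChannelVolume:
    """Superimpose two reconstructed channels into one multi-channel volume.

    Stacking is lossless; channel order follows argument order and labels
    are retained.
    """
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.voxel_size_um, b.voxel_size_um):
        raise ParameterError(
            f"voxel size mismatch: {a.voxel_size_um} vs {b.voxel_size_um}"
        )
    return MultiChannelVolume(
        data=np.stack([a.data, b.data]),
        voxel_size_um=a.voxel_size_um,
        channel_labels=(a.channel_label, b.channel_label),
    )
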