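"""Projection simulation and FBP reconstruction against analytic oracles."""

import numpy as np
import pytest
from skimage.transform import iradon

from gutopt import (
    ParameterError,
    ProjectionSet,
    VoxelGrid,
    forward_project,
    overlay_channels,
    ramp_filter,
    reconstruct_fbp,
)
from gutopt.opt_core import _pad_size


def _disk(n, radius, value=1.0):
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - n // 2, xx - n // 2)
    return np.where(r < radius, value, 0.0), r


class TestForwardProject:
    def test_angular_step_matches_acquisition(self):
        vol = VoxelGrid(np.zeros((1, 32, 32)), 1.0)
        ps = forward_project(vol, 1200)
        steps = np.diff(ps.angles_deg)
        assert np.allclose(steps, 0.3)
        assert ps.angles_deg[0] == 0.0 and ps.angles_deg[-1] < 360.0

    def test_empty_volume_projects_to_zero(self):
        ps = forward_project(VoxelGrid(np.zeros((2, 32, 32)), 1.0), 10)
        assert not ps.projections.any()

    def test_mass_conserved_per_angle(self, disk_slice):
        vol = VoxelGrid(disk_slice[None], 1.0)
        ps = forward_project(vol, 50)
        sums = ps.projections[:, 0, :].sum(axis=1)
        assert np.allclose(sums, disk_slice.sum(), rtol=5e-3)

    def test_disk_profile_is_chord_length(self):
        n, radius = 128, 40.0
        disk, _ = _disk(n, radius)
        ps = forward_project(VoxelGrid(disk[None], 1.0), 8)
        s = np.arange(n) - n // 2
        chord = 2 * np.sqrt(np.maximum(radius**2 - s**2, 0.0))
        core = np.abs(s) < 0.9 * radius  # rim excluded: chord slope diverges
        for profile in ps.projections[:, 0, :]:
            rel = np.abs(profile[core] - chord[core]) / chord[core]
            assert rel.max() < 0.03

    def test_rejects_bad_inputs(self):
        vol = VoxelGrid(np.zeros((1, 16, 16)), 1.0)
        with pytest.raises(ParameterError):
            forward_project(vol, 1)
        bad = VoxelGrid(np.full((1, 16, 16), np.nan), 1.0)
        with pytest.raises(ParameterError):
            forward_project(bad, 4)


class TestRampFilter:
    def test_delta_gives_discrete_ramp_kernel(self):
        n = 100
        profile = np.zeros(n)
        profile[40] = 1.0
        out = ramp_filter(profile)
        # independent oracle: inverse FFT of |f| on the padded grid
        n_pad = _pad_size(n)
        kernel = np.real(np.fft.ifft(2.0 * np.abs(np.fft.fftfreq(n_pad))))
        assert np.allclose(out, np.roll(kernel, 40)[:n], atol=1e-12)

    def test_ramlak_kills_dc(self):
        from gutopt.opt_core import _fourier_ramp

        assert _fourier_ramp(_pad_size(128), "ramlak")[0] == 0.0
        # a constant profile is suppressed except for zero-padding edge leakage
        out = ramp_filter(np.ones(128))
        assert np.abs(out[16:-16]).max() < 0.01

    def test_linearity_to_machine_precision(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=64), rng.normal(size=64)
        assert np.allclose(
            ramp_filter(a + b), ramp_filter(a) + ramp_filter(b), atol=1e-12
        )

    def test_hann_attenuates_high_frequencies(self):
        rng = np.random.default_rng(1)
        noisy = rng.normal(size=256)
        assert np.abs(ramp_filter(noisy, "hann")).sum() < np.abs(ramp_filter(noisy)).sum()

    def test_unknown_window_rejected(self):
        with pytest.raises(ParameterError):
            ramp_filter(np.ones(16), window="blackman")


class TestReconstruct:
    def test_round_trip_and_skimage_oracle(self, disk_slice):
        vol = VoxelGrid(disk_slice[None], 1.0)
        ps = forward_project(vol, 200)
        rec = reconstruct_fbp(ps).data[0]
        n = disk_slice.shape[0]
        yy, xx = np.indices((n, n))
        inside = np.hypot(yy - n // 2, xx - n // 2) <= n / 2 - 2
        ncc = np.corrcoef(rec[inside], disk_slice[inside])[0, 1]
        assert ncc >= 0.95
        # independent oracle: skimage's own FBP on the same sinogram
        sk = iradon(ps.projections[:, 0, :].T, theta=ps.angles_deg,
                    filter_name="ramp", circle=True)
        assert np.corrcoef(rec[inside], sk[inside])[0, 1] > 0.98

    def test_more_angles_never_hurt(self, disk_slice):
        vol = VoxelGrid(disk_slice[None], 1.0)
        n = disk_slice.shape[0]
        yy, xx = np.indices((n, n))
        inside = np.hypot(yy - n // 2, xx - n // 2) <= n / 2 - 2
        nccs = []
        for n_angles in (100, 400):
            rec = reconstruct_fbp(forward_project(vol, n_angles)).data[0]
            nccs.append(np.corrcoef(rec[inside], disk_slice[inside])[0, 1])
        assert nccs[1] >= nccs[0]

    def test_zero_projections_give_zero_volume(self):
        ps = ProjectionSet(np.zeros((10, 2, 32)), np.arange(10) * 36.0, 1.0)
        assert not reconstruct_fbp(ps).data.any()

    def test_rotation_consistency(self):
        # odd slice size: the 90-degree rotation pivot then coincides with
        # the tomographic rotation axis at the grid centre
        n = 97
        yy, xx = np.indices((n, n))
        r = np.hypot(yy - n // 2, xx - n // 2)
        img = np.where(r < 20, 1.0, 0.0) + np.where((r > 25) & (r < 40), 0.5, 0.0)
        img[30:40, 50:60] += 0.7  # break rotational symmetry
        rec = reconstruct_fbp(forward_project(VoxelGrid(img[None], 1.0), 400)).data[0]
        rec90 = reconstruct_fbp(
            forward_project(VoxelGrid(np.rot90(img)[None].copy(), 1.0), 400)
        ).data[0]
        mad = np.abs(np.rot90(rec) - rec90).mean()
        assert mad < 0.02 * np.ptp(rec)

    def test_angle_validation(self):
        with pytest.raises(ParameterError):
            ProjectionSet(np.zeros((2, 1, 8)), np.array([10.0, 5.0]), 1.0)
        with pytest.raises(ParameterError):
            ProjectionSet(np.zeros((2, 1, 8)), np.array([0.0, 360.0]), 1.0)


class TestOverlay:
    def test_overlay_preserves_channels_and_order(self):
        a = VoxelGrid(np.ones((2, 4, 4)), 1.0, "autofluorescence")
        b = VoxelGrid(np.zeros((2, 4, 4)), 1.0, "marker")
        two = overlay_channels(a, b)
        assert two.channel_labels == ("autofluorescence", "marker")
        assert np.array_equal(two.channel(0).data, a.data)
        assert not two.channel(1).data.any()

    def test_mismatch_rejected(self):
        a = VoxelGrid(np.ones((2, 4, 4)), 1.0)
        with pytest.raises(ParameterError):
            overlay_channels(a, VoxelGrid(np.ones((2, 4, 5)), 1.0))
        with pytest.raises(ParameterError):
            overlay_channels(a, VoxelGrid(np.ones((2, 4, 4)), 2.0))
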