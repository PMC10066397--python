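"""Virtual unfolding against analytic annulus/cylinder oracles."""

import numpy as np
import pytest
from scipy.ndimage import rotate

from gutopt import (
    EmptyMaskError,
    compute_seam,
    make_annulus_phantom,
    segment_tissue,
    straighten_slice,
    unfold_volume,
)

R_OUT = 120.0
TRUE_PERIMETER = 2 * np.pi * R_OUT


@pytest.fixture(scope="module")
def annulus_outline(annulus_volume):
    return segment_tissue(annulus_volume.data[0], slice_index=0)


class TestSegmentTissue:
    def test_outline_is_outer_circle(self, annulus_outline):
        o = annulus_outline
        centre = np.array([130.0, 130.0])
        assert np.allclose(o.centroid, centre, atol=1.0)
        radii = np.hypot(*(o.polygon - centre).T)
        assert np.allclose(radii, R_OUT, atol=1.5)
        assert o.perimeter_px == pytest.approx(TRUE_PERIMETER, rel=0.02)

    def test_largest_component_kept(self):
        img = np.zeros((64, 64))
        img[10:50, 10:40] = 1.0  # 1200 px
        img[5:10, 55:64] = 1.0  # 45 px debris
        o = segment_tissue(img)
        xs = o.polygon[:, 0]
        assert xs.max() < 45  # outline never reaches the debris blob

    def test_lumen_hole_filled(self, annulus_outline):
        # the centroid lies in the (filled) lumen, inside the outline
        rel = annulus_outline.polygon - annulus_outline.centroid
        assert np.hypot(*rel.T).min() > 100  # no inner-boundary vertices

    def test_blank_slice_raises(self):
        with pytest.raises(EmptyMaskError):
            segment_tissue(np.zeros((32, 32)))


class TestComputeSeam:
    def test_seam_on_circle_matches_trigonometry(self, annulus_outline):
        o = compute_seam(annulus_outline, 45.0)
        seam = o.polygon[o.seam_vertex]
        expected = o.centroid + R_OUT * np.array(
            [np.cos(np.deg2rad(45)), -np.sin(np.deg2rad(45))]  # y-down convention
        )
        assert np.hypot(*(seam - expected)) <= 1.0

    def test_axis_aligned_seam(self, annulus_outline):
        o = compute_seam(annulus_outline, 0.0)
        seam = o.polygon[o.seam_vertex]
        assert seam[0] == pytest.approx(130.0 + R_OUT, abs=1.0)
        assert seam[1] == pytest.approx(130.0, abs=1.0)

    def test_angle_periodicity(self, annulus_outline):
        v1 = compute_seam(annulus_outline, 45.0).seam_vertex
        v2 = compute_seam(annulus_outline, 405.0).seam_vertex
        assert v1 == v2


class TestStraighten:
    def test_width_matches_perimeter(self, annulus_volume):
        o = compute_seam(segment_tissue(annulus_volume.data[0]), 45.0)
        strip = straighten_slice(annulus_volume.data[0], o, 45.0, 5.0, 1.0)
        assert strip.shape[1] == pytest.approx(TRUE_PERIMETER, rel=0.02)

    def test_annulus_strip_uniform_along_arc(self, annulus_volume):
        o = compute_seam(segment_tissue(annulus_volume.data[0]), 45.0)
        strip = straighten_slice(annulus_volume.data[0], o, 35.0, 0.0, 1.0)
        band = strip[10:30]  # rows fully inside the annulus
        cv = band.std(axis=1) / band.mean(axis=1)
        assert cv.max() < 0.01

    def test_rotation_equivariance(self, annulus_volume):
        sl = annulus_volume.data[0]
        rotated = rotate(sl, 30.0, reshape=False, order=1)
        s1 = straighten_slice(sl, compute_seam(segment_tissue(sl), 45.0), 45, 5, 1.0)
        s2 = straighten_slice(
            rotated, compute_seam(segment_tissue(rotated), 15.0), 45, 5, 1.0
        )
        m = min(s1.shape[1], s2.shape[1])
        assert np.abs(s1[:, :m] - s2[:, :m]).mean() < 0.02 * np.ptp(s1)

    def test_band_mass_preserved(self, annulus_volume):
        # Jacobian (1 - d/R) + trapezoid end weights turn the flattened sum
        # back into the polar band integral; valid for bands thin vs. R
        sl = annulus_volume.data[0]
        o = compute_seam(segment_tissue(sl), 45.0)
        strip = straighten_slice(sl, o, 10.0, 0.0, 1.0)
        d = np.arange(strip.shape[0], dtype=float)
        w = 1.0 - d / R_OUT
        w[0] *= 0.5
        w[-1] *= 0.5
        flattened_mass = float((strip * w[:, None]).sum())
        yy, xx = np.indices(sl.shape)
        r = np.hypot(yy - 130.0, xx - 130.0)
        band_mass = sl[(r < R_OUT) & (r >= R_OUT - 10)].sum()
        assert flattened_mass == pytest.approx(band_mass, rel=0.05)

    def test_overdeep_band_warns_and_clamps(self, annulus_volume):
        o = compute_seam(segment_tissue(annulus_volume.data[0]), 45.0)
        with pytest.warns(UserWarning):
            strip = straighten_slice(annulus_volume.data[0], o, 200.0, 0.0, 1.0)
        assert np.isfinite(strip).all()


class TestUnfoldVolume:
    def test_band_layers_uniform_and_outside_empty(self, annulus_volume):
        res = unfold_volume(annulus_volume, 45.0, 45.0, 5.0)
        mid = res.unfolded_volume[30]  # 25 um inside the outline: in the annulus
        assert mid.std() / mid.mean() < 0.01
        assert res.unfolded_volume[0].max() < 0.05  # 5 um outside: background

    def test_unfolded_is_transposition_of_straightened(self, annulus_volume):
        res = unfold_volume(annulus_volume, 45.0, 30.0, 0.0)
        assert np.array_equal(
            res.unfolded_volume, np.transpose(res.straightened_stack, (1, 0, 2))
        )
        assert np.array_equal(
            np.sort(res.unfolded_volume, axis=None),
            np.sort(res.straightened_stack, axis=None),
        )

    def test_single_slice_volume(self):
        vol = make_annulus_phantom(80.0, 120.0, (1, 260, 260), 1.0)
        res = unfold_volume(vol, 45.0, 20.0, 0.0)
        assert res.unfolded_volume.shape[1] == 1

    def test_seam_collinear_across_slices(self, annulus_volume):
        res = unfold_volume(annulus_volume, 45.0, 10.0, 0.0)
        seams = np.array(
            [o.polygon[o.seam_vertex] for o in res.seam_metadata]
        )
        assert np.ptp(seams[:, 0]) <= 1.0 and np.ptp(seams[:, 1]) <= 1.0

    def test_failed_slices_recorded_then_abort(self):
        good = make_annulus_phantom(80.0, 120.0, (10, 260, 260), 1.0).data.copy()
        good[3] = 0.0  # 10% failures: tolerated and recorded
        from gutopt import VoxelGrid

        res = unfold_volume(VoxelGrid(good, 1.0), 45.0, 10.0, 0.0)
        assert res.failed_slices == [3]
        assert not res.straightened_stack[3].any()
        good[5:9] = 0.0  # 50% failures: abort
        with pytest.raises(EmptyMaskError):
            unfold_volume(VoxelGrid(good, 1.0), 45.0, 10.0, 0.0)
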