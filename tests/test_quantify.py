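"""Villous density, follicle segmentation/statistics and cell density."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from gutopt import (
    FollicleSpec,
    FollicleTable,
    InsufficientObjectsError,
    ParameterError,
    PhantomSpec,
    VoxelGrid,
    cell_density,
    follicle_stats,
    make_gut_phantom,
    make_section_image,
    nearest_neighbour_distances,
    opt_visible,
    segment_follicles,
    unfold_volume,
    villous_density,
)

FOLLICLE_BASE = dict(
    grid_shape=(560, 96, 96),
    voxel_size_um=5.0,
    lumen_radius_um=60.0,
    mucosa_outer_radius_um=150.0,
    submucosa_outer_radius_um=190.0,
    muscularis_outer_radius_um=220.0,
)


def _table_from_centroids(centroids):
    """Minimal FollicleTable for pure distance arithmetic."""
    rows = [
        {"label": i + 1, "voxel_count": 1, "volume_um3": 1.0,
         "centroid_z_um": z, "centroid_y_um": y, "centroid_x_um": x,
         "bbox_zmin_index": 0, "bbox_zmax_index": 0}
        for i, (z, y, x) in enumerate(centroids)
    ]
    return FollicleTable(pd.DataFrame(rows), 0.5, 2.0, 1, 5.0)


class TestVillousDensity:
    def test_exact_count_on_noiseless_phantom(self, gut_spec, apex_layer):
        dmap = villous_density(apex_layer, 5.0, 250.0, 0.05, 40.0)
        assert dmap.total_count == len(gut_spec.follicle_specs) * 0 + 48
        assert dmap.total_count == 8 * 6  # villi per ring x rings

    def test_count_robust_to_ten_percent_noise(self, gut_spec, gut_unfolded):
        noisy_spec = dataclasses.replace(gut_spec, noise_sigma=0.08, rng_seed=3)
        autofluo, _, truth = make_gut_phantom(noisy_spec)
        res = unfold_volume(autofluo, 45.0, 200.0, 10.0, 5.0)
        layer = res.unfolded_volume[33]
        dmap = villous_density(layer, 5.0, 250.0, 0.05, 40.0)
        n_true = len(truth.villus_apexes)
        assert abs(dmap.total_count - n_true) <= 0.1 * n_true

    def test_sector_counts_partition_total(self, apex_layer):
        dmap = villous_density(apex_layer, 5.0, 120.0, 0.05, 40.0)
        assert dmap.sector_counts.sum() == dmap.total_count
        area_mm2 = (120.0**2) * 1e-6
        assert np.allclose(dmap.density_per_mm2, dmap.sector_counts / area_mm2)

    def test_constant_layer_yields_zero(self):
        dmap = villous_density(np.full((64, 64), 0.7), 5.0, 100.0, 0.05)
        assert dmap.total_count == 0

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            villous_density(np.ones((8, 8)), 5.0, 5.0, 0.05)  # sector < 2 px


@pytest.fixture(scope="module")
def sphere_phantom():
    vols = [1e6, 2e6, 3e6, 5e6]
    radii = [(3 * v / (4 * math.pi)) ** (1 / 3) for v in vols]
    specs = [
        FollicleSpec((250.0 + 500.0 * k + 150.0, 240.0, 240.0), (r, r, r))
        for k, r in enumerate(radii)
    ]
    spec = PhantomSpec(**FOLLICLE_BASE, follicle_specs=specs, rng_seed=0)
    _, marker, truth = make_gut_phantom(spec)
    return marker, truth


class TestSegmentFollicles:
    def test_volumes_recovered_within_ten_percent(self, sphere_phantom):
        marker, truth = sphere_phantom
        table = segment_follicles(marker, 0.5, smoothing_sigma_um=2.0, min_voxels=10)
        assert len(table) == len(truth.follicles)
        measured = np.sort(table.volumes_um3)
        analytic = np.sort([v for _, v in truth.follicles])
        assert np.all(np.abs(measured - analytic) / analytic < 0.10)
        # ordering preserved (sorting by centroid z matches analytic order)
        by_z = table.table.sort_values("centroid_z_um")["volume_um3"].to_numpy()
        assert np.all(np.diff(by_z) > 0)

    def test_voxel_filter_is_exact_around_cutoff(self):
        data = np.zeros((20, 20, 20))
        data[2:4, 2:4, 2:4] = 1.0  # 8 voxels
        data[10:13, 10:13, 10:13] = 1.0  # 27 voxels
        grid = VoxelGrid(data, 5.0)
        kept = segment_follicles(grid, 0.5, smoothing_sigma_um=0.0, min_voxels=9)
        assert kept.table["voxel_count"].tolist() == [27]
        both = segment_follicles(grid, 0.5, smoothing_sigma_um=0.0, min_voxels=8)
        assert sorted(both.table["voxel_count"]) == [8, 27]
        none = segment_follicles(grid, 0.5, smoothing_sigma_um=0.0, min_voxels=28)
        assert len(none) == 0

    def test_volume_estimate_converges_with_voxel_size(self):
        errs = []
        for v in (10.0, 5.0, 2.5):
            f = FollicleSpec((300.0, 300.0, 300.0), (100.0, 100.0, 100.0))
            n = int(600 / v)
            spec = PhantomSpec((n, n, n), v, 60.0, 150.0, 190.0, 230.0,
                               follicle_specs=[f], rng_seed=0)
            _, marker, _ = make_gut_phantom(spec)
            table = segment_follicles(marker, 0.5, 2.0, 1)
            errs.append(abs(table.volumes_um3[0] - f.analytic_volume_um3)
                        / f.analytic_volume_um3)
        assert errs[0] < 0.10
        assert errs[2] <= errs[0]

    def test_threshold_outside_range_rejected(self):
        grid = VoxelGrid(np.zeros((4, 4, 4)), 1.0)
        with pytest.raises(ParameterError):
            segment_follicles(grid, 0.5)


class TestFollicleStats:
    def test_collinear_hand_arithmetic(self):
        table = _table_from_centroids([(0, 0, 0), (500, 0, 0), (1000, 0, 0)])
        stats = follicle_stats(table).table
        mid = stats.iloc[1]
        assert (mid["min_distance_um"], mid["mean_distance_um"],
                mid["max_distance_um"]) == (500, 500, 500)
        for end in (stats.iloc[0], stats.iloc[2]):
            assert (end["min_distance_um"], end["mean_distance_um"],
                    end["max_distance_um"]) == (500, 750, 1000)

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(0)
        cents = rng.uniform(0, 2000, size=(12, 3))
        stats = follicle_stats(_table_from_centroids(cents)).table
        for i in range(len(cents)):
            d = np.array([np.linalg.norm(cents[i] - cents[j])
                          for j in range(len(cents)) if j != i])
            assert stats.iloc[i]["min_distance_um"] == pytest.approx(d.min(), abs=1e-12)
            assert stats.iloc[i]["mean_distance_um"] == pytest.approx(d.mean(), abs=1e-9)
            assert stats.iloc[i]["max_distance_um"] == pytest.approx(d.max(), abs=1e-12)

    def test_duplicate_centroids_give_zero(self):
        stats = follicle_stats(_table_from_centroids([(5, 5, 5), (5, 5, 5)])).table
        assert np.all(stats["min_distance_um"] == 0.0)

    def test_single_follicle_rejected(self):
        with pytest.raises(InsufficientObjectsError):
            follicle_stats(_table_from_centroids([(0, 0, 0)]))

    def test_axial_nn_mode_uses_neighbours_only(self):
        table = _table_from_centroids([(0, 0, 0), (400, 0, 0), (1000, 0, 0)])
        stats = follicle_stats(table, mode="axial_nn").table
        assert stats.iloc[0]["max_distance_um"] == 400  # not 1000
        assert stats.iloc[1]["max_distance_um"] == 600

    def test_nearest_neighbour_helper(self):
        table = _table_from_centroids([(0, 0, 0), (500, 0, 0), (1200, 0, 0)])
        assert nearest_neighbour_distances(table).tolist() == [500, 500, 700]


class TestCellDensity:
    def test_round_trip_with_section_generator(self):
        _, mask, truth = make_section_image(400, 1.0, 1.0, seed=5)
        density = cell_density(truth.cell_coords_um, mask, 1.0)
        assert density == truth.density_cells_per_mm2 == 400.0

    def test_points_outside_mask_ignored(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:40, 10:40] = True
        outside = np.array([[1.0, 1.0], [45.5, 45.5]])
        assert cell_density(outside, mask, 1.0) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            cell_density(np.zeros((0, 2)), np.zeros((8, 8), dtype=bool), 1.0)

    @pytest.mark.parametrize(
        "density,expected", [(400.0, True), (399.9, False), (0.0, False), (1e4, True)]
    )
    def test_visibility_threshold_inclusive(self, density, expected):
        assert opt_visible(density) is expected

    def test_negative_density_rejected(self):
        with pytest.raises(ParameterError):
            opt_visible(-1.0)
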