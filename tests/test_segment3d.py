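"""Unit and property tests for the 3-stage watershed segmentation."""

import numpy as np
import pytest

import mcts_nucleus.synthetic_mcts as syn
from mcts_nucleus.nucfeatures import measure_nuclei
from mcts_nucleus.segment3d import (
    SeedSet,
    SegmentationConfig,
    adaptive_threshold,
    clean_mask,
    find_oversized,
    generate_seeds,
    inject_seeds,
    interpolate_isotropic,
    prune_small_seeds,
    segment_nuclei,
    smooth,
    watershed_split,
)
from mcts_nucleus.stack_io import LabelVolume, VoxelGrid

from conftest import resample_labels_to_iso, voxel_sphere


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

class TestInterpolateIsotropic:
    def test_constant_field_invariant(self):
        grid = VoxelGrid(np.full((5, 8, 8), 3.5, np.float32), (0.9, 0.45, 0.45))
        out = interpolate_isotropic(grid)
        assert out.shape == (9, 8, 8)  # same physical extent, dz/dx = 2
        assert out.spacing == pytest.approx((0.45, 0.45, 0.45))
        np.testing.assert_allclose(out.data, 3.5)

    def test_linear_ramp_matches_analytic(self):
        # I = z-index; physical I(z) = z/0.9 so at new pitch 0.45 the
        # interpolated plane j must equal j/2 exactly (linear in z)
        nz = 7
        data = np.broadcast_to(np.arange(nz, dtype=np.float32)[:, None, None], (nz, 4, 4)).copy()
        out = interpolate_isotropic(VoxelGrid(data, (0.9, 0.45, 0.45)))
        expected = np.arange(out.shape[0]) * 0.5
        np.testing.assert_allclose(out.data[:, 2, 2], expected, atol=1e-6)

    def test_isotropic_identity(self):
        grid = VoxelGrid(np.random.default_rng(0).random((4, 4, 4)), (0.5, 0.5, 0.5))
        out = interpolate_isotropic(grid)
        assert out.shape == grid.shape
        np.testing.assert_array_equal(out.data, grid.data)

    def test_anisotropic_lateral_rejected(self):
        with pytest.raises(ValueError, match="lateral"):
            interpolate_isotropic(VoxelGrid(np.zeros((4, 4, 4)), (0.9, 0.5, 0.4)))


class TestSmooth:
    def test_sigma_zero_identity(self):
        g = VoxelGrid(np.random.default_rng(0).random((6, 6, 6)).astype(np.float32), (1, 1, 1))
        assert smooth(g, 0.0) is g

    def test_point_source_matches_sampled_kernel(self):
        # independent oracle: sampled-and-normalized 3D Gaussian kernel
        n = 17
        data = np.zeros((n, n, n), np.float32)
        data[n // 2, n // 2, n // 2] = 1.0
        out = smooth(VoxelGrid(data, (1.0, 1.0, 1.0)), sigma=1.0)
        ax = np.arange(n) - n // 2
        k1 = np.exp(-0.5 * ax**2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        np.testing.assert_allclose(out.data, kernel, atol=1e-5)

    def test_constant_unchanged_and_mass_conserved(self):
        g = VoxelGrid(np.full((12, 12, 12), 7.0, np.float32), (0.5, 0.5, 0.5))
        out = smooth(g, 1.0)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-5)
        assert out.data.sum() == pytest.approx(g.data.sum(), rel=1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth(VoxelGrid(np.zeros((4, 4, 4)), (1, 1, 1)), -1.0)


class TestAdaptiveThreshold:
    def test_recovers_bright_cube(self):
        data = np.zeros((60, 60, 60), np.float32)
        data[20:40, 20:40, 20:40] = 100.0
        mask = adaptive_threshold(VoxelGrid(data, (1, 1, 1)))
        truth = data > 0
        agreement = (mask == truth).mean()
        assert agreement >= 0.99

    def test_constant_grid_gives_empty_foreground(self):
        mask = adaptive_threshold(VoxelGrid(np.full((10, 10, 10), 5.0), (1, 1, 1)))
        assert not mask.any()  # strict inequality against the local mean

    def test_matches_bruteforce_local_mean(self):
        # independent oracle: explicit clipped-window mean via loops
        rng = np.random.default_rng(3)
        data = rng.random((6, 6, 6)).astype(np.float32)
        grid = VoxelGrid(data, (1, 1, 1))
        mask = adaptive_threshold(grid, window_fraction=0.5)  # window 3³
        expected = np.zeros_like(data, dtype=bool)
        h = 1  # half-width of a size-3 window
        for z in range(6):
            for y in range(6):
                for x in range(6):
                    w = data[
                        max(z - h, 0) : z + h + 1,
                        max(y - h, 0) : y + h + 1,
                        max(x - h, 0) : x + h + 1,
                    ]
                    expected[z, y, x] = data[z, y, x] > w.mean()
        np.testing.assert_array_equal(mask, expected)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="window"):
            adaptive_threshold(VoxelGrid(np.zeros((4, 4, 4)), (1, 1, 1)), window_fraction=0.25)

    def test_step_image_boundary_within_one_voxel(self):
        data = np.zeros((8, 8, 40), np.float32)
        data[:, :, 20:] = 10.0
        mask = adaptive_threshold(VoxelGrid(data, (1, 1, 1)))
        # the transition sits exactly at the step (deep inside the bright
        # plateau the local window saturates and the strict ">" drops out)
        assert not mask[:, :, :20].any()
        assert mask[:, :, 20:29].all()


class TestCleanMask:
    def test_hollow_sphere_filled(self):
        solid = voxel_sphere(8)
        shell = solid & ~voxel_sphere(6, pad=4)
        assert shell.sum() < solid.sum()
        out = clean_mask(shell, 0.0, (1, 1, 1))
        np.testing.assert_array_equal(out, solid)

    def test_small_objects_removed(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[2:4, 2:4, 2:4] = True  # 8 voxels
        mask[10:32, 10:32, 10:32] = True  # 10648 voxels
        out = clean_mask(mask, 100.0, (1, 1, 1))
        assert not out[2, 2, 2]
        assert out[20, 20, 20]

    def test_empty_mask_passthrough(self):
        out = clean_mask(np.zeros((5, 5, 5), bool), 50.0, (1, 1, 1))
        assert not out.any()


# ---------------------------------------------------------------------------
# Seeding and watershed
# ---------------------------------------------------------------------------

def _dumbbell(r=6, sep=9, pad=4):
    """Two overlapping balls with centers ``sep`` voxels apart along x."""
    nz = 2 * r + 2 * pad + 1
    nx = 2 * r + sep + 2 * pad + 1
    zz, yy, xx = np.mgrid[:nz, :nz, :nx]
    cz = (nz - 1) / 2
    c1x = pad + r
    c2x = c1x + sep
    m1 = (zz - cz) ** 2 + (yy - cz) ** 2 + (xx - c1x) ** 2 <= r * r
    m2 = (zz - cz) ** 2 + (yy - cz) ** 2 + (xx - c2x) ** 2 <= r * r
    return m1 | m2, c1x, c2x


class TestGenerateSeeds:
    def test_single_sphere_single_central_seed(self):
        mask = voxel_sphere(7)
        seeds = generate_seeds(mask, 1.0, (1, 1, 1))
        assert len(seeds) == 1
        center = (np.array(mask.shape) - 1) / 2
        assert np.linalg.norm(np.array(seeds.points[0]) - center) <= 2.0

    def test_dumbbell_two_seeds_small_hmin(self):
        mask, c1x, c2x = _dumbbell()
        seeds = generate_seeds(mask, 0.5, (1, 1, 1))
        assert len(seeds) == 2
        xs = sorted(p[2] for p in seeds.points)
        assert abs(xs[0] - c1x) <= 2 and abs(xs[1] - c2x) <= 2

    def test_dumbbell_merges_at_large_hmin(self):
        mask, *_ = _dumbbell(r=6)
        seeds = generate_seeds(mask, 3.5, (1, 1, 1))  # depth > r/2
        assert len(seeds) == 1

    @pytest.mark.parametrize("shape_seed", [0, 1])
    def test_seed_count_monotone_in_hmin(self, shape_seed):
        rng = np.random.default_rng(shape_seed)
        mask = np.zeros((30, 30, 30), bool)
        for _ in range(6):  # random overlapping balls
            c = rng.integers(6, 24, size=3)
            r = rng.integers(3, 7)
            zz, yy, xx = np.mgrid[:30, :30, :30]
            mask |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r
        counts = [len(generate_seeds(mask, h, (1, 1, 1))) for h in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_mask(self):
        assert len(generate_seeds(np.zeros((5, 5, 5), bool), 1.0, (1, 1, 1))) == 0


class TestWatershedSplit:
    def test_single_sphere_single_label(self):
        mask = voxel_sphere(7)
        c = tuple(int(v) for v in (np.array(mask.shape) - 1) // 2)
        labels = watershed_split(mask, SeedSet([c]), (1, 1, 1))
        assert labels.ids().tolist() == [1]
        assert (labels.labels > 0).sum() == mask.sum()

    def test_dumbbell_divides_at_symmetry_plane(self):
        mask, c1x, c2x = _dumbbell()
        cz = (mask.shape[0] - 1) // 2
        labels = watershed_split(mask, SeedSet([(cz, cz, c1x), (cz, cz, c2x)]), (1, 1, 1))
        mid = (c1x + c2x) / 2
        left = labels.labels[:, :, : int(mid - 1)]
        right = labels.labels[:, :, int(mid + 2) :]
        assert set(np.unique(left[left > 0])) == {1}
        assert set(np.unique(right[right > 0])) == {2}

    def test_partition_property(self):
        mask, c1x, c2x = _dumbbell()
        cz = (mask.shape[0] - 1) // 2
        labels = watershed_split(mask, SeedSet([(cz, cz, c1x), (cz, cz, c2x)]), (1, 1, 1))
        counts = np.bincount(labels.labels.ravel())
        assert counts[1:].sum() == mask.sum()  # every foreground voxel labelled once

    def test_background_seed_rejected(self):
        mask = voxel_sphere(5)
        with pytest.raises(ValueError, match=r"\(0, 0, 0\)"):
            watershed_split(mask, SeedSet([(0, 0, 0)]), (1, 1, 1))


def _blocks_volume(volumes_vox):
    """Disjoint cuboid labels with prescribed voxel counts + their seeds."""
    shape = (10, 10, 12 * len(volumes_vox))
    arr = np.zeros(shape, np.int32)
    seeds = []
    for i, v in enumerate(volumes_vox):
        nx = v // 25  # 5 × 5 × nx cuboid
        x0 = 12 * i
        arr[2:7, 2:7, x0 : x0 + nx] = i + 1
        seeds.append((4, 4, x0))
    return LabelVolume(arr, (1.0, 1.0, 1.0)), SeedSet(seeds)


class TestSeedCorrection:
    def test_prune_small_seed_below_median_fraction(self):
        labels, seeds = _blocks_volume([100, 100, 50, 100])  # 50 < 0.7 × 100
        pruned = prune_small_seeds(labels, seeds, 0.7)
        assert len(pruned) == 3
        assert pruned.source == "PRUNED"
        assert seeds.points[2] not in pruned.points

    def test_prune_keeps_equal_volumes(self):
        labels, seeds = _blocks_volume([100, 100, 100])
        assert len(prune_small_seeds(labels, seeds, 0.7)) == 3

    def test_single_object_never_pruned(self):
        labels, seeds = _blocks_volume([100])
        assert len(prune_small_seeds(labels, seeds, 0.7)) == 1

    def test_prune_detects_mismatched_correspondence(self):
        labels, seeds = _blocks_volume([100, 100])
        bad = SeedSet([seeds.points[1], seeds.points[0]])  # swapped
        with pytest.raises(ValueError, match="label"):
            prune_small_seeds(labels, bad, 0.7)

    def test_find_oversized_strict_inequality(self):
        labels, _ = _blocks_volume([100, 100, 150])
        assert find_oversized(labels, 1.4) == [3]
        labels, _ = _blocks_volume([100, 100, 100])
        assert find_oversized(labels, 1.4) == []
        # 139% of the median is not *more than* 40% larger
        labels, _ = _blocks_volume([100, 100, 125])
        assert find_oversized(labels, 1.25) == []

    def test_find_oversized_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            find_oversized(LabelVolume(np.zeros((4, 4, 4), np.int32), (1, 1, 1)), 1.4)

    def test_inject_empty_map_identity(self):
        labels, seeds = _blocks_volume([100, 100])
        assert inject_seeds(seeds, {}, labels) is seeds

    def test_inject_point_in_wrong_label_rejected(self):
        labels, seeds = _blocks_volume([100, 100])
        with pytest.raises(ValueError, match="label"):
            inject_seeds(seeds, {1: [(4, 4, 12)]}, labels)  # lies in label 2

    def test_inject_splits_merged_cluster(self):
        mask, c1x, c2x = _dumbbell()
        cz = (mask.shape[0] - 1) // 2
        merged = watershed_split(mask, SeedSet([(cz, cz, (c1x + c2x) // 2)]), (1, 1, 1))
        assert merged.ids().size == 1
        seeds = inject_seeds(
            SeedSet([(cz, cz, (c1x + c2x) // 2)]),
            {1: [(cz, cz, c1x), (cz, cz, c2x)]},
            merged,
        )
        assert seeds.source == "INJECTED"
        split = watershed_split(mask, seeds, (1, 1, 1))
        assert split.ids().size == 2


# ---------------------------------------------------------------------------
# Orchestration on phantoms
# ---------------------------------------------------------------------------

class TestSegmentNuclei:
    def test_sparse_phantom_fully_recovered(self, sparse_phantom):
        spec, channels, truth_labels, truth = sparse_phantom
        labels, seeds = segment_nuclei(channels["dapi"], SegmentationConfig())
        assert labels.ids().size == len(truth)
        records = measure_nuclei(labels)
        centroids = np.array([r.centroid for r in records])
        match = syn.match_detections(truth, centroids)
        assert match["f1"] == 1.0
        tl_iso = resample_labels_to_iso(truth_labels, labels.shape, labels.spacing)
        jac = syn.overlap_jaccard(tl_iso, labels)
        assert (jac["jaccard"] >= 0.7).all()

    def test_empty_stack_zero_labels(self):
        grid = VoxelGrid(np.zeros((12, 20, 20), np.float32), (0.9, 0.45, 0.45))
        labels, seeds = segment_nuclei(grid, SegmentationConfig())
        assert labels.ids().size == 0
        assert len(seeds) == 0

    def test_xy_rotation_equivariance(self):
        spec = syn.PhantomSpec(spheroid_radius=25.0, n_nuclei=8, transfection_rate=0.0)
        channels, _, _ = syn.generate_phantom(spec, seed=9)
        grid = channels["dapi"]
        rot = VoxelGrid(np.rot90(grid.data, axes=(1, 2)).copy(), grid.spacing)
        cfg = SegmentationConfig()
        lab = segment_nuclei(grid, cfg)[0]
        lab_rot = segment_nuclei(rot, cfg)[0]
        assert lab.ids().size == lab_rot.ids().size
        # foreground masks must agree up to border effects
        fg_rot = np.rot90(lab.labels > 0, axes=(1, 2))
        agreement = (fg_rot == (lab_rot.labels > 0)).mean()
        assert agreement >= 0.995


class TestSegmentationConfig:
    def test_fraction_ordering_enforced(self):
        with pytest.raises(ValueError):
            SegmentationConfig(small_seed_fraction=1.2)
        with pytest.raises(ValueError):
            SegmentationConfig(oversize_fraction=0.9)

    def test_connectivity_validated(self):
        with pytest.raises(ValueError):
            SegmentationConfig(connectivity=4)
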