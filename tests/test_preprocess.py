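"""Preprocessing: remapping, equalization, cropping, patching, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neuroseg3d as ns
from neuroseg3d.io_nifti import IntensityVolume, LabelVolume
from neuroseg3d.preprocess import (histogram_equalize, load_patch_stack,
                                   save_patch_stack)


def _lab(arr):
    return LabelVolume(voxels=np.asarray(arr, dtype=np.int32))


def _img(arr):
    return IntensityVolume(voxels=np.asarray(arr, dtype=np.float32))


# ---------------------------------------------------------------------------
# remap_labels
# ---------------------------------------------------------------------------

class TestRemapLabels:
    def test_all_background_unchanged(self):
        lab = _lab(np.zeros((4, 4, 4)))
        out = ns.remap_labels(lab, {2: 1, 41: 2})
        assert not out.voxels.any()

    def test_direct_substitution(self):
        lab = _lab(np.array([2, 41]).reshape(1, 1, 2))
        out = ns.remap_labels(lab, {2: 1, 41: 2})
        np.testing.assert_array_equal(out.voxels.ravel(), [1, 2])

    def test_unmapped_ids_become_background(self, rng):
        """Unmapped source IDs go to 0; verified by exhaustive voxel scan."""
        src = rng.integers(0, 100, (6, 6, 6)).astype(np.int32)
        mapping = {2: 1, 41: 2, 99: 3}
        out = ns.remap_labels(_lab(src), mapping)
        for idx in np.ndindex(src.shape):  # brute-force per-voxel check
            expected = mapping.get(int(src[idx]), 0)
            assert out.voxels[idx] == expected
        assert out.voxels.size == src.size  # total voxel count preserved
        assert set(np.unique(out.voxels)) <= {0, 1, 2, 3}

    @pytest.mark.parametrize("bad", [{5: 0}, {1: 2, 3: 2}, {0: 1}])
    def test_invalid_mappings_rejected(self, bad):
        with pytest.raises(ValueError):
            ns.remap_labels(_lab(np.zeros((2, 2, 2))), bad)


# ---------------------------------------------------------------------------
# normalize_intensity
# ---------------------------------------------------------------------------

class TestNormalizeIntensity:
    def test_four_voxel_toy_matches_hand_cdf(self):
        """[0,1,2,3] with 4 bins: per-bin CDF (0.25,0.5,0.75,1.0) min-max
        rescales to (0, 1/3, 2/3, 1)."""
        vol = _img(np.array([0.0, 1.0, 2.0, 3.0]).reshape(1, 2, 2))
        out = ns.normalize_intensity(vol, nbins=4)
        np.testing.assert_allclose(np.sort(out.voxels.ravel()),
                                   [0.0, 1 / 3, 2 / 3, 1.0], atol=1e-6)

    def test_output_range_exactly_unit_interval(self, rng):
        out = ns.normalize_intensity(_img(rng.random((8, 8, 8)) * 100 - 7))
        assert out.voxels.min() == 0.0
        assert out.voxels.max() == 1.0

    def test_uniform_histogram_is_near_fixed_point(self, rng):
        """An already-uniform intensity distribution is (nearly) a fixed
        point: deviations are bounded by bin quantization plus the sampling
        error of the empirical CDF (~3/√n)."""
        v = rng.random((32, 32, 32))
        out = ns.normalize_intensity(_img(v), nbins=256)
        assert np.abs(out.voxels - v).max() < 1 / 256 + 3 / np.sqrt(v.size) + 1e-3

    def test_constant_volume_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ns.normalize_intensity(_img(np.full((4, 4, 4), 3.7)))
        assert not out.voxels.any()

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_equalization_is_monotone(self, seed):
        """Voxel intensity order is preserved up to equalization-bin ties."""
        v = np.random.default_rng(seed).random(200)
        eq = histogram_equalize(v, nbins=16)
        order = np.argsort(v, kind="stable")
        diffs = np.diff(eq[order])
        assert (diffs >= -1e-12).all()


# ---------------------------------------------------------------------------
# remove_empty_slices
# ---------------------------------------------------------------------------

class TestRemoveEmptySlices:
    def test_constructed_padding_removed(self, rng):
        core = rng.random((12, 12, 12)) + 0.1
        vol = np.zeros((32, 12, 12))
        vol[10:22] = core
        img, lab = _img(vol), _lab(np.zeros_like(vol))
        out_img, out_lab = ns.remove_empty_slices(img, lab)
        assert out_img.shape == (12, 12, 12)
        assert out_lab.shape == (12, 12, 12)
        np.testing.assert_allclose(out_img.voxels, core, atol=1e-6)

    def test_no_empty_slices_is_identity(self, rng):
        v = rng.random((8, 8, 8)) + 0.1
        img, lab = ns.remove_empty_slices(_img(v), _lab(np.zeros((8, 8, 8))))
        np.testing.assert_array_equal(img.voxels, np.float32(v))

    def test_crop_box_equals_brute_force_bounding_box(self, rng):
        """Crop equals the brute-force bounding box of nonzero intensities."""
        vol = np.zeros((20, 24, 18))
        off = (3, 7, 2)
        spec = ns.PhantomSpec(shape=(9, 9, 9), n_structures=2, seed=5,
                              intensity_means=(0.3, 0.6, 0.9))
        phantom_img, _ = ns.generate_phantom(spec)
        vol[off[0]:off[0] + 9, off[1]:off[1] + 9, off[2]:off[2] + 9] = phantom_img.voxels
        img, _ = ns.remove_empty_slices(_img(vol), _lab(np.zeros_like(vol, dtype=np.int32)))
        nz = np.argwhere(vol > 0)  # brute-force bounding box
        lo, hi = nz.min(axis=0), nz.max(axis=0)
        assert img.shape == tuple(hi - lo + 1)

    def test_fully_empty_volume_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ns.remove_empty_slices(_img(np.zeros((4, 4, 4))),
                                   _lab(np.zeros((4, 4, 4))))


# ---------------------------------------------------------------------------
# extract / reassemble
# ---------------------------------------------------------------------------

class TestPatching:
    def test_192_cube_gives_27_patches(self):
        v = np.random.default_rng(0).random((192, 192, 192)).astype(np.float32)
        stack = ns.extract_patches(_img(v), _lab(np.zeros_like(v, dtype=np.int32)),
                                   patch_size=64)
        assert len(stack) == 27
        assert stack.padded_shape == (192, 192, 192)

    def test_65_cube_pads_to_128_eight_patches(self):
        v = np.zeros((65, 65, 65), dtype=np.float32)
        stack = ns.extract_patches(_img(v), _lab(np.zeros_like(v, dtype=np.int32)),
                                   patch_size=64)
        assert stack.padded_shape == (128, 128, 128)
        assert len(stack) == 8

    @pytest.mark.parametrize("shape,patch", [((40, 33, 21), 16), ((64, 64, 64), 64),
                                             ((17, 9, 30), 8)])
    def test_round_trip_identity(self, rng, shape, patch):
        """reassemble∘extract reproduces the source volume voxel-for-voxel."""
        img = _img(rng.random(shape))
        lab = _lab(rng.integers(0, 5, shape))
        stack = ns.extract_patches(img, lab, patch_size=patch)
        back_img, back_lab = ns.reassemble_patches(stack, crop=True)
        np.testing.assert_array_equal(back_img.voxels, img.voxels)
        np.testing.assert_array_equal(back_lab.voxels, lab.voxels)

    def test_patch_partition_covers_padded_volume_once(self, rng):
        """Summing per-patch indicator volumes gives exactly 1 everywhere."""
        img = _img(rng.random((20, 12, 9)))
        lab = _lab(rng.integers(0, 3, (20, 12, 9)))
        stack = ns.extract_patches(img, lab, patch_size=8)
        cover = np.zeros(stack.padded_shape, dtype=int)
        p = stack.patch_size
        for (i, j, k) in stack.grid_origin:
            cover[i:i + p, j:j + p, k:k + p] += 1
        assert (cover == 1).all()

    def test_missing_block_raises_with_grid_index(self, rng):
        img = _img(rng.random((16, 16, 16)))
        lab = _lab(rng.integers(0, 2, (16, 16, 16)))
        stack = ns.extract_patches(img, lab, patch_size=8)
        del stack.patches[3], stack.grid_origin[3]
        with pytest.raises(ValueError, match=r"\(0, 8, 8\)"):
            ns.reassemble_patches(stack)

    def test_drop_background_and_refill(self, rng):
        lab_arr = np.zeros((16, 16, 16), dtype=np.int32)
        lab_arr[:8, :8, :8] = 1
        img = _img(rng.random((16, 16, 16)))
        stack = ns.extract_patches(img, _lab(lab_arr), patch_size=8,
                                   drop_background=True)
        assert len(stack) == 1
        _, back = ns.reassemble_patches(stack, allow_missing=True)
        np.testing.assert_array_equal(back.voxels, lab_arr)

    def test_hdf5_stack_round_trip(self, tmp_path, rng):
        img = _img(rng.random((20, 20, 20)))
        lab = _lab(rng.integers(0, 4, (20, 20, 20)))
        stack = ns.extract_patches(img, lab, patch_size=16)
        save_patch_stack(stack, tmp_path / "s.h5")
        back = load_patch_stack(tmp_path / "s.h5")
        assert back.patch_size == 16 and back.source_shape == (20, 20, 20)
        for (a_img, a_lab), (b_img, b_lab) in zip(stack.patches, back.patches):
            np.testing.assert_array_equal(a_img, b_img)
            np.testing.assert_array_equal(a_lab, b_lab)


# ---------------------------------------------------------------------------
# split_dataset
# ---------------------------------------------------------------------------

class TestSplitDataset:
    def test_ten_volumes_split_eight_two(self):
        train, val = ns.split_dataset(list(range(10)), seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_every_stratum_reaches_validation(self):
        strata = ["a"] * 5 + ["b"] * 5
        train, val = ns.split_dataset(list(range(10)), strata=strata, seed=1)
        val_strata = {strata[i] for i in val}
        assert val_strata == {"a", "b"}

    def test_deterministic_under_seed(self):
        a = ns.split_dataset(list(range(20)), seed=42)
        b = ns.split_dataset(list(range(20)), seed=42)
        assert a == b

    def test_singleton_stratum_goes_to_training_with_warning(self):
        with pytest.warns(UserWarning, match="single member"):
            train, val = ns.split_dataset([0, 1, 2, 3], strata=["a", "a", "a", "b"],
                                          seed=0)
        assert 3 in train
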