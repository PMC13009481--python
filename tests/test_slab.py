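import numpy as np
import pytest

from slabrestore.kspace import ScaleFactor
from slabrestore.slab import (
    PatchGeometry, extract_patch_pairs, extract_slabs, grid_starts,
    self_ensemble, stitch,
)


def identity_round_trip(volume, geom):
    """extract -> identity network -> stitch, returning both ensemble modes."""
    pairs = extract_patch_pairs(volume, volume, geom)
    outputs = [(p.slab_start, p.y, p.x, p.lr) for p in pairs]
    return (
        stitch(outputs, volume.shape, geom, ensemble=True),
        stitch(outputs, volume.shape, geom, ensemble=False),
    )


class TestSlabs:
    def test_middle_slice_in_three_slabs(self, rng):
        vol = rng.random((4, 4, 5))
        slabs = extract_slabs(vol, M=3)
        assert [s for s, _ in slabs] == [0, 1, 2]
        assert all(np.array_equal(arr, np.moveaxis(vol, 2, 0)[s:s + 3])
                   for s, arr in slabs)

    def test_single_slice_slabs(self, rng):
        vol = rng.random((4, 4, 6))
        assert len(extract_slabs(vol, M=1)) == 6

    def test_full_depth_single_slab(self, rng):
        vol = rng.random((4, 4, 5))
        assert len(extract_slabs(vol, M=5)) == 1

    def test_m_exceeding_depth_rejected(self, rng):
        with pytest.raises(ValueError, match="depth"):
            extract_slabs(rng.random((4, 4, 3)), M=5)

    @pytest.mark.parametrize("D", range(5, 13))
    @pytest.mark.parametrize("M", [1, 3, 5])
    def test_coverage_count_closed_form(self, D, M, rng):
        vol = rng.random((4, 4, D))
        slabs = extract_slabs(vol, M=M)
        counts = np.zeros(D, dtype=int)
        for s, _ in slabs:
            counts[s:s + M] += 1
        for i in range(D):
            assert counts[i] == min(i, M - 1, D - 1 - i, D - M) + 1


class TestPatchGrid:
    def test_exact_tiling_320(self):
        assert grid_starts(320, 128, 32) == [0, 96, 192]

    def test_exact_tiling_160(self):
        assert grid_starts(160, 64, 16) == [0, 48, 96]

    def test_snapped_last_patch(self):
        starts = grid_starts(100, 64, 16)
        assert starts[-1] == 36 and starts[0] == 0

    def test_patch_larger_than_extent_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            grid_starts(30, 64, 16)


class TestPairs:
    def test_through_plane_pair_slice_counts(self, rng):
        lr = rng.random((32, 32, 8))
        hr = rng.random((32, 32, 16))
        geom = PatchGeometry(scale=ScaleFactor(1, 1, 2), M=3, lr_size=16, lr_overlap=4)
        pairs = extract_patch_pairs(hr, lr, geom)
        assert pairs[0].lr.shape == (3, 16, 16)
        assert pairs[0].hr.shape == (6, 16, 16)

    def test_inplane_scaling_geometry(self, rng):
        lr = rng.random((16, 16, 6))
        hr = rng.random((32, 32, 6))
        geom = PatchGeometry(scale=ScaleFactor(2, 2, 1), M=3, lr_size=8, lr_overlap=2)
        pairs = extract_patch_pairs(hr, lr, geom)
        assert pairs[0].lr.shape == (3, 8, 8)
        assert pairs[0].hr.shape == (3, 16, 16)

    def test_shape_mismatch_names_axis(self, rng):
        lr = rng.random((16, 16, 6))
        hr = rng.random((32, 30, 6))
        geom = PatchGeometry(scale=ScaleFactor(2, 2, 1), M=3, lr_size=8, lr_overlap=2)
        with pytest.raises(ValueError, match="PE"):
            extract_patch_pairs(hr, lr, geom)

    def test_default_sizes_follow_128_grid(self):
        assert PatchGeometry(scale=ScaleFactor(2, 2, 1)).lr_size == 64
        assert PatchGeometry(scale=ScaleFactor(2, 2, 1)).lr_overlap == 16
        assert PatchGeometry(scale=ScaleFactor(4, 4, 1)).lr_size == 32
        assert PatchGeometry(scale=ScaleFactor(1, 1, 2)).lr_size == 128


class TestStitch:
    @pytest.mark.parametrize("M", [1, 3, 5])
    @pytest.mark.parametrize("size,overlap", [(16, 4), (8, 2)])
    def test_identity_round_trip_exact(self, M, size, overlap, rng):
        vol = rng.random((24, 20, 7))
        geom = PatchGeometry(scale=ScaleFactor(1, 1, 1), M=M,
                             lr_size=size, lr_overlap=overlap)
        ens, center = identity_round_trip(vol, geom)
        assert np.array_equal(ens, vol)
        assert np.array_equal(center, vol)

    def test_identity_round_trip_non_tiling_grid(self, rng):
        vol = rng.random((25, 21, 5))  # forces snapped final patches
        geom = PatchGeometry(scale=ScaleFactor(1, 1, 1), M=3, lr_size=16, lr_overlap=4)
        ens, _ = identity_round_trip(vol, geom)
        assert np.array_equal(ens, vol)

    def test_two_constant_patches_give_constant_plane(self):
        geom = PatchGeometry(scale=ScaleFactor(1, 1, 1), M=1, lr_size=8, lr_overlap=4)
        patch = np.full((1, 8, 8), 0.3)
        outputs = [(0, 0, 0, patch), (0, 4, 0, patch), (0, 0, 4, patch), (0, 4, 4, patch)]
        out = stitch(outputs, (12, 12, 1), geom)
        assert np.allclose(out, 0.3)

    def test_coverage_gap_rejected(self, rng):
        geom = PatchGeometry(scale=ScaleFactor(1, 1, 1), M=1, lr_size=8, lr_overlap=4)
        outputs = [(0, 0, 0, rng.random((1, 8, 8)))]
        with pytest.raises(ValueError, match="coverage gap"):
            stitch(outputs, (12, 12, 2), geom)


class TestSelfEnsemble:
    def test_single_candidate_identity(self, rng):
        v = rng.random((4, 4, 4))
        assert np.array_equal(self_ensemble([v]), v)

    def test_mean_of_zero_and_one(self):
        out = self_ensemble([np.zeros((3, 3, 3)), np.ones((3, 3, 3))])
        assert np.allclose(out, 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            self_ensemble([])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            self_ensemble([rng.random((3, 3, 3)), rng.random((3, 3, 2))])
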