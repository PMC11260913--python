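"""Thresholding, wheel extraction and cavity labeling."""

import numpy as np
import pytest

from cheesect.segmentation import (
    BinaryMask,
    NoWheelError,
    extract_wheel,
    label_cavities,
    labeling_oracle,
    threshold_volume,
)
from cheesect.volume_io import DensityVolume

from conftest import (
    SPACING,
    density_volume_with_cavities,
    digitized_sphere,
    full_wheel_mask,
)


def _sphere_mask_at(shape, center, r, spacing=SPACING):
    dz, dy, dx = spacing
    z = np.arange(shape[0])[:, None, None] * dz
    y = np.arange(shape[1])[None, :, None] * dy
    x = np.arange(shape[2])[None, None, :] * dx
    cz, cy, cx = center
    return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r * r


class TestThreshold:
    def test_uniform_cheese_all_true(self):
        rho = DensityVolume(rho=np.full((3, 3, 3), 1150.0), spacing=SPACING)
        assert threshold_volume(rho).mask.all()

    def test_boundary_inclusive(self):
        rho = DensityVolume(
            rho=np.array([[[849.0, 850.0, 851.0]]]), spacing=SPACING
        )
        mask = threshold_volume(rho).mask
        assert mask.tolist() == [[[False, True, True]]]

    def test_air_is_not_cheese(self):
        rho = DensityVolume(rho=np.full((2, 2, 2), 1.2), spacing=SPACING)
        assert not threshold_volume(rho).mask.any()

    def test_nonpositive_threshold_rejected(self):
        rho = DensityVolume(rho=np.zeros((2, 2, 2)), spacing=SPACING)
        with pytest.raises(ValueError):
            threshold_volume(rho, threshold=0)


class TestExtractWheel:
    def test_drops_isolated_specks(self):
        mask = np.zeros((10, 20, 20), dtype=bool)
        mask[2:8, 5:15, 5:15] = True  # the wheel
        for vox in [(0, 0, 0), (9, 19, 0), (0, 19, 19)]:
            mask[vox] = True
        wheel = extract_wheel(BinaryMask(mask=mask, spacing=SPACING))
        assert wheel.mask.sum() == 6 * 10 * 10
        assert not wheel.mask[0, 0, 0]

    def test_all_true_is_identity(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        wheel = extract_wheel(BinaryMask(mask=mask, spacing=SPACING))
        assert wheel.mask.all()

    def test_empty_mask_raises(self):
        with pytest.raises(NoWheelError):
            extract_wheel(BinaryMask(mask=np.zeros((3, 3, 3), bool), spacing=SPACING))

    def test_equal_components_tie_break_deterministic(self, caplog):
        mask = np.zeros((3, 3, 8), dtype=bool)
        mask[1, 1, 0:2] = True   # component A, smaller linear index
        mask[1, 1, 5:7] = True   # component B, same size
        with caplog.at_level("WARNING"):
            wheel = extract_wheel(BinaryMask(mask=mask, spacing=SPACING))
        assert wheel.mask[1, 1, 0] and not wheel.mask[1, 1, 5]
        assert any("tie" in rec.message for rec in caplog.records)


class TestLabelCavities:
    def test_single_interior_sphere(self):
        cav = _sphere_mask_at((24, 24, 24), (15, 12, 12), 5.0)
        rho = density_volume_with_cavities(cav)
        mask = threshold_volume(rho)
        lm = label_cavities(mask, full_wheel_mask(cav.shape))
        assert lm.n_cavities == 1

    def test_overlapping_spheres_coalesce(self):
        shape = (32, 40, 40)
        a = _sphere_mask_at(shape, (20, 20, 15), 5.0)
        b = _sphere_mask_at(shape, (20, 20, 22), 5.0)  # centers 7 mm < 10 mm apart
        rho = density_volume_with_cavities(a | b)
        lm = label_cavities(threshold_volume(rho), full_wheel_mask(shape))
        assert lm.n_cavities == 1

    def test_fifty_disjoint_spheres(self):
        # 50 spheres on a grid, all interior, radius 1.6 mm
        shape = (40, 50, 64)
        cav = np.zeros(shape, dtype=bool)
        k = 0
        for zi in range(2):
            for yi in range(5):
                for xi in range(5):
                    if k >= 50:
                        break
                    c = (12 + zi * 20, 8 + yi * 8, 8 + xi * 10)
                    cav |= _sphere_mask_at(shape, c, 1.6)
                    k += 1
        rho = density_volume_with_cavities(cav)
        lm = label_cavities(
            threshold_volume(rho), full_wheel_mask(shape), min_volume_cm3=0.0
        )
        assert lm.n_cavities == 50

    def test_labels_contiguous_and_sorted_by_volume(self):
        shape = (30, 30, 30)
        cav = _sphere_mask_at(shape, (18, 15, 8), 5.0) | _sphere_mask_at(
            shape, (18, 15, 22), 3.0
        )
        lm = label_cavities(
            threshold_volume(density_volume_with_cavities(cav)),
            full_wheel_mask(shape),
        )
        assert lm.n_cavities == 2
        assert set(np.unique(lm.labels)) == {0, 1, 2}
        assert lm.voxel_counts[1] > lm.voxel_counts[2]

    def test_min_volume_monotonicity(self):
        shape = (30, 30, 30)
        cav = _sphere_mask_at(shape, (18, 15, 8), 4.0) | _sphere_mask_at(
            shape, (18, 15, 22), 2.0
        )
        mask = threshold_volume(density_volume_with_cavities(cav))
        wheel = full_wheel_mask(shape)
        ks = [
            label_cavities(mask, wheel, min_volume_cm3=v).n_cavities
            for v in [0.0, 0.01, 0.05, 0.5]
        ]
        assert ks == sorted(ks, reverse=True)

    def test_rind_open_cavity_merges_into_air(self, caplog):
        # a channel from the sphere to the boundary joins it to external air
        shape = (24, 24, 24)
        cav = _sphere_mask_at(shape, (15, 12, 12), 4.0)
        cav[:, 12, 12] = True  # open channel to both z faces
        mask = threshold_volume(density_volume_with_cavities(cav))
        with caplog.at_level("WARNING"):
            lm = label_cavities(mask, full_wheel_mask(shape))
        assert lm.n_cavities == 0
        assert lm.rind_open_merged

    def test_partition_conservation(self, rng):
        shape = (20, 20, 20)
        mask_arr = rng.random(shape) < 0.7
        mask = BinaryMask(mask=mask_arr, spacing=SPACING)
        wheel = full_wheel_mask(shape)
        lm = label_cavities(mask, wheel, min_volume_cm3=0.004)
        below = int((~mask_arr).sum())
        cavity_vox = int((lm.labels > 0).sum())
        assert (
            cavity_vox + lm.external_air_voxels + lm.discarded_speck_voxels == below
        )

    def test_count_invariant_under_axis_permutation_and_flip(self, rng):
        shape = (18, 18, 18)
        mask_arr = rng.random(shape) < 0.75
        base = label_cavities(
            BinaryMask(mask=mask_arr, spacing=(1, 1, 1)),
            full_wheel_mask(shape, (1, 1, 1)),
            min_volume_cm3=0.0,
        ).n_cavities
        for perm in [(1, 0, 2), (2, 1, 0)]:
            permuted = np.transpose(mask_arr, perm)
            k = label_cavities(
                BinaryMask(mask=permuted, spacing=(1, 1, 1)),
                full_wheel_mask(permuted.shape, (1, 1, 1)),
                min_volume_cm3=0.0,
            ).n_cavities
            assert k == base
        flipped = mask_arr[::-1, :, ::-1]
        k = label_cavities(
            BinaryMask(mask=flipped.copy(), spacing=(1, 1, 1)),
            full_wheel_mask(shape, (1, 1, 1)),
            min_volume_cm3=0.0,
        ).n_cavities
        assert k == base

    def test_2d_stacked_mode_agrees_on_volume(self):
        shape = (24, 24, 24)
        cav = _sphere_mask_at(shape, (15, 12, 12), 5.0)
        mask = threshold_volume(density_volume_with_cavities(cav))
        wheel = full_wheel_mask(shape)
        lm3 = label_cavities(mask, wheel, mode="3d")
        lm2 = label_cavities(mask, wheel, mode="2d-stacked")
        assert (lm2.labels > 0).sum() == (lm3.labels > 0).sum()
        # one 3D sphere spans several slices → more 2D regions than 3D ones
        assert lm2.n_cavities >= lm3.n_cavities


class TestOracleEquivalence:
    def _partitions_equal(self, a, b):
        """Label arrays equal up to relabeling."""
        if (a > 0).sum() != (b > 0).sum():
            return False
        pairs = set(zip(a[a > 0].ravel().tolist(), b[a > 0].ravel().tolist()))
        return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_on_random_volumes(self, connectivity, rng):
        for _ in range(30):
            arr = rng.random((20, 20, 20)) < rng.uniform(0.55, 0.9)
            mask = BinaryMask(mask=arr, spacing=(1, 1, 1))
            wheel = full_wheel_mask(arr.shape, (1, 1, 1))
            ours = label_cavities(
                mask, wheel, connectivity=connectivity, min_volume_cm3=0.0
            )
            oracle = labeling_oracle(mask, connectivity=connectivity)
            assert ours.n_cavities == oracle.n_cavities
            assert ours.external_air_voxels == oracle.external_air_voxels
            assert self._partitions_equal(ours.labels, oracle.labels)

    def test_all_false_interior_single_cavity(self):
        arr = np.ones((6, 6, 6), dtype=bool)
        arr[1:-1, 1:-1, 1:-1] = False
        lm = labeling_oracle(BinaryMask(mask=arr, spacing=(1, 1, 1)))
        assert lm.n_cavities == 1
        assert (lm.labels > 0).sum() == 4**3

    def test_all_true_zero_cavities(self):
        lm = labeling_oracle(
            BinaryMask(mask=np.ones((5, 5, 5), bool), spacing=(1, 1, 1))
        )
        assert lm.n_cavities == 0

    def test_oversize_refused(self):
        with pytest.raises(ValueError):
            labeling_oracle(
                BinaryMask(mask=np.ones((33, 33, 33), bool), spacing=(1, 1, 1))
            )
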