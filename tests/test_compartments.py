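"""Signed distance maps, subpleural partition, and lobar aggregation."""

import numpy as np
import pytest

import pulmofat as pf
from conftest import oracle_interior_distances, oracle_subpleural_labels, random_blob_mask


def _cube_mask(n=30, pad=5, spacing=(1.0, 1.0, 1.0)):
    shape = tuple(n + 2 * pad for _ in range(3))
    data = np.zeros(shape, np.int32)
    data[pad : pad + n, pad : pad + n, pad : pad + n] = 1
    return pf.LabelMask(data, spacing=spacing)


class TestSignedDistance:
    def test_sign_convention(self):
        mask = _cube_mask(6, 3)
        d = pf.signed_distance(mask)
        assert (d.data[mask.data == 1] <= 0).all()
        assert (d.data[mask.data == 0] >= 0).all()

    def test_cube_center_matches_brute_force(self):
        mask = _cube_mask(30, 2)
        d = pf.signed_distance(mask)
        oracle = oracle_interior_distances(mask.data.astype(bool), mask.spacing)
        fg = np.argwhere(mask.data)
        center_i = np.where((fg == [16, 16, 16]).all(axis=1))[0][0]
        assert -d.data[16, 16, 16] == pytest.approx(oracle[center_i], abs=1e-9)
        # and everywhere, not just the center
        np.testing.assert_allclose(-d.data[tuple(fg.T)], oracle, atol=1e-9)

    def test_single_voxel_interior_distance_at_most_one_spacing(self):
        data = np.zeros((21, 21, 21), np.int32)
        data[10, 10, 10] = 1
        d = pf.signed_distance(pf.LabelMask(data, spacing=(0.8, 0.8, 2.0)))
        assert 0 < -d.data[10, 10, 10] <= 0.8

    def test_anisotropic_slab_measures_mm(self):
        """A 3-voxel slab along z at (1,1,3) mm spacing: interior distances
        are physical mm, matching brute force."""
        data = np.zeros((12, 12, 9), np.int32)
        data[2:10, 2:10, 3:6] = 1
        mask = pf.LabelMask(data, spacing=(1.0, 1.0, 3.0))
        d = pf.signed_distance(mask)
        fg = np.argwhere(data)
        oracle = oracle_interior_distances(data.astype(bool), mask.spacing)
        np.testing.assert_allclose(-d.data[tuple(fg.T)], oracle, atol=1e-9)
        assert -d.data[6, 6, 3] == pytest.approx(3.0)  # one 3-mm z-step beats 4 in-plane steps

    def test_magnitude_bounded_by_half_diagonal(self, scattered_phantom):
        _, _, lung, _, _ = scattered_phantom
        d = pf.signed_distance(lung)
        half_diag = 0.5 * np.linalg.norm(
            [(n - 1) * s for n, s in zip(lung.shape, lung.spacing)]
        )
        assert np.abs(d.data[lung.data == 1]).max() <= half_diag

    def test_empty_and_full_masks_refused(self):
        with pytest.raises(pf.EmptyMaskError):
            pf.signed_distance(pf.LabelMask(np.zeros((5, 5, 5), np.int32)))
        with pytest.raises(pf.EmptyMaskError):
            pf.signed_distance(pf.LabelMask(np.ones((5, 5, 5), np.int32)))

    def test_simpleitk_cross_check(self):
        """Independent route: the Maurer map of the inverted mask, evaluated
        at foreground voxels, equals the interior distance magnitude."""
        import SimpleITK as sitk

        rng = np.random.default_rng(17)
        mask = random_blob_mask(rng, (20, 22, 18))
        lm = pf.LabelMask(mask.astype(np.int32), spacing=(0.9, 1.1, 2.0))
        d = pf.signed_distance(lm)
        inv = sitk.GetImageFromArray((~mask).transpose(2, 1, 0).astype(np.uint8))
        inv.SetSpacing(lm.spacing)
        ref = sitk.SignedMaurerDistanceMap(
            inv, squaredDistance=False, useImageSpacing=True, insideIsPositive=False
        )
        ref_arr = sitk.GetArrayFromImage(ref).transpose(2, 1, 0)
        np.testing.assert_allclose(-d.data[mask], ref_arr[mask], atol=1e-4)


class TestSubpleuralPartition:
    def test_cube_counts_match_hand_derivation(self):
        """30^3 cube at 1 mm, depth 10 mm: the nonsubpleural core is the
        inner 10^3 block (1,000 voxels), the shell has 26,000."""
        mask = _cube_mask(30, 3)
        sub, nonsub = pf.subpleural_partition(mask, depth_mm=10.0)
        assert nonsub.data.sum() == 1000
        assert sub.data.sum() == 26000

    def test_partition_is_exact(self, scattered_phantom):
        _, _, lung, _, _ = scattered_phantom
        sub, nonsub = pf.subpleural_partition(lung, 10.0)
        assert not (sub.data.astype(bool) & nonsub.data.astype(bool)).any()
        np.testing.assert_array_equal(
            sub.data.astype(bool) | nonsub.data.astype(bool), lung.data.astype(bool)
        )

    def test_depth_beyond_inradius_saturates(self):
        mask = _cube_mask(10, 3)
        sub, nonsub = pf.subpleural_partition(mask, depth_mm=50.0)
        assert nonsub.data.sum() == 0
        assert sub.data.sum() == mask.data.sum()

    def test_disjoint_components_equal_standalone(self):
        """Two far-apart components partition exactly as each would alone."""
        data = np.zeros((40, 14, 14), np.int32)
        data[2:10, 3:11, 3:11] = 1
        data[25:37, 3:11, 3:11] = 1
        both = pf.LabelMask(data)
        sub_b, non_b = pf.subpleural_partition(both, depth_mm=3.0)
        for sl in (slice(0, 15), slice(20, 40)):
            solo = np.zeros_like(data)
            solo[sl] = data[sl]
            sub_s, non_s = pf.subpleural_partition(pf.LabelMask(solo), depth_mm=3.0)
            np.testing.assert_array_equal(sub_s.data[sl], sub_b.data[sl])
            np.testing.assert_array_equal(non_s.data[sl], non_b.data[sl])

    def test_depth_monotonicity(self, scattered_phantom):
        _, _, lung, _, _ = scattered_phantom
        counts = [
            pf.subpleural_partition(lung, depth)[0].data.sum()
            for depth in (2.0, 5.0, 8.0, 12.0, 20.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_geometry_scaling_invariance(self):
        """Scaling spacing and depth together leaves the voxel partition
        identical."""
        rng = np.random.default_rng(4)
        mask = random_blob_mask(rng, (18, 18, 18))
        for s in (0.5, 3.0):
            a, _ = pf.subpleural_partition(pf.LabelMask(mask.astype(np.int32)), 4.0)
            b, _ = pf.subpleural_partition(
                pf.LabelMask(mask.astype(np.int32), spacing=(s, s, s)), 4.0 * s
            )
            np.testing.assert_array_equal(a.data, b.data)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(10, 24, size=3))
        spacing = tuple(rng.uniform(0.5, 3.0, size=3))
        depth = float(rng.uniform(1.0, 10.0))
        mask = random_blob_mask(rng, shape)
        sub, nonsub = pf.subpleural_partition(pf.LabelMask(mask.astype(np.int32), spacing=spacing), depth)
        oracle = oracle_subpleural_labels(mask, spacing, depth)
        np.testing.assert_array_equal(sub.data.astype(bool), oracle == 1)
        np.testing.assert_array_equal(nonsub.data.astype(bool), oracle == 2)


class TestCompartmentQuant:
    def test_shallow_fat_only_in_subpleural(self):
        spec = pf.default_spec(
            fat_set=tuple(pf.FatSphere(radius_mm=1.5) for _ in range(4)),
            placement=pf.Placement(subpleural_within_mm=5.0),
            seed=2,
        )
        image, lung, _, _ = pf.generate_phantom(spec)
        comp = pf.compartment_quant(image, lung, depth_mm=10.0)
        assert comp.subpleural.ctpfav_ml > 0
        assert comp.nonsubpleural.ctpfav_ml == 0.0

    def test_deep_fat_only_in_core(self):
        spec = pf.default_spec(
            fat_set=(pf.FatSphere(radius_mm=2.0),),
            placement=pf.Placement(deeper_than_mm=13.0),
            seed=3,
        )
        image, lung, _, _ = pf.generate_phantom(spec)
        comp = pf.compartment_quant(image, lung, depth_mm=10.0)
        assert comp.subpleural.ctpfav_ml == 0.0
        assert comp.nonsubpleural.ctpfav_ml > 0

    def test_conservation(self, scattered_phantom):
        _, image, lung, _, _ = scattered_phantom
        whole = pf.compute_ctpfav(image, lung)
        comp = pf.compartment_quant(image, lung, depth_mm=10.0)
        assert (
            comp.subpleural.lung_voxel_count + comp.nonsubpleural.lung_voxel_count
            == whole.lung_voxel_count
        )
        assert comp.subpleural.ctpfav_ml + comp.nonsubpleural.ctpfav_ml == pytest.approx(
            whole.ctpfav_ml, abs=1e-9
        )

    def test_uniform_scatter_similar_pfi_both_compartments(self):
        """Fat assigned uniformly at random over lung voxels: the two
        compartments see the same expected fat fraction."""
        spec = pf.default_spec(seed=8)
        image, lung, _, _ = pf.generate_phantom(spec)
        rng = np.random.default_rng(8)
        data = image.data.copy()
        lung_idx = np.argwhere(lung.data)
        pick = lung_idx[rng.uniform(size=len(lung_idx)) < 0.05]
        data[tuple(pick.T)] = -100.0
        comp = pf.compartment_quant(pf.ImageVolume(data, spacing=image.spacing), lung, depth_mm=10.0)
        assert comp.subpleural.pfi_pct == pytest.approx(comp.nonsubpleural.pfi_pct, rel=0.2)

    def test_empty_compartment_reported_as_zero_with_nan_pfi(self):
        mask = _cube_mask(8, 3)
        img = pf.ImageVolume(np.full(mask.shape, -850.0), spacing=mask.spacing)
        comp = pf.compartment_quant(img, mask, depth_mm=50.0)
        assert comp.nonsubpleural.lung_voxel_count == 0
        assert np.isnan(comp.nonsubpleural.pfi_pct)


class TestLobarQuant:
    def test_fat_in_lower_lobes_only(self):
        spec = pf.default_spec(
            fat_set=(
                pf.FatSphere(radius_mm=3.0),
                pf.FatSphere(radius_mm=3.0),
            ),
            placement=pf.Placement(lobe="LLL"),
            seed=6,
        )
        image, _, lobes, _ = pf.generate_phantom(spec)
        lobar = pf.lobar_quant(image, lobes)
        assert lobar.per_group["lower"].pfi_pct > 0
        assert lobar.per_group["upper"].pfi_pct == 0.0
        assert lobar.per_group["middle"].pfi_pct == 0.0

    def test_lobes_tile_lung_sums_match(self, scattered_phantom):
        _, image, lung, lobes, _ = scattered_phantom
        whole = pf.compute_ctpfav(image, lung)
        lobar = pf.lobar_quant(image, lobes)
        assert sum(r.fat_voxel_count for r in lobar.per_lobe.values()) == whole.fat_voxel_count
        assert sum(r.lung_voxel_count for r in lobar.per_lobe.values()) == whole.lung_voxel_count

    def test_group_pfi_pools_volumes(self, scattered_phantom):
        """Group PFI is 100*sum(fat)/sum(lung) over members, not a mean of PFIs."""
        _, image, _, lobes, _ = scattered_phantom
        lobar = pf.lobar_quant(image, lobes)
        low = lobar.per_group["lower"]
        members = [lobar.per_lobe["LLL"], lobar.per_lobe["RLL"]]
        assert low.fat_voxel_count == sum(m.fat_voxel_count for m in members)
        assert low.pfi_pct == pytest.approx(
            100 * sum(m.ctpfav_ml for m in members) / sum(m.lung_volume_ml for m in members),
            rel=1e-12,
        )

    def test_single_lobe_mask_reports_only_its_group(self, scattered_phantom):
        _, image, _, lobes, _ = scattered_phantom
        only_rml = pf.LabelMask(
            np.where(lobes.data == 4, 4, 0).astype(np.int32),
            spacing=lobes.spacing,
            label_map=dict(pf.DEFAULT_LOBE_LABELS),
        )
        lobar = pf.lobar_quant(image, only_rml)
        assert set(lobar.per_lobe) == {"RML"}
        assert set(lobar.per_group) == {"middle"}

    def test_unknown_label_rejected(self, scattered_phantom):
        _, image, _, lobes, _ = scattered_phantom
        bad = pf.LabelMask(
            np.where(lobes.data == 1, 9, lobes.data).astype(np.int32), spacing=lobes.spacing
        )
        with pytest.raises(ValueError, match="9"):
            pf.lobar_quant(image, bad)
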