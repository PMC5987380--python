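"""Stack I/O and the preprocessing chain."""

import json

import numpy as np
import pytest
from scipy import ndimage

from bonemap import phantom, volio
from bonemap.volio import (AlignedBone, VoxelVolume, align_longitudinal,
                           extract_trabecular_roi, find_trabecular_reference,
                           read_stack, remove_fibula, threshold_minimum,
                           write_stack)


class TestStackIO:
    def test_round_trip_lossless(self, tmp_path, circular_tube):
        _, gray, binary, _ = circular_tube
        for vol in (gray, binary):
            path = tmp_path / "vol.tif"
            write_stack(vol, path)
            back = read_stack(path)
            assert back.voxel_um == vol.voxel_um
            assert back.data.dtype == vol.data.dtype
            assert np.array_equal(back.data, vol.data)

    def test_missing_sidecar_is_hard_error(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "bare.tif",
                         np.zeros((4, 5, 6), dtype=np.uint8),
                         photometric="minisblack")
        with pytest.raises(ValueError, match="voxel size"):
            read_stack(tmp_path / "bare.tif")

    def test_anisotropic_voxels_rejected(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "v.tif", np.zeros((4, 5, 6), np.uint8),
                         photometric="minisblack")
        (tmp_path / "v.json").write_text(json.dumps(
            {"voxel_um": [5.0, 5.0, 10.0]}))
        with pytest.raises(ValueError, match="anisotropic"):
            read_stack(tmp_path / "v.tif")

    def test_single_slice_is_not_a_volume(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "s.tif", np.zeros((1, 5, 6), np.uint8),
                         photometric="minisblack")
        (tmp_path / "s.json").write_text(json.dumps({"voxel_um": 5.0}))
        with pytest.raises(ValueError, match="3D"):
            read_stack(tmp_path / "s.tif")


class TestThreshold:
    def test_noiseless_phantom_recovers_binary_exactly(self, circular_tube):
        spec, gray, binary, _ = circular_tube
        # noiseless and rod-free gray differs from binary only by blur;
        # regenerate without blur influence by thresholding at midpoint
        mask = threshold_minimum(gray, (spec.bone_value
                                        + spec.background_value) / 2)
        dice = 2 * (mask.data & binary.data).sum() / (
            mask.data.sum() + binary.data.sum())
        assert dice > 0.99

    def test_threshold_above_max_errors_with_percentiles(self, circular_tube):
        _, gray, _, _ = circular_tube
        with pytest.raises(ValueError, match="percentiles"):
            threshold_minimum(gray, 1e9)

    def test_otsu_threshold_dice_on_noisy_phantom(self):
        spec = phantom.PhantomSpec(
            length_mm=4.0, voxel_um=25.0, outer_a=1.0, outer_b=0.8,
            wall_thickness=0.3, wall_mode="offset", noise_sd=6.0,
            calibration_rod_values=None, seed=3)
        gray, binary, _ = phantom.generate_bone(spec)
        thr = volio.suggest_threshold(gray)
        mask = threshold_minimum(gray, thr)
        dice = 2 * (mask.data & binary.data).sum() / (
            mask.data.sum() + binary.data.sum())
        assert dice >= 0.98


class TestRemoveFibula:
    @pytest.fixture(scope="class")
    def bone_with_fibula(self):
        spec = phantom.PhantomSpec(
            length_mm=4.0, voxel_um=50.0, outer_a=0.9, outer_b=0.7,
            wall_thickness=0.25, wall_mode="axis",
            fibula=phantom.FibulaSpec(radius_mm=0.2, offset_mm=1.4,
                                      span=(0.2, 0.8)),
            calibration_rod_values=None, seed=0)
        return phantom.generate_bone(spec)

    def test_nonfused_fibula_removed_exactly(self, bone_with_fibula):
        _, binary, gt = bone_with_fibula
        clean, info = remove_fibula(binary)
        assert not (clean.data & gt.fibula_mask).any()
        assert np.array_equal(clean.data, binary.data & ~gt.fibula_mask)
        assert info["fused_slices"] == []

    def test_no_fibula_is_identity(self, circular_tube):
        _, _, binary, _ = circular_tube
        clean, info = remove_fibula(binary)
        assert np.array_equal(clean.data, binary.data)
        assert info["removed_voxels"] == 0

    def test_fused_fibula_removal_confined_to_collar(self):
        spec = phantom.PhantomSpec(
            length_mm=4.0, voxel_um=50.0, outer_a=0.9, outer_b=0.7,
            wall_thickness=0.25, wall_mode="axis",
            fibula=phantom.FibulaSpec(radius_mm=0.2, offset_mm=1.05,
                                      span=(0.55, 0.70), fused=True),
            calibration_rod_values=None, seed=0)
        _, binary, gt = phantom.generate_bone(spec)
        clean, info = remove_fibula(binary)
        removed = binary.data & ~clean.data
        collar = ndimage.binary_dilation(
            gt.fibula_mask, structure=np.ones((3, 3, 3), bool))
        assert removed.sum() > 0
        assert (removed & ~collar).sum() == 0  # only fibula + one-voxel collar

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            remove_fibula(VoxelVolume(np.zeros((4, 5, 6), bool), 50.0))


class TestAlignment:
    def test_rotated_tube_recovered(self):
        spec = phantom.PhantomSpec(
            length_mm=8.0, voxel_um=40.0, outer_a=0.8, outer_b=0.8,
            wall_thickness=0.3, wall_mode="axis",
            calibration_rod_values=None, seed=0)
        _, binary, _ = phantom.generate_bone(spec)
        rot = ndimage.rotate(binary.data.astype(np.uint8), 20, axes=(0, 1),
                             order=0, reshape=True).astype(bool)
        aligned = align_longitudinal(VoxelVolume(rot, 40.0))
        coords = np.argwhere(aligned.mask).astype(float)
        coords -= coords.mean(axis=0)
        _, evecs = np.linalg.eigh(np.cov(coords.T))
        axis = evecs[:, -1]
        angle = np.degrees(np.arccos(min(abs(axis[0]), 1.0)))
        assert angle < 0.5
        assert aligned.length_mm == pytest.approx(8.0, abs=0.04)
        # alignment is an isometry: voxel count conserved within 0.5%
        assert abs(aligned.mask.sum() / binary.data.sum() - 1) < 0.005

    @pytest.fixture(scope="class")
    def long_tube(self):
        spec = phantom.PhantomSpec(
            length_mm=6.0, voxel_um=50.0, outer_a=0.8, outer_b=0.8,
            wall_thickness=0.3, wall_mode="axis",
            calibration_rod_values=None, seed=0)
        return phantom.generate_bone(spec)[1]

    def test_already_aligned_is_identity(self, long_tube):
        aligned = align_longitudinal(long_tube)
        assert np.allclose(aligned.transform, np.eye(4))
        assert aligned.mask.sum() == long_tube.data.sum()

    def test_landmark_chord_maps_onto_z(self):
        spec = phantom.PhantomSpec(
            length_mm=6.0, voxel_um=50.0, outer_a=0.8, outer_b=0.8,
            wall_thickness=0.3, wall_mode="axis",
            calibration_rod_values=None, seed=0)
        _, binary, _ = phantom.generate_bone(spec)
        nz = binary.data.shape[0]
        cy = (binary.data.shape[1] - 1) / 2
        cx = (binary.data.shape[2] - 1) / 2
        aligned = align_longitudinal(binary,
                                     landmarks=[(0, cy, cx), (nz - 1, cy, cx)])
        assert np.allclose(aligned.transform, np.eye(4))

    def test_isotropic_cloud_has_no_axis(self):
        ball = np.zeros((31, 31, 31), bool)
        zz, yy, xx = np.mgrid[:31, :31, :31]
        ball[(zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2 <= 144] = True
        with pytest.raises(ValueError, match="dominant"):
            align_longitudinal(VoxelVolume(ball, 50.0))

    def test_percentile_index_monotone(self, long_tube):
        aligned = align_longitudinal(long_tube)
        idx = [aligned.percentile_index(p) for p in range(10, 91, 10)]
        assert all(b > a for a, b in zip(idx, idx[1:]))


class TestTrabecularAnchor:
    @pytest.fixture(scope="class")
    def metaphyseal_bone(self):
        spec = phantom.PhantomSpec(
            length_mm=10.0, voxel_um=40.0, outer_a=0.9, outer_b=0.7,
            wall_thickness=0.25, wall_mode="scaled",
            trabecular=phantom.TrabLatticeSpec(
                lattice_kind="rods", spacing_mm=0.45,
                element_thickness_mm=0.16, span=(0.04, 0.18), bridge_z=0.07,
                island_gap_mm=0.25),
            calibration_rod_values=None, seed=1)
        gray, binary, gt = phantom.generate_bone(spec)
        aligned = AlignedBone(binary.data, 40.0, 10.0)
        return aligned, gt

    def test_bridge_slice_found_within_one_slice(self, metaphyseal_bone):
        aligned, gt = metaphyseal_bone
        ref = find_trabecular_reference(aligned)
        assert abs(ref - gt.bridge_slice) <= 1

    def test_roi_spans_five_percent_toward_diaphysis(self, metaphyseal_bone):
        aligned, gt = metaphyseal_bone
        roi = extract_trabecular_roi(aligned, gt.bridge_slice, 0.05)
        n = round(0.05 * aligned.n_slices)
        assert roi.slices == (gt.bridge_slice, gt.bridge_slice + n)

    def test_roi_bone_matches_generator_count_in_envelope(self,
                                                          metaphyseal_bone):
        aligned, gt = metaphyseal_bone
        roi = extract_trabecular_roi(aligned, gt.bridge_slice, 0.05)
        sl = slice(*roi.slices)
        truth = (gt.trab_mask[sl] & roi.envelope).sum()
        assert roi.bone.sum() == truth

    def test_zero_fraction_rejected(self, metaphyseal_bone):
        aligned, _ = metaphyseal_bone
        with pytest.raises(ValueError, match="empty ROI"):
            extract_trabecular_roi(aligned, 10, 0.0)

    def test_roi_exiting_volume_rejected(self, metaphyseal_bone):
        aligned, _ = metaphyseal_bone
        with pytest.raises(ValueError, match="exits"):
            extract_trabecular_roi(aligned, aligned.n_slices - 2, 0.05)

    def test_no_intramedullary_bone_is_error(self, circular_tube):
        _, _, binary, _ = circular_tube
        aligned = AlignedBone(binary.data, 25.0, 2.0)
        with pytest.raises(ValueError, match="intramedullary"):
            find_trabecular_reference(aligned)

    def test_single_island_warns_and_returns_proximal(self):
        spec = phantom.PhantomSpec(
            length_mm=10.0, voxel_um=40.0, outer_a=0.9, outer_b=0.7,
            wall_thickness=0.25, wall_mode="scaled",
            trabecular=phantom.TrabLatticeSpec(
                lattice_kind="rods", spacing_mm=0.45,
                element_thickness_mm=0.16, span=(0.04, 0.18), bridge_z=0.04,
                island_gap_mm=0.0),
            calibration_rod_values=None, seed=1)
        _, binary, gt = phantom.generate_bone(spec)
        aligned = AlignedBone(binary.data, 40.0, 10.0)
        with pytest.warns(UserWarning, match="single"):
            ref = find_trabecular_reference(aligned)
        occ = np.flatnonzero(np.any(gt.trab_mask, axis=(1, 2)))
        assert ref == occ[0]
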