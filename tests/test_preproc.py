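"""Unit tests for volume I/O, normalization, smoothing, and feature assembly."""

import nibabel as nib
import numpy as np
import pytest

from petsurv.preproc import (
    BrainMask,
    BrainVolume,
    assemble_features,
    gaussian_smooth,
    load_volume,
    normalize_whole_brain,
    save_volume,
)


def _vol(data, subject_id="s"):
    return BrainVolume(data=np.asarray(data, dtype=float), affine=np.eye(4), subject_id=subject_id)


class TestIO:
    def test_write_then_load_round_trip(self, tmp_path, rng):
        data = rng.random((6, 7, 8))
        save_volume(_vol(data), tmp_path / "v.nii.gz")
        back = load_volume(tmp_path / "v.nii.gz")
        assert np.allclose(back.data, data, atol=1e-7)  # float32 on disk

    def test_four_dimensional_file_rejected(self, tmp_path):
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4)),
                 str(tmp_path / "v4.nii.gz"))
        with pytest.raises(ValueError, match="3-D"):
            load_volume(tmp_path / "v4.nii.gz")

    def test_nan_voxel_rejected_with_count(self, tmp_path):
        data = np.zeros((4, 4, 4), dtype=np.float32)
        data[1, 2, 3] = np.nan
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "bad.nii.gz"))
        with pytest.raises(ValueError, match="1 non-finite"):
            load_volume(tmp_path / "bad.nii.gz")

    def test_expected_shape_guard(self, tmp_path):
        save_volume(_vol(np.zeros((4, 4, 4))), tmp_path / "v.nii.gz")
        with pytest.raises(ValueError, match="shape"):
            load_volume(tmp_path / "v.nii.gz", expected_shape=(5, 5, 5))


class TestNormalize:
    def test_constant_volume_becomes_one(self):
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        out = normalize_whole_brain(_vol(np.full((3, 3, 3), 7.0)), mask)
        assert np.allclose(out.data, 1.0)

    def test_hand_computed_division_by_masked_mean(self):
        data = np.zeros((2, 2, 2))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask.flat[:4] = True
        data.flat[:4] = [1, 2, 3, 4]  # mean 2.5
        out = normalize_whole_brain(_vol(data), BrainMask(mask))
        assert np.allclose(np.sort(out.data[mask]), [0.4, 0.8, 1.2, 1.6])
        assert np.all(out.data[~mask] == 0)
        assert out.data[mask].mean() == pytest.approx(1.0, abs=1e-10)

    def test_zero_volume_rejected(self):
        mask = BrainMask(np.ones((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError, match="mean"):
            normalize_whole_brain(_vol(np.zeros((2, 2, 2))), mask)


class TestSmooth:
    def test_tiny_fwhm_is_identity(self, rng):
        data = rng.random((5, 5, 5))
        vol = BrainVolume(data=data, affine=np.diag([4.0, 4.0, 4.0, 1.0]))
        out = gaussian_smooth(vol, fwhm_mm=1.0)  # 0.25 voxels < bypass threshold
        assert np.array_equal(out.data, data)

    def test_constant_volume_unchanged(self):
        vol = BrainVolume(data=np.full((8, 8, 8), 3.3), affine=np.diag([4.0, 4.0, 4.0, 1.0]))
        out = gaussian_smooth(vol, fwhm_mm=10.0)
        assert np.allclose(out.data, 3.3, atol=1e-12)

    def test_total_intensity_conserved(self, rng):
        data = rng.random((10, 12, 9))
        vol = BrainVolume(data=data, affine=np.diag([4.0, 4.0, 4.0, 1.0]))
        out = gaussian_smooth(vol, fwhm_mm=10.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_impulse_matches_dense_separable_convolution(self):
        """A central unit impulse reproduces the truncated separable kernel and
        its centre approximates the analytic 3-D Gaussian normalization."""
        shape = (21, 21, 21)
        data = np.zeros(shape)
        data[10, 10, 10] = 1.0
        vol = BrainVolume(data=data, affine=np.diag([4.0, 4.0, 4.0, 1.0]))
        sigma = (10.0 / 4.0) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out = gaussian_smooth(vol, fwhm_mm=10.0)

        r = int(4.0 * sigma + 0.5)  # matches the filter's truncation
        x = np.arange(-r, r + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        expected = np.zeros(shape)
        expected[10 - r : 10 + r + 1, 10 - r : 10 + r + 1, 10 - r : 10 + r + 1] = kernel
        assert np.allclose(out.data, expected, atol=1e-12)

        analytic_peak = (2 * np.pi * sigma**2) ** -1.5
        assert out.data[10, 10, 10] == pytest.approx(analytic_peak, rel=0.05)

    def test_nonpositive_fwhm_rejected(self):
        vol = _vol(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            gaussian_smooth(vol, fwhm_mm=0.0)


class TestAssemble:
    def test_shape_contract(self, rng):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask.flat[[0, 5, 9, 14, 20]] = True
        vols = [_vol(rng.random((3, 3, 3)), f"s{i}") for i in range(2)]
        fm = assemble_features(vols, BrainMask(mask))
        assert fm.values.shape == (2, 5)
        assert fm.subject_ids == ["s0", "s1"]

    def test_full_grid_column_count_at_study_resolution(self):
        mask = BrainMask(np.ones((91, 109, 91), dtype=bool))
        vol = BrainVolume(data=np.zeros((91, 109, 91)), affine=np.eye(4))
        fm = assemble_features([vol], mask)
        assert fm.n_voxels == 902629

    def test_scatter_round_trip_is_exact(self, rng):
        mask = rng.random((6, 5, 4)) > 0.5
        data = rng.random((6, 5, 4))
        fm = assemble_features([_vol(data)], BrainMask(mask))
        back = fm.to_volume(fm.values[0])
        assert np.array_equal(back[mask], data[mask])
        assert np.all(back[~mask] == 0)

    def test_shape_mismatch_names_subject(self, rng):
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        bad = _vol(np.zeros((4, 4, 4)), "odd-one")
        with pytest.raises(ValueError, match="odd-one"):
            assemble_features([bad], mask)

    def test_normalize_then_assemble_commutes_with_row_division(self, rng):
        mask_arr = rng.random((5, 5, 5)) > 0.3
        mask = BrainMask(mask_arr)
        vols = [_vol(rng.random((5, 5, 5)) + 0.5, f"s{i}") for i in range(3)]
        fm_pre = assemble_features([normalize_whole_brain(v, mask) for v in vols], mask)
        fm_raw = assemble_features(vols, mask)
        divided = fm_raw.values / fm_raw.values.mean(axis=1, keepdims=True)
        assert np.allclose(fm_pre.values, divided, atol=1e-12)
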