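"""CT I/O, windowing, resizing and patient-split behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faseg import imaging
from faseg.imaging import (CTImage, FormatError, SegmentationMask, WindowSpec,
                           apply_window, read_dicom_slice, read_mask_png,
                           read_nifti_volume, resize_mask, resize_to_model,
                           split_by_patient, write_dicom_slice, write_mask_png,
                           write_nifti_volume)


class TestDicom:
    @pytest.mark.parametrize("slope,intercept,stored,expected_hu", [
        (1, -1024, 1024, 0.0),
        (2, 0, 50, 100.0),
    ])
    def test_rescale(self, tmp_path, slope, intercept, stored, expected_hu):
        path = tmp_path / "s.dcm"
        img = CTImage(np.zeros((16, 16)), patient_id="p1")
        write_dicom_slice(path, img)
        import pydicom
        ds = pydicom.dcmread(path)
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = np.full((16, 16), stored, dtype=np.int16).tobytes()
        ds.save_as(path, enforce_file_format=True)
        out = read_dicom_slice(path)
        assert out.pixels[0, 0] == expected_hu

    def test_round_trip_bitwise(self, tmp_path, rng):
        hu = np.rint(rng.uniform(-1000, 1000, (32, 24))).astype(np.float64)
        src = CTImage(hu, patient_id="p9", slice_index=3,
                      pixel_spacing=(0.7, 0.7))
        path = tmp_path / "rt.dcm"
        write_dicom_slice(path, src)
        out = read_dicom_slice(path)
        np.testing.assert_array_equal(out.pixels, hu)
        assert out.patient_id == "p9"
        assert out.slice_index == 3

    def test_unreadable_file_is_format_error(self, tmp_path):
        path = tmp_path / "junk.dcm"
        path.write_bytes(b"not dicom at all")
        with pytest.raises(FormatError):
            read_dicom_slice(path)


class TestNifti:
    def test_axis_split(self, tmp_path, rng):
        vol = rng.normal(0, 100, (16, 16, 4))
        path = tmp_path / "v.nii.gz"
        import nibabel as nib
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
        slices = read_nifti_volume(path)
        assert len(slices) == 4
        assert all(s.pixels.shape == (16, 16) for s in slices)
        assert [s.slice_index for s in slices] == [0, 1, 2, 3]

    def test_round_trip(self, tmp_path, rng):
        planes = [rng.normal(0, 300, (16, 16)) for _ in range(3)]
        path = tmp_path / "rt.nii.gz"
        write_nifti_volume(path, planes)
        out = read_nifti_volume(path)
        for src, got in zip(planes, out):
            np.testing.assert_array_equal(got.pixels, src)

    def test_non_3d_rejected(self, tmp_path, rng):
        import nibabel as nib
        path = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(rng.normal(0, 1, (8, 8)), np.eye(4)), str(path))
        with pytest.raises(FormatError):
            read_nifti_volume(path)


class TestWindowing:
    def test_midpoint_maps_to_half(self):
        w = WindowSpec(width=1500, center=600)
        assert apply_window(np.array([[600.0] * 8] * 8), w)[0, 0] == 0.5

    def test_clipping_limits(self):
        w = WindowSpec(width=1500, center=600)
        arr = np.array([[-150.0, -151, -5000], [1350.0, 1400, 5000],
                        [0, 0, 0]] + [[0] * 3] * 5)
        out = apply_window(arr, w)
        assert out[0, 0] == 0.0 and out[0, 2] == 0.0
        assert out[1, 0] == 1.0 and out[1, 2] == 1.0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_elementwise_formula(self, seed):
        rng = np.random.default_rng(seed)
        hu = rng.uniform(-2000, 3000, (12, 12))
        w = WindowSpec(width=float(rng.uniform(10, 3000)),
                       center=float(rng.uniform(-1000, 1000)))
        out = apply_window(hu, w)
        low = w.center - w.width / 2
        expect = np.empty_like(hu)
        for i in range(12):
            for j in range(12):
                expect[i, j] = min(max((hu[i, j] - low) / w.width, 0.0), 1.0)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_monotone_in_hu(self, rng):
        w = WindowSpec(width=800, center=-600)
        hu = np.sort(rng.uniform(-2000, 1000, 64)).reshape(8, 8)
        out = apply_window(hu, w).ravel()
        assert np.all(np.diff(out) >= 0)

    def test_identity_window_on_normalized_signal(self, rng):
        # a signal already in [0,1] passes through the unit window unchanged
        sig = rng.uniform(0, 1, (8, 8))
        out = apply_window(sig, WindowSpec(width=1.0, center=0.5))
        np.testing.assert_allclose(out, sig, atol=1e-12)


class TestResize:
    def test_constant_image_preserved(self):
        out = resize_to_model(np.full((32, 32), 0.37), 16)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_512_to_256_shape(self, rng):
        out = resize_to_model(rng.uniform(0, 1, (512, 512)), 256)
        assert out.shape == (256, 256)

    def test_checkerboard_halving_matches_bilinear_oracle(self):
        img = np.indices((16, 16)).sum(axis=0) % 2.0
        out = resize_to_model(img, 8)
        # pixel-centre-aligned bilinear at exact 2x decimation averages
        # each 2x2 block
        oracle = img.reshape(8, 2, 8, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_mask_resize_stays_binary(self, rng):
        mask = SegmentationMask((rng.uniform(0, 1, (33, 33)) > 0.5).astype(int))
        for side in (16, 64):
            out = resize_mask(mask, side)
            assert out.pixels.shape == (side, side)
            assert set(np.unique(out.pixels)) <= {0, 1}

    def test_all_ones_and_zeros_masks(self):
        ones = resize_mask(SegmentationMask(np.ones((32, 32), int)), 16)
        zeros = resize_mask(SegmentationMask(np.zeros((32, 32), int)), 16)
        assert ones.pixels.all()
        assert not zeros.pixels.any()

    def test_small_target_rejected(self, rng):
        with pytest.raises(ValueError):
            resize_to_model(rng.uniform(0, 1, (32, 32)), 4)


class TestMaskPng:
    def test_round_trip(self, tmp_path, rng):
        mask = SegmentationMask((rng.uniform(0, 1, (20, 20)) > 0.7).astype(int))
        path = tmp_path / "m.png"
        write_mask_png(path, mask)
        out = read_mask_png(path)
        np.testing.assert_array_equal(out.pixels, mask.pixels)


class TestSplit:
    def test_study_sizes(self):
        ids = [f"P{i:02d}" for i in range(60)]
        split = split_by_patient(ids, (50, 4, 6), seed=3)
        assert (len(split.train_ids), len(split.val_ids),
                len(split.test_ids)) == (50, 4, 6)

    def test_deterministic_and_partition(self):
        ids = {f"P{i}" for i in range(17)}
        a = split_by_patient(ids, (10, 3, 4), seed=9)
        b = split_by_patient(ids, (10, 3, 4), seed=9)
        assert a == b
        assert a.train_ids | a.val_ids | a.test_ids == ids

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_by_patient({"a", "b"}, (2, 1, 0), seed=0)

    def test_patient_slices_stay_together(self):
        # every slice is keyed by patient id, so subset lookup is unique
        ids = [f"P{i}" for i in range(12)]
        split = split_by_patient(ids, (8, 2, 2), seed=1)
        subsets = {pid: split.subset_of(pid) for pid in ids}
        assert all(subsets[pid] in {"train", "val", "test"} for pid in ids)
        assert sum(v == "train" for v in subsets.values()) == 8
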