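"""Format round-trips and labeling conventions for DICOM/NIfTI/PNG readers."""

import numpy as np
import pytest
from PIL import Image

from aimunet.imaging_io import (BinaryMask, CTSlice, FormatError, PairingError,
                                read_dicom_series, read_mask_png, read_nifti,
                                read_slice_pair, write_dicom, write_image,
                                write_mask_png, write_nifti)


def _write_series(directory, n=3, patient="pat1", rng=None):
    rng = rng or np.random.default_rng(0)
    slices = []
    for i in range(n):
        hu = rng.integers(-200, 300, size=(8, 8)).astype(np.float64)
        slices.append(hu)
        # write files in shuffled order of position to exercise sorting
        write_dicom(directory / f"im{n - i}.dcm", hu, patient_id=patient,
                    instance=i + 1, position=float(i * 2.5))
    return slices


class TestDicom:
    def test_series_round_trip_in_position_order(self, tmp_path):
        truth = _write_series(tmp_path, n=3)
        vol = read_dicom_series(tmp_path)
        assert len(vol) == 3
        assert vol.patient_id == "pat1"
        for i, s in enumerate(vol.slices):
            assert s.slice_index == i
            assert np.array_equal(s.pixels, truth[i])

    def test_linear_rescale_to_hu(self, tmp_path):
        # stored value 1084 with slope 1, intercept -1024 -> 60 HU
        write_dicom(tmp_path / "a.dcm", np.full((4, 4), 60.0), patient_id="p",
                    instance=1, position=0.0, slope=1.0, intercept=-1024.0)
        vol = read_dicom_series(tmp_path)
        assert np.all(vol.slices[0].pixels == 60.0)

    def test_empty_directory_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_dicom_series(tmp_path)

    def test_mixed_patients_rejected(self, tmp_path):
        write_dicom(tmp_path / "a.dcm", np.zeros((4, 4)), "p1", 1, 0.0)
        write_dicom(tmp_path / "b.dcm", np.zeros((4, 4)), "p2", 2, 2.5)
        with pytest.raises(FormatError, match="mixed patients"):
            read_dicom_series(tmp_path)

    def test_bad_file_error_identifies_file(self, tmp_path):
        write_dicom(tmp_path / "good.dcm", np.zeros((4, 4)), "p", 1, 0.0)
        (tmp_path / "notdicom.dcm").write_bytes(b"\x00" * 140)
        with pytest.raises(FormatError, match="notdicom"):
            read_dicom_series(tmp_path)

    def test_missing_rescale_tag_is_format_error(self, tmp_path):
        from aimunet.imaging_io import read_dicom_file
        path = tmp_path / "norescale.dcm"
        write_dicom(path, np.zeros((4, 4)), "p", 1, 0.0)
        data = bytearray(path.read_bytes())
        # retag RescaleSlope (0028,1053) to a private group so it goes missing
        idx = data.find(b"\x28\x00\x53\x10")
        assert idx > 0
        data[idx:idx + 4] = b"\x29\x00\x53\x10"
        path.write_bytes(bytes(data))
        with pytest.raises(FormatError, match="RescaleSlope"):
            read_dicom_file(path)


class TestNifti:
    def test_axis_split(self, tmp_path):
        arr = np.random.default_rng(1).random((8, 8, 5))
        import nibabel as nib
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(tmp_path / "v.nii.gz"))
        vol = read_nifti(tmp_path / "v.nii.gz")
        assert len(vol) == 5
        assert vol.slices[0].pixels.shape == (8, 8)
        assert np.allclose(vol.slices[2].pixels, arr[:, :, 2])

    def test_round_trip(self, tmp_path):
        arr = np.random.default_rng(2).random((5, 8, 8))  # (n, h, w)
        write_nifti(tmp_path / "w.nii.gz", arr)
        vol = read_nifti(tmp_path / "w.nii.gz")
        assert np.allclose(vol.to_array(), arr)

    def test_nan_voxel_is_format_error(self, tmp_path):
        arr = np.zeros((4, 4, 3))
        arr[1, 1, 1] = np.nan
        import nibabel as nib
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(tmp_path / "nan.nii.gz"))
        with pytest.raises(FormatError, match="non-finite"):
            read_nifti(tmp_path / "nan.nii.gz")

    def test_4d_is_format_error(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 3, 2)), np.eye(4)),
                 str(tmp_path / "v4.nii.gz"))
        with pytest.raises(FormatError, match="3-D"):
            read_nifti(tmp_path / "v4.nii.gz")


class TestSlicePairs:
    def test_mask_binarization_0_255(self, tmp_path):
        mask255 = np.zeros((8, 8), dtype=np.uint8)
        mask255[2:5, 2:5] = 255
        Image.fromarray(mask255, mode="L").save(tmp_path / "m.png")
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(tmp_path / "i.png")
        _, mask = read_slice_pair(tmp_path / "i.png", tmp_path / "m.png")
        assert set(np.unique(mask.pixels)) == {0, 1}
        assert mask.pixels.sum() == 9

    def test_equal_channels_collapse(self, tmp_path):
        gray = np.arange(64, dtype=np.uint8).reshape(8, 8)
        Image.fromarray(np.stack([gray] * 3, axis=-1)).save(tmp_path / "i.png")
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8), mode="L").save(tmp_path / "m.png")
        ct, _ = read_slice_pair(tmp_path / "i.png", tmp_path / "m.png")
        assert np.array_equal(ct.pixels, gray.astype(float))

    def test_shape_mismatch_is_pairing_error(self, tmp_path):
        Image.fromarray(np.zeros((16, 16, 3), dtype=np.uint8)).save(tmp_path / "i.png")
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8), mode="L").save(tmp_path / "m.png")
        with pytest.raises(PairingError):
            read_slice_pair(tmp_path / "i.png", tmp_path / "m.png")

    def test_mask_png_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        mask = BinaryMask(pixels=(rng.random((16, 16)) > 0.5).astype(np.uint8))
        write_mask_png(tmp_path / "m.png", mask)
        again = read_mask_png(tmp_path / "m.png")
        assert np.array_equal(again.pixels, mask.pixels)
        write_mask_png(tmp_path / "m2.png", again)
        assert (tmp_path / "m.png").read_bytes() == (tmp_path / "m2.png").read_bytes()


class TestInvariants:
    def test_normalized_slice_range_enforced(self):
        with pytest.raises(FormatError):
            CTSlice(pixels=np.array([[0.0, 1.5]]), intensity_state="normalized")

    def test_non_finite_rejected(self):
        with pytest.raises(FormatError):
            CTSlice(pixels=np.array([[np.inf, 0.0]]))

    def test_mask_values_enforced(self):
        with pytest.raises(FormatError):
            BinaryMask(pixels=np.array([[0, 2]]))

    def test_image_export_readable(self, tmp_path):
        ct = CTSlice(pixels=np.linspace(-150, 250, 64).reshape(8, 8))
        write_image(tmp_path / "i.png", ct)
        arr = np.asarray(Image.open(tmp_path / "i.png"))
        assert arr.shape == (8, 8, 3)
        assert np.all(arr[..., 0] == arr[..., 1])
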