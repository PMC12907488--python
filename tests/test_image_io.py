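"""External representations: NIfTI, DICOM series, YOLO labels, mask boxes."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from ventriseg.detection import Detection
from ventriseg.image_io import (LabelVolume, NativeVolume, boxes_from_mask,
                                read_dicom_series, read_nifti,
                                read_yolo_labels, write_nifti,
                                write_yolo_labels)


# ---------------------------------------------------------------------------
# helpers

def make_ct_slice(path, z_mm, series_uid, pixels, slope=1.0, intercept=-1024.0,
                  pixel_spacing=(0.45, 0.45)):
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
    ds.PixelSpacing = list(pixel_spacing)
    ds.SliceThickness = 1.2
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_series(directory, n=12, gap=1.2, names=None, series_uid=None):
    series_uid = series_uid or generate_uid()
    rng = np.random.default_rng(0)
    frames = [rng.integers(0, 3000, (16, 16)).astype(np.uint16)
              for _ in range(n)]
    names = names or [f"slice_{i:03d}.dcm" for i in range(n)]
    for i, (name, frame) in enumerate(zip(names, frames)):
        make_ct_slice(directory / name, z_mm=i * gap, series_uid=series_uid,
                      pixels=frame)
    return frames


# ---------------------------------------------------------------------------
# DICOM

class TestDicomSeries:
    def test_metadata_passthrough(self, tmp_path):
        write_series(tmp_path, n=12, gap=1.2)
        vol = read_dicom_series(tmp_path)
        assert vol.data.shape == (16, 16, 12)
        assert vol.spacing == pytest.approx((0.45, 0.45, 1.2))

    def test_rescale_to_hounsfield(self, tmp_path):
        px = np.full((16, 16), 1024, dtype=np.uint16)
        make_ct_slice(tmp_path / "a.dcm", 0.0, generate_uid(), px)
        vol = read_dicom_series(tmp_path)
        assert np.all(vol.data == 0.0)  # 1024 * 1 - 1024

    def test_invariant_to_file_name_permutation(self, tmp_path):
        d1, d2 = tmp_path / "fwd", tmp_path / "rev"
        d1.mkdir()
        d2.mkdir()
        uid = generate_uid()
        frames = write_series(d1, n=8, series_uid=uid)
        # reversed names relative to spatial order
        names = [f"slice_{7 - i:03d}.dcm" for i in range(8)]
        for i, (name, frame) in enumerate(zip(names, frames)):
            make_ct_slice(d2 / name, z_mm=i * 1.2, series_uid=uid, pixels=frame)
        v1, v2 = read_dicom_series(d1), read_dicom_series(d2)
        assert np.array_equal(v1.data, v2.data)

    def test_mixed_series_rejected(self, tmp_path):
        write_series(tmp_path, n=3, series_uid=generate_uid())
        make_ct_slice(tmp_path / "other.dcm", 50.0, generate_uid(),
                      np.zeros((16, 16), np.uint16))
        with pytest.raises(ValueError, match="multiple series"):
            read_dicom_series(tmp_path)

    def test_non_uniform_gap_rejected(self, tmp_path):
        uid = generate_uid()
        for i, z in enumerate([0.0, 1.2, 2.4, 4.5]):  # last gap 75% off
            make_ct_slice(tmp_path / f"s{i}.dcm", z, uid,
                          np.zeros((16, 16), np.uint16))
        with pytest.raises(ValueError, match="non-uniform slice spacing"):
            read_dicom_series(tmp_path)


# ---------------------------------------------------------------------------
# NIfTI

class TestNifti:
    def test_native_round_trip(self, tmp_path, rng):
        vol = NativeVolume(rng.normal(30, 10, (20, 22, 24)).astype(np.float32),
                           spacing=(0.7, 0.7, 1.5),
                           affine=np.diag([0.7, 0.7, 1.5, 1.0]))
        path = tmp_path / "v.nii.gz"
        write_nifti(vol, path)
        back = read_nifti(path)
        assert np.allclose(back.data, vol.data, atol=1e-6)
        assert back.spacing == pytest.approx(vol.spacing)
        assert np.allclose(back.affine, vol.affine)

    def test_label_round_trip_preserves_counts(self, tmp_path, rng):
        labels = rng.integers(0, 13, (16, 16, 16)).astype(np.int16)
        lv = LabelVolume(labels, "native", (1, 1, 1))
        path = tmp_path / "l.nii.gz"
        write_nifti(lv, path)
        back = read_nifti(path, as_labels=True)
        assert np.array_equal(back.labels, labels)

    def test_background_only_labels(self, tmp_path):
        lv = LabelVolume(np.zeros((8, 8, 8), np.int16), "native", (1, 1, 1))
        path = tmp_path / "bg.nii.gz"
        write_nifti(lv, path)
        assert read_nifti(path, as_labels=True).labels.sum() == 0

    def test_canonical_header_reports_isotropic(self, tmp_path, canonical_pair):
        canonical, _ = canonical_pair
        path = tmp_path / "c.nii.gz"
        write_nifti(canonical, path)
        import nibabel as nib
        hdr = nib.load(str(path)).header
        assert tuple(hdr.get_zooms()) == pytest.approx((1.0, 1.0, 1.0))

    def test_out_of_range_label_rejected(self, tmp_path):
        import nibabel as nib
        bad = np.zeros((6, 6, 6), np.int16)
        bad[0, 0, 0] = 13
        nib.save(nib.Nifti1Image(bad, np.eye(4)), str(tmp_path / "bad.nii"))
        with pytest.raises(ValueError, match="label values"):
            read_nifti(tmp_path / "bad.nii", as_labels=True)

    def test_4d_rejected(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), np.float32), np.eye(4)),
                 str(tmp_path / "4d.nii"))
        with pytest.raises(ValueError, match="expected 3D volume"):
            read_nifti(tmp_path / "4d.nii")

    def test_sparse_label_set_accepted(self, tmp_path):
        lab = np.zeros((6, 6, 6), np.int16)
        lab[1] = 1
        lab[3] = 5
        write_nifti(LabelVolume(lab, "native", (1, 1, 1)), tmp_path / "s.nii")
        back = read_nifti(tmp_path / "s.nii", as_labels=True)
        assert set(np.unique(back.labels)) == {0, 1, 5}


# ---------------------------------------------------------------------------
# YOLO labels

class TestYoloLabels:
    def test_full_frame_box_line(self, tmp_path):
        det = Detection(class_id=2, z_index=0, cx=0.5, cy=0.5, w=1.0, h=1.0)
        path = tmp_path / "l.txt"
        write_yolo_labels([det], (256, 256), path)
        assert path.read_text().strip() == "2 0.500000 0.500000 1.000000 1.000000"

    def test_round_trip_50_random_boxes(self, tmp_path, rng):
        dets = [Detection(class_id=int(rng.integers(0, 12)), z_index=7,
                          cx=float(rng.uniform(0.2, 0.8)),
                          cy=float(rng.uniform(0.2, 0.8)),
                          w=float(rng.uniform(0.05, 0.3)),
                          h=float(rng.uniform(0.05, 0.3)),
                          confidence=float(rng.uniform(0.01, 0.99)))
                for _ in range(50)]
        path = tmp_path / "p.txt"
        write_yolo_labels(dets, (256, 256), path)
        back = read_yolo_labels(path, z_index=7)
        assert len(back) == 50
        for a, b in zip(dets, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h", "confidence"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    def test_empty_list_round_trip(self, tmp_path):
        path = tmp_path / "e.txt"
        write_yolo_labels([], (256, 256), path)
        assert path.read_text() == ""
        assert read_yolo_labels(path) == []

    def test_out_of_range_rejected(self, tmp_path):
        bad_class = Detection(class_id=12, z_index=0, cx=0.5, cy=0.5,
                              w=0.1, h=0.1)
        with pytest.raises(ValueError, match="class id"):
            write_yolo_labels([bad_class], (256, 256), tmp_path / "x.txt")

    def test_mixed_slices_rejected(self, tmp_path):
        dets = [Detection(0, 1, 0.5, 0.5, 0.1, 0.1),
                Detection(0, 2, 0.5, 0.5, 0.1, 0.1)]
        with pytest.raises(ValueError, match="more than one slice"):
            write_yolo_labels(dets, (256, 256), tmp_path / "x.txt")


# ---------------------------------------------------------------------------
# boxes from masks

class TestBoxesFromMask:
    def test_centered_rectangle_geometry(self):
        lab = np.zeros((256, 256, 3), np.int16)
        # 10 wide (x / columns) by 20 tall (y / rows), centered
        lab[118:138, 123:133, 1] = 5  # class id 4
        dets = boxes_from_mask(LabelVolume(lab, "canonical", (1, 1, 1)))
        assert len(dets) == 1
        d = dets[0]
        assert d.class_id == 4 and d.z_index == 1
        assert (d.cx, d.cy) == (0.5, 0.5)
        assert d.w == pytest.approx(10 / 256)
        assert d.h == pytest.approx(20 / 256)

    def test_disjoint_blobs_merge_into_one_box(self):
        lab = np.zeros((64, 64, 1), np.int16)
        lab[5:10, 5:10, 0] = 3
        lab[40:50, 45:55, 0] = 3
        dets = boxes_from_mask(LabelVolume(lab, "canonical", (1, 1, 1)))
        assert len(dets) == 1
        d = dets[0]
        # brute-force min/max over labelled voxels
        ys, xs = np.nonzero(lab[:, :, 0] == 3)
        assert d.w * 64 == pytest.approx(xs.max() + 1 - xs.min())
        assert d.h * 64 == pytest.approx(ys.max() + 1 - ys.min())

    def test_empty_volume_yields_no_boxes(self):
        lab = LabelVolume(np.zeros((16, 16, 4), np.int16), "canonical", (1, 1, 1))
        assert boxes_from_mask(lab) == []

    def test_phantom_boxes_match_per_slice_presence(self, canonical_pair):
        _, labels = canonical_pair
        dets = boxes_from_mask(labels)
        # exhaustive scan: one box per (class, slice) with presence
        expected = set()
        for z in range(labels.labels.shape[2]):
            for v in np.unique(labels.labels[:, :, z]):
                if v > 0:
                    expected.add((int(v) - 1, z))
        assert {(d.class_id, d.z_index) for d in dets} == expected

    def test_boxes_contain_all_class_voxels(self, canonical_pair):
        _, labels = canonical_pair
        for d in boxes_from_mask(labels)[::7]:
            x0, y0, x1, y1 = d.pixel_box(256)
            plane = labels.labels[:, :, d.z_index] == d.class_id + 1
            assert plane[y0:y1, x0:x1].sum() == plane.sum()
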