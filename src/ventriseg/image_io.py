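"""Reading and writing of every external representation the pipeline
touches: DICOM series, NIfTI volumes, integer label volumes, YOLO-format
detection annotations, and PNG slice exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom

from ventriseg.detection import Detection
from ventriseg.subregions import N_CLASSES

log = logging.getLogger(__name__)

MAX_LABEL = N_CLASSES  # voxel codes are 0 (background) .. 12


@dataclass
class NativeVolume:
    """A CT volume on its native grid, in Hounsfield units.

    ``affine`` maps voxel indices to scanner (world) coordinates in mm;
    ``spacing`` is the per-axis voxel size.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("expected 3D volume")
        self.spacing = tuple(float(s) for s in self.spacing)
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def orientation(self) -> tuple[str, str, str]:
        return nib.aff2axcodes(self.affine)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3]


@dataclass
class LabelVolume:
    """Integer subregion map: 0 background, k+1 for class id k (k = 0..11)."""

    labels: np.ndarray
    frame: str = "native"  # "native" | "canonical"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("expected 3D label volume")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("label volume must be integer valued")
            lab = np.round(lab).astype(np.int16)
        if lab.min() < 0 or lab.max() > MAX_LABEL:
            raise ValueError(f"label values must lie in 0..{MAX_LABEL}")
        self.labels = lab.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.labels == class_id + 1

    def classes_present(self) -> list[int]:
        values = np.unique(self.labels)
        return [int(v) - 1 for v in values if v > 0]


# ---------------------------------------------------------------------------
# DICOM

def read_dicom_series(directory_path) -> NativeVolume:
    """Read a single-series stack of single-frame CT slices.

    Slices are ordered by their projected position along the slice
    normal (never by file name) and rescaled to Hounsfield units with
    each file's slope/intercept.
    """
    directory = Path(directory_path)
    datasets = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # non-DICOM clutter is skipped
            continue
    if not datasets:
        raise ValueError(f"no DICOM slices found in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", "") for ds in datasets}
    if len(uids) > 1:
        raise ValueError("multiple series in directory")

    iop = np.array(datasets[0].ImageOrientationPatient, dtype=float)
    col_dir, row_dir = iop[:3], iop[3:]
    normal = np.cross(col_dir, row_dir)
    datasets.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))
    positions = [float(np.dot(np.array(ds.ImagePositionPatient, float), normal))
                 for ds in datasets]

    if len(datasets) > 1:
        gaps = np.diff(positions)
        mean_gap = float(np.mean(gaps))
        if mean_gap <= 0 or np.any(np.abs(gaps - mean_gap) > 0.10 * abs(mean_gap)):
            raise ValueError("non-uniform slice spacing")
        dz = mean_gap
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    data = np.stack(slices, axis=-1)  # (rows, cols, slices)

    dr, dc = (float(v) for v in datasets[0].PixelSpacing)
    affine = np.eye(4)
    affine[:3, 0] = row_dir * dr
    affine[:3, 1] = col_dir * dc
    affine[:3, 2] = normal * dz
    affine[:3, 3] = np.array(datasets[0].ImagePositionPatient, dtype=float)
    return NativeVolume(data=data, spacing=(dr, dc, dz), affine=affine)


# ---------------------------------------------------------------------------
# NIfTI

def read_nifti(path, as_labels: bool = False) -> NativeVolume | LabelVolume:
    """Read a 3D NIfTI-1 volume; with ``as_labels`` validate and return a
    LabelVolume (integer values 0..12)."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError("expected 3D volume")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if as_labels:
        return LabelVolume(labels=data, frame="native", spacing=spacing,
                           affine=np.asarray(img.affine))
    return NativeVolume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_nifti(volume, path) -> None:
    """Write a NativeVolume, LabelVolume or CanonicalVolume as NIfTI-1.

    Label volumes are stored with an integer on-disk dtype.
    """
    path = str(path)
    if hasattr(volume, "labels"):
        img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine)
    else:
        img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                              np.asarray(volume.affine, dtype=float))
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


# ---------------------------------------------------------------------------
# YOLO annotation text files

def yolo_label_path(directory, stem: str, z_index: int) -> Path:
    return Path(directory) / f"{stem}_z{z_index:03d}.txt"


def write_yolo_labels(detections, slice_shape, path,
                      with_confidence: bool | None = None) -> None:
    """Write one text line per box: ``class cx cy w h [conf]``, 6 decimals.

    All detections must reference the same slice.  Confidence is
    appended only for predictions; by default it is written whenever any
    detection carries a confidence below 1.
    """
    detections = list(detections)
    if len({d.z_index for d in detections}) > 1:
        raise ValueError("detections reference more than one slice")
    if with_confidence is None:
        with_confidence = any(d.confidence < 1.0 for d in detections)
    lines = []
    for d in detections:
        if not 0 <= d.class_id < N_CLASSES:
            raise ValueError(f"class id {d.class_id} out of range")
        for v in (d.cx, d.cy, d.w, d.h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coordinate {v} outside [0, 1]")
        fields = f"{d.class_id} {d.cx:.6f} {d.cy:.6f} {d.w:.6f} {d.h:.6f}"
        if with_confidence:
            fields += f" {d.confidence:.6f}"
        lines.append(fields)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, z_index: int = 0) -> list[Detection]:
    """Inverse of :func:`write_yolo_labels` (5- or 6-field lines)."""
    out = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise ValueError(f"malformed YOLO line: {line!r}")
        cid = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else 1.0
        out.append(Detection(class_id=cid, z_index=z_index,
                             cx=cx, cy=cy, w=w, h=h, confidence=conf))
    return out


# ---------------------------------------------------------------------------
# ground-truth boxes from masks

def boxes_from_mask(label_volume: LabelVolume, axis: str = "axial") -> list[Detection]:
    """Tightest per-slice, per-class bounding boxes of a label volume.

    One box per class per slice: disjoint components of the same class
    on one slice are merged into a single tight box.  Boxes are
    normalized center/size with confidence 1.0.
    """
    if axis != "axial":
        raise ValueError("only axial slicing is supported")
    labels = label_volume.labels
    n_rows, n_cols, n_slices = labels.shape
    out = []
    for z in range(n_slices):
        plane = labels[:, :, z]
        for value in np.unique(plane):
            if value == 0:
                continue
            ys, xs = np.nonzero(plane == value)
            x0, x1 = int(xs.min()), int(xs.max()) + 1
            y0, y1 = int(ys.min()), int(ys.max()) + 1
            out.append(Detection(
                class_id=int(value) - 1, z_index=z,
                cx=(x0 + x1) / 2 / n_cols, cy=(y0 + y1) / 2 / n_rows,
                w=(x1 - x0) / n_cols, h=(y1 - y0) / n_rows,
                confidence=1.0))
    return out


# ---------------------------------------------------------------------------
# PNG export

def write_slice_png(pixels: np.ndarray, path) -> None:
    """Export a windowed [0, 1] slice as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(str(path), (arr * 255).round().astype(np.uint8))
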