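"""Standardization of native CT volumes to the frame the models consume:
RAS orientation, 1 mm isotropic, 256-cube grid, CSF window [0, 80] HU
mapped to [0, 1], axially sliced.

The full geometric chain (reorientation, isotropic resampling, symmetric
center crop/pad) is recorded in a CanonicalTransform whose affine maps
canonical voxel indices back to native voxel indices, so predictions can
be related to the original grid and labels can follow the images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from nibabel import orientations as _ornt
from skimage.transform import resize as _sk_resize

from ventriseg.image_io import LabelVolume, NativeVolume

GRID = 256
SPACING_MM = 1.0
WINDOW = (0.0, 80.0)


def window_hu(volume: np.ndarray, lo: float = WINDOW[0],
              hi: float = WINDOW[1]) -> np.ndarray:
    """Linear intensity window: clip((hu - lo) / (hi - lo), 0, 1)."""
    if hi <= lo:
        raise ValueError("window upper bound must exceed lower bound")
    v = np.asarray(volume, dtype=np.float32)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class CanonicalTransform:
    """Invertible record of the native -> canonical standardization."""

    ornt: np.ndarray                 # nibabel orientation transform, (3, 2)
    native_shape: tuple[int, int, int]
    reoriented_spacing: tuple[float, float, float]
    resampled_shape: tuple[int, int, int]
    offset: tuple[int, int, int]     # canonical origin in resampled coords
    grid: int = GRID

    def canonical_to_native_affine(self) -> np.ndarray:
        """4x4 affine taking canonical voxel indices to native voxel indices."""
        a1 = np.eye(4)
        a1[:3, 3] = self.offset
        reoriented_shape = np.array(
            [self.native_shape[int(ax)] for ax, _ in self.ornt], dtype=float)
        scale = reoriented_shape / np.array(self.resampled_shape, dtype=float)
        a2 = np.diag([*scale, 1.0])
        a2[:3, 3] = 0.5 * scale - 0.5
        a3 = _ornt.inv_ornt_aff(self.ornt, self.native_shape)
        return a3 @ a2 @ a1

    def map_points(self, canonical_points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(canonical_points, dtype=float))
        hom = np.c_[pts, np.ones(len(pts))]
        return (self.canonical_to_native_affine() @ hom.T).T[:, :3]


@dataclass
class CanonicalVolume:
    """A 256-cube, 1 mm isotropic, CSF-windowed volume in [0, 1]."""

    data: np.ndarray
    transform: CanonicalTransform
    window: tuple[float, float] = WINDOW
    source_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        g = self.transform.grid
        if self.data.shape != (g, g, g):
            raise ValueError(f"canonical volume must be {g}^3")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("canonical intensities must lie in [0, 1]")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (SPACING_MM,) * 3

    @property
    def affine(self) -> np.ndarray:
        return np.eye(4)


@dataclass
class AxialSlice:
    """One 2D axial plane of a canonical volume."""

    pixels: np.ndarray
    z_index: int
    source_id: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice pixels must be finite")
        if not 0 <= self.z_index:
            raise ValueError("negative z index")


def _center_window(resampled_shape, grid: int):
    """Per-axis symmetric placement of the grid window; same parity was
    enforced upstream so the centering is exact."""
    return tuple((s - grid) // 2 for s in resampled_shape)


def _even(n: int) -> int:
    n = max(1, int(round(n)))
    return n + (n % 2)  # match the parity of the (even) canonical grid


def _reorient(data: np.ndarray, affine: np.ndarray):
    ornt = _ornt.ornt_transform(_ornt.io_orientation(affine),
                                _ornt.axcodes2ornt(("R", "A", "S")))
    return _ornt.apply_orientation(data, ornt), ornt


def _place(resampled: np.ndarray, grid: int, fill: float = 0.0) -> np.ndarray:
    out = np.full((grid,) * 3, fill, dtype=resampled.dtype)
    src, dst = [], []
    for s in resampled.shape:
        off = (s - grid) // 2
        if off >= 0:
            src.append(slice(off, off + grid))
            dst.append(slice(0, grid))
        else:
            src.append(slice(0, s))
            dst.append(slice(-off, -off + s))
    out[tuple(dst)] = resampled[tuple(src)]
    return out


def resample_canonical(native: NativeVolume, grid: int = GRID,
                       spacing_mm: float = SPACING_MM,
                       window: tuple[float, float] = WINDOW,
                       source_id: str = "") -> CanonicalVolume:
    """Reorient to RAS, resample to isotropic spacing (trilinear), center
    in a ``grid``-cube, and apply the CSF window.

    Interpolation happens in HU space; windowing comes last.  The target
    extent per axis is rounded to the grid's parity so the symmetric
    crop/pad keeps the volume center fixed exactly.
    """
    if min(native.spacing) <= 0:
        raise ValueError("degenerate spacing")
    data_r, ornt = _reorient(native.data, native.affine)
    spacing_r = tuple(native.spacing[int(ax)] for ax, _ in ornt)
    new_shape = tuple(_even(s * sp / spacing_mm)
                      for s, sp in zip(data_r.shape, spacing_r))
    if new_shape == data_r.shape:
        resampled = np.asarray(data_r, dtype=np.float32)
    else:
        resampled = _sk_resize(data_r.astype(np.float32), new_shape, order=1,
                               anti_aliasing=False, preserve_range=True)
    # pad in HU with the window floor so padding maps to 0 after windowing
    placed = _place(resampled.astype(np.float32), grid, fill=window[0])
    transform = CanonicalTransform(
        ornt=np.asarray(ornt), native_shape=tuple(native.data.shape),
        reoriented_spacing=spacing_r, resampled_shape=new_shape,
        offset=_center_window(new_shape, grid), grid=grid)
    return CanonicalVolume(data=window_hu(placed, *window),
                           transform=transform, window=window,
                           source_id=source_id)


def resample_labels(label_volume: LabelVolume,
                    transform: CanonicalTransform) -> LabelVolume:
    """Carry a native-frame label volume through a recorded
    standardization, with nearest-neighbour interpolation (classes are
    preserved or shrunk, never invented)."""
    if label_volume.labels.shape != tuple(transform.native_shape):
        raise ValueError("frame mismatch between labels and transform")
    data_r = _ornt.apply_orientation(label_volume.labels, transform.ornt)
    if tuple(transform.resampled_shape) == data_r.shape:
        resampled = data_r
    else:
        resampled = _sk_resize(data_r.astype(np.float32),
                               transform.resampled_shape, order=0,
                               anti_aliasing=False, preserve_range=True)
    placed = _place(np.round(resampled).astype(np.int16), transform.grid)
    return LabelVolume(labels=placed, frame="canonical",
                       spacing=(SPACING_MM,) * 3)


def slice_axial(volume: CanonicalVolume) -> list[AxialSlice]:
    """All 256 axial planes, z ascending (inferior to superior in RAS)."""
    return [AxialSlice(pixels=volume.data[:, :, z], z_index=z,
                       source_id=volume.source_id)
            for z in range(volume.data.shape[2])]


def stack_axial(slices: list[AxialSlice]) -> np.ndarray:
    """Exact inverse of :func:`slice_axial`."""
    ordered = sorted(slices, key=lambda s: s.z_index)
    return np.stack([s.pixels for s in ordered], axis=-1)
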