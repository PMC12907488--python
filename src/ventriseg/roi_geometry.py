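"""Invertible ROI geometry: box enlargement, crop/pad/resize, and the
exact inverse used for backsampling.

Pixel boxes are half-open integer rectangles (x0, y0, x1, y1) with the
origin at the top-left, x = column and y = row.  Every patch carries a
CropTransform recording exactly what was done so the operation can be
inverted bit-faithfully (pad-only mode) or up to interpolation (resize
mode).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

Box = tuple[int, int, int, int]


@dataclass(frozen=True)
class CropTransform:
    """Record of one ROI crop: enlarged source box, squarifying pad,
    centering pad, and the resize factor from the padded square to the
    target patch size."""

    source_box: Box                       # (x0, y0, x1, y1), half-open pixels
    pad_square: tuple[int, int, int, int]  # (top, bottom, left, right) to square
    pad_target: tuple[int, int, int, int]  # further pad to target (pad-only mode)
    resize_factor: float                  # target / square side (1.0 = pad-only)
    square_size: int
    target: int
    z_index: int = 0
    class_id: int = -1

    def __post_init__(self):
        x0, y0, x1, y1 = self.source_box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate source box {self.source_box}")
        if min(self.pad_square) < 0 or min(self.pad_target) < 0:
            raise ValueError("negative padding")
        if self.resize_factor <= 0:
            raise ValueError("resize_factor must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CropTransform":
        d = json.loads(s)
        d["source_box"] = tuple(d["source_box"])
        d["pad_square"] = tuple(d["pad_square"])
        d["pad_target"] = tuple(d["pad_target"])
        return cls(**d)


def clip_box(box: Box, bounds: int) -> Box:
    x0, y0, x1, y1 = box
    return (max(0, min(x0, bounds)), max(0, min(y0, bounds)),
            max(0, min(x1, bounds)), max(0, min(y1, bounds)))


def enlarge_box(box: Box, factor: float, bounds: int = 256) -> Box:
    """Scale a box about its center, rounding outward and clipping to the slice.

    ``factor`` is the linear enlargement (3.0 triples width and height);
    the result always contains the original box and never exceeds the
    ``bounds`` x ``bounds`` slice.
    """
    if not 1.0 <= factor <= 4.0:
        raise ValueError(f"enlargement factor {factor} outside [1, 4]")
    x0, y0, x1, y1 = box
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    hw, hh = (x1 - x0) * factor / 2.0, (y1 - y0) * factor / 2.0
    out = (math.floor(cx - hw), math.floor(cy - hh),
           math.ceil(cx + hw), math.ceil(cy + hh))
    out = clip_box(out, bounds)
    # clipping can only shrink toward the slice, never past the original box
    return (min(out[0], x0), min(out[1], y0), max(out[2], x1), max(out[3], y1))


def _split_pad(total: int) -> tuple[int, int]:
    """Symmetric split, extra pixel on the trailing side."""
    return total // 2, total - total // 2


def _resize2d(img: np.ndarray, shape: tuple[int, int], is_mask: bool) -> np.ndarray:
    order = 0 if is_mask else 1
    out = _sk_resize(img.astype(np.float32), shape, order=order,
                     anti_aliasing=False, preserve_range=True)
    if is_mask:
        out = (out >= 0.5).astype(img.dtype)
    return out


def crop_pad_resize(slice_2d: np.ndarray, box: Box, factor: float = 1.0,
                    target: int = 256, mode: str = "auto",
                    is_mask: bool = False, z_index: int = 0,
                    class_id: int = -1) -> tuple[np.ndarray, CropTransform]:
    """Enlarge ``box`` by ``factor``, crop it from a slice and
    standardize it to a target-square patch.

    The crop is zero-padded symmetrically to a square.  In resize mode the
    square is rescaled to ``target``; in pad-only mode (resize_factor 1)
    it is centered in the target frame with further zero padding, which
    makes the round trip bit-exact for masks.  ``mode`` is "auto"
    (pad-only only when the box is already square and fits), "pad"
    (force pad-only; box must fit inside the target) or "resize".
    """
    h_s, w_s = slice_2d.shape
    if factor != 1.0:
        box = enlarge_box(box, factor, bounds=max(h_s, w_s))
    box = clip_box(box, max(h_s, w_s))
    x0, y0, x1, y1 = box
    if x0 >= x1 or y0 >= y1:
        raise ValueError("empty box after clipping")
    crop = slice_2d[y0:y1, x0:x1]
    h, w = crop.shape
    side = max(h, w)
    pt, pb = _split_pad(side - h)
    pl, pr = _split_pad(side - w)
    square = np.zeros((side, side), dtype=slice_2d.dtype)
    square[pt:pt + h, pl:pl + w] = crop

    if mode == "pad" or (mode == "auto" and h == w and side <= target):
        if side > target:
            raise ValueError(f"box side {side} exceeds target {target} in pad-only mode")
        qt, qb = _split_pad(target - side)
        ql, qr = _split_pad(target - side)
        patch = np.zeros((target, target), dtype=slice_2d.dtype)
        patch[qt:qt + side, ql:ql + side] = square
        tr = CropTransform(box, (pt, pb, pl, pr), (qt, qb, ql, qr), 1.0,
                           side, target, z_index, class_id)
    elif mode in ("auto", "resize"):
        patch = _resize2d(square, (target, target), is_mask)
        tr = CropTransform(box, (pt, pb, pl, pr), (0, 0, 0, 0),
                           target / side, side, target, z_index, class_id)
    else:
        raise ValueError(f"unknown crop mode {mode!r}")
    return patch, tr


def invert_crop(patch: np.ndarray, transform: CropTransform,
                out_shape: tuple[int, int] = (256, 256),
                is_mask: bool = True) -> np.ndarray:
    """Exact geometric inverse of :func:`crop_pad_resize`.

    Pixels outside the source box are zero.  Pad-only transforms invert
    bit-exactly; resize transforms invert through nearest (masks) or
    bilinear (images) interpolation.
    """
    t = transform
    if patch.shape != (t.target, t.target):
        raise ValueError(f"patch shape {patch.shape} != target {t.target}")
    x0, y0, x1, y1 = t.source_box
    if x1 > out_shape[1] or y1 > out_shape[0]:
        raise ValueError("source box lies outside the output shape")
    if t.resize_factor == 1.0:
        qt, _, ql, _ = t.pad_target
        square = patch[qt:qt + t.square_size, ql:ql + t.square_size]
    else:
        square = _resize2d(patch, (t.square_size, t.square_size), is_mask)
    pt, _, pl, _ = t.pad_square
    h, w = y1 - y0, x1 - x0
    out = np.zeros(out_shape, dtype=patch.dtype)
    out[y0:y1, x0:x1] = square[pt:pt + h, pl:pl + w]
    return out
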