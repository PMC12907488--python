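"""Backsampling of per-ROI 2D predictions into a fused 3D label volume,
and subregion volumetry with grouped volumes and relative volumetric
errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ventriseg.image_io import LabelVolume
from ventriseg.roi_geometry import CropTransform, invert_crop
from ventriseg.subregions import GROUPS, SUBREGIONS, N_CLASSES, fusion_rank

log = logging.getLogger(__name__)


def backsample(predictions, grid: tuple[int, int, int] = (256, 256, 256)
               ) -> tuple[LabelVolume, int]:
    """Invert each (mask patch, CropTransform) onto its slice and fuse
    the per-class binary volumes into one exclusive label volume.

    Returns (label volume, number of contested voxels).  Duplicate
    (class, slice) predictions are rejected.
    """
    seen: set[tuple[int, int]] = set()
    per_class = {cid: np.zeros(grid, dtype=bool) for cid in range(N_CLASSES)}
    for patch, transform in predictions:
        key = (transform.class_id, transform.z_index)
        if key in seen:
            raise ValueError("conflicting ROI predictions")
        seen.add(key)
        plane = invert_crop(np.asarray(patch), transform,
                            out_shape=grid[:2], is_mask=True)
        per_class[transform.class_id][:, :, transform.z_index] |= plane > 0
    return fuse_overlaps(per_class)


def fuse_overlaps(per_class_volumes: dict) -> tuple[LabelVolume, int]:
    """Exclusive fusion of per-class binary volumes.

    Voxels claimed by several classes go to the rarest/smallest
    structure (posterior horn > temporal horn > atrium > anterior horn >
    third > fourth > body), ties broken by class id; the contested-voxel
    count is logged and returned.
    """
    shape = next(iter(per_class_volumes.values())).shape
    n_claims = np.zeros(shape, dtype=np.int8)
    labels = np.zeros(shape, dtype=np.int16)
    # visit classes from lowest priority upward so higher priority
    # overwrites; iterate ids descending first so equal-rank ties go to
    # the lower class id
    order = sorted(per_class_volumes,
                   key=lambda cid: (-fusion_rank(cid), -cid))
    for cid in order:
        mask = per_class_volumes[cid]
        n_claims += mask.astype(np.int8)
        labels[mask] = cid + 1
    contested = int((n_claims > 1).sum())
    if contested:
        log.info("fuse_overlaps: %d contested voxels resolved by priority",
                 contested)
    return LabelVolume(labels=labels, frame="canonical",
                       spacing=(1.0, 1.0, 1.0)), contested


@dataclass
class VolumeReport:
    """Per-subregion and grouped volumes in ml, with optional relative
    volumetric errors against a reference."""

    per_class_ml: dict = field(default_factory=dict)
    groups_ml: dict = field(default_factory=dict)
    rve: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"per_class_ml": self.per_class_ml,
                           "groups_ml": self.groups_ml, "rve": self.rve},
                          indent=2, sort_keys=True)

    def to_csv(self) -> str:
        lines = ["entry,volume_ml,rve"]
        for name in list(self.per_class_ml) + list(self.groups_ml):
            vol = self.per_class_ml.get(name, self.groups_ml.get(name))
            rve = self.rve.get(name)
            lines.append(f"{name},{vol:.6f},{'' if rve is None else f'{rve:.6f}'}")
        return "\n".join(lines) + "\n"

    def save(self, path_json, path_csv=None) -> None:
        Path(path_json).write_text(self.to_json())
        if path_csv is not None:
            Path(path_csv).write_text(self.to_csv())


def relative_volumetric_error(predicted_ml: float,
                              reference_ml: float) -> float | None:
    """Signed (predicted - reference) / reference; None when the
    reference is empty (posterior horns are often truly 0 ml)."""
    if reference_ml <= 0:
        return None
    return (predicted_ml - reference_ml) / reference_ml


def compute_volumes(label_volume: LabelVolume,
                    spacing: tuple[float, float, float] | float | None = None,
                    reference: dict | None = None) -> VolumeReport:
    """Per-class and grouped volumes in ml (voxel count x voxel volume).

    ``reference`` maps entry names (class or group) to reference ml; when
    given, signed relative volumetric errors are attached.
    """
    if spacing is None:
        spacing = label_volume.spacing
    spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing, float)), (3,))
    if np.any(spacing <= 0):
        raise ValueError("unknown or invalid spacing")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    report = VolumeReport()
    counts = np.bincount(label_volume.labels.ravel(), minlength=N_CLASSES + 1)
    for cls in SUBREGIONS:
        report.per_class_ml[cls.name] = float(counts[cls.label_value]) * voxel_ml
    for group, members in GROUPS.items():
        report.groups_ml[group] = float(
            sum(report.per_class_ml[SUBREGIONS[cid].name] for cid in members))
    if reference:
        for name in list(report.per_class_ml) + list(report.groups_ml):
            if name in reference:
                pred = report.per_class_ml.get(name, report.groups_ml.get(name))
                report.rve[name] = relative_volumetric_error(pred, reference[name])
    return report


def reference_volumes_from_labels(label_volume: LabelVolume,
                                  spacing=None) -> dict:
    """Reference ml per class and group from a ground-truth label volume."""
    rep = compute_volumes(label_volume, spacing)
    return {**rep.per_class_ml, **rep.groups_ml}


def export_overlays(canonical_data: np.ndarray, labels: np.ndarray,
                    directory, stride: int = 8) -> list[Path]:
    """Color-overlay PNGs of every ``stride``-th axial slice for review."""
    import imageio.v3 as iio

    palette = np.array(
        [[0, 0, 0]] + [[int(c) for c in np.random.default_rng(7 + i).integers(64, 255, 3)]
                       for i in range(N_CLASSES)], dtype=np.uint8)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for z in range(0, canonical_data.shape[2], stride):
        gray = (np.clip(canonical_data[:, :, z], 0, 1) * 255).astype(np.uint8)
        rgb = np.stack([gray] * 3, axis=-1)
        lab = labels[:, :, z]
        color = palette[lab]
        mask = lab > 0
        rgb[mask] = (0.5 * rgb[mask] + 0.5 * color[mask]).astype(np.uint8)
        path = directory / f"overlay_z{z:03d}.png"
        iio.imwrite(path, rgb)
        written.append(path)
    return written
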