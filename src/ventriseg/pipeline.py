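"""End-to-end orchestration of the inference chain (standardize ->
detect -> crop -> segment -> backsample -> volumetry) and of training,
both as library functions and as the engine behind the CLI.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from ventriseg import __version__
from ventriseg.detection import (ConvDetector, Detection, DetectorConfig,
                                 OracleDetector, detect, train_detector)
from ventriseg.image_io import (LabelVolume, NativeVolume, boxes_from_mask,
                                read_nifti, read_yolo_labels, write_nifti,
                                yolo_label_path)
from ventriseg.preprocessing import (resample_canonical,
                                     resample_labels, slice_axial)
from ventriseg.reconstruction import (VolumeReport, backsample,
                                      compute_volumes,
                                      reference_volumes_from_labels)
from ventriseg.roi_geometry import crop_pad_resize
from ventriseg.segmentation import (ModelRegistry, SegModelConfig,
                                    registry_key, train_subregion_model,
                                    POSTERIOR_KEY)
from ventriseg.subregions import SUBREGIONS, N_CLASSES

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single source of truth for one pipeline run; serializable to YAML
    and written next to every run's outputs."""

    input: str = ""
    labels: str | None = None
    models_dir: str | None = None
    output_dir: str = "out"
    detector: str = "oracle"          # oracle | builtin | external-yolo-labels
    detector_model: str | None = None
    yolo_dir: str | None = None
    segmenter: str = "models"         # models | oracle
    enlargement_factor: float = 3.0
    crop_mode: str = "auto"           # auto | pad | resize
    seg_threshold: float = 0.5
    window_lo: float = 0.0
    window_hi: float = 80.0
    grid_size: int = 256
    iou_threshold: float = 0.6
    confidence_threshold: float = 0.001
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def write(self, path) -> None:
        payload = {**asdict(self), "version": __version__}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


class ExternalYoloDetector:
    """Detector source replaying YOLO-format prediction files written by
    any external detector (one ``<stem>_z###.txt`` per slice)."""

    def __init__(self, directory, stem: str = "slice"):
        self.directory = Path(directory)
        self.stem = stem

    def predict_raw(self, slice_) -> list[Detection]:
        path = yolo_label_path(self.directory, self.stem, slice_.z_index)
        if not path.exists():
            return []
        return read_yolo_labels(path, z_index=slice_.z_index)


def _segment_patch(registry: ModelRegistry | None, class_id: int,
                   patch: np.ndarray, threshold: float,
                   gt_plane: np.ndarray | None, box, mode: str):
    """One ROI's binary mask: model prediction, or the ground-truth mask
    pushed through the identical crop geometry (oracle passthrough)."""
    if gt_plane is not None:
        mask_patch, _ = crop_pad_resize(gt_plane, box, target=patch.shape[0],
                                        mode=mode, is_mask=True)
        return mask_patch.astype(bool)
    return registry.predict(class_id, patch, threshold)


def run_inference_volume(native: NativeVolume,
                         config: PipelineConfig,
                         detector_model=None,
                         registry: ModelRegistry | None = None,
                         gt_labels: LabelVolume | None = None
                         ) -> dict:
    """Execute the full chain on one native volume.

    Returns a dict with the canonical volume, the ground-truth labels on
    the canonical frame (when given), the fused predicted LabelVolume,
    the contested-voxel count, the VolumeReport, and per-stage timings.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    canonical = resample_canonical(native, grid=config.grid_size,
                                   window=(config.window_lo, config.window_hi))
    gt_canonical = (resample_labels(gt_labels, canonical.transform)
                    if gt_labels is not None else None)
    timings["preprocess_s"] = time.perf_counter() - t0

    if config.detector == "oracle":
        if gt_canonical is None:
            raise ValueError("oracle detector requires ground-truth labels")
        detector_model = OracleDetector(gt_canonical)
    elif config.detector == "external-yolo-labels":
        if detector_model is None:
            if config.yolo_dir is None:
                raise ValueError("external detector requires yolo_dir")
            detector_model = ExternalYoloDetector(config.yolo_dir)
    elif detector_model is None:
        raise ValueError("builtin detector requires a loaded model")
    det_config = DetectorConfig(iou_threshold=config.iou_threshold,
                                confidence_threshold=config.confidence_threshold,
                                image_size=config.grid_size)

    if config.segmenter == "oracle" and gt_canonical is None:
        raise ValueError("oracle segmenter requires ground-truth labels")
    if config.segmenter == "models":
        if registry is None:
            raise ValueError("segmenter 'models' requires a model registry")
        registry.validate()

    t0 = time.perf_counter()
    predictions = []
    n_boxes = 0
    for sl in slice_axial(canonical):
        for det in detect(sl, detector_model, det_config):
            n_boxes += 1
            box = det.pixel_box(config.grid_size)
            patch, transform = crop_pad_resize(
                sl.pixels, box, factor=config.enlargement_factor,
                target=256, mode=config.crop_mode,
                z_index=sl.z_index, class_id=det.class_id)
            gt_plane = None
            if config.segmenter == "oracle":
                gt_plane = gt_canonical.class_mask(det.class_id)[:, :, sl.z_index]
            mask_patch = _segment_patch(
                registry if config.segmenter == "models" else None,
                det.class_id, patch, config.seg_threshold, gt_plane,
                (transform.source_box), config.crop_mode)
            predictions.append((mask_patch, transform))
    timings["detect_segment_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fused, contested = backsample(predictions, grid=(config.grid_size,) * 3)
    reference = (reference_volumes_from_labels(gt_canonical)
                 if gt_canonical is not None else None)
    report = compute_volumes(fused, (1.0, 1.0, 1.0), reference=reference)
    timings["reconstruct_s"] = time.perf_counter() - t0
    log.info("inference: %d ROIs, %d contested voxels, timings %s",
             n_boxes, contested, {k: round(v, 2) for k, v in timings.items()})
    return {"canonical": canonical, "gt_canonical": gt_canonical,
            "fused": fused, "contested": contested, "report": report,
            "n_rois": n_boxes, "timings": timings}


def run_inference(config: PipelineConfig) -> tuple[Path, Path]:
    """File-level entry point: read inputs, run, write outputs.

    Writes the fused label NIfTI, the volume report (JSON + CSV) and the
    resolved config into ``config.output_dir``; returns the two main
    output paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    native = read_nifti(config.input)
    gt = read_nifti(config.labels, as_labels=True) if config.labels else None

    registry = None
    if config.segmenter == "models":
        if config.models_dir is None:
            raise FileNotFoundError("no models directory configured; "
                                    "missing models for all 12 classes")
        registry = ModelRegistry.load(config.models_dir)
    detector_model = None
    if config.detector == "builtin":
        if config.detector_model is None:
            raise FileNotFoundError("builtin detector selected but no model file")
        detector_model = ConvDetector.load(config.detector_model)

    result = run_inference_volume(native, config, detector_model=detector_model,
                                  registry=registry, gt_labels=gt)
    labels_path = out / "segmentation.nii.gz"
    write_nifti(result["fused"], labels_path)
    report_path = out / "volumes.json"
    result["report"].save(report_path, out / "volumes.csv")
    config.write(out / "run_config.yaml")
    (out / "run_log.json").write_text(json.dumps(
        {"n_rois": result["n_rois"], "contested": result["contested"],
         "timings": result["timings"], "seed": config.seed}, indent=2))
    return labels_path, report_path


# ---------------------------------------------------------------------------
# training orchestration

def collect_training_patches(subjects, factor: float = 3.0,
                             mode: str = "auto", grid: int = 256,
                             classes=None) -> dict:
    """Ground-truth ROI patches per class from (canonical, labels) pairs.

    ``subjects`` is a list of (CanonicalVolume, LabelVolume-on-canonical)
    tuples.  Crops use the ground-truth boxes, mirroring the published
    construction of the segmentation training set.  ``classes`` limits
    collection to a subset of class ids.
    """
    wanted = set(range(N_CLASSES)) if classes is None else set(classes)
    per_class = {cid: {"patches": [], "masks": [], "subjects": []}
                 for cid in range(N_CLASSES)}
    for subj_id, (canonical, labels) in enumerate(subjects):
        boxes = [b for b in boxes_from_mask(labels) if b.class_id in wanted]
        for det in boxes:
            plane = canonical.data[:, :, det.z_index]
            gt_plane = labels.class_mask(det.class_id)[:, :, det.z_index]
            box = det.pixel_box(grid)
            patch, tr = crop_pad_resize(plane, box, factor=factor, mode=mode,
                                        z_index=det.z_index,
                                        class_id=det.class_id)
            mask, _ = crop_pad_resize(gt_plane, box, factor=factor, mode=mode,
                                      is_mask=True)
            entry = per_class[det.class_id]
            entry["patches"].append(patch)
            entry["masks"].append(mask.astype(np.uint8))
            entry["subjects"].append(subj_id)
    return per_class


def train_registry(per_class: dict, config: SegModelConfig,
                   n_folds: int = 1, min_patches: int = 10
                   ) -> tuple[ModelRegistry, dict]:
    """Train the eleven models (posterior horns pooled, right mirrored
    into left chirality).  Classes with too few patches are skipped with
    a prominent warning and the registry left incomplete."""
    registry = ModelRegistry()
    fold_metrics: dict[str, list[float]] = {}
    grouped: dict[str, dict] = {}
    for cid in range(N_CLASSES):
        key = registry_key(cid)
        bucket = grouped.setdefault(key, {"patches": [], "masks": [],
                                          "subjects": []})
        entry = per_class[cid]
        mirror = (key == POSTERIOR_KEY
                  and SUBREGIONS[cid].laterality == "right")
        for p, m, s in zip(entry["patches"], entry["masks"], entry["subjects"]):
            if mirror:
                # into left chirality: mirror the lateral (row) axis
                p, m = p[::-1, :].copy(), m[::-1, :].copy()
            bucket["patches"].append(p)
            bucket["masks"].append(m)
            bucket["subjects"].append(s)
    for key, bucket in grouped.items():
        if len(bucket["patches"]) < min_patches:
            log.warning("SKIPPING model %r: only %d patches", key,
                        len(bucket["patches"]))
            continue
        model, fold_dice = train_subregion_model(
            bucket["patches"], bucket["masks"], config,
            subject_ids=bucket["subjects"], n_folds=n_folds)
        registry.models[key] = model
        fold_metrics[key] = fold_dice
    return registry, fold_metrics


def run_training(subjects, seg_config: SegModelConfig,
                 det_config: DetectorConfig | None = None,
                 n_folds: int = 1, output_dir=None):
    """Train the detector (optional) and the 11 segmentation models.

    ``subjects`` is a list of (CanonicalVolume, canonical LabelVolume).
    Writes fold metrics and the registry when ``output_dir`` is given.
    """
    per_class = collect_training_patches(subjects)
    registry, fold_metrics = train_registry(per_class, seg_config,
                                            n_folds=n_folds)
    detector = None
    if det_config is not None:
        slices, labels = [], []
        for canonical, lab in subjects:
            by_z: dict[int, list[Detection]] = {}
            for det in boxes_from_mask(lab):
                by_z.setdefault(det.z_index, []).append(det)
            for sl in slice_axial(canonical):
                if sl.z_index in by_z:
                    slices.append(sl)
                    labels.append(by_z[sl.z_index])
        detector = train_detector(slices, labels, det_config)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        registry.save(out / "models")
        lines = ["model,fold,val_dice"]
        for key, dices in fold_metrics.items():
            for f, d in enumerate(dices):
                lines.append(f"{key},{f},{d:.4f}")
        (out / "fold_metrics.csv").write_text("\n".join(lines) + "\n")
        if detector is not None:
            detector.save(out / "detector.npz")
    return registry, fold_metrics, detector
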