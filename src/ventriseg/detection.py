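"""Per-slice multi-class bounding-box detection.

Three detector sources satisfy one contract (``detect(slice, model,
config)``): an oracle detector that replays ground-truth boxes, a
minimal single-scale anchor-free convolutional detector trainable on
CPU (per-class objectness/offset/size heads on a 32x32 cell grid), and
externally produced YOLO-format label files (handled by the pipeline).
Post-processing is shared: confidence filtering, class-wise NMS, and at
most one surviving box per class per slice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ventriseg import nn
from ventriseg.subregions import MIRROR_CLASS, N_CLASSES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Detection:
    """One bounding box on one axial slice, normalized xywh in [0, 1]."""

    class_id: int
    z_index: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box has no extent")
        if (self.cx + self.w / 2 <= 0 or self.cx - self.w / 2 >= 1
                or self.cy + self.h / 2 <= 0 or self.cy - self.h / 2 >= 1):
            raise ValueError("box does not intersect the slice")

    def pixel_box(self, size: int = 256) -> tuple[int, int, int, int]:
        """Half-open integer pixel box (x0, y0, x1, y1), clipped to the slice."""
        x0 = int(np.floor((self.cx - self.w / 2) * size))
        y0 = int(np.floor((self.cy - self.h / 2) * size))
        x1 = int(np.ceil((self.cx + self.w / 2) * size))
        y1 = int(np.ceil((self.cy + self.h / 2) * size))
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(size, max(x1, x0 + 1)), min(size, max(y1, y0 + 1))
        return x0, y0, x1, y1


@dataclass
class DetectorConfig:
    """Detector training/inference settings.

    Validation defaults follow the published operating point: IoU
    threshold 0.6 for NMS and confidence threshold 0.001.
    """

    epochs: int = 300
    batch_size: int = 64
    image_size: int = 256
    augmentation: dict = field(default_factory=lambda: {
        "flip": True, "scale": True, "translate": True})
    iou_threshold: float = 0.6
    confidence_threshold: float = 0.001
    learning_rate: float = 1e-2
    seed: int = 0
    grid: int = 32

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("iou_threshold", "confidence_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")


def _box_iou(a: Detection, b: Detection) -> float:
    from ventriseg.evaluation import box_iou
    return box_iou((a.cx, a.cy, a.w, a.h), (b.cx, b.cy, b.w, b.h))


def nms(candidates: list[Detection], iou_threshold: float) -> list[Detection]:
    """Class-wise non-maximum suppression, invariant to input order."""
    kept: list[Detection] = []
    order = sorted(candidates,
                   key=lambda d: (-d.confidence, d.class_id, d.cx, d.cy, d.w, d.h))
    for cand in order:
        if any(k.class_id == cand.class_id and _box_iou(k, cand) >= iou_threshold
               for k in kept):
            continue
        kept.append(cand)
    return kept


def detect(slice_, model, config: DetectorConfig) -> list[Detection]:
    """Run a detector on one axial slice and post-process its candidates.

    Candidates below the confidence threshold are dropped, class-wise
    NMS is applied at the configured IoU threshold, and at most one box
    per class (the most confident) is forwarded.
    """
    candidates = model.predict_raw(slice_)
    candidates = [c for c in candidates if c.confidence >= config.confidence_threshold]
    survivors = nms(candidates, config.iou_threshold)
    best: dict[int, Detection] = {}
    for det in survivors:
        if det.class_id not in best or det.confidence > best[det.class_id].confidence:
            best[det.class_id] = det
    return [best[cid] for cid in sorted(best)]


# ---------------------------------------------------------------------------
# oracle detector

class OracleDetector:
    """Detector replaying the tight ground-truth boxes of a label volume.

    Mirrors the training-set construction, where the segmentation crops
    come from the boxes derived from the manual masks.
    """

    def __init__(self, label_volume):
        from ventriseg.image_io import boxes_from_mask
        self._by_z: dict[int, list[Detection]] = {}
        for det in boxes_from_mask(label_volume):
            self._by_z.setdefault(det.z_index, []).append(det)

    def predict_raw(self, slice_) -> list[Detection]:
        return list(self._by_z.get(slice_.z_index, []))


def oracle_detector(label_volume) -> OracleDetector:
    return OracleDetector(label_volume)


# ---------------------------------------------------------------------------
# minimal trainable detector

class ConvDetector:
    """Single-scale anchor-free convolutional detector.

    The input slice is pooled to 128x128 and augmented with two
    normalized coordinate channels (the subregion classes are defined by
    absolute position in the head, which translation-invariant
    convolutions cannot see on their own), passed through four 3x3 conv
    stages, and read out on a ``grid`` x ``grid`` cell map with, per
    class, an objectness logit and (dx, dy, log w, log h) box
    regressors relative to the cell.
    """

    def __init__(self, config: DetectorConfig, rng: np.random.Generator):
        g = config.grid
        if config.image_size % (g * 2) != 0:
            raise ValueError("image size must be a multiple of 2*grid")
        self.config = config
        self.grid = g
        self.head_ch = N_CLASSES * 5
        self.trunk = nn.Sequential(
            nn.Conv2d(3, 8, rng=rng), nn.ReLU(), nn.MaxPool2(),    # -> 64
            nn.Conv2d(8, 16, rng=rng), nn.ReLU(), nn.MaxPool2(),   # -> 32
            nn.Conv2d(16, 32, rng=rng), nn.ReLU(),
            nn.Conv2d(32, 64, rng=rng), nn.ReLU(),
        )
        # the head also sees the coordinate channels directly so absolute
        # position can gate each class's objectness
        self.head = nn.Conv2d(64 + 2, self.head_ch, k=1, rng=rng)
        self.trunk.layers[0].needs_dx = False
        # start the objectness near the background prior so early training
        # is not dominated by confident false positives
        self.head.b.value[:N_CLASSES] = -4.0
        # learnable per-class spatial prior added to the objectness logits:
        # the subregions live at fixed locations in the standardized frame,
        # and a direct per-cell bias learns that prior orders of magnitude
        # faster than squeezing it through shared convolution weights
        self.obj_bias = nn.Param(np.zeros((N_CLASSES, g, g)))
        self.train_loss: list[float] = []
        self._stem_pool = nn.MaxPool2()

    def params(self) -> list[nn.Param]:
        return self.trunk.params() + self.head.params() + [self.obj_bias]

    @staticmethod
    def _coord_maps(n: int, h: int, w: int) -> np.ndarray:
        ramp_y = np.linspace(0.0, 1.0, h, dtype=np.float32)
        ramp_x = np.linspace(0.0, 1.0, w, dtype=np.float32)
        maps = np.stack([np.broadcast_to(ramp_y[:, None], (h, w)),
                         np.broadcast_to(ramp_x[None, :], (h, w))])[None]
        return np.broadcast_to(maps, (n, 2, h, w))

    def forward(self, pixels: np.ndarray, train: bool) -> np.ndarray:
        x = np.ascontiguousarray(pixels[:, None], dtype=np.float32)
        x = self._stem_pool.forward(x, train)   # 256 -> 128, no grads needed
        n, _, h, w = x.shape
        x = np.ascontiguousarray(
            np.concatenate([x, self._coord_maps(n, h, w)], axis=1))
        f = self.trunk.forward(x, train)
        g = f.shape[2]
        f = np.ascontiguousarray(
            np.concatenate([f, self._coord_maps(n, g, g)], axis=1))
        out = self.head.forward(f, train)
        out[:, :N_CLASSES] += self.obj_bias.value[None]
        return out

    def backward(self, dy: np.ndarray) -> None:
        self.obj_bias.grad += dy[:, :N_CLASSES].sum(axis=0)
        df = self.head.backward(dy)
        self.trunk.backward(np.ascontiguousarray(df[:, :-2]))

    def predict_raw(self, slice_, top_k: int = 8) -> list[Detection]:
        out = self.forward(slice_.pixels[None], False)[0]
        g = self.grid
        obj = nn.sigmoid(out[:N_CLASSES])
        reg = out[N_CLASSES:].reshape(N_CLASSES, 4, g, g)
        dets = []
        for cid in range(N_CLASSES):
            flat = obj[cid].ravel()
            idx = np.argsort(flat)[::-1][:top_k]
            for cell in idx:
                gi, gj = divmod(int(cell), g)
                conf = float(flat[cell])
                if conf <= 0:
                    continue
                dx, dy, lw, lh = (float(v) for v in reg[cid, :, gi, gj])
                cx = (gj + 0.5 + np.clip(dx, -4.0, 4.0)) / g
                cy = (gi + 0.5 + np.clip(dy, -4.0, 4.0)) / g
                w = float(np.exp(np.clip(lw, -6, 3.5))) / g
                h = float(np.exp(np.clip(lh, -6, 3.5))) / g
                cx, cy = float(np.clip(cx, 0, 1)), float(np.clip(cy, 0, 1))
                if (cx + w / 2 <= 0 or cx - w / 2 >= 1
                        or cy + h / 2 <= 0 or cy - h / 2 >= 1):
                    continue
                dets.append(Detection(cid, slice_.z_index, cx, cy,
                                      min(w, 2.0), min(h, 2.0),
                                      min(1.0, max(0.0, conf))))
        return dets

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        values = [p.value.copy() for p in self.params()]
        np.savez(str(path), config=json.dumps(asdict(self.config)),
                 **{f"p{i}": v for i, v in enumerate(values)})

    @classmethod
    def load(cls, path) -> "ConvDetector":
        archive = np.load(str(path), allow_pickle=False)
        config = DetectorConfig(**json.loads(str(archive["config"])))
        model = cls(config, np.random.default_rng(config.seed))
        own = model.params()
        values = [archive[f"p{i}"] for i in range(len(archive.files) - 1)]
        if len(own) != len(values):
            raise ValueError("parameter count mismatch")
        for param, value in zip(own, values):
            param.value[...] = value
        return model


def _targets(boxes: list[Detection], grid: int):
    """Cell-map targets: every cell whose center falls in the central
    half of a box is a positive and regresses its own offset to the box
    center plus the log box size."""
    obj = np.zeros((N_CLASSES, grid, grid), dtype=np.float32)
    reg = np.zeros((N_CLASSES, 4, grid, grid), dtype=np.float32)
    mask = np.zeros((N_CLASSES, grid, grid), dtype=np.float32)
    for b in boxes:
        u, v = b.cx * grid, b.cy * grid
        cj = min(grid - 1, max(0, int(u)))
        ci = min(grid - 1, max(0, int(v)))
        j0 = min(cj, max(0, int(np.ceil(u - b.w * grid / 4 - 0.5))))
        j1 = max(cj, min(grid - 1, int(np.floor(u + b.w * grid / 4 - 0.5))))
        i0 = min(ci, max(0, int(np.ceil(v - b.h * grid / 4 - 0.5))))
        i1 = max(ci, min(grid - 1, int(np.floor(v + b.h * grid / 4 - 0.5))))
        lw = np.log(max(b.w, 1e-4) * grid)
        lh = np.log(max(b.h, 1e-4) * grid)
        for gi in range(i0, i1 + 1):
            for gj in range(j0, j1 + 1):
                obj[b.class_id, gi, gj] = 1.0
                mask[b.class_id, gi, gj] = 1.0
                reg[b.class_id, :, gi, gj] = (u - gj - 0.5, v - gi - 0.5,
                                              lw, lh)
    return obj, reg, mask


def _augment_sample(pixels: np.ndarray, boxes: list[Detection],
                    aug: dict, rng: np.random.Generator):
    """Jointly flip/scale/translate one slice and its boxes."""
    from skimage.transform import rescale

    px = pixels
    out = list(boxes)
    if aug.get("flip") and rng.random() < 0.5:
        # left/right mirror: rows are the lateral axis of the canonical plane
        px = px[::-1, :]
        out = [Detection(MIRROR_CLASS[b.class_id], b.z_index, b.cx,
                         1.0 - b.cy, b.w, b.h, b.confidence) for b in out]
    if aug.get("scale") and rng.random() < 0.5:
        s = float(rng.uniform(0.9, 1.1))
        size = px.shape[0]
        scaled = rescale(px, s, order=1, anti_aliasing=False, preserve_range=True)
        if s >= 1.0:
            o = (scaled.shape[0] - size) // 2
            px = scaled[o:o + size, o:o + size]
            shift = o / (size * s)
        else:
            pad = (size - scaled.shape[0]) // 2
            canvas = np.zeros_like(px)
            canvas[pad:pad + scaled.shape[0], pad:pad + scaled.shape[1]] = scaled
            px = canvas
            shift = -pad / size  # in output units, handled below
        new = []
        for b in out:
            if s >= 1.0:
                cx, cy = (b.cx - shift) * s, (b.cy - shift) * s
            else:
                cx, cy = b.cx * s + pad / size, b.cy * s + pad / size
            w, h = b.w * s, b.h * s
            if 0.0 < cx < 1.0 and 0.0 < cy < 1.0:
                new.append(Detection(b.class_id, b.z_index,
                                     float(np.clip(cx, 1e-4, 1 - 1e-4)),
                                     float(np.clip(cy, 1e-4, 1 - 1e-4)),
                                     w, h, b.confidence))
        out = new
    if aug.get("translate") and rng.random() < 0.5:
        size = px.shape[0]
        tx, ty = rng.integers(-16, 17, size=2)
        px = np.roll(np.roll(px, int(ty), axis=0), int(tx), axis=1)
        if ty >= 0:
            px[:ty] = 0
        else:
            px[ty:] = 0
        if tx >= 0:
            px[:, :tx] = 0
        else:
            px[:, tx:] = 0
        new = []
        for b in out:
            cx, cy = b.cx + tx / size, b.cy + ty / size
            if 0.0 < cx < 1.0 and 0.0 < cy < 1.0:
                new.append(Detection(b.class_id, b.z_index, cx, cy,
                                     b.w, b.h, b.confidence))
        out = new
    return np.ascontiguousarray(px, dtype=np.float32), out


def train_detector(slices, yolo_labels, config: DetectorConfig) -> ConvDetector:
    """Train the built-in detector on (slice, boxes) pairs.

    ``slices`` are axial slices in [0, 1]; ``yolo_labels`` is the
    aligned list of ground-truth Detection lists.  Deterministic under
    ``config.seed``; the per-epoch loss trace is stored on the model.
    """
    if len(slices) != len(yolo_labels):
        raise ValueError("slices and labels differ in length")
    present = {b.class_id for boxes in yolo_labels for b in boxes}
    for cid in range(N_CLASSES):
        if cid not in present:
            log.warning("class %d absent from training data; it will never "
                        "be predicted", cid)
    rng = np.random.default_rng(config.seed)
    model = ConvDetector(config, rng)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    g = config.grid
    n = len(slices)
    pos_weight = 5.0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pixels, objs, regs, masks = [], [], [], []
            for i in idx:
                px, boxes = _augment_sample(slices[i].pixels, yolo_labels[i],
                                            config.augmentation, rng)
                o, r, m = _targets(boxes, g)
                pixels.append(px)
                objs.append(o)
                regs.append(r)
                masks.append(m)
            batch = np.stack(pixels)
            obj_t = np.stack(objs)
            reg_t = np.stack(regs)
            mask = np.stack(masks)
            out = model.forward(batch, True)
            obj_logits = out[:, :N_CLASSES]
            reg_pred = out[:, N_CLASSES:].reshape(-1, N_CLASSES, 4, g, g)
            loss_obj, d_obj = nn.bce_with_logits(obj_logits, obj_t,
                                                 pos_weight=pos_weight)
            n_pos = max(1.0, float(mask.sum()))
            diff = (reg_pred - reg_t) * mask[:, :, None]
            loss_reg = float((diff ** 2).sum() / n_pos)
            d_reg = (2.0 * diff / n_pos).astype(np.float32)
            dy = np.concatenate(
                [d_obj, d_reg.reshape(-1, N_CLASSES * 4, g, g)], axis=1)
            opt.zero_grad()
            model.backward(np.ascontiguousarray(dy))
            opt.step()
            epoch_loss += loss_obj + loss_reg
            n_batches += 1
        model.train_loss.append(epoch_loss / max(1, n_batches))
        log.info("detector epoch %d/%d loss %.4f", epoch + 1, config.epochs,
                 model.train_loss[-1])
    return model


def lr_confusion_rate(gt_boxes, pred_boxes, iou_thresh: float = 0.5) -> float:
    """Fraction of predictions matching the mirror-image class's box.

    Diagnostic for flip-augmentation-induced left/right confusion; not a
    pass/fail quantity.
    """
    from ventriseg.evaluation import box_iou
    n_conf = 0
    preds = list(pred_boxes)
    if not preds:
        return 0.0
    gt_by_key = {}
    for b in gt_boxes:
        gt_by_key.setdefault((b.z_index, b.class_id), []).append(b)
    for p in preds:
        mirrored = gt_by_key.get((p.z_index, MIRROR_CLASS[p.class_id]), [])
        own = gt_by_key.get((p.z_index, p.class_id), [])
        hit_mirror = any(box_iou((p.cx, p.cy, p.w, p.h), (b.cx, b.cy, b.w, b.h))
                         >= iou_thresh for b in mirrored)
        hit_own = any(box_iou((p.cx, p.cy, p.w, p.h), (b.cx, b.cy, b.w, b.h))
                      >= iou_thresh for b in own)
        if hit_mirror and not hit_own:
            n_conf += 1
    return n_conf / len(preds)
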