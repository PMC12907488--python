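"""Per-subregion 2D U-Net segmentation.

One binary encoder--decoder model per subregion, with the left and
right posterior horns pooled into a single model (right-sided patches
are mirrored into left chirality for training and their predictions
mirrored back).  Training uses binary cross-entropy on logits, Adam,
optional flip/shift/rotate/brightness augmentation, subject-level
k-fold cross-validation, and early stopping on validation Dice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ventriseg import nn
from ventriseg.evaluation import dice
from ventriseg.subregions import SUBREGIONS, STRUCTURE, N_CLASSES

log = logging.getLogger(__name__)

#: hyperparameter ranges of the production search space
PRODUCTION_RANGES = {
    "start_filters": (32, 128),
    "depth": (3, 5),
    "blocks_per_level": (2, 5),
    "batch_size": (32, 64),
    "learning_rate": (1e-3, 1e-4),
}


@dataclass
class SegModelConfig:
    """U-Net hyperparameters.

    The activation (rectified linear) and loss (binary cross-entropy)
    are fixed.  ``desk=True`` marks a reduced test-scale configuration
    and disables the production range validation (e.g. start_filters
    below 32 or a single block per level).
    """

    start_filters: int = 32
    depth: int = 3
    blocks_per_level: int = 2
    dropout: bool = False
    dropout_rate: float = 0.25
    batch_norm: bool = False
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 50
    seed: int = 0
    threshold: float = 0.5
    patch_size: int = 256
    desk: bool = False
    early_stop_patience: int = 2
    early_stop_min_delta: float = 0.005
    augment: bool = True

    def __post_init__(self):
        if not self.desk:
            lo, hi = PRODUCTION_RANGES["start_filters"]
            if not lo <= self.start_filters <= hi:
                raise ValueError(f"start_filters outside {lo}..{hi}")
            if not 3 <= self.depth <= 5:
                raise ValueError("depth outside 3..5")
            if not 2 <= self.blocks_per_level <= 5:
                raise ValueError("blocks_per_level outside 2..5")
            if self.batch_size not in (32, 64):
                raise ValueError("batch_size must be 32 or 64")
            if self.learning_rate not in (1e-3, 1e-4):
                raise ValueError("learning_rate must be 0.001 or 0.0001")
        if self.patch_size % (2 ** self.depth) != 0:
            raise ValueError("patch size not divisible by 2^depth")


class UNet:
    """Binary 2D U-Net: ``depth`` encoder levels each halving resolution
    with filter count doubling from ``start_filters``, a bottleneck, and
    a symmetric decoder with skip connections; sigmoid output."""

    def __init__(self, config: SegModelConfig,
                 rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        f0, depth, blocks = config.start_filters, config.depth, config.blocks_per_level

        def block(c_in, c_out):
            layers = [nn.Conv2d(c_in, c_out, rng=rng)]
            if config.batch_norm:
                layers.append(nn.BatchNorm(c_out))
            layers.append(nn.ReLU())
            return layers

        self.encoder: list[nn.Sequential] = []
        c_in = 1
        for level in range(depth):
            f = f0 * 2 ** level
            layers = block(c_in, f)
            for _ in range(blocks - 1):
                layers += block(f, f)
            if config.dropout:
                layers.append(nn.Dropout(config.dropout_rate, rng))
            self.encoder.append(nn.Sequential(*layers))
            c_in = f
        self.encoder[0].layers[0].needs_dx = False
        self.pools = [nn.MaxPool2() for _ in range(depth)]

        f_b = f0 * 2 ** depth
        layers = block(c_in, f_b)
        for _ in range(blocks - 1):
            layers += block(f_b, f_b)
        if config.dropout:
            layers.append(nn.Dropout(config.dropout_rate, rng))
        self.bottleneck = nn.Sequential(*layers)

        # decoder runs at half the encoder width: enough capacity for a
        # single foreground structure while halving the dominant cost of
        # the full-resolution levels
        self.ups: list[nn.Upsample2] = []
        self.reducers: list[nn.Sequential] = []
        self.decoder: list[nn.Sequential] = []
        c_in = f_b
        for level in reversed(range(depth)):
            f = f0 * 2 ** level
            g = max(f // 2, 4)
            self.ups.append(nn.Upsample2())
            self.reducers.append(nn.Sequential(nn.Conv2d(c_in, g, k=1, rng=rng)))
            layers = block(f + g, g)
            for _ in range(blocks - 1):
                layers += block(g, g)
            self.decoder.append(nn.Sequential(*layers))
            c_in = g
        self.head = nn.Conv2d(c_in, 1, k=1, rng=rng)

    @property
    def bottleneck_filters(self) -> int:
        return self.config.start_filters * 2 ** self.config.depth

    def _modules(self):
        return (self.encoder + self.pools + [self.bottleneck] + self.ups
                + self.reducers + self.decoder + [self.head])

    def params(self) -> list[nn.Param]:
        return [p for m in self._modules() for p in m.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected (N, 1, H, W) input")
        if x.shape[2] % (2 ** self.config.depth) or x.shape[3] % (2 ** self.config.depth):
            raise ValueError("input size not divisible by 2^depth")
        skips = []
        for enc, pool in zip(self.encoder, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, red, dec, skip in zip(self.ups, self.reducers, self.decoder,
                                      reversed(skips)):
            x = red.forward(up.forward(x, train), train)
            self._skip_channels.append(x.shape[1])
            x = dec.forward(np.concatenate([skip, x], axis=1), train)
        return self.head.forward(x, train)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(dy)
        d_skips = []
        for up, red, dec, f in zip(reversed(self.ups), reversed(self.reducers),
                                   reversed(self.decoder),
                                   reversed(self._skip_channels)):
            d = dec.backward(dy)
            d_skip, d_up = d[:, :-f], d[:, -f:]
            d_skips.append(d_skip)
            dy = up.backward(red.backward(np.ascontiguousarray(d_up)))
        dy = self.bottleneck.backward(dy)
        for enc, pool, d_skip in zip(reversed(self.encoder), reversed(self.pools),
                                     reversed(d_skips)):
            dy = pool.backward(dy)
            dy = enc.backward(np.ascontiguousarray(dy + d_skip))

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Sigmoid probability maps for a (N, H, W) stack of patches."""
        x = np.ascontiguousarray(patches[:, None], dtype=np.float32)
        logits = self.forward(x, train=False)
        return nn.sigmoid(logits[:, 0])

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        values = nn.save_params(self)
        np.savez(str(path), config=json.dumps(asdict(self.config)),
                 **{f"p{i}": v for i, v in enumerate(values)})

    @classmethod
    def load(cls, path) -> "UNet":
        archive = np.load(str(path), allow_pickle=False)
        config = SegModelConfig(**json.loads(str(archive["config"])))
        model = cls(config, np.random.default_rng(config.seed))
        nn.load_params(model, [archive[f"p{i}"]
                               for i in range(len(archive.files) - 1)])
        return model


def build_unet(config: SegModelConfig) -> UNet:
    """Construct a seeded, untrained U-Net from a configuration."""
    return UNet(config, np.random.default_rng(config.seed))


# ---------------------------------------------------------------------------
# cross-validation folds

def fold_split(subject_ids, k: int = 5, seed: int = 0) -> list[list]:
    """Subject-level split into k disjoint folds of near-equal size."""
    unique = sorted(set(subject_ids))
    if len(unique) < k:
        raise ValueError(f"need at least {k} subjects, got {len(unique)}")
    order = np.random.default_rng(seed).permutation(len(unique))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(unique[idx])
    return folds


# ---------------------------------------------------------------------------
# augmentation

def augment(patch: np.ndarray, mask: np.ndarray,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random flip / integer shift / small rotation / brightness change.

    Geometric transforms are applied identically to patch and mask;
    the multiplicative brightness change touches only the patch.
    """
    from skimage.transform import rotate as _sk_rotate

    if patch.shape != mask.shape:
        raise ValueError("patch and mask must share a shape")
    p, m = patch, mask
    if rng.random() < 0.5:
        # mirror across the sagittal plane (rows = lateral axis)
        p, m = p[::-1, :], m[::-1, :]
    dy, dx = (int(v) for v in rng.integers(-16, 17, size=2))
    if dy or dx:
        p = np.roll(np.roll(p, dy, axis=0), dx, axis=1)
        m = np.roll(np.roll(m, dy, axis=0), dx, axis=1)
        for arr in (p, m):
            if dy > 0:
                arr[:dy] = 0
            elif dy < 0:
                arr[dy:] = 0
            if dx > 0:
                arr[:, :dx] = 0
            elif dx < 0:
                arr[:, dx:] = 0
    angle = float(rng.uniform(-10.0, 10.0))
    if abs(angle) > 0.5:
        p = _sk_rotate(p.astype(np.float32), angle, order=1, preserve_range=True)
        m = (_sk_rotate(m.astype(np.float32), angle, order=0,
                        preserve_range=True) >= 0.5).astype(mask.dtype)
    bright = float(rng.uniform(0.8, 1.2))
    p = np.clip(p * bright, 0.0, 1.0)
    return np.ascontiguousarray(p, dtype=np.float32), np.ascontiguousarray(m)


# ---------------------------------------------------------------------------
# training

def _mean_dice(model: UNet, patches: np.ndarray, masks: np.ndarray,
               threshold: float, batch: int = 8) -> float:
    scores = []
    for start in range(0, len(patches), batch):
        prob = model.predict_proba(patches[start:start + batch])
        pred = prob >= threshold
        for p, m in zip(pred, masks[start:start + batch]):
            scores.append(dice(p, m))
    return float(np.mean(scores))


def _train_one(patches, masks, config: SegModelConfig, val_idx, train_idx,
               rng: np.random.Generator) -> tuple[UNet, float]:
    model = UNet(config, np.random.default_rng(config.seed))
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    # balance the foreground against the ~95% background pixels
    pos_frac = float(np.mean([masks[i].mean() for i in train_idx]))
    pos_weight = float(np.clip((1 - pos_frac) / max(pos_frac, 1e-4), 1.0, 20.0))
    best_dice, best_params, patience = -1.0, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = [train_idx[i] for i in order[start:start + config.batch_size]]
            xs, ys = [], []
            for i in sel:
                if config.augment:
                    p, m = augment(patches[i], masks[i], rng)
                else:
                    p, m = patches[i], masks[i]
                xs.append(p)
                ys.append(m)
            x = np.ascontiguousarray(np.stack(xs)[:, None], dtype=np.float32)
            t = np.stack(ys)[:, None].astype(np.float32)
            logits = model.forward(x, train=True)
            loss, grad = nn.bce_with_logits(logits, t, pos_weight=pos_weight)
            opt.zero_grad()
            model.backward(np.ascontiguousarray(grad))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_dice = _mean_dice(model, patches[val_idx], masks[val_idx],
                              config.threshold)
        log.info("epoch %d/%d loss %.4f val dice %.4f", epoch + 1,
                 config.epochs, epoch_loss / max(1, n_batches), val_dice)
        if val_dice > best_dice + config.early_stop_min_delta:
            best_dice, patience = val_dice, 0
            best_params = nn.save_params(model)
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                log.info("early stop at epoch %d (best val dice %.4f)",
                         epoch + 1, best_dice)
                break
    if best_params is not None:
        nn.load_params(model, best_params)
    return model, best_dice


def train_subregion_model(patches, masks, config: SegModelConfig,
                          subject_ids=None, n_folds: int = 1,
                          val_fraction: float = 0.25
                          ) -> tuple[UNet, list[float]]:
    """Train one binary subregion model; returns (model, per-fold val Dice).

    With ``n_folds`` > 1 the split is subject-level k-fold
    cross-validation (one model per fold; the first fold's model is
    returned).  With ``n_folds`` = 1 a single held-out validation split
    of ``val_fraction`` is used.
    """
    patches = np.asarray(patches, dtype=np.float32)
    masks = np.asarray(masks)
    if len(patches) < 10:
        raise ValueError("need at least 10 patches")
    if masks.sum() == 0:
        raise ValueError("no positive pixels in training masks")
    if subject_ids is None:
        subject_ids = list(range(len(patches)))
    subject_ids = list(subject_ids)
    rng = np.random.default_rng(config.seed + 1)

    if n_folds > 1:
        folds = fold_split(subject_ids, k=n_folds, seed=config.seed)
        fold_dice, first_model = [], None
        for f, fold in enumerate(folds):
            fold_set = set(fold)
            val_idx = [i for i, s in enumerate(subject_ids) if s in fold_set]
            train_idx = [i for i, s in enumerate(subject_ids) if s not in fold_set]
            model, vd = _train_one(patches, masks, config, val_idx, train_idx,
                                   np.random.default_rng(config.seed + 100 + f))
            fold_dice.append(vd)
            if first_model is None:
                first_model = model
        return first_model, fold_dice

    unique = sorted(set(subject_ids))
    shuffled = [unique[i] for i in rng.permutation(len(unique))]
    n_val = max(1, int(round(val_fraction * len(unique))))
    val_set = set(shuffled[:n_val])
    val_idx = [i for i, s in enumerate(subject_ids) if s in val_set]
    train_idx = [i for i, s in enumerate(subject_ids) if s not in val_set]
    model, vd = _train_one(patches, masks, config, val_idx, train_idx, rng)
    return model, [vd]


def predict_mask(model: UNet, patch: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binary mask from one [0, 1] patch (sigmoid output thresholded)."""
    if patch.ndim != 2:
        raise ValueError("expected a single 2D patch")
    prob = model.predict_proba(patch[None])[0]
    return prob >= threshold


# ---------------------------------------------------------------------------
# model registry

POSTERIOR_KEY = "posterior_horn"


def registry_key(class_id: int) -> str:
    """Model key for a class: its name, except the pooled posterior horns."""
    if STRUCTURE[class_id] == "posterior_horn":
        return POSTERIOR_KEY
    return SUBREGIONS[class_id].name


@dataclass
class ModelRegistry:
    """The eleven trained models covering the twelve classes."""

    models: dict = field(default_factory=dict)

    EXPECTED_KEYS = tuple(sorted({registry_key(c) for c in range(N_CLASSES)}))

    def validate(self) -> None:
        missing = set(self.EXPECTED_KEYS) - set(self.models)
        if missing:
            raise ValueError(f"missing models: {sorted(missing)}")
        if len(self.models) != 11:
            raise ValueError(f"expected 11 models, found {len(self.models)}")

    def resolve(self, class_id: int) -> tuple[object, bool]:
        """(model, mirror) for a class.  ``mirror`` is True for the right
        posterior horn, whose patches are flipped into the pooled
        model's left chirality and whose predictions are flipped back."""
        key = registry_key(class_id)
        mirror = (key == POSTERIOR_KEY
                  and SUBREGIONS[class_id].laterality == "right")
        return self.models[key], mirror

    def predict(self, class_id: int, patch: np.ndarray,
                threshold: float = 0.5) -> np.ndarray:
        model, mirror = self.resolve(class_id)
        p = patch[::-1, :] if mirror else patch
        mask = predict_mask(model, np.ascontiguousarray(p), threshold)
        return mask[::-1, :] if mirror else mask

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for key, model in self.models.items():
            model.save(directory / f"{key}.npz")
        (directory / "registry.json").write_text(
            json.dumps({"keys": sorted(self.models)}, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelRegistry":
        directory = Path(directory)
        meta = json.loads((directory / "registry.json").read_text())
        reg = cls(models={key: UNet.load(directory / f"{key}.npz")
                          for key in meta["keys"]})
        reg.validate()
        return reg
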