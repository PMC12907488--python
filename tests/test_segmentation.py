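"""U-Net construction, folds, augmentation, registry semantics.

Training quality itself is exercised by the acceptance suite; here the
structural and deterministic properties are checked with tiny patches.
"""

import numpy as np
import pytest

from ventriseg import nn
from ventriseg.segmentation import (ModelRegistry, SegModelConfig, UNet,
                                    augment, build_unet, fold_split,
                                    predict_mask, registry_key,
                                    train_subregion_model, POSTERIOR_KEY)
from ventriseg.subregions import SUBREGIONS


def tiny_config(**kw):
    base = dict(desk=True, start_filters=4, depth=3, blocks_per_level=1,
                patch_size=32, epochs=2, batch_size=8, augment=False, seed=0)
    base.update(kw)
    return SegModelConfig(**base)


class TestConfig:
    def test_production_ranges_enforced(self):
        SegModelConfig(start_filters=32, depth=3, blocks_per_level=2)
        with pytest.raises(ValueError):
            SegModelConfig(start_filters=16)
        with pytest.raises(ValueError):
            SegModelConfig(depth=6)
        with pytest.raises(ValueError):
            SegModelConfig(blocks_per_level=1)
        with pytest.raises(ValueError):
            SegModelConfig(batch_size=16)
        with pytest.raises(ValueError):
            SegModelConfig(learning_rate=0.01)

    def test_desk_configs_may_go_below_range(self):
        cfg = SegModelConfig(desk=True, start_filters=16, blocks_per_level=1)
        assert cfg.start_filters == 16

    def test_patch_size_divisibility(self):
        with pytest.raises(ValueError):
            SegModelConfig(desk=True, depth=5, patch_size=100)


class TestUNet:
    def test_bottleneck_filter_doubling_rule(self):
        model = build_unet(SegModelConfig(start_filters=32, depth=3))
        assert model.bottleneck_filters == 32 * 2 ** 3 == 256

    def test_output_shape_equals_input_shape(self):
        model = build_unet(tiny_config())
        x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
        assert model.forward(x, train=False).shape == (2, 1, 32, 32)

    def test_indivisible_input_rejected(self):
        model = build_unet(tiny_config())
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 30, 30), np.float32), False)

    def test_same_seed_identical_initial_predictions(self):
        x = np.random.default_rng(1).random((1, 1, 32, 32)).astype(np.float32)
        p1 = build_unet(tiny_config(seed=9)).predict_proba(x[:, 0])
        p2 = build_unet(tiny_config(seed=9)).predict_proba(x[:, 0])
        assert np.array_equal(p1, p2)

    def test_save_load_round_trip(self, tmp_path):
        model = build_unet(tiny_config(seed=4))
        path = tmp_path / "m.npz"
        model.save(path)
        back = UNet.load(path)
        x = np.random.default_rng(2).random((32, 32)).astype(np.float32)
        assert np.array_equal(model.predict_proba(x[None]),
                              back.predict_proba(x[None]))

    def test_batchnorm_and_dropout_variants_run(self):
        cfg = tiny_config(batch_norm=True, dropout=True, dropout_rate=0.3)
        model = build_unet(cfg)
        x = np.random.default_rng(3).random((2, 1, 32, 32)).astype(np.float32)
        assert np.all(np.isfinite(model.forward(x, train=True)))
        # eval mode is deterministic despite dropout
        a = model.forward(x, train=False)
        b = model.forward(x, train=False)
        assert np.array_equal(a, b)


class TestFoldSplit:
    def test_80_subjects_give_five_folds_of_16(self):
        folds = fold_split(range(80), k=5, seed=0)
        assert [len(f) for f in folds] == [16] * 5

    def test_folds_disjoint_exhaustive_and_reproducible(self):
        ids = [f"subj{i}" for i in range(23)]
        folds = fold_split(ids, k=5, seed=3)
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(flat)
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1
        assert fold_split(ids, k=5, seed=3) == folds
        assert fold_split(ids, k=5, seed=4) != folds

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            fold_split([1, 2, 3], k=5, seed=0)


class TestAugment:
    def test_geometry_applied_jointly_and_mask_stays_binary(self, rng):
        patch = rng.random((64, 64)).astype(np.float32)
        mask = np.zeros((64, 64), np.uint8)
        mask[20:40, 25:45] = 1
        for seed in range(10):
            p, m = augment(patch, mask, np.random.default_rng(seed))
            assert p.shape == (64, 64) and m.shape == (64, 64)
            assert set(np.unique(m)) <= {0, 1}
            assert 0.0 <= p.min() and p.max() <= 1.0
            # area approximately preserved (border loss, rotation resampling)
            assert 0.5 * mask.sum() <= m.sum() <= 1.05 * mask.sum()

    def test_brightness_never_touches_mask(self):
        patch = np.full((32, 32), 0.5, np.float32)
        mask = np.zeros((32, 32), np.uint8)
        mask[10:20, 10:20] = 1
        # seed chosen arbitrarily; mask values must stay in {0, 1} and the
        # patch must stay within the unit interval whatever was composed
        for seed in range(20):
            p, m = augment(patch, mask, np.random.default_rng(seed))
            assert set(np.unique(m)) <= {0, 1}
            assert p.max() <= 1.0


class TestTraining:
    def _toy_data(self, n=16):
        rng = np.random.default_rng(0)
        patches, masks = [], []
        for i in range(n):
            m = np.zeros((32, 32), np.uint8)
            c = rng.integers(10, 22, 2)
            m[c[0] - 6:c[0] + 6, c[1] - 6:c[1] + 6] = 1
            p = 0.1 + 0.4 * m + rng.normal(0, 0.03, (32, 32))
            patches.append(np.clip(p, 0, 1).astype(np.float32))
            masks.append(m)
        return patches, masks

    def test_requires_positive_pixels(self):
        patches, _ = self._toy_data()
        zeros = [np.zeros((32, 32), np.uint8) for _ in patches]
        with pytest.raises(ValueError, match="positive"):
            train_subregion_model(patches, zeros, tiny_config())

    def test_validation_subjects_never_in_training(self):
        """Audit via fold_split on the k-fold path."""
        patches, masks = self._toy_data(20)
        ids = [i // 2 for i in range(20)]  # 10 subjects, 2 patches each
        folds = fold_split(sorted(set(ids)), k=5, seed=tiny_config().seed)
        for fold in folds:
            assert not set(fold) & {s for f in folds if f is not fold for s in f}

    def test_seeded_training_reproducible(self):
        patches, masks = self._toy_data(12)
        cfg = tiny_config(epochs=1)
        m1, d1 = train_subregion_model(patches, masks, cfg)
        m2, d2 = train_subregion_model(patches, masks, cfg)
        assert d1 == d2
        x = patches[0]
        assert np.array_equal(m1.predict_proba(x[None]), m2.predict_proba(x[None]))

    def test_predict_mask_thresholding(self):
        model = build_unet(tiny_config())
        patch = np.random.default_rng(5).random((32, 32)).astype(np.float32)
        out = predict_mask(model, patch, threshold=0.5)
        assert out.dtype == bool and out.shape == (32, 32)
        prob = model.predict_proba(patch[None])[0]
        assert np.array_equal(out, prob >= 0.5)


class TestRegistry:
    def test_eleven_keys_cover_twelve_classes(self):
        keys = {registry_key(c.id) for c in SUBREGIONS}
        assert len(keys) == 11
        assert registry_key(6) == registry_key(10) == POSTERIOR_KEY

    def test_resolution_and_posterior_mirroring(self):
        reg = ModelRegistry(models={k: object() for k in ModelRegistry.EXPECTED_KEYS})
        reg.validate()
        model_r, mirror_r = reg.resolve(6)   # right posterior horn
        model_l, mirror_l = reg.resolve(10)  # left posterior horn
        assert model_r is model_l
        assert mirror_r is True and mirror_l is False
        for cid in (0, 1, 2, 3, 4, 5, 7, 8, 9, 11):
            _, mirror = reg.resolve(cid)
            assert mirror is False

    def test_incomplete_registry_rejected(self):
        reg = ModelRegistry(models={"third_ventricle": object()})
        with pytest.raises(ValueError, match="missing models"):
            reg.validate()
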