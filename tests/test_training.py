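import dataclasses

import numpy as np
import pytest

from coloseg.losses import LossConfig
from coloseg.model import ModelSpec, build_model
from coloseg.training import (EpochRecord, PatchSampler, TrainConfig,
                              TrainHistory, augment, schedule_lr, should_stop,
                              train)


def history_from_losses(losses, lr=1e-4):
    h = TrainHistory()
    for i, v in enumerate(losses):
        h.records.append(EpochRecord(epoch=i, train_loss=v, val_loss=v,
                                     val_dice=0.5, lr=lr))
    return h


class TestTrainConfig:
    def test_paper_protocol_defaults(self):
        cfg = TrainConfig()
        assert (cfg.patch_px, cfg.batch_size) == (512, 5)
        assert (cfg.max_epochs, cfg.iters_per_epoch) == (500, 300)
        assert cfg.lr_init == 1e-4 and cfg.lr_factor == 0.5
        assert (cfg.lr_patience_epochs, cfg.stop_patience_epochs) == (20, 50)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(lr_patience_epochs=30, stop_patience_epochs=20)

    def test_round_trip(self):
        cfg = TrainConfig(seed=9, loss=LossConfig(kind="focal"))
        assert TrainConfig.from_dict(cfg.to_dict()) == cfg


class TestPatchSampler:
    def test_balanced_anchor_frequencies(self, tiny_tiles):
        # restrict to two classes: anchors should split ~50/50
        two = [t for t in tiny_tiles[:4]]
        for t in two:
            t.mask[~np.isin(t.mask, (0, 5))] = 0
        sampler = PatchSampler(two, patch_px=32, seed=0)
        anchors = [sampler.sample_one()[1] for _ in range(1000)]
        freq = np.mean(np.asarray(anchors) == 0)
        assert abs(freq - 0.5) < 0.05

    def test_batch_shapes(self, tiny_tiles):
        sampler = PatchSampler(tiny_tiles, patch_px=32, seed=1)
        batch = sampler.sample_batch(5)
        assert len(batch) == 5
        assert all(t.image.shape == (32, 32, 3) for t in batch)
        assert all((t.mask != 255).any() for t in batch)

    def test_seeded_determinism(self, tiny_tiles):
        a = PatchSampler(tiny_tiles, patch_px=32, seed=3).sample_batch(8)
        b = PatchSampler(tiny_tiles, patch_px=32, seed=3).sample_batch(8)
        assert all(np.array_equal(x.image, y.image) and
                   np.array_equal(x.mask, y.mask) for x, y in zip(a, b))

    def test_empty_source_rejected(self):
        with pytest.raises(ValueError):
            PatchSampler([], patch_px=32)


class TestAugment:
    def test_flip_is_involution(self, checker_tile):
        once = augment(checker_tile, ("flip_h",))
        twice = augment(once, ("flip_h",))
        assert np.array_equal(twice.image, checker_tile.image)
        assert np.array_equal(twice.mask, checker_tile.mask)

    def test_photometric_preserves_mask(self, checker_tile):
        rng = np.random.default_rng(0)
        out = augment(checker_tile, ("blur", "gamma", "stain", "color",
                                     "contrast"), rng, p_apply=1.0)
        assert np.array_equal(out.mask, checker_tile.mask)
        assert not np.array_equal(out.image, checker_tile.image)

    def test_zero_magnitude_elastic_is_identity(self, checker_tile):
        rng = np.random.default_rng(0)
        out = augment(checker_tile, ("elastic",), rng, elastic_alpha=0.0)
        assert np.array_equal(out.image, checker_tile.image)
        assert np.array_equal(out.mask, checker_tile.mask)

    def test_geometric_moves_image_and_mask_together(self, checker_tile):
        rng = np.random.default_rng(2)
        out = augment(checker_tile, ("flip", "rotate", "elastic"), rng,
                      p_apply=1.0)
        # class-5 pixels keep their bright pink color wherever they moved
        sel = out.mask == 5
        assert sel.any()
        assert np.abs(out.image[sel].mean(axis=0)
                      - (250, 160, 185)).max() < 10


class TestSchedule:
    def test_twenty_flat_epochs_halve_lr(self):
        cfg = TrainConfig()
        h = history_from_losses([1.0] + [1.0] * 20)
        assert schedule_lr(h, cfg) == pytest.approx(5e-5)

    def test_improvement_resets_patience(self):
        cfg = TrainConfig()
        losses = [1.0] * 19 + [0.5] + [0.5]
        assert schedule_lr(history_from_losses(losses), cfg) == \
            pytest.approx(1e-4)

    def test_forty_flat_epochs_quarter_lr(self):
        cfg = TrainConfig()
        h = history_from_losses([1.0] + [1.0] * 40)
        assert schedule_lr(h, cfg) == pytest.approx(2.5e-5)

    def test_lr_is_always_init_times_factor_power(self):
        cfg = TrainConfig()
        r = np.random.default_rng(0)
        h = history_from_losses(list(r.random(120)))
        lr = schedule_lr(h, cfg)
        k = np.log(lr / cfg.lr_init) / np.log(cfg.lr_factor)
        assert abs(k - round(k)) < 1e-9 and round(k) >= 0

    def test_stop_after_fifty_non_improving(self):
        cfg = TrainConfig()
        assert not should_stop(history_from_losses([1.0] + [1.0] * 49), cfg)
        assert should_stop(history_from_losses([1.0] + [1.0] * 50), cfg)

    def test_no_stop_while_improving(self):
        cfg = TrainConfig()
        h = history_from_losses(list(np.linspace(1.0, 0.1, 120)))
        assert not should_stop(h, cfg)


@pytest.fixture(scope="module")
def tiny_task():
    from coloseg.synthetic import make_texture_task

    tr, va, k = make_texture_task(n_train=12, n_val=3, tile_px=64, seed=2)
    return tr, va, k


class TestTrainLoop:
    def _cfg(self, **kw):
        base = dict(patch_px=32, batch_size=3, max_epochs=2, iters_per_epoch=6,
                    lr_init=1e-3, seed=0, augmentations=("flip",))
        base.update(kw)
        return TrainConfig(**base)

    @pytest.mark.parametrize("kind", ["cross_entropy", "focal", "bi_tempered",
                                      "lovasz_softmax"])
    def test_validation_loss_improves(self, tiny_task, kind):
        tr, va, k = tiny_task
        cfg = self._cfg(loss=LossConfig(kind=kind))
        model = build_model(ModelSpec(n_classes=k, base_filters=4, depth=2),
                            seed=1)
        _, hist = train(model, tr, va, cfg)
        assert hist.records[-1].val_loss < hist.records[0].train_loss

    def test_seeded_runs_are_identical(self, tiny_task):
        tr, va, k = tiny_task
        spec = ModelSpec(n_classes=k, base_filters=4, depth=2)
        hists = []
        for _ in range(2):
            cfg = self._cfg(loss=LossConfig(kind="cross_entropy"))
            _, h = train(build_model(spec, seed=1), tr, va, cfg)
            hists.append([dataclasses.astuple(r) for r in h.records])
        assert hists[0] == hists[1]

    def test_empty_sets_rejected(self, tiny_task):
        tr, va, k = tiny_task
        model = build_model(ModelSpec(n_classes=k, base_filters=4, depth=2),
                            seed=0)
        with pytest.raises(ValueError):
            train(model, [], va, self._cfg())
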