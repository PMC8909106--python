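from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import lbcscreen.model as model_mod
from lbcscreen import nn
from lbcscreen.errors import ConfigError
from lbcscreen.model import (
    AugmentRanges,
    ModelConfig,
    TrainConfig,
    augment_tile,
    build_model,
    load_checkpoint,
    pooled_grid,
    save_checkpoint,
    train_model,
    trainable_parameters,
)
from lbcscreen.pipeline import (
    build_sampler,
    load_cohort,
    run_training,
    validation_tiles,
)

RNG = np.random.default_rng(7)


class TestGeometry:
    def test_reference_geometry_sequence_length_36(self):
        # production geometry: input 1024, grid 32 -> pooled 6x6 -> 36
        for backbone in ("cnn32", "efficientnet-b0"):
            cfg = ModelConfig(backbone=backbone, input_size=1024)
            assert cfg.feature_grid == 32
            assert cfg.pooled_grid == 6
            assert cfg.sequence_length == 36

    def test_tiny_geometry_sequence_length_4(self):
        cfg = ModelConfig(backbone="tiny-cnn", input_size=128)
        assert cfg.feature_grid == 16
        assert cfg.sequence_length == 4

    @pytest.mark.parametrize("g,expect", [(16, 2), (32, 6), (7, 1), (12, 2)])
    def test_pooled_grid_formula(self, g, expect):
        assert pooled_grid(g, 7, 5) == expect
        assert pooled_grid(g, 7, 5) == (g - 7) // 5 + 1

    def test_grid_smaller_than_kernel_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(backbone="tiny-cnn", input_size=48)  # grid 6 < 7
        with pytest.raises(ConfigError):
            pooled_grid(5, 7, 5)

    def test_reference_backbone_not_buildable(self):
        with pytest.raises(ConfigError):
            build_model(ModelConfig(backbone="efficientnet-b0",
                                    input_size=1024))


class TestForward:
    def test_output_is_probability(self):
        m = build_model(ModelConfig(input_size=128), seed=0)
        x = RNG.integers(0, 256, (2, 128, 128, 3), dtype=np.uint8)
        p = m.predict_proba(x)
        assert p.shape == (2,)
        assert ((p > 0) & (p < 1)).all()

    def test_pooled_sequence_shape_seen_by_gru(self):
        m = build_model(ModelConfig(input_size=128), seed=0)
        x = RNG.integers(0, 256, (1, 128, 128, 3), dtype=np.uint8)
        m.forward_logits(x)
        n, c, gp = m._pool_shape
        assert (n, c, gp) == (1, 32, 2)  # sequence length 4


class TestPartialFinetune:
    def test_parameter_partition(self):
        m = build_model(ModelConfig(input_size=128), seed=0)
        subset = trainable_parameters(m, partial_finetune=True)
        norm = [p for p in subset if p.tag == "norm_affine"]
        # tiny-cnn has 3 BN layers -> 3 scale + 3 shift tensors
        assert len(norm) == 6
        assert not any(p.tag == "conv" for p in subset)
        # GRU (9 tensors) + head (2) always train
        assert sum(p.tag == "rnn" for p in subset) == 9
        assert sum(p.tag == "head" for p in subset) == 2
        assert len(trainable_parameters(m, False)) == len(m.parameters())

    def test_frozen_kernels_unchanged_after_step(self):
        m = build_model(ModelConfig(input_size=128), seed=0)
        before = {p.name: p.value.copy() for p in m.parameters()
                  if p.tag == "conv"}
        opt = nn.Adam(trainable_parameters(m, True), lr=0.01)
        x = RNG.integers(0, 256, (4, 128, 128, 3), dtype=np.uint8)
        y = np.array([1, 0, 1, 0], dtype=np.float32)
        logits = m.forward_logits(x, train=True)
        _, d = nn.bce_with_logits(logits, y)
        opt.zero_grad()
        m.backward(d)
        opt.step()
        for p in m.parameters():
            if p.tag == "conv":
                assert (p.value == before[p.name]).all()


class TestAugmentation:
    class _StubRng:
        """Returns the upper end of every uniform draw."""

        def uniform(self, lo, hi):
            return hi

    def test_identity_when_ranges_collapse(self):
        img = RNG.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        out = augment_tile(img, RNG, AugmentRanges(0.0, (1, 1), (1, 1)))
        assert (out == img).all()

    def test_full_brightness_shift_on_mid_grey(self):
        img = np.full((16, 16, 3), 128, np.uint8)
        out = augment_tile(img, self._StubRng(),
                           AugmentRanges(0.2, (1, 1), (1, 1)))
        assert abs(int(out.mean()) - (128 + 51)) <= 1

    def test_outputs_valid_and_mean_shift_bounded(self):
        img = RNG.integers(30, 220, (32, 32, 3), dtype=np.uint8)
        shifts = []
        for _ in range(100):
            out = augment_tile(img, RNG)
            assert out.dtype == np.uint8
            shifts.append(out.astype(float).mean() - img.mean())
        # brightness bounded by ±0.2*255, contrast/saturation move the mean
        # little on this image
        assert max(np.abs(shifts)) < 0.25 * 255


class TestTrainLoop:
    def test_lr_schedule_decays_every_two_epochs(self):
        tc = TrainConfig()
        assert tc.lr_at_epoch(0) == tc.lr_at_epoch(1) == 0.001
        assert np.isclose(tc.lr_at_epoch(2), 0.00095)
        assert np.isclose(tc.lr_at_epoch(3), 0.00095)
        assert np.isclose(tc.lr_at_epoch(4), 0.0009025)
        assert np.isclose(tc.lr_at_epoch(5), 0.0009025)

    def test_early_stopping_returns_best_epoch_weights(
            self, tiny_cohorts, monkeypatch):
        # scripted validation losses: improvement only at epoch 1
        losses = iter([0.7] + [0.6] * 30)
        monkeypatch.setattr(model_mod, "_validation_loss",
                            lambda *a, **k: next(losses))
        tr = load_cohort(tiny_cohorts / "train")
        va = load_cohort(tiny_cohorts / "val")
        state = build_sampler(tr, 128, 64, mask_downsample=8)
        val = validation_tiles(va, 128, 64, n_per_class=2, mask_downsample=8)
        m = build_model(ModelConfig(input_size=128), seed=0)
        slides = dict(tr.slides)
        slides.update(va.slides)
        tc = TrainConfig(max_epochs=40, steps_per_epoch=1, batch_size=2,
                         patience=10, hard_mining=False, augment=False)
        res = train_model(m, state, slides, val, tc)
        assert res.best_epoch == 1
        assert len(res.history) == 12  # epochs 0..11 then stop

    def test_fixed_seed_reproducible_histories(self, tiny_cohorts):
        tr = load_cohort(tiny_cohorts / "train")
        va = load_cohort(tiny_cohorts / "val")
        mc = ModelConfig(input_size=128)
        tc = TrainConfig(seed=5, max_epochs=2, steps_per_epoch=4,
                         batch_size=4, augment=False, hard_mining=False,
                         mask_downsample=8)
        h1 = run_training(tr, va, mc, tc, 128, 64).history
        h2 = run_training(tr, va, mc, tc, 128, 64).history
        for a, b in zip(h1, h2):
            assert abs(a["train_loss"] - b["train_loss"]) < 1e-6
            assert abs(a["val_loss"] - b["val_loss"]) < 1e-6

    def test_training_reduces_validation_loss(self, tiny_cohorts):
        tr = load_cohort(tiny_cohorts / "train")
        va = load_cohort(tiny_cohorts / "val")
        mc = ModelConfig(input_size=128)
        tc = TrainConfig(seed=7, max_epochs=5, steps_per_epoch=16,
                         batch_size=8, augment=False, hard_mining=False,
                         partial_finetune=False, mask_downsample=8)
        res = run_training(tr, va, mc, tc, 128, 64)
        assert res.best_val_loss < res.history[0]["val_loss"]


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        m = build_model(ModelConfig(input_size=128), seed=3)
        x = RNG.integers(0, 256, (2, 128, 128, 3), dtype=np.uint8)
        save_checkpoint(m, tmp_path / "ckpt", history=[{"epoch": 0}])
        m2, hist = load_checkpoint(tmp_path / "ckpt")
        assert hist == [{"epoch": 0}]
        assert np.allclose(m.predict_proba(x), m2.predict_proba(x))

    def test_yaml_config_round_trip(self, tmp_path):
        from lbcscreen.model import load_train_config

        (tmp_path / "cfg.yaml").write_text(
            "model:\n  backbone: tiny-cnn\n  input_size: 128\n"
            "train:\n  max_epochs: 3\n  augment: false\n"
            "  augment_ranges: {brightness: 0.1, saturation: [0.9, 1.1],"
            " contrast: [1.0, 1.0]}\n")
        mc, tc = load_train_config(tmp_path / "cfg.yaml")
        assert mc.input_size == 128
        assert tc.max_epochs == 3
        assert tc.augment_ranges.brightness == 0.1
        assert tc.augment_ranges.saturation == (0.9, 1.1)
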