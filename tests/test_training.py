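"""Training protocol: LR plateau schedule, augmentation, freezing, head
transplant, determinism, and desk-scale convergence on a separable toy."""

import numpy as np
import pytest

import her2light as hl
from her2light.training import _replay_lr


def _history(val_accs, lr0=6e-3):
    h = hl.TrainingHistory()
    h.val_accuracy = list(val_accs)
    h.learning_rate = [lr0] * len(val_accs)
    return h


def _cfg(**kw):
    base = dict(initial_lr=6e-3, plateau_patience=5, early_stop_patience=10,
                max_epochs=80, batch_size=24, seed=0)
    base.update(kw)
    return hl.TrainConfig(**base)


class TestLRSchedule:
    def test_monotone_improvement_keeps_initial_lr(self):
        cfg = _cfg()
        hist = _history([0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
        assert hl.lr_schedule_step(hist, cfg) == cfg.initial_lr

    def test_plateau_triggers_factor_of_ten_reduction(self):
        cfg = _cfg(plateau_patience=3)
        hist = _history([0.8, 0.8, 0.8, 0.8])  # 3 stale epochs after the first
        assert hl.lr_schedule_step(hist, cfg) == pytest.approx(6e-4)

    def test_two_successive_plateaus_from_6e2(self):
        cfg = _cfg(initial_lr=6e-2, plateau_patience=2)
        hist = _history([0.8, 0.8, 0.8, 0.8, 0.8])  # two back-to-back plateaus
        assert hl.lr_schedule_step(hist, cfg) == pytest.approx(6e-4)

    def test_improvement_resets_the_wait_counter(self):
        cfg = _cfg(plateau_patience=3)
        hist = _history([0.8, 0.8, 0.8, 0.9, 0.9, 0.9])
        assert hl.lr_schedule_step(hist, cfg) == cfg.initial_lr

    def test_requires_at_least_one_epoch(self):
        with pytest.raises(ValueError):
            hl.lr_schedule_step(_history([]), _cfg())


class TestAugmentation:
    def test_disabled_augmentation_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 16, 16, 3)).astype(np.float32)
        cfg = hl.AugmentConfig(horizontal_flip=False, vertical_flip=False,
                               width_shift_fraction=0, height_shift_fraction=0)
        np.testing.assert_array_equal(hl.augment_batch(x, cfg, rng), x)

    def test_double_flip_is_identity(self):
        x = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
        assert np.array_equal(x[:, :, ::-1][:, :, ::-1], x)
        assert np.array_equal(x[:, ::-1][:, ::-1], x)

    def test_shape_and_range_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 20, 20, 3)).astype(np.float32)
        out = hl.augment_batch(x, hl.AugmentConfig(), rng)
        assert out.shape == x.shape
        assert out.min() >= x.min() - 1e-6 and out.max() <= x.max() + 1e-6

    def test_seeded_determinism(self):
        x = np.random.default_rng(2).random((5, 16, 16, 3)).astype(np.float32)
        a = hl.augment_batch(x, hl.AugmentConfig(), np.random.default_rng(7))
        b = hl.augment_batch(x, hl.AugmentConfig(), np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_shift_fraction_validation(self):
        with pytest.raises(ValueError):
            hl.AugmentConfig(width_shift_fraction=0.6)


def _toy_task(n=120, size=64, seed=0):
    """Linearly separable two-class image toy: class 1 is globally brighter."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.random((n, size, size, 3)).astype(np.float32) * 0.4
    x += y[:, None, None, None] * 0.3
    return x.astype(np.float32), y


@pytest.fixture(scope="module")
def toy_model_and_data():
    x, y = _toy_task()
    model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=0)
    return model, x, y


class TestFreezing:
    def test_freeze_bounds(self):
        model, _ = hl.build_ather2((96, 96, 3), 2, seed=0)
        n_weighted = len(model.weighted_layers())
        with pytest.raises(ValueError):
            hl.freeze_first_layers(model, n_weighted + 1)
        hl.freeze_first_layers(model, 0)
        assert all(p.trainable for p in model.parameters()
                   if not p.name.endswith(("moving_mean", "moving_variance")))

    def test_frozen_weights_unchanged_by_training(self):
        x, y = _toy_task(n=48)
        model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=1)
        hl.freeze_first_layers(model, 2)
        frozen_before = [p.value.copy() for _, l in model.weighted_layers()[:2]
                         for p in l.parameters()]
        cfg = _cfg(max_epochs=2, batch_size=16, augment=hl.AugmentConfig(
            horizontal_flip=False, vertical_flip=False,
            width_shift_fraction=0, height_shift_fraction=0))
        hl.train(model, (x[:32], y[:32]), (x[32:], y[32:]), cfg)
        frozen_after = [p.value for _, l in model.weighted_layers()[:2]
                        for p in l.parameters()]
        for before, after in zip(frozen_before, frozen_after):
            np.testing.assert_array_equal(before, after)


class TestTrain:
    def test_learns_separable_toy_to_high_accuracy(self):
        x, y = _toy_task()
        model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=0)
        cfg = _cfg(max_epochs=25, plateau_patience=3, early_stop_patience=25,
                   batch_size=24)
        model, hist = hl.train(model, (x[:96], y[:96]), (x[96:], y[96:]), cfg)
        assert max(hist.train_accuracy) >= 0.99

    def test_history_lr_trace_is_step_function_with_ratio_point_one(self):
        x, y = _toy_task(n=60)
        model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=2)
        cfg = _cfg(max_epochs=12, plateau_patience=2, early_stop_patience=12)
        _, hist = hl.train(model, (x[:40], y[:40]), (x[40:], y[40:]), cfg)
        lrs = hist.learning_rate
        assert lrs[0] == cfg.initial_lr
        for a, b in zip(lrs, lrs[1:]):
            assert b == a or b == pytest.approx(a * 0.1)
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        # the recorded trace is reproducible from the schedule rule
        for i in range(1, len(lrs)):
            assert _replay_lr(hist.val_accuracy[:i], cfg) == pytest.approx(lrs[i])

    def test_early_stopping_halts_before_max_epochs(self):
        x, y = _toy_task(n=60)
        model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=3)
        # constant validation set the model saturates on -> stale accuracy
        cfg = _cfg(max_epochs=60, plateau_patience=2, early_stop_patience=4)
        _, hist = hl.train(model, (x[:40], y[:40]), (x[40:], y[40:]), cfg)
        assert len(hist) < 60

    def test_identical_seed_identical_history(self):
        x, y = _toy_task(n=48)
        cfg = _cfg(max_epochs=3, seed=11)
        runs = []
        for _ in range(2):
            model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=5)
            _, hist = hl.train(model, (x[:32], y[:32]), (x[32:], y[32:]), cfg)
            runs.append(hist)
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_accuracy == runs[1].val_accuracy

    def test_label_and_emptiness_validation(self):
        x, y = _toy_task(n=16)
        model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=0)
        with pytest.raises(ValueError, match="empty"):
            hl.train(model, (x[:0], y[:0]), (x, y), _cfg())
        with pytest.raises(ValueError, match="labels"):
            hl.train(model, (x, y + 2), (x, y), _cfg())


class TestPretraining:
    def test_head_transplant_changes_arity_and_keeps_features(self):
        model, _ = hl.build_ather2((64, 64, 3), 2, variant="right_only", seed=0)
        feature_weights = {p.name: p.value.copy() for p in model.parameters()
                           if not p.name.startswith("C-5")}
        new = hl.replace_head(model, 4, seed=1)
        x = np.zeros((1, 64, 64, 3), dtype=np.float32)
        assert new.forward(x).outputs[new.output_name].shape == (1, 4)
        for p in new.parameters():
            if p.name in feature_weights:
                np.testing.assert_array_equal(p.value, feature_weights[p.name])

    def test_stage2_starts_from_stage1_feature_weights(self):
        x, y = _toy_task(n=60)
        captured = {}

        def builder(num_classes, seed):
            model, _ = hl.build_ather2((64, 64, 3), num_classes,
                                       variant="right_only", seed=seed)
            return model

        plan = hl.PretrainPlan((x[:40], y[:40]), (x[40:], y[40:]), 2,
                               (x[:40], y[:40]), (x[40:], y[40:]), 3,
                               frozen_layer_count=0)
        cfg1 = _cfg(max_epochs=2, seed=0)
        cfg2 = _cfg(max_epochs=1, seed=0)

        import her2light.training as tr
        orig_replace = tr.replace_head

        def spy(model, k, seed=0):
            captured["features"] = {p.name: p.value.copy()
                                    for p in model.parameters()
                                    if not p.name.startswith("C-5")}
            return orig_replace(model, k, seed)

        tr.replace_head = spy
        try:
            yt = np.clip(y, 0, 2)
            plan = hl.PretrainPlan((x[:40], y[:40]), (x[40:], y[40:]), 2,
                                   (x[:40], yt[:40]), (x[40:], yt[40:]), 3)
            model, h1, h2 = hl.domain_pretrain_finetune(builder, plan, cfg1, cfg2)
        finally:
            tr.replace_head = orig_replace
        assert len(h1) >= 1 and len(h2) >= 1
        assert captured["features"]  # stage-1 weights were transplanted
        out = model.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))
        assert out.outputs[model.output_name].shape == (1, 3)
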