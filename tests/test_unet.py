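import numpy as np
import pytest

import spindlekit.unet as unet_mod
from spindlekit.errors import ContractError, ParameterError
from spindlekit.io import Event, EventList
from spindlekit.unet import (
    SpindleUNet,
    TrainConfig,
    UNetConfig,
    amplitude_augment,
    build_unet,
    events_to_masks,
    generalized_dice_loss,
    load_checkpoint,
    masks_to_events,
    save_checkpoint,
    train,
)
from conftest import all_n2_blocks

SMALL = UNetConfig(base_filters=4, kernel_size=3)


class TestArchitecture:
    def test_output_length_equals_input_length(self):
        model = build_unet(SMALL, seed=0)
        for n in (11500, 100, 37, 5):
            x = np.zeros((1, 1, n), dtype=np.float32)
            assert model.predict_masks(x).shape == (1, 2, n)

    def test_same_seed_identical_initial_weights(self):
        w1 = build_unet(SMALL, seed=5).get_weights()
        w2 = build_unet(SMALL, seed=5).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_too_short_input_reports_minimum(self):
        model = build_unet(SMALL, seed=0)
        with pytest.raises(ParameterError, match=str(model.min_input_length)):
            model.forward(np.zeros((1, 1, 3), dtype=np.float32))

    def test_probabilities_sum_to_one(self):
        model = build_unet(SMALL, seed=1)
        x = np.random.default_rng(0).normal(size=(2, 1, 64)).astype(np.float32)
        p = model.predict_masks(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_unet(SMALL, seed=2)
        x = np.random.default_rng(1).normal(size=(1, 1, 48)).astype(np.float32)
        path = tmp_path / "m.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.config == model.config
        np.testing.assert_array_equal(back.predict_masks(x), model.predict_masks(x))


class TestGeneralizedDice:
    def _one_hot(self, cls, n):
        t = np.zeros((1, 2, n), dtype=np.float32)
        t[0, 0] = cls
        t[0, 1] = 1 - cls
        return t

    def test_perfect_prediction_near_zero(self):
        cls = np.zeros(50)
        cls[10:20] = 1
        t = self._one_hot(cls, 50)
        assert generalized_dice_loss(t, t) < 1e-6

    def test_complement_prediction_near_one(self):
        cls = np.zeros(50)
        cls[10:20] = 1
        t = self._one_hot(cls, 50)
        comp = t[:, ::-1, :].copy()
        assert generalized_dice_loss(comp, t) > 0.99

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=(1, 2, 40)).astype(np.float32)
        p /= p.sum(axis=1, keepdims=True)
        cls = (rng.random(40) < 0.3).astype(float)
        t = self._one_hot(cls, 40)
        perm = rng.permutation(40)
        a = generalized_dice_loss(p, t)
        b = generalized_dice_loss(p[:, :, perm], t[:, :, perm])
        assert abs(a - b) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            generalized_dice_loss(np.zeros((1, 2, 10)), np.zeros((1, 2, 12)))


class TestAugmentation:
    def test_factor_ranges_and_branch_split(self):
        rng = np.random.default_rng(0)
        x = np.ones(4)
        factors = np.array([amplitude_augment(x, rng)[0] for _ in range(10_000)])
        assert factors.min() >= 0.5 and factors.max() <= 2.0
        up = np.mean(factors >= 1.0)
        assert 0.48 < up < 0.52

    def test_seeded_reproducibility(self):
        x = np.ones(4)
        a = amplitude_augment(x, np.random.default_rng(42))
        b = amplitude_augment(x, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_pure_rescaling(self):
        rng = np.random.default_rng(1)
        x = np.arange(10.0)
        y = amplitude_augment(x, rng)
        ratios = y[1:] / x[1:]
        np.testing.assert_allclose(ratios, ratios[0])


class TestMaskEventConversion:
    def test_run_length_example(self):
        ev = masks_to_events(np.array([0, 0, 1, 1, 1, 0]), 100.0)
        assert len(ev) == 1
        assert ev[0].onset_s == pytest.approx(0.02)
        assert ev[0].duration_s == pytest.approx(0.03)

    def test_all_background_empty(self):
        assert len(masks_to_events(np.zeros(500), 100.0)) == 0

    def test_all_spindle_single_event(self):
        ev = masks_to_events(np.ones(11500), 100.0)
        assert len(ev) == 1
        assert ev[0].duration_s == pytest.approx(115.0)

    def test_score_masks_tie_resolves_to_background(self):
        masks = np.zeros((2, 10))
        assert len(masks_to_events(masks, 100.0)) == 0

    def test_roundtrip_identity_on_sample_aligned_events(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = 2000
            starts = np.sort(rng.choice(np.arange(0, n - 120, 120), 5, replace=False))
            events = EventList([
                Event(s / 100.0, int(rng.integers(30, 100)) / 100.0)
                for s in starts
            ])
            masks = events_to_masks(events, n, 100.0)
            back = masks_to_events(masks[0], 100.0)
            assert len(back) == len(events)
            for a, b in zip(events, back):
                assert a.onset_s == pytest.approx(b.onset_s)
                assert a.duration_s == pytest.approx(b.duration_s)


class TestTraining:
    def test_early_stop_after_patience_without_improvement(self, monkeypatch):
        monkeypatch.setattr(unet_mod, "_validation_iou_f1",
                            lambda *a, **k: 0.5)
        blocks = [np.zeros(32, dtype=np.float32)] * 10
        labels = [EventList([])] * 10
        model = build_unet(SMALL, seed=0)
        cfg = TrainConfig(patience=1, max_epochs=50, seed=0)
        _, history = train(model, blocks, labels, cfg)
        assert len(history) == 2

    def test_same_seed_identical_history(self):
        blocks, labels = all_n2_blocks(6, seed=21)
        histories = []
        for _ in range(2):
            model = build_unet(SMALL, seed=9)
            _, h = train(model, blocks, labels,
                         TrainConfig(max_epochs=3, patience=10, seed=9))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_loss_decreases_early(self):
        blocks, labels = all_n2_blocks(8, seed=22)
        model = build_unet(SMALL, seed=4)
        _, h = train(model, blocks, labels,
                     TrainConfig(max_epochs=6, patience=10, seed=4))
        assert h[-1]["loss"] < h[0]["loss"]

    def test_empty_validation_split_rejected(self):
        blocks, labels = all_n2_blocks(3, seed=23)
        model = build_unet(SMALL, seed=0)
        with pytest.raises(ParameterError):
            train(model, blocks, labels,
                  TrainConfig(val_fraction=0.0, max_epochs=1, seed=0))
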