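import numpy as np
import pytest

from mudrop.segmentation import (ModelSpec, TrainingConfig, build_model,
                                 dice_loss, load_checkpoint, predict,
                                 save_checkpoint, train)
from mudrop.synthetic import make_arrays

TINY = ModelSpec(base_width=64, width_scale=0.0625, working_resolution=64)


def _one_hot(mask, n=5):
    out = np.zeros((n,) + mask.shape, dtype=np.float64)
    for c in range(n):
        out[c] = mask == c
    return out


class TestDiceLoss:
    def test_perfect_prediction_has_zero_loss(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[2:5, 2:5] = 3
        assert dice_loss(_one_hot(mask), mask) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_foregrounds_have_loss_one(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[:2, :2] = 1
        pred_mask = np.zeros((8, 8), np.uint8)
        pred_mask[6:, 6:] = 2
        assert dice_loss(_one_hot(pred_mask), truth) == \
            pytest.approx(1.0, abs=1e-6)

    def test_half_overlap_gives_half_loss(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[0, :4] = 1                      # |y| = 4
        pred_mask = np.zeros((8, 8), np.uint8)
        pred_mask[0, 2:6] = 1                 # |x| = 4, |x ∩ y| = 2
        assert dice_loss(_one_hot(pred_mask), truth) == \
            pytest.approx(0.5, abs=1e-6)

    def test_matches_pixel_set_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            truth = rng.integers(0, 5, (8, 8)).astype(np.uint8)
            pred_mask = rng.integers(0, 5, (8, 8)).astype(np.uint8)
            # brute-force Eq. over explicit pixel sets
            terms = []
            for c in (1, 2, 3, 4):
                x = {(r, cc) for r in range(8) for cc in range(8)
                     if pred_mask[r, cc] == c}
                y = {(r, cc) for r in range(8) for cc in range(8)
                     if truth[r, cc] == c}
                if not x and not y:
                    continue
                terms.append(1 - (2 * len(x & y) + 1e-6)
                             / (len(x) + len(y) + 1e-6))
            want = float(np.mean(terms)) if terms else 0.0
            got = dice_loss(_one_hot(pred_mask), truth)
            assert got == pytest.approx(want, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((5, 8, 8)), np.zeros((4, 4), np.uint8))


class TestBuildModel:
    def test_head_is_1x1_conv_with_five_channels(self):
        net = build_model(ModelSpec(), seed=0)
        assert net.head.k == 1
        assert net.head.cout == 5

    def test_width_scaling_strictly_reduces_parameters(self):
        small = build_model(ModelSpec(width_scale=0.25), seed=0)
        full = build_model(ModelSpec(width_scale=1.0), seed=0)
        assert small.n_params < full.n_params

    def test_same_seed_gives_identical_initialization(self):
        a = build_model(TINY, seed=5)
        b = build_model(TINY, seed=5)
        for (o1, n1, _), (o2, n2, _) in zip(a.params(), b.params()):
            assert np.array_equal(getattr(o1, n1), getattr(o2, n2))

    def test_working_resolution_must_match_pooling_depth(self):
        with pytest.raises(ValueError):
            ModelSpec(working_resolution=100)

    def test_five_class_head_is_fixed(self):
        with pytest.raises(ValueError):
            ModelSpec(num_classes=3)


class TestPredict:
    def test_large_frame_round_trips_through_working_resolution(self):
        net = build_model(TINY, seed=0)
        frame = np.random.default_rng(0).integers(
            0, 255, (192, 108, 3)).astype(np.uint8)
        mask = predict(net, frame, working_resolution=64)
        assert mask.shape == (192, 108)
        assert set(np.unique(mask)) <= {0, 1, 2, 3, 4}

    def test_native_resolution_needs_no_resize(self):
        net = build_model(TINY, seed=0)
        frame = np.random.default_rng(1).integers(
            0, 255, (64, 64, 3)).astype(np.uint8)
        assert predict(net, frame, 64).shape == (64, 64)

    def test_inference_is_deterministic(self):
        net = build_model(TINY, seed=0)
        frame = np.random.default_rng(2).integers(
            0, 255, (64, 64, 3)).astype(np.uint8)
        assert np.array_equal(predict(net, frame, 64),
                              predict(net, frame, 64))

    def test_non_rgb_input_rejected(self):
        net = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            predict(net, np.zeros((64, 64), np.uint8), 64)

    def test_batched_inference_matches_single_frame(self):
        from mudrop.segmentation import predict_batch
        net = build_model(TINY, seed=4)
        rng = np.random.default_rng(3)
        frames = [rng.integers(0, 255, (96, 96, 3)).astype(np.uint8)
                  for _ in range(5)]
        batched = predict_batch(net, frames, 64, chunk=2)
        for f, m in zip(frames, batched):
            assert np.array_equal(m, predict(net, f, 64))


class TestTrain:
    def test_single_epoch_bookkeeping(self):
        imgs, masks = make_arrays(4, seed=0)
        imgs = imgs[:, ::2, ::2]     # 64 x 64 for speed
        masks = masks[:, ::2, ::2]
        net = build_model(TINY, seed=0)
        cfg = TrainingConfig(epochs=1, batch_size=2, seed=0)
        hist = train(net, imgs[:2], masks[:2], imgs[2:], masks[2:], cfg)
        assert len(hist.train_loss) == len(hist.val_loss) == 1
        assert len(hist.val_miou) == len(hist.learning_rate) == 1

    def test_learning_rate_trace_follows_cosine_schedule(self):
        from mudrop.nn import cosine_annealing_lr
        imgs, masks = make_arrays(4, seed=0)
        imgs = imgs[:, ::2, ::2]
        masks = masks[:, ::2, ::2]
        net = build_model(TINY, seed=0)
        cfg = TrainingConfig(epochs=7, batch_size=2, seed=0,
                             early_stop_miou=2.0)
        hist = train(net, imgs[:2], masks[:2], imgs[2:], masks[2:], cfg)
        want = [cosine_annealing_lr(e, cfg.learning_rate,
                                    cfg.min_learning_rate,
                                    cfg.scheduler_period) for e in range(7)]
        np.testing.assert_allclose(hist.learning_rate, want, rtol=1e-12)

    def test_training_smoke_reduces_smoothed_validation_loss(self):
        imgs, masks = make_arrays(28, seed=9)
        imgs = imgs[:, ::2, ::2]
        masks = masks[:, ::2, ::2]
        net = build_model(TINY, seed=9)
        cfg = TrainingConfig(epochs=20, batch_size=2, seed=9,
                             learning_rate=1e-3, early_stop_miou=2.0)
        hist = train(net, imgs[:20], masks[:20], imgs[20:], masks[20:], cfg)
        first = np.mean(hist.val_loss[:3])
        last = np.mean(hist.val_loss[-3:])
        assert last < first

    def test_empty_partition_rejected(self):
        net = build_model(TINY, seed=0)
        empty = np.zeros((0, 64, 64, 3), np.uint8)
        with pytest.raises(ValueError):
            train(net, empty, np.zeros((0, 64, 64), np.uint8),
                  empty, np.zeros((0, 64, 64), np.uint8))


def test_checkpoint_round_trip(tmp_path):
    net = build_model(TINY, seed=3)
    save_checkpoint(tmp_path / "ck", net, TINY, TrainingConfig())
    net2, spec2 = load_checkpoint(tmp_path / "ck")
    assert spec2 == TINY
    frame = np.random.default_rng(0).integers(0, 255, (64, 64, 3)).astype(np.uint8)
    assert np.array_equal(predict(net, frame, 64), predict(net2, frame, 64))
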