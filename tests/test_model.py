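"""Multi-task CNN construction, loss, training behaviour and prediction."""

import numpy as np
import pytest

from plaquescope import nn
from plaquescope.model import (ClassifyThresholds, ModelConfig, PredictionTriple,
                               TrainConfig, build_model, classify, load_checkpoint,
                               multilabel_soft_margin_loss, parameter_count, predict,
                               predict_batch, save_checkpoint, train)


def separable_tiles(n_per_class=12, px=64, seed=0):
    """Trivially separable two-class set: bright disks vs dark squares."""
    rng = np.random.default_rng(seed)
    tiles, labels = [], []
    for i in range(n_per_class):
        t = np.full((px, px, 3), 30, dtype=np.uint8)
        yy, xx = np.mgrid[0:px, 0:px]
        r = rng.integers(10, 20)
        t[(yy - px // 2) ** 2 + (xx - px // 2) ** 2 <= r * r] = 220
        tiles.append(t)
        labels.append([1, 0, 0])
    for i in range(n_per_class):
        t = np.full((px, px, 3), 200, dtype=np.uint8)
        s = rng.integers(8, 16)
        t[px // 2 - s:px // 2 + s, px // 2 - s:px // 2 + s] = 15
        tiles.append(t)
        labels.append([0, 1, 0])
    return np.stack(tiles), np.array(labels, dtype=np.float32)


SMALL = ModelConfig(input_px=64, conv_channels=(4, 4, 8, 8, 16, 16),
                    fc_sizes=(32, 16), seed=11)


class TestArchitecture:
    def test_forward_yields_three_finite_logits(self, tiny_model, rng):
        x = tiny_model.scale_input(rng.integers(0, 255, (64, 64, 3), dtype=np.uint8))
        logits = tiny_model.net.forward(x)
        assert logits.shape == (1, 3)
        assert np.isfinite(logits).all()

    def test_flatten_length_after_six_pools(self):
        model = build_model(ModelConfig(conv_channels=(16, 16, 32, 32, 64, 64)))
        # 256 / 2^6 = 4 per side -> 16 * 64 features into the first dense layer
        dense = [l for l in model.net.layers if isinstance(l, nn.Dense)][0]
        assert dense.params[0][1].shape[0] == 4 * 4 * 64

    def test_parameter_count_matches_closed_form(self):
        cfg = ModelConfig(conv_channels=(16, 16, 32, 32, 64, 64), fc_sizes=(512, 100))
        expected = 0
        cin = 3
        for cout in cfg.conv_channels:
            expected += 9 * cin * cout + cout
            cin = cout
        nin = (256 // 64) ** 2 * cfg.conv_channels[-1]
        for nout in (512, 100, 3):
            expected += nin * nout + nout
            nin = nout
        assert parameter_count(cfg) == expected

    def test_input_not_divisible_by_64_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_px=200)

    def test_six_conv_layers_required(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_channels=(8, 8, 8))


class TestLoss:
    def test_zero_logits_give_ln2(self):
        assert multilabel_soft_margin_loss([0.0, 0.0, 0.0], [1, 0, 1]) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_saturated_logit_contributes_nothing(self):
        loss = multilabel_soft_margin_loss([20.0, 20.0, 20.0], [1, 1, 1])
        assert loss < 1e-8

    def test_matches_direct_formula_on_random_cases(self, rng):
        def oracle(x, y):
            s = 1 / (1 + np.exp(-np.asarray(x, dtype=np.float64)))
            y = np.asarray(y, dtype=np.float64)
            return float(np.mean(-(y * np.log(s) + (1 - y) * np.log(1 - s))))
        for _ in range(1000):
            x = rng.normal(0, 3, 3)
            y = rng.integers(0, 2, 3)
            assert multilabel_soft_margin_loss(x, y) == pytest.approx(oracle(x, y), abs=1e-9)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            multilabel_soft_margin_loss([0.0, 0.0, 0.0], [0.5, 0, 1])


class TestTraining:
    def test_loss_decreases_on_separable_classes(self):
        tiles, labels = separable_tiles()
        model = build_model(SMALL)
        cfg = TrainConfig(learning_rate=1e-3, epochs=5, batch_size=8, seed=0)
        _, history = train(model, tiles, labels, cfg)
        assert history.loc[4, "train_loss"] < history.loc[0, "train_loss"]

    def test_same_seed_reproduces_epoch_losses(self):
        tiles, labels = separable_tiles(6)
        h = []
        for _ in range(2):
            model = build_model(SMALL)
            cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=8, seed=9)
            _, history = train(model, tiles, labels, cfg)
            h.append(history["train_loss"].tolist())
        assert h[0] == h[1]

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        tiles, labels = separable_tiles(4)
        model = build_model(SMALL)
        before = {k: v.copy() for k, v in model.net.state_dict().items()}
        cfg = TrainConfig(learning_rate=0.0, epochs=2, batch_size=8, seed=0)
        train(model, tiles, labels, cfg)
        after = model.net.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(SMALL), np.empty((0, 64, 64, 3)), np.empty((0, 3)),
                  TrainConfig(epochs=1))

    def test_nan_loss_aborts_with_diagnostic(self):
        tiles = np.full((4, 64, 64, 3), np.nan, dtype=np.float32)
        labels = np.tile([1, 0, 0], (4, 1)).astype(np.float32)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(build_model(SMALL), tiles, labels, TrainConfig(epochs=1, batch_size=4))


class TestPredict:
    def test_deterministic_and_in_unit_interval(self, tiny_model, rng):
        tile = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        p1 = predict(tiny_model, tile)
        p2 = predict(tiny_model, tile)
        assert p1 == p2
        assert all(0.0 <= v <= 1.0 for v in p1.as_array())

    def test_batch_equals_per_tile_loop(self, tiny_model, rng):
        tiles = rng.integers(0, 255, (5, 64, 64, 3), dtype=np.uint8)
        batched = predict_batch(tiny_model, tiles)
        looped = np.stack([predict(tiny_model, t).as_array() for t in tiles])
        assert np.array_equal(batched, looped)

    def test_task_independence(self, rng):
        """Altering one task's output weights never changes the other
        confidences (multi-label heads are uncoupled)."""
        model = build_model(SMALL)
        tile = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        base = predict(model, tile).as_array()
        head = model.net.layers[-1]
        head.params[0][1][:, 0] += 1.0  # shift the cored logit only
        new = predict(model, tile).as_array()
        assert new[1] == base[1] and new[2] == base[2]
        assert new[0] != base[0]

    def test_wrong_shape_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            predict(tiny_model, np.zeros((32, 32, 3), dtype=np.uint8))


class TestClassify:
    def test_single_label(self):
        assert classify(PredictionTriple(0.92, 0.05, 0.20)) == {"cored"}

    def test_exact_thresholds_give_empty_set(self):
        assert classify(PredictionTriple(0.91, 0.10, 0.85)) == set()

    def test_all_above(self):
        assert classify(PredictionTriple(0.95, 0.95, 0.95)) == {"cored", "diffuse", "caa"}

    def test_custom_thresholds(self):
        thr = ClassifyThresholds(cored=0.5, diffuse=0.5, caa=0.5)
        assert classify(PredictionTriple(0.6, 0.4, 0.51), thr) == {"cored", "caa"}


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    tile = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
    save_checkpoint(tiny_model, tmp_path / "ckpt")
    loaded = load_checkpoint(tmp_path / "ckpt")
    assert loaded.config == tiny_model.config
    assert predict(loaded, tile) == predict(tiny_model, tile)
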