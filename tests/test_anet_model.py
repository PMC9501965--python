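"""A-net architecture arithmetic, loss, weight map, and training."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anetsr.anet_model import (
    Anet,
    AnetConfig,
    TrainConfig,
    WeightMap,
    compute_weight_map,
    feature_shape,
    load_model,
    pixel_softmax,
    predict_proba,
    save_model,
    softmax_ce_with_grad,
    train,
    weighted_cross_entropy,
)


class TestFeatureShape:
    @pytest.mark.parametrize("side,depth,expect",
                             [(512, 4, 32), (2048, 4, 128), (16, 4, 1)])
    def test_bottleneck_side(self, side, depth, expect):
        assert feature_shape(side, depth) == expect

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            feature_shape(100, 4)


class TestPixelSoftmax:
    def test_equal_activations_split_evenly(self):
        for c in (-5.0, 0.0, 3.7):
            P = pixel_softmax(np.full((2, 3, 3), c))
            assert np.allclose(P, 0.5)

    def test_hand_computed_two_class_case(self):
        P = pixel_softmax(np.array([[[np.log(2.0)]], [[0.0]]]))
        assert P[0, 0, 0] == pytest.approx(2 / 3)
        assert P[1, 0, 0] == pytest.approx(1 / 3)

    @given(seed=st.integers(0, 10_000))
    def test_normalizes_at_every_pixel(self, seed):
        a = np.random.default_rng(seed).normal(0, 5, (3, 4, 4))
        assert np.allclose(pixel_softmax(a).sum(axis=0), 1.0)

    def test_agrees_with_unstabilized_form(self, rng):
        a = rng.uniform(-20, 20, (2, 8, 8))
        direct = np.exp(a) / np.exp(a).sum(axis=0, keepdims=True)
        assert np.abs(pixel_softmax(a) - direct).max() < 1e-6

    def test_stable_for_large_activations(self):
        P = pixel_softmax(np.array([[[1000.0]], [[-1000.0]]]))
        assert np.isfinite(P).all()
        assert P[0, 0, 0] == pytest.approx(1.0)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_has_zero_loss(self):
        g = np.array([[0, 1], [1, 0]])
        P = np.zeros((2, 2, 2))
        rows, cols = np.indices(g.shape)
        P[g, rows, cols] = 1.0
        wm = WeightMap(omega=np.ones((2, 2)), ground_truth=g)
        assert weighted_cross_entropy(P, wm) == pytest.approx(0.0)

    def test_single_pixel_unit_weight(self):
        P = np.array([[[np.exp(-1.0)]], [[1 - np.exp(-1.0)]]])
        wm = WeightMap(omega=np.ones((1, 1)), ground_truth=np.zeros((1, 1)))
        assert weighted_cross_entropy(P, wm) == pytest.approx(1.0)

    def test_linear_in_weights(self, rng):
        a = rng.normal(0, 1, (2, 4, 4))
        P = pixel_softmax(a)
        g = rng.integers(0, 2, (4, 4))
        w = rng.uniform(0.1, 2, (4, 4))
        e1 = weighted_cross_entropy(P, WeightMap(w, g))
        e3 = weighted_cross_entropy(P, WeightMap(3 * w, g))
        assert e3 == pytest.approx(3 * e1)

    def test_shape_mismatch_rejected(self):
        P = np.ones((2, 4, 4)) / 2
        wm = WeightMap(omega=np.ones((2, 2)), ground_truth=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            weighted_cross_entropy(P, wm)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(0, 1, (2, 4, 4))
        wm = WeightMap(omega=rng.uniform(0.5, 2, (4, 4)),
                       ground_truth=rng.integers(0, 2, (4, 4)))
        _, grad = softmax_ce_with_grad(logits, wm)
        eps = 1e-6
        num = np.zeros_like(grad)
        for idx in np.ndindex(*logits.shape):
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            num[idx] = (softmax_ce_with_grad(lp, wm)[0]
                        - softmax_ce_with_grad(lm, wm)[0]) / (2 * eps)
        assert np.abs(num - grad).max() < 1e-4


class TestComputeWeightMap:
    def test_uniform_label_reduces_to_class_term(self):
        wm = compute_weight_map(np.zeros((8, 8), dtype=np.uint8))
        assert np.allclose(wm.omega, wm.omega[0, 0])

    def test_weight_decreases_away_from_boundary(self):
        lab = np.zeros((16, 16), dtype=np.uint8)
        lab[:, 8:] = 1
        wm = compute_weight_map(lab)
        # boundary runs between columns 7 and 8
        assert wm.omega[4, 7] > wm.omega[4, 2] > wm.omega[4, 0]

    def test_matches_brute_force_distance_oracle(self):
        lab = np.zeros((8, 8), dtype=np.uint8)
        lab[3:5, :] = 1  # one 2-px strip
        w0, sigma = 10.0, 5.0
        wm = compute_weight_map(lab, w0=w0, sigma=sigma)
        # oracle: explicit O(n^2) nearest-boundary search
        boundary = [(r, c) for r in range(8) for c in range(8)
                    if any(0 <= r + dr < 8 and 0 <= c + dc < 8
                           and lab[r + dr, c + dc] != lab[r, c]
                           for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)))]
        n = lab.size
        counts = {0: (lab == 0).sum(), 1: (lab == 1).sum()}
        for r in range(8):
            for c in range(8):
                d2 = min((r - br) ** 2 + (c - bc) ** 2 for br, bc in boundary)
                expect = n / (2.0 * counts[lab[r, c]]) \
                    + w0 * np.exp(-d2 / (2 * sigma**2))
                assert wm.omega[r, c] == pytest.approx(expect, rel=1e-9)


class TestForward:
    def test_output_matches_input_size(self, rng):
        net = Anet(AnetConfig(depth=2, base_channels=4), seed=0)
        for side in (16, 64):
            out = net.forward(rng.normal(0, 1, (side, side)))
            assert out.shape == (2, side, side)

    def test_probability_output_normalized(self, rng):
        net = Anet(AnetConfig(depth=2, base_channels=4), seed=0)
        P = predict_proba(net, rng.integers(0, 100, (32, 32)).astype(np.uint16))
        assert P.shape == (2, 32, 32)
        assert np.allclose(P.sum(axis=0), 1.0)

    def test_non_divisible_input_rejected(self, rng):
        net = Anet(AnetConfig(depth=2, base_channels=4), seed=0)
        with pytest.raises(ValueError):
            net.forward(rng.normal(0, 1, (30, 30)))

    def test_channel_doubling_per_level(self):
        net = Anet(AnetConfig(depth=3, base_channels=8), seed=0)
        widths = [blk.layers[3].cout for blk in net.enc]
        assert widths == [8, 16, 32]
        assert net.bottleneck.layers[3].cout == 64


class TestTrain:
    def test_overfits_a_single_pair(self, rng):
        img = rng.integers(0, 4000, (32, 32)).astype(np.uint16)
        lab = np.zeros((32, 32), dtype=bool)
        lab[10:14, :] = True
        res = train([(img, lab)], AnetConfig(depth=2, base_channels=8),
                    TrainConfig(epochs=200, seed=0))
        P = predict_proba(res.model, img)
        assert (((P[1] >= 0.5) == lab).mean()) > 0.99

    def test_zero_epochs_returns_initialized_model(self, rng):
        img = rng.integers(0, 100, (16, 16)).astype(np.uint16)
        lab = np.zeros((16, 16), dtype=bool)
        res = train([(img, lab)], AnetConfig(depth=1, base_channels=4),
                    TrainConfig(epochs=0, seed=3))
        fresh = Anet(AnetConfig(depth=1, base_channels=4),
                     rng=np.random.default_rng(3))
        for a, b in zip(res.model.state_arrays(), fresh.state_arrays()):
            assert np.array_equal(a, b)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], AnetConfig(depth=1, base_channels=4), TrainConfig(epochs=1))

    def test_reference_scale_settings_accepted(self):
        cfg = TrainConfig(epochs=200, batch_size=1)
        assert cfg.epochs == 200
        with pytest.raises(ValueError):
            TrainConfig(batch_size=4)

    def test_validation_checkpointing_tracks_best(self, rng):
        img = rng.integers(0, 4000, (16, 16)).astype(np.uint16)
        lab = np.zeros((16, 16), dtype=bool)
        lab[5:8, :] = True
        res = train([(img, lab)], AnetConfig(depth=1, base_channels=4),
                    TrainConfig(epochs=5, seed=0), val_pairs=[(img, lab)])
        assert res.best_epoch <= 4
        assert all(h["val_loss"] is not None for h in res.history)

    def test_save_load_roundtrip(self, rng, tmp_path):
        img = rng.integers(0, 1000, (16, 16)).astype(np.uint16)
        lab = np.zeros((16, 16), dtype=bool)
        lab[4:6, :] = True
        res = train([(img, lab)], AnetConfig(depth=1, base_channels=4),
                    TrainConfig(epochs=2, seed=1))
        path = tmp_path / "m.npz"
        save_model(path, res.model)
        loaded = load_model(path)
        assert np.array_equal(predict_proba(loaded, img),
                              predict_proba(res.model, img))
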