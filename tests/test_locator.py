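"""Window classifier and sliding-window localization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echowall.cnn import EchoNet, LocatorConfig, conv_output_size
from echowall.locator import (TrainConfig, WindowScanParams, build_locator,
                              locate_target, prefilter_windows, train_locator,
                              window_grid)
from echowall.types import ParameterError, RoiWindow, StageError


class TestConvOutputSize:
    @pytest.mark.parametrize("inp,k,s,expected", [
        (208, 3, 1, 206),
        (110, 3, 1, 108),
        (5, 5, 1, 1),
        (206, 3, 2, 102),   # valid placements 0,2,...,202
    ])
    def test_values(self, inp, k, s, expected):
        assert conv_output_size(inp, k, s) == expected

    def test_kernel_too_large(self):
        with pytest.raises(ParameterError):
            conv_output_size(4, 5, 1)

    def test_layer_chain_consistency(self):
        cfg = LocatorConfig()
        sizes = cfg.layer_sizes()
        assert sizes == [206, 102, 100, 98]
        # every step reproduces conv_output_size applied successively
        s = cfg.input_size
        expect = []
        for k, stride in [(3, 1), (3, 2), (3, 1), (3, 1)]:
            s = conv_output_size(s, k, stride)
            expect.append(s)
        assert sizes == expect


class TestBuildLocator:
    def test_probability_contract(self):
        net = build_locator(LocatorConfig(input_size=24, conv_channels=2,
                                          fc_units=8), seed=0)
        x = np.random.default_rng(0).integers(0, 256, (3, 24, 24)).astype(np.uint8)
        probs = net.forward(x)
        assert probs.shape == (3, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_seeded_init_deterministic(self):
        cfg = LocatorConfig(input_size=24, conv_channels=2, fc_units=8)
        rng = np.random.default_rng(9)
        x = rng.integers(0, 256, (1, 24, 24)).astype(np.uint8)
        p1 = build_locator(cfg, seed=5).forward(x)
        p2 = build_locator(cfg, seed=5).forward(x)
        p3 = build_locator(cfg, seed=6).forward(x)
        assert np.array_equal(p1, p2)
        assert not np.array_equal(p1, p3)

    def test_c1_output_side_on_208(self):
        assert conv_output_size(LocatorConfig().input_size, 3, 1) == 206

    def test_invalid_plan_raises(self):
        with pytest.raises(ParameterError):
            LocatorConfig(input_size=6).validate()  # chain collapses below kernel
        with pytest.raises(ParameterError):
            LocatorConfig(n_classes=3).validate()


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences (float64)."""
        cfg = LocatorConfig(input_size=16, conv_channels=2, fc_units=5,
                            dropout_p=0.0)
        net = EchoNet(cfg, seed=3)
        for layer in net._layers:
            layer.W = layer.W.astype(np.float64)
            layer.b = layer.b.astype(np.float64)
        rng = np.random.default_rng(0)
        x = rng.integers(0, 256, size=(3, 16, 16)).astype(np.uint8)
        y = np.array([0, 1, 1])

        def loss():
            p = net.forward(x)
            return -np.mean(np.log(p[np.arange(3), y] + 1e-12))

        caches = [None] * 7
        probs = net.forward(x, training=True, rng=rng, caches=caches)
        net.backward(probs, y, caches)
        for layer in net._layers:
            W, gW = layer.W, layer.dW
            idxs = [tuple(t) for t in
                    np.stack([rng.integers(0, s, 6) for s in W.shape], axis=1)]
            for idx in idxs:
                eps, old = 1e-5, W[idx]
                W[idx] = old + eps
                lp = loss()
                W[idx] = old - eps
                lm = loss()
                W[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gW[idx]) <= 1e-4 * max(1.0, abs(num))


class TestTraining:
    @staticmethod
    def _tiny_set(separable: bool, n: int = 12):
        rng = np.random.default_rng(0)
        patches = np.empty((n, 16, 16), np.uint8)
        labels = np.arange(n) % 2
        for i in range(n):
            base = 200 if (labels[i] and separable) else 40
            patches[i] = np.clip(base + rng.integers(-20, 20, (16, 16)), 0, 255)
        if not separable:
            patches[:] = patches[0]
        return patches, labels

    def test_separable_tiny_set_learns(self):
        cfg = LocatorConfig(input_size=16, conv_channels=2, fc_units=8)
        net = EchoNet(cfg, seed=0)
        patches, labels = self._tiny_set(separable=True)
        net, hist = train_locator(net, patches, labels,
                                  TrainConfig(iterations=300, batch_size=8,
                                              learning_rate=1e-2, seed=0))
        assert len(hist["loss"]) == 300
        assert hist["loss"][-1] < hist["loss"][0]
        probs = net.predict_proba(patches)
        assert np.mean(probs.argmax(axis=1) == labels) >= 0.9

    def test_no_signal_gives_chance_accuracy(self):
        cfg = LocatorConfig(input_size=16, conv_channels=2, fc_units=8)
        net = EchoNet(cfg, seed=0)
        patches, labels = self._tiny_set(separable=False)
        net, hist = train_locator(net, patches, labels,
                                  TrainConfig(iterations=100, batch_size=8,
                                              learning_rate=1e-3, seed=0))
        assert abs(np.mean(hist["accuracy"][-20:]) - 0.5) <= 0.15

    def test_empty_and_single_class_error(self):
        net = EchoNet(LocatorConfig(input_size=16, conv_channels=2, fc_units=8))
        with pytest.raises(ParameterError):
            train_locator(net, np.empty((0, 16, 16), np.uint8), np.array([]))
        with pytest.raises(ParameterError):
            train_locator(net, np.zeros((4, 16, 16), np.uint8), np.zeros(4))

    def test_save_load_roundtrip(self, tmp_path):
        cfg = LocatorConfig(input_size=16, conv_channels=2, fc_units=8)
        net = EchoNet(cfg, seed=1)
        net.save(tmp_path / "model")
        again = EchoNet.load(tmp_path / "model.npz")
        x = np.random.default_rng(2).integers(0, 256, (2, 16, 16)).astype(np.uint8)
        assert np.array_equal(net.forward(x), again.forward(x))


class TestWindowGrid:
    def test_single_window(self):
        assert window_grid((200, 200), WindowScanParams()) == [RoiWindow(0, 0, 200)]

    def test_enumeration_oracle(self):
        wins = window_grid((225, 250), WindowScanParams())
        expected = [RoiWindow(r, c, 200)
                    for r in (0, 25) for c in (0, 25, 50)]
        assert wins == expected

    def test_too_small_errors(self):
        with pytest.raises(ParameterError):
            window_grid((199, 500), WindowScanParams())

    @given(h=st.integers(200, 400), w=st.integers(200, 400))
    @settings(max_examples=30, deadline=None)
    def test_count_formula(self, h, w):
        n = len(window_grid((h, w), WindowScanParams()))
        assert n == ((h - 200) // 25 + 1) * ((w - 200) // 25 + 1)


class TestPrefilter:
    def _windows(self, img):
        return window_grid(img.shape, WindowScanParams())

    @pytest.mark.parametrize("value,threshold,kept", [
        (0, 50, False),      # all-dark: discarded
        (255, 70, True),     # bright: kept
        (50, 50, True),      # boundary: discard rule is strict <
    ])
    def test_boundaries(self, value, threshold, kept):
        img = np.full((200, 200), value, np.uint8)
        out = prefilter_windows(img, self._windows(img), threshold)
        assert bool(out) is kept

    @given(t1=st.integers(0, 255), t2=st.integers(0, 255))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        t1, t2 = min(t1, t2), max(t1, t2)
        img = np.random.default_rng(0).integers(0, 256, (250, 250)).astype(np.uint8)
        wins = self._windows(img)
        hi = {(w.row, w.col) for w in prefilter_windows(img, wins, t2)}
        lo = {(w.row, w.col) for w in prefilter_windows(img, wins, t1)}
        assert hi <= lo


class _ConstantModel:
    """Scores every window identically: exposes the tie-break."""

    config = LocatorConfig()

    def predict_proba(self, images, batch_size=16):
        n = len(images)
        return np.tile([0.3, 0.7], (n, 1))


class TestLocateTarget:
    def test_tie_breaks_to_smallest_row_col(self):
        img = np.full((250, 250), 200, np.uint8)
        win = locate_target(img, _ConstantModel(), WindowScanParams())
        assert (win.row, win.col) == (0, 0)

    def test_all_dark_raises_no_candidate(self):
        img = np.zeros((250, 250), np.uint8)
        with pytest.raises(StageError, match="no candidate"):
            locate_target(img, _ConstantModel(), WindowScanParams())
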