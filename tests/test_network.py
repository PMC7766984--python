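import itertools

import numpy as np
import pytest

from medfuse._conv import SELU_ALPHA, SELU_LAMBDA, conv3x3, selu
from medfuse.metrics import gaussian_kernel
from medfuse.network import (
    ArchitectureError,
    FeatureStack,
    NetParams,
    decode,
    encode,
    init_params,
)
from medfuse.training import TrainConfig, _batch_loss_and_grads

TINY = {"c1": 3, "cidn": 3, "d1": 3, "d2": 2}


class TestSelu:
    def test_zero(self):
        assert selu(np.array(0.0)) == 0.0

    def test_positive_branch_scales(self):
        assert selu(np.array(1.0)) == pytest.approx(1.0507009873554805)

    def test_negative_saturation(self):
        limit = -SELU_LAMBDA * SELU_ALPHA  # ~ -1.7581
        assert selu(np.array(-50.0)) == pytest.approx(limit, abs=1e-9)

    def test_continuous_at_origin(self):
        eps = 1e-9
        assert abs(selu(np.array(eps)) - selu(np.array(-eps))) < 1e-8


class TestConv:
    def test_matches_brute_force_sliding_window(self, rng):
        x = rng.normal(size=(1, 1, 5, 5))
        k = rng.normal(size=(1, 1, 3, 3))
        y = conv3x3(x, k, np.array([0.25]))
        xp = np.pad(x[0, 0], 1)
        for i in range(5):
            for j in range(5):
                ref = (xp[i : i + 3, j : j + 3] * k[0, 0]).sum() + 0.25
                assert y[0, 0, i, j] == pytest.approx(ref, abs=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv3x3(rng.normal(size=(1, 2, 4, 4)), rng.normal(size=(1, 3, 3, 3)), np.zeros(1))


class TestEncodeDecode:
    def test_shape_preserved_arbitrary_size(self, tiny_params):
        img = np.random.default_rng(0).random((17, 23))
        stack = encode(img, tiny_params)
        assert stack.spatial_shape == (17, 23)
        assert stack.n == tiny_params.encoder_out_channels
        out = decode(stack, tiny_params)
        assert out.shape == (17, 23)

    def test_zero_parameters_give_zero_features_and_half_output(self, rng):
        p = init_params(seed=0, widths=TINY)
        zeroed = NetParams(
            {n: (np.zeros_like(k), np.zeros_like(b)) for n, (k, b) in p.layers.items()},
            arch=dict(p.arch),
        )
        img = rng.random((9, 9))
        stack = encode(img, zeroed)
        np.testing.assert_array_equal(stack.maps, 0.0)
        out = decode(stack, zeroed)
        np.testing.assert_array_equal(out, 0.5)

    def test_decoder_output_in_open_unit_interval(self, tiny_params, rng):
        stack = encode(rng.random((31, 9)), tiny_params)
        out = decode(stack, tiny_params)
        assert out.shape == (31, 9)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_translation_covariance_in_interior(self, tiny_params, rng):
        img = rng.random((20, 20))
        shifted = np.roll(img, 1, axis=1)
        f0 = encode(img, tiny_params).maps
        f1 = encode(shifted, tiny_params).maps
        # compare interior crops: responses shift with the input
        np.testing.assert_allclose(
            f1[:, 5:-5, 6:-4], f0[:, 5:-5, 5:-5], atol=1e-10
        )

    def test_too_small_input_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            encode(np.zeros((4, 4)), tiny_params)

    def test_wrong_stack_width_rejected(self, tiny_params):
        bad = FeatureStack(np.zeros((tiny_params.encoder_out_channels + 1, 9, 9)))
        with pytest.raises(ArchitectureError):
            decode(bad, tiny_params)


class TestParams:
    def test_init_deterministic(self):
        a = init_params(seed=7)
        b = init_params(seed=7)
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name][0], b.layers[name][0])

    def test_serialization_round_trip_bit_identical(self, tmp_path, rng):
        p = init_params(seed=3, widths=TINY)
        path = tmp_path / "weights.npz"
        p.save(path)
        q = NetParams.load(path)
        assert q.arch == p.arch
        img = rng.random((12, 12))
        np.testing.assert_array_equal(encode(img, p).maps, encode(img, q).maps)

    def test_inconsistent_wiring_rejected(self):
        p = init_params(seed=0, widths=TINY)
        layers = dict(p.layers)
        k, b = layers["d1"]
        layers["d1"] = (k[:, :-1], b)  # break the fused-stack input width
        with pytest.raises(ArchitectureError):
            NetParams(layers, arch=dict(p.arch))


class TestBackprop:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """End-to-end check of the hand-derived backward pass."""
        params = init_params(seed=2, widths=TINY)
        cfg = TrainConfig(alpha=2.0, beta=1.0)
        kernel = gaussian_kernel(11, 1.5)
        x = rng.random((2, 1, 12, 12))
        _, grads = _batch_loss_and_grads(params, x, cfg, kernel)

        def loss():
            value, _ = _batch_loss_and_grads(params, x, cfg, kernel)
            return value

        h = 1e-6
        for name in ("c1", "cidn2", "d1", "d3"):
            kk, _ = params.layers[name]
            gk, _ = grads[name]
            step = max(1, kk.size // 4)
            for idx in itertools.islice(np.ndindex(kk.shape), 0, None, step):
                old = kk[idx]
                kk[idx] = old + h
                lp = loss()
                kk[idx] = old - h
                lm = loss()
                kk[idx] = old
                numeric = (lp - lm) / (2 * h)
                assert gk[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)
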