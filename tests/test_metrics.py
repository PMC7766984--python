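import numpy as np
import pytest

from medfuse import metrics as M


@pytest.fixture
def img(rng):
    return rng.random((32, 32))


class TestEntropy:
    def test_constant_zero(self):
        assert M.entropy_EN(np.full((8, 8), 0.4)) == 0.0

    def test_two_equiprobable_levels(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        assert M.entropy_EN(img) == pytest.approx(1.0)

    def test_uniform_ramp_saturates_eight_bits(self):
        img = (np.arange(256) / 255.0).reshape(16, 16)
        assert M.entropy_EN(img) == pytest.approx(8.0)


class TestCrossEntropy:
    def test_identical_triple_is_zero(self, img):
        assert M.cross_entropy_CE(img, img, img) == 0.0

    def test_symmetric_divergence(self, rng):
        p = M._hist_prob(rng.random((16, 16)), 256)
        q = M._hist_prob(rng.random((16, 16)), 256)
        assert M._sym_divergence(p, q) == pytest.approx(M._sym_divergence(q, p))

    def test_nonnegative(self, rng):
        a, b, f = (rng.random((16, 16)) for _ in range(3))
        assert M.cross_entropy_CE(a, b, f) >= 0.0

    def test_survey_default_weights(self):
        assert M.ETA_A == 0.7 and M.ETA_B == 0.3


class TestRmse:
    def test_identical_triple_zero(self, img):
        assert M.rmse(img, img, img) == 0.0

    def test_constant_offset_closed_form(self, rng):
        a = rng.uniform(0.2, 0.8, size=(10, 10))
        f = a + 0.1
        assert M.rmse(a, f, f) == pytest.approx(0.05, abs=1e-12)


class TestAvgGradient:
    def test_constant_zero(self):
        assert M.avg_gradient(np.full((5, 5), 0.3)) == 0.0

    def test_horizontal_ramp(self):
        s = 0.02
        img = np.tile(np.arange(10) * s, (10, 1))
        assert M.avg_gradient(img) == pytest.approx(s / np.sqrt(2), abs=1e-12)

    def test_high_frequency_pattern_increases_sharpness(self):
        flat = np.full((12, 12), 0.5)
        pattern = flat.copy()
        pattern[::2, ::2] += 0.2
        assert M.avg_gradient(pattern) > M.avg_gradient(flat)


class TestSsim:
    def test_self_similarity_is_one(self, img):
        assert M.ssim(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self, rng):
        x, y = rng.random((20, 20)), rng.random((20, 20))
        assert M.ssim(x, y) == pytest.approx(M.ssim(y, x), abs=1e-12)

    def test_mean_shift_penalized(self, img):
        assert M.ssim(img, np.clip(img + 0.5, 0, 1)) < 1.0

    def test_agrees_with_skimage(self, rng):
        from skimage.metrics import structural_similarity

        x = rng.random((40, 40))
        y = np.clip(x + 0.1 * rng.normal(size=(40, 40)), 0, 1)
        ref = structural_similarity(
            x,
            y,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            win_size=11,
        )
        assert M.ssim(x, y) == pytest.approx(ref, abs=1e-10)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            M.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestQ0Family:
    def test_q0_self_is_one(self, img):
        assert M.q0(img, img) == pytest.approx(1.0, abs=1e-9)

    def test_q0_anticorrelation_negative(self, rng):
        a = (rng.random((16, 16)) > 0.5).astype(float)
        assert M.q0(a, 1.0 - a) < 0.0

    def test_qabf_identity(self, img):
        assert M.qabf(img, img, img) == pytest.approx(1.0, abs=1e-9)

    def test_qabf_collapses_to_q0_when_sources_equal(self, rng):
        a = rng.random((16, 16))
        f = rng.random((16, 16))
        assert M.qabf(a, a, f) == pytest.approx(M.q0(a, f), abs=1e-9)

    def test_qw_identity_and_bounds(self, rng):
        a = rng.random((16, 16))
        assert M.qw(a, a, a) == pytest.approx(1.0, abs=1e-9)
        for _ in range(5):
            x, y, z = (rng.random((16, 16)) for _ in range(3))
            assert -1.0 - 1e-9 <= M.qw(x, y, z) <= 1.0 + 1e-9

    def test_qe_exponent_collapse(self, rng):
        a, b, f = (rng.random((20, 20)) for _ in range(3))
        assert M.qe(a, b, f, alpha_edge=0.0) == M.qw(a, b, f)
        edges = [M.gradient_magnitude(x) for x in (a, b, f)]
        assert M.qe(a, b, f, alpha_edge=1.0) == M.qw(*edges)

    def test_qe_identity(self, img):
        assert M.qe(img, img, img) == pytest.approx(1.0, abs=1e-9)


class TestFmi:
    def test_identity_triple_doubles_feature_entropy(self, rng):
        a = rng.random((32, 32))
        g = M.gradient_magnitude(a)
        h, _ = np.histogram(g, bins=64)
        p = h / h.sum()
        ent = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert M.fmi(a, a, a) == pytest.approx(2.0 * ent, abs=1e-9)

    def test_independent_noise_has_negligible_mi(self):
        rng = np.random.default_rng(77)
        x = rng.random((256, 256))
        y = rng.random((256, 256))
        term = M.mutual_information(M.gradient_magnitude(x), M.gradient_magnitude(y))
        assert term <= 0.05


class TestVif:
    def test_identity(self, rng):
        x = rng.random((64, 64))
        assert M.vif(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_blur_loses_information(self, rng):
        from scipy.ndimage import gaussian_filter

        x = rng.random((64, 64))
        assert M.vif(x, gaussian_filter(x, 2.0)) < 1.0

    def test_noise_monotone_degradation(self, rng):
        x = rng.random((64, 64))
        noisy = np.clip(x + 0.05 * rng.normal(size=x.shape), 0, 1)
        assert M.vif(x, noisy) < M.vif(x, x)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            M.vif(np.zeros((16, 16)), np.zeros((16, 16)))


class TestEvaluateAll:
    def test_identity_triple_key_values(self, rng):
        a = rng.random((64, 64))
        rep = M.evaluate_all(a, a, a)
        assert rep.ssim == pytest.approx(1.0, abs=1e-12)
        assert rep.rmse == 0.0
        assert rep.ce == 0.0
        assert rep.qabf == pytest.approx(1.0, abs=1e-9)
        assert rep.qw == pytest.approx(1.0, abs=1e-9)
        assert rep.qe == pytest.approx(1.0, abs=1e-9)
        assert rep.vif == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_and_echoes_params(self, rng):
        a, b, f = (rng.random((48, 48)) for _ in range(3))
        r1 = M.evaluate_all(a, b, f)
        r2 = M.evaluate_all(a, b, f)
        assert r1.to_dict() == r2.to_dict()
        assert r1.params["eta_a"] == 0.7
        assert r1.params["q0_win"] == 8
        assert set(r1.to_dict()) == set(M.MetricReport.NAMES)
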