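"""Blind and linear spectral unmixing, backgrounds, diagnostics."""

import numpy as np
import pytest

from cyclescope.unmixing import (
    BackgroundModel,
    channel_proportions,
    crosstalk_correlation,
    estimate_leakage_blind,
    estimate_leakage_linear,
    mutual_information,
    subtract_background,
    unmix,
)
from cyclescope.synthetic import PhantomSpec, make_phantom


def phantom_pair(x_true: float, shape=(256, 256), seed=9,
                 noise_sd: float = 0.0):
    """Independent source/target scenes with known leakage x_true."""
    m = np.eye(2)
    m[1, 0] = x_true
    spec = PhantomSpec(shape=shape, n_channels=2,
                       structures=("blobs", "rings"),
                       mixing_matrix=m, background_level=0.0,
                       noise_sd=noise_sd, rng_seed=seed)
    ph = make_phantom(spec)
    Di = ph.observed[0].astype(float)
    Dj = ph.observed[1].astype(float)
    return Di, Dj, ph


class TestBackground:
    def test_mode_plus_sd_level(self):
        rng = np.random.default_rng(0)
        img = np.full((100, 100), 100.0)
        img[:20] += rng.integers(0, 40, (20, 100))
        model = BackgroundModel.from_image(img)
        vals = img.ravel()
        counts = np.bincount(np.rint(vals).astype(int))
        expected = counts.argmax() + vals.std()
        assert model.global_level == pytest.approx(expected)
        out = subtract_background(img, model)
        assert out.min() == 0.0
        assert np.all(out == np.maximum(img - expected, 0))

    def test_zero_background_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        model = BackgroundModel("mode_plus_sd", global_level=0.0)
        assert np.array_equal(subtract_background(img, model), img)

    def test_all_below_level_clips_to_zero(self):
        img = np.full((8, 8), 5.0)
        model = BackgroundModel("mode_plus_sd", global_level=10.0)
        assert np.all(subtract_background(img, model) == 0)

    def test_reference_image_variant(self):
        img = np.full((8, 8), 30.0)
        ref = np.full((8, 8), 12.0)
        model = BackgroundModel("reference_image", reference=ref)
        assert np.all(subtract_background(img, model) == 18.0)
        with pytest.raises(ValueError, match="register"):
            subtract_background(np.zeros((4, 4)), model)


class TestMutualInformation:
    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1000, (256, 256))
        b = rng.uniform(0, 1000, (256, 256))
        # plug-in estimator bias ~ (bins-1)^2 / (2N) nats ~ 0.03
        assert mutual_information(a, b) < 0.1

    def test_self_information_equals_entropy(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1000, (128, 128))
        hist, _ = np.histogram(a, bins=64)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(a, a) == pytest.approx(entropy, rel=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 100, (64, 64))
        b = a * 0.5 + rng.uniform(0, 50, (64, 64))
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(b, a), rel=1e-9)

    def test_nonnegative_and_mask(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 10, (32, 32))
        b = rng.uniform(0, 10, (32, 32))
        mask = np.zeros((32, 32), bool)
        mask[:16] = True
        assert mutual_information(a, b, mask=mask) >= 0
        with pytest.raises(ValueError):
            mutual_information(a, b, mask=np.zeros((32, 32), bool))


class TestBlindEstimator:
    def test_recovers_known_leakage(self):
        Di, Dj, _ = phantom_pair(0.30)
        est = estimate_leakage_blind(Di, Dj)
        assert 0.25 <= est.x <= 0.35

    def test_no_crosstalk_gives_near_zero(self):
        Di, Dj, _ = phantom_pair(0.0)
        est = estimate_leakage_blind(Di, Dj)
        assert est.x <= 0.05

    def test_degenerate_single_point_grid(self):
        Di, Dj, _ = phantom_pair(0.3, shape=(64, 64))
        est = estimate_leakage_blind(Di, Dj, x_grid=np.array([0.0]))
        assert est.x == 0.0 and est.warning

    def test_monotone_profile_returns_boundary_with_warning(self):
        Di, Dj, _ = phantom_pair(0.3)
        with pytest.warns(UserWarning, match="monotone"):
            est = estimate_leakage_blind(Di, Dj,
                                         x_grid=np.linspace(0.5, 2.0, 16))
        assert est.x in (0.5, 2.0)
        assert est.warning


class TestLinearEstimator:
    def test_exact_on_noiseless_line(self):
        Di, _, _ = phantom_pair(0.0)
        Dj = 0.4 * Di
        est = estimate_leakage_linear(Di, Dj)
        assert est.x == pytest.approx(0.4, abs=1e-12)

    def test_noisy_line_within_sampling_error(self):
        rng = np.random.default_rng(6)
        Di = rng.uniform(0, 1000, 10_000)
        Dj = 0.4 * Di + rng.normal(0, 20, 10_000)
        est = estimate_leakage_linear(Di, Dj)
        assert est.x == pytest.approx(0.40, abs=0.02)

    def test_uncorrelated_near_zero(self):
        rng = np.random.default_rng(7)
        Di = rng.uniform(0, 1000, 50_000)
        Dj = rng.uniform(0, 1000, 50_000)
        est = estimate_leakage_linear(Di, Dj - Dj.mean() + 0.0)
        # slope of uncorrelated data ~ mean(Dj)/mean-scale; use centered Dj
        assert abs(est.x) < 0.05 or est.x == 0.0

    def test_zero_source_rejected(self):
        with pytest.raises(ValueError):
            estimate_leakage_linear(np.zeros(100), np.ones(100))


class TestUnmix:
    def test_x_zero_is_bit_exact_identity(self):
        Dj = np.arange(12, dtype=np.uint16).reshape(3, 4)
        assert unmix(Dj, np.ones_like(Dj), 0.0) is Dj

    def test_true_x_decorrelates_channels(self):
        Di, Dj, _ = phantom_pair(0.30)
        r_pre = crosstalk_correlation(Di, Dj, background_level=10,
                                      rng_seed=0)
        un = unmix(Dj, Di, 0.30)
        r_post = crosstalk_correlation(Di, un, background_level=10,
                                       rng_seed=0)
        assert r_pre > 0.15
        assert abs(r_post) < 0.1

    def test_oversubtraction_detectable_before_clipping(self):
        Di, Dj, _ = phantom_pair(0.05)
        raw = unmix(Dj, Di, 2.0, clip_negative=False)
        assert (raw < 0).mean() > 0.01
        assert unmix(Dj, Di, 2.0).min() == 0.0

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            unmix(np.zeros((2, 2)), np.zeros((2, 2)), -0.1)


class TestProportionsAndCorrelation:
    def test_single_channel_pixel(self):
        px = np.array([[100.0, 0, 0, 0], [50, 50, 0, 0]])
        props, keep = channel_proportions(px, primary_index=0)
        assert np.array_equal(props[0], [1, 0, 0, 0])
        assert np.array_equal(props[1], [0.5, 0.5, 0, 0])

    def test_rows_sum_to_one_and_zero_pixels_excluded(self):
        rng = np.random.default_rng(8)
        px = rng.uniform(0, 100, (500, 4))
        px[:50] = 0.0
        props, keep = channel_proportions(px, primary_index=0,
                                          background_level=0.0)
        assert np.allclose(props.sum(axis=1), 1.0)
        assert keep.sum() == props.shape[0] <= 450

    def test_spillover_shows_in_adjacent_channel_proportion(self):
        # singleplex source with 0.3 leakage into the adjacent channel
        Di, Dj, _ = phantom_pair(0.30)
        stack = np.stack([Di, Dj, np.zeros_like(Di), np.zeros_like(Di)])
        props, _ = channel_proportions(stack, primary_index=0,
                                       background_level=50.0)
        mean_props = props.mean(axis=0)
        assert mean_props[0] > 0.6            # mass in the primary channel
        assert mean_props[1] > 0.15           # visible spillover

    def test_identical_images_give_r_one(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(10, 100, (200, 200))
        assert crosstalk_correlation(a, a, rng_seed=0) == pytest.approx(1.0)

    def test_independent_noise_r_below_null_bound(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(10, 100, (200, 200))
        b = rng.uniform(10, 100, (200, 200))
        assert abs(crosstalk_correlation(a, b, rng_seed=0)) < 0.05

    def test_insufficient_pixels_warns_and_samples_all(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(10, 100, (20, 20))
        with pytest.warns(UserWarning, match="sampling all"):
            crosstalk_correlation(a, a, n_sample=10_000, rng_seed=0)


@pytest.mark.parametrize("x_true", [0.1, 0.6])
def test_blind_and_linear_agree(x_true):
    """The two estimators give similar leakage on the same phantom."""
    Di, Dj, ph = phantom_pair(x_true)
    blind = estimate_leakage_blind(Di, Dj)
    pure_i = ph.pure[0]
    pure_leaked = ph.pure[1] * 0 + x_true * pure_i  # singleplex reference
    linear = estimate_leakage_linear(pure_i, pure_leaked)
    assert abs(blind.x - linear.x) <= 0.1
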