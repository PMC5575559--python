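import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carrierscope import (
    AnalysisConfig,
    DetectedCircle,
    GrayImage,
    confluence_on_carrier,
    local_std_map,
    segment_confluence,
)
from conftest import window_std_oracle


class TestLocalStdMap:
    def test_constant_image_gives_zero_map(self):
        m = local_std_map(np.full((40, 40), 128.0), 15, 0.93)
        assert np.all(m == 0.0)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            local_std_map(np.zeros((10, 10)), 15, 0.93)

    def test_split_window_matches_direct_population_std(self):
        # 15x15 window: half 0s, half-plus-one-row 255s along a 1-D split.
        img = np.zeros((15, 15))
        img[:8, :] = 255.0
        expected = np.std(img)  # direct per-window population std
        m = local_std_map(img, 15, 0.93)
        assert m[7, 7] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_window_oracle_stride1(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (64, 64)).astype(float)
        m = local_std_map(img, 15, 0.93)  # 93% overlap => stride 1
        assert np.abs(m - window_std_oracle(img, 15, stride=1)).max() < 1e-9

    def test_matches_oracle_at_coarser_stride(self, rng):
        img = rng.integers(0, 256, (50, 47)).astype(float)
        # overlap 0.5 with kernel 15 -> stride round(7.5) = 8
        m = local_std_map(img, 15, 0.5)
        assert np.abs(m - window_std_oracle(img, 15, stride=8)).max() < 1e-9

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        img = np.random.default_rng(seed).uniform(0, 255, (32, 32))
        m = local_std_map(img, 7, 0.9)
        assert np.abs(m - window_std_oracle(img, 7, stride=1)).max() < 1e-9


class TestSegmentConfluence:
    def test_constant_image_is_zero_percent_with_warning(self):
        img = GrayImage(np.full((64, 64), 77.0))
        with pytest.warns(UserWarning, match="featureless"):
            res = segment_confluence(img)
        assert res.confluence_pct == 0.0
        assert res.sigma_image == 0.0

    def test_pure_high_amplitude_noise_is_fully_confluent(self, rng):
        img = GrayImage(rng.integers(0, 256, (64, 64)).astype(float))
        res = segment_confluence(img)
        assert res.confluence_pct == 100.0

    def test_constant_mode_uses_configured_threshold(self, rng):
        cfg = AnalysisConfig(constant_threshold=0.4 * 21.1)
        img = GrayImage(rng.integers(0, 256, (64, 64)).astype(float))
        res = segment_confluence(img, cfg, mode="constant")
        assert res.threshold_used == pytest.approx(8.44)

    def test_adaptive_threshold_is_factor_times_sigma(self, rng):
        img = GrayImage(rng.integers(0, 256, (64, 64)).astype(float))
        res = segment_confluence(img)
        assert res.threshold_used == pytest.approx(0.35 * np.std(img.pixels))

    def test_confluence_equals_mask_fraction(self, rng):
        px = np.full((64, 64), 100.0)
        px[:, :20] = rng.integers(0, 256, (64, 20))
        res = segment_confluence(GrayImage(px))
        assert res.confluence_pct == pytest.approx(
            100.0 * res.mask.sum() / res.mask.size)
        assert 0.0 <= res.confluence_pct <= 100.0

    def test_adaptive_mode_invariant_to_affine_rescaling(self, rng):
        px = np.full((64, 64), 40.0)
        px[20:50, 10:40] = rng.integers(0, 140, (30, 30))
        base = segment_confluence(GrayImage(px))
        scaled = segment_confluence(GrayImage(1.5 * px + 20.0))
        assert scaled.confluence_pct == pytest.approx(base.confluence_pct)
        assert np.array_equal(scaled.mask, base.mask)

    def test_lower_factor_never_decreases_confluence(self, rng):
        px = np.full((64, 64), 100.0)
        px[10:40, 10:40] = rng.integers(0, 256, (30, 30))
        img = GrayImage(px)
        pcts = [
            segment_confluence(
                img, AnalysisConfig(confluence_threshold_factor=f)
            ).confluence_pct
            for f in (0.6, 0.45, 0.35, 0.2, 0.1)
        ]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))

    def test_unknown_mode_rejected(self, rng):
        img = GrayImage(rng.integers(0, 256, (32, 32)).astype(float))
        with pytest.raises(ValueError):
            segment_confluence(img, mode="other")


def _textured_disk_image(rng, r=220, size=560, textured="none"):
    """A disk on flat background; `textured` = none | full | half."""
    px = np.full((size, size), 40.0)
    yy, xx = np.mgrid[0:size, 0:size]
    center = size // 2
    inside = (yy - center) ** 2 + (xx - center) ** 2 <= r * r
    px[inside] = 90.0
    if textured == "full":
        px[inside] += rng.normal(0, 45, inside.sum())
    elif textured == "half":
        half = inside & (xx >= center)
        px[half] += rng.normal(0, 45, half.sum())
    circle = DetectedCircle(center, center, r, score=1.0)
    return GrayImage(np.clip(px, 0, 255)), circle, inside


class TestConfluenceOnCarrier:
    def test_uniform_disk_is_zero_percent(self, rng):
        img, circle, _ = _textured_disk_image(rng, r=60, size=160)
        with pytest.warns(UserWarning, match="featureless"):
            res = confluence_on_carrier(img, circle)
        assert res.confluence_pct == 0.0

    def test_fully_textured_disk_is_hundred_percent(self, rng):
        img, circle, _ = _textured_disk_image(rng, r=60, size=160,
                                              textured="full")
        res = confluence_on_carrier(img, circle)
        assert res.confluence_pct == 100.0

    def test_half_textured_disk_near_fifty_percent(self, rng):
        img, circle, _ = _textured_disk_image(rng, textured="half")
        res = confluence_on_carrier(img, circle)
        # kernel-edge effects dilate the textured half slightly
        assert res.confluence_pct == pytest.approx(50.0, abs=5.0)

    def test_matches_per_window_oracle_inside_circle(self, rng):
        img, circle, _ = _textured_disk_image(rng, r=40, size=120,
                                              textured="half")
        cfg = AnalysisConfig()
        res = confluence_on_carrier(img, circle, cfg)
        from carrierscope import crop_to_circle
        from scipy.ndimage import distance_transform_edt
        crop = crop_to_circle(img, circle, margin_px=cfg.confluence_kernel_px)
        # oracle: any fully-in-circle window; uncovered in-circle pixels
        # inherit the nearest covered pixel's value
        px, inside, k = crop.image.pixels, crop.mask, 15
        stds = np.full(px.shape, -np.inf)
        for i in range(px.shape[0] - k + 1):
            for j in range(px.shape[1] - k + 1):
                if inside[i:i + k, j:j + k].all():
                    s = np.std(px[i:i + k, j:j + k])
                    stds[i:i + k, j:j + k] = np.maximum(
                        stds[i:i + k, j:j + k], s)
        covered = np.isfinite(stds)
        _, (ir, ic) = distance_transform_edt(~covered, return_indices=True)
        stds = stds[ir, ic]
        expected = (stds >= res.threshold_used) & inside
        assert np.array_equal(res.mask.astype(bool), expected)
        assert res.confluence_pct == pytest.approx(
            100.0 * expected.sum() / inside.sum())

    def test_circle_outside_image_rejected(self, rng):
        img, _, _ = _textured_disk_image(rng, r=40, size=120)
        far = DetectedCircle(500.0, 500.0, 40.0, score=1.0)
        with pytest.raises(ValueError):
            confluence_on_carrier(img, far)
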