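"""Unit and property tests for the two-stage adaptive gamma transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfseg.gamma import (
    GrayscaleImage,
    adaptive_gamma,
    apply_gamma,
    compute_beta,
    compute_cdf,
    compute_gamma,
    enhance_two_stage,
    fixed_gamma,
    histogram_equalization,
    quantile_points,
)


def _rank_quantile(values: np.ndarray, q: float) -> float:
    """Sorting oracle: smallest data value whose empirical CDF reaches q."""
    v = np.sort(values.ravel())
    k = int(np.ceil(q * v.size)) - 1
    return float(v[max(k, 0)])


class TestCdf:
    def test_constant_image_step_cdf(self):
        prof = compute_cdf(GrayscaleImage(np.full((8, 8), 0.5)))
        below = prof.cdf[prof.support < 0.5]
        assert np.all(below == 0.0)
        assert prof.cdf[np.searchsorted(prof.support, 0.5)] == 1.0

    def test_four_pixel_counts(self):
        img = GrayscaleImage(np.array([[0.1, 0.2], [0.3, 0.4]]))
        prof = compute_cdf(img)
        # CDF at 0.25 equals count(values <= 0.25)/4 = 0.5
        k = np.searchsorted(prof.support, 0.25)
        assert prof.cdf[k] == pytest.approx(0.5)

    @pytest.mark.parametrize("n_bins", [64, 256, 1024])
    def test_matches_sorting_oracle_at_every_bin(self, rng, n_bins):
        values = rng.uniform(0, 1, (32, 32))
        prof = compute_cdf(GrayscaleImage(values), n_bins=n_bins)
        flat = np.sort(values.ravel())
        for edge, c in zip(prof.support[:: max(n_bins // 16, 1)], prof.cdf[:: max(n_bins // 16, 1)]):
            oracle = np.searchsorted(flat, edge, side="right") / flat.size
            assert c == pytest.approx(oracle, abs=1.0 / flat.size)

    def test_cdf_monotone_ends_at_one(self, rng):
        prof = compute_cdf(GrayscaleImage(rng.uniform(0, 1, (10, 10))))
        assert np.all(np.diff(prof.cdf) >= 0)
        assert prof.cdf[-1] == 1.0


class TestQuantiles:
    def test_uniform_image_quantiles(self, rng):
        values = rng.uniform(0, 1, (128, 128))
        x0, x1 = quantile_points(compute_cdf(GrayscaleImage(values)))
        assert x0 == pytest.approx(0.5, abs=0.02)
        assert x1 == pytest.approx(0.75, abs=0.02)

    def test_degenerate_constant(self):
        x0, x1 = quantile_points(compute_cdf(GrayscaleImage(np.full((5, 5), 0.2))))
        assert x0 == x1 == pytest.approx(0.2, abs=1 / 256)

    def test_four_pixel_rank_rule(self):
        img = GrayscaleImage(np.array([[0.1, 0.2], [0.3, 0.4]]))
        x0, x1 = quantile_points(compute_cdf(img))
        assert x0 == pytest.approx(0.2, abs=1 / 256)
        assert x1 == pytest.approx(0.3, abs=1 / 256)

    def test_matches_rank_oracle_random(self, rng):
        for _ in range(25):
            values = rng.uniform(0, 1, (32, 32))
            x0, x1 = quantile_points(compute_cdf(GrayscaleImage(values)))
            assert x0 == pytest.approx(_rank_quantile(values, 0.5), abs=1 / 256)
            assert x1 == pytest.approx(_rank_quantile(values, 0.75), abs=1 / 256)
            assert x0 <= x1


class TestBetaGamma:
    @pytest.mark.parametrize(
        "x0,x1,expected", [(0.4, 0.6, 0.5), (0.2, 0.5, 1.5), (0.3, 0.3, 0.0)]
    )
    def test_beta_values(self, x0, x1, expected):
        assert compute_beta(x0, x1) == pytest.approx(expected)

    def test_beta_zero_floor(self):
        # all-black frame: epsilon guard instead of division by zero
        assert compute_beta(0.0, 0.5) == pytest.approx(0.5 / 1e-6)

    @pytest.mark.parametrize(
        "x0,beta,expected",
        [
            (0.5, 0.5, 1.0),
            (0.5, 2.0, 1.0),
            (0.3, 0.5, 0.8),
            (0.3, 2.0, 1.25),
            (0.8, 0.5, 1.0 / 0.7),
            (0.8, 2.0, 0.7),
        ],
    )
    def test_gamma_branches(self, x0, beta, expected):
        assert compute_gamma(x0, beta) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_regime_reciprocity(self, x0):
        g_low = compute_gamma(x0, beta=0.5)
        g_high = compute_gamma(x0, beta=2.0)
        assert g_high == pytest.approx(1.0 / g_low, abs=1e-12)
        assert g_low > 0 and g_high > 0

    def test_continuity_at_half(self):
        eps = 1e-9
        for beta in (0.5, 2.0):
            below = compute_gamma(0.5 - eps, beta)
            above = compute_gamma(0.5 + eps, beta)
            assert below == pytest.approx(above, abs=1e-6)
            assert compute_gamma(0.5, beta) == 1.0


class TestApplyGamma:
    def test_identity_exponent(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (6, 6)))
        assert np.array_equal(apply_gamma(img, 1.0).values, img.values)

    def test_square_root(self):
        out = apply_gamma(GrayscaleImage(np.array([[0.25]])), 0.5)
        assert out.values[0, 0] == pytest.approx(0.5)

    def test_endpoints_fixed(self):
        img = GrayscaleImage(np.array([[0.0, 1.0]]))
        for g in (0.3, 1.0, 2.5):
            assert np.array_equal(apply_gamma(img, g).values, img.values)

    @given(st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_and_bounded(self, g):
        v = np.linspace(0.01, 0.99, 50)
        out = apply_gamma(GrayscaleImage(v[None, :]), g).values[0]
        assert np.all(np.diff(out) > 0)
        assert out.min() >= 0 and out.max() <= 1


class TestEnhanceTwoStage:
    def test_constant_half_is_identity(self):
        img = GrayscaleImage(np.full((10, 10), 0.5))
        out, params = enhance_two_stage(img)
        assert params.gamma == 1.0
        assert np.array_equal(out.values, img.values)

    def test_dark_image_brightens(self, rng):
        # mass concentrated just below 0.5 with a tight upper quartile:
        # x0 < 0.5 and beta <= 1 select the brightening branch
        values = np.clip(rng.normal(0.35, 0.03, (64, 64)), 0.0, 1.0)
        img = GrayscaleImage(values)
        out, params = enhance_two_stage(img)
        assert params.beta <= 1
        assert params.gamma < 1
        assert out.values.mean() > img.values.mean()
        assert np.median(out.values) >= np.median(img.values)

    def test_high_contrast_selects_late_regime(self, rng):
        # dark background with a bright quartile: beta > 1 by the rank oracle
        values = np.concatenate(
            [np.full(3000, 0.15), np.full(1096, 0.9)]
        ) + rng.normal(0, 0.01, 4096)
        values = np.clip(values, 0, 1).reshape(64, 64)
        x0o = _rank_quantile(values, 0.5)
        x1o = _rank_quantile(values, 0.75)
        assert (x1o - x0o) / x0o > 1  # oracle confirms the regime
        _, params = enhance_two_stage(GrayscaleImage(values))
        assert params.beta > 1

    def test_deterministic(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (16, 16)))
        a, pa = enhance_two_stage(img)
        b, pb = enhance_two_stage(img)
        assert np.array_equal(a.values, b.values) and pa == pb


class TestBaselines:
    def test_fixed_gamma_identity(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (8, 8)))
        assert np.array_equal(fixed_gamma(img, 1.0).values, img.values)

    def test_equalized_cdf_near_diagonal(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (64, 64)))
        out = histogram_equalization(img)
        prof = compute_cdf(out)
        # rank oracle: the equalized CDF should track the diagonal
        keep = (prof.support > 0.05) & (prof.support < 0.95)
        assert np.abs(prof.cdf[keep] - prof.support[keep]).max() < 0.02

    def test_adaptive_baseline_always_early_branch(self, rng):
        # high-contrast input: two-stage picks beta>1, the one-regime
        # baseline still applies the beta<=1 formula
        values = np.clip(
            np.concatenate([np.full(3000, 0.15), np.full(1096, 0.9)])
            + rng.normal(0, 0.01, 4096), 0, 1,
        ).reshape(64, 64)
        img = GrayscaleImage(values)
        _, p2 = enhance_two_stage(img)
        _, p1 = adaptive_gamma(img)
        assert p2.beta > 1 and p1.beta > 1
        x0 = p1.x0
        expected = 0.5 + x0 if x0 <= 0.5 else 1 / (1.5 - x0)
        assert p1.gamma == pytest.approx(expected)
        assert p2.gamma == pytest.approx(1.0 / expected)
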