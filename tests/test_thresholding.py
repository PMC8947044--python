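import numpy as np
import pytest

import lfaquant as lq
from lfaquant.thresholding import (
    ConvergenceError,
    DegenerateImageError,
    MethodUnavailableError,
    LI_ZERO_SHIFT,
)


# --------------------------------------------------------------------------
# Independent brute-force oracles (naive loops, no shared code paths)
# --------------------------------------------------------------------------

def brute_force_otsu(pixels, n_bins=256):
    counts, _ = np.histogram(pixels, bins=n_bins, range=(0, 1))
    centers = (np.arange(n_bins) + 0.5) / n_bins
    best_score, best_t = -1.0, None
    total = counts.sum()
    for k in range(n_bins - 1):  # split after bin k
        n0 = counts[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / n1
        score = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if score > best_score + 1e-15:
            best_score, best_t = score, (k + 1) / n_bins
    return best_t


def brute_force_triangle(pixels, n_bins=256):
    counts, _ = np.histogram(pixels, bins=n_bins, range=(0, 1))
    centers = (np.arange(n_bins) + 0.5) / n_bins
    nz = np.flatnonzero(counts)
    peak = int(np.argmax(counts))
    tail = int(nz[-1]) if (nz[-1] - peak) >= (peak - nz[0]) else int(nz[0])
    x1, y1 = peak, counts[peak]
    x2, y2 = tail, counts[tail]
    denom = np.hypot(x2 - x1, y2 - y1)
    best_d, best_t = -1.0, None
    for i in range(min(x1, x2), max(x1, x2) + 1):
        d = abs((y2 - y1) * (i - x1) - (x2 - x1) * (counts[i] - y1)) / denom
        if d > best_d + 1e-12:
            best_d, best_t = d, centers[i]
    return best_t


class TestHistogram:
    def test_single_value_one_bin(self):
        counts, centers = lq.histogram(np.full(4, 0.5))
        assert counts.sum() == 4
        assert np.count_nonzero(counts) == 1
        assert counts[128] == 4  # floor(0.5 * 256)

    def test_counts_conserved_and_boundary_rule(self, rng):
        px = rng.uniform(0, 1, 1000)
        counts, _ = lq.histogram(px)
        assert counts.sum() == 1000
        counts1, _ = lq.histogram(np.array([1.0, 0.999999]))
        assert counts1[255] == 2  # p = 1 goes to the last bin

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lq.histogram(np.empty(0))


class TestOtsu:
    def test_bimodal_split_between_modes(self):
        px = np.r_[np.full(100, 0.2), np.full(100, 0.8)]
        t = lq.threshold_otsu(px)
        assert 0.2 < t < 0.8
        assert (px <= t).sum() == 100 and (px > t).sum() == 100

    @pytest.mark.parametrize("case", ["uniform", "unbalanced", "beta"])
    def test_matches_brute_force_oracle(self, case, rng):
        if case == "uniform":
            px = rng.uniform(0, 1, 200)
        elif case == "unbalanced":
            px = np.r_[np.full(190, 0.1), np.full(10, 0.9)]
        else:
            px = rng.beta(2, 5, 300)
        assert lq.threshold_otsu(px) == pytest.approx(brute_force_otsu(px))

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            lq.threshold_otsu(np.full(50, 0.3))

    def test_close_to_skimage_reference(self, rng):
        from skimage.filters import threshold_otsu as sk_otsu
        px = rng.normal(0.5, 0.12, 2000).clip(0, 1)
        assert abs(lq.threshold_otsu(px) - sk_otsu(px, nbins=256)) <= 2 / 256


class TestLi:
    def test_two_level_closed_form(self):
        px = np.r_[np.full(40, 0.2), np.full(40, 0.8)]
        expected = (0.2 - 0.8) / (np.log(0.2) - np.log(0.8))
        t, n_iter = lq.threshold_li(px)
        assert t == pytest.approx(expected, abs=1e-6)
        assert t == pytest.approx(0.4328, abs=5e-5)
        assert n_iter <= 100

    def test_fixed_point_residual_below_tolerance(self, rng):
        for seed in range(10):
            px = np.random.default_rng(seed).beta(2, 3, 500)
            t, _ = lq.threshold_li(px, tol=1e-6)
            mu_low = px[px <= t].mean()
            mu_high = px[px > t].mean()
            residual = abs(t - (mu_low - mu_high) / (np.log(mu_low) - np.log(mu_high)))
            assert residual < 1e-6

    def test_symmetric_bimodal_threshold_below_center(self, rng):
        px = np.r_[rng.normal(0.3, 0.02, 500), rng.normal(0.7, 0.02, 500)].clip(0, 1)
        t, _ = lq.threshold_li(px)
        assert t <= 0.5  # log-mean pulls below the arithmetic midpoint

    def test_zero_pixels_handled_by_shift(self):
        px = np.r_[np.zeros(50), np.full(50, 0.6)]
        t, _ = lq.threshold_li(px)
        assert 0.0 < t < 0.6
        # result is reported on the original scale
        assert t < 0.6 - LI_ZERO_SHIFT

    def test_non_convergence_carries_last_threshold(self, rng):
        px = rng.uniform(0.2, 0.9, 300)
        with pytest.raises(ConvergenceError) as exc_info:
            lq.threshold_li(px, tol=0.0, max_iter=3)
        assert 0.0 < exc_info.value.last_threshold < 1.0


class TestQuantile:
    def test_median_of_five(self):
        px = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert lq.threshold_quantile(px, 0.5) == pytest.approx(0.3)

    def test_linear_interpolation_near_one(self):
        px = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert lq.threshold_quantile(px, 0.99) == pytest.approx(0.496)

    def test_constant_background(self):
        assert lq.threshold_quantile(np.full(10, 0.25), 0.3) == 0.25

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5])
    def test_probability_strictly_inside_unit_interval(self, q):
        with pytest.raises(ValueError):
            lq.threshold_quantile(np.array([0.1, 0.2]), q)


class TestTriangle:
    def test_exponential_decay_matches_oracle(self, rng):
        # counts proportional to exp(-bin/20), peak at bin 0
        probs = np.exp(-np.arange(256) / 20.0)
        px = (rng.choice(256, size=5000, p=probs / probs.sum()) + 0.5) / 256
        assert lq.threshold_triangle(px) == pytest.approx(brute_force_triangle(px))

    def test_mirror_symmetry(self, rng):
        px = rng.beta(1.5, 6, 4000)
        t_fwd = lq.threshold_triangle(px)
        t_rev = lq.threshold_triangle(1.0 - px)
        assert abs((1.0 - t_fwd) - t_rev) <= 1 / 256 + 1e-12

    def test_two_bin_histogram_threshold_between(self):
        px = np.r_[np.full(90, 0.1), np.full(10, 0.9)]
        t = lq.threshold_triangle(px)
        assert 0.1 < t < 0.9

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            lq.threshold_triangle(np.full(20, 0.7))


class TestOffset:
    @pytest.mark.parametrize("t,o,expected", [
        (0.4, 0.05, 0.45), (0.99, 0.05, 1.0), (0.3, 0.0, 0.3),
        (0.02, -0.1, 0.0),
    ])
    def test_offset_with_clipping(self, t, o, expected):
        assert lq.apply_offset(t, o) == pytest.approx(expected)


class TestExtraction:
    @pytest.fixture
    def simple_grid(self):
        # 4x1 image, L=2 grid: rows [0,1), [1,2), [2,4)
        px = np.array([[0.9], [0.9], [0.1], [0.1]])
        img = lq.RasterImage(px[..., None])
        grid = lq.build_grid(lq.GridSpec(lq.Rect(0, 0, 4, 1), 2, 1))
        return img, grid

    def test_mean_median_after_subtraction(self):
        px = np.array([[0.9, 0.9], [0.1, 0.1]])
        img = lq.RasterImage(px[..., None])
        grid = lq.build_grid(lq.GridSpec(lq.Rect(0, 0, 2, 2), 1, 1))
        (line,) = lq.extract_line_intensities(img, grid, 0, t=0.4)
        assert line.n_above == 2
        assert line.mean_signal == pytest.approx(0.5)
        assert line.median_signal == pytest.approx(0.5)

    def test_saturated_threshold_gives_zeros(self, simple_grid):
        img, grid = simple_grid
        lines = lq.extract_line_intensities(img, grid, 0, t=1.0)
        assert all(l.mean_signal == 0 and l.median_signal == 0 and l.n_above == 0
                   for l in lines)

    def test_lines_ordered_top_to_bottom_and_amplitude_monotone(self):
        spec = lq.StripSpec(amplitudes=np.array([[0.5, 0.2]]), sigma_noise=0.0)
        img, _, grid_spec = lq.render_strip_image(spec)
        grid = lq.build_grid(grid_spec)
        prepared = lq.prepare_image(img, lq.ThresholdSpec(inverted=True))
        l0, l1 = lq.extract_line_intensities(prepared, grid, 0, t=0.15)
        assert l0.line == 0 and l1.line == 1
        assert l0.mean_signal > l1.mean_signal

    def test_mean_signal_non_increasing_in_threshold_on_tight_grid(self):
        # the monotone guarantee applies to line cells drawn around the band
        spec = lq.StripSpec(seed=3, amplitudes=0.4)
        img, _, _ = lq.render_strip_image(spec)
        grid = lq.build_grid(spec.tight_grid_spec())
        prep = lq.prepare_image(img, lq.ThresholdSpec(inverted=True))
        for line in (0, 1):
            prev = np.inf
            for off in np.linspace(0.0, 0.3, 31):
                li = lq.extract_line_intensities(
                    prep, grid, 0, lq.apply_offset(0.15, off))[line]
                assert li.mean_signal <= prev + 1e-12
                prev = li.mean_signal


class TestPerStripPipeline:
    def test_quantile_unavailable_for_single_line_grid(self):
        img = lq.RasterImage(np.full((8, 8, 1), 0.5))
        grid = lq.build_grid(lq.GridSpec(lq.Rect(0, 0, 8, 8), 1, 1))
        with pytest.raises(MethodUnavailableError):
            lq.compute_threshold(img, grid, 0, lq.ThresholdSpec(method="quantile"))

    def test_quantile_uses_only_background_cells(self):
        spec = lq.StripSpec(sigma_noise=0.0)
        img, _, grid_spec = lq.render_strip_image(spec)
        grid = lq.build_grid(grid_spec)
        prepared = lq.prepare_image(img, lq.ThresholdSpec(method="quantile",
                                                          inverted=True))
        res = lq.compute_threshold(prepared, grid, 0,
                                   lq.ThresholdSpec(method="quantile",
                                                    inverted=True))
        # noise-free background is 1 - 0.85 up to the far Gaussian band tails
        assert res.threshold == pytest.approx(0.15, abs=1e-6)

    def test_inversion_duality(self):
        base = dict(amplitudes=0.4, sigma_noise=0.0, seed=11)
        dark = lq.StripSpec(polarity="dark_bands", background=0.8, **base)
        bright = lq.StripSpec(polarity="bright_bands", background=0.2, **base)
        img_d, _, gs = lq.render_strip_image(dark)
        img_b, _, _ = lq.render_strip_image(bright)
        grid = lq.build_grid(gs)
        spec_inv = lq.ThresholdSpec(method="otsu", inverted=True)
        spec_raw = lq.ThresholdSpec(method="otsu", inverted=False)
        res_d = lq.analyze_image(img_d, grid, spec_inv)
        res_b = lq.analyze_image(img_b, grid, spec_raw)
        # same geometry, no noise: the inverted dark image IS the bright image
        for (_, lines_d), (_, lines_b) in zip(res_d, res_b):
            for ld, lb in zip(lines_d, lines_b):
                assert ld.mean_signal == pytest.approx(lb.mean_signal, abs=1e-12)
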