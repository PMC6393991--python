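import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecmorph import (
    BinaryMask,
    DegenerateInputError,
    FractalConfig,
    ValidationError,
    box_counts,
    dyadic_epsilons,
    estimate_fractal_dimension,
    generate_reference_shape,
    geometric_epsilons,
    resistant_line_slope,
    select_linear_segment,
)

CARPET_D = math.log(8) / math.log(3)


def naive_box_count(grid: np.ndarray, eps: int) -> int:
    """Independent oracle: scan every grid box with explicit loops."""
    H, W = grid.shape
    n = 0
    for r0 in range(0, H, eps):
        for c0 in range(0, W, eps):
            if grid[r0:r0 + eps, c0:c0 + eps].any():
                n += 1
    return n


class TestBoxCounts:
    def test_filled_64_eps8(self):
        mask = generate_reference_shape("filled_square", 64)
        assert box_counts(mask, [8]) == [64]

    def test_single_pixel_any_eps(self):
        mask = generate_reference_shape("point", 64)
        assert box_counts(mask, [1, 2, 4, 8, 16]) == [1] * 5

    def test_horizontal_line(self):
        mask = generate_reference_shape("hline", 64)
        assert box_counts(mask, [4]) == [16]

    def test_empty_mask_degenerate(self):
        with pytest.raises(DegenerateInputError):
            box_counts(BinaryMask(grid=np.zeros((16, 16), bool)), [2])

    def test_oversized_eps_rejected(self):
        mask = generate_reference_shape("point", 16)
        with pytest.raises(ValidationError):
            box_counts(mask, [32])

    def test_agrees_with_naive_scanner(self, rng):
        """Exact equality with a double-loop oracle on random masks."""
        for _ in range(20):
            grid = rng.random((64, 64)) < rng.uniform(0.01, 0.5)
            if not grid.any():
                grid[0, 0] = True
            mask = BinaryMask(grid=grid)
            eps = [2, 4, 8, 16]
            assert box_counts(mask, eps) == [naive_box_count(grid, e) for e in eps]

    def test_counts_non_increasing_in_eps(self, rng):
        for _ in range(5):
            grid = rng.random((128, 128)) < 0.1
            grid[0, 0] = True
            counts = box_counts(BinaryMask(grid=grid), [2, 4, 8, 16, 32][::-1])
            assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestSelectLinearSegment:
    def test_collinear_points_select_full_range(self):
        pts = [(x, 2.0 * x + 1.0) for x in range(8)]
        assert select_linear_segment(pts, min_points=4) == (0, 8)

    def test_kink_selects_collinear_prefix(self):
        """First 6 points collinear, last 4 deviate strongly: brute-force R²
        enumeration must pick a window inside the first 6."""
        pts = [(float(x), 3.0 * x) for x in range(6)]
        pts += [(float(x), 3.0 * x + 50.0 * (x - 5) ** 2) for x in range(6, 10)]
        start, stop = select_linear_segment(pts, min_points=4)
        assert (start, stop) == (0, 6)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            select_linear_segment([(0, 0), (1, 1), (2, 2)], min_points=4)

    def test_min_points_floor(self):
        with pytest.raises(ValidationError):
            select_linear_segment([(x, x) for x in range(8)], min_points=3)


def oracle_resistant_slope(pts, max_iter=10, tol=1e-6):
    """Direct transcription of the three-group median rule, for cross-check."""
    pts = sorted(pts)
    n = len(pts)
    k = n // 3
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    xl = float(np.median(xs[:k]))
    xr = float(np.median(xs[n - k:]))
    slope = 0.0
    for _ in range(max_iter):
        resid = [y - slope * x for x, y in pts]
        d = (float(np.median(resid[n - k:])) - float(np.median(resid[:k]))) / (xr - xl)
        slope += d
        if abs(d) < tol:
            break
    return slope


class TestResistantLine:
    def test_exact_on_collinear(self):
        pts = [(x, 2.0 * x + 1.0) for x in range(9)]
        slope, _ = resistant_line_slope(pts)
        assert slope == pytest.approx(2.0, abs=1e-12)

    def test_immune_to_middle_third_outlier(self):
        pts = [(float(x), 2.0 * x + 1.0) for x in range(9)]
        pts[4] = (4.0, 500.0)  # gross outlier in the middle third
        slope, _ = resistant_line_slope(pts)
        assert slope == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_median_formula_on_noisy_data(self, rng):
        xs = np.arange(9, dtype=float)
        ys = xs + rng.normal(0, 0.3, 9)
        pts = list(zip(xs, ys))
        slope, _ = resistant_line_slope(pts)
        assert slope == pytest.approx(oracle_resistant_slope(pts), abs=1e-12)

    def test_identical_x_rejected(self):
        with pytest.raises(ValidationError):
            resistant_line_slope([(1.0, y) for y in range(5)])

    @given(
        a=st.floats(-5, 5), b=st.floats(-10, 10),
        n=st.integers(min_value=5, max_value=30),
    )
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_equals_ols_on_collinear_data(self, a, b, n):
        """On exactly collinear points the resistant slope is the OLS slope."""
        xs = np.arange(n, dtype=float)
        pts = [(x, a * x + b) for x in xs]
        slope, _ = resistant_line_slope(pts)
        assert slope == pytest.approx(a, abs=1e-9)


class TestEstimateDimension:
    def test_space_filling_square(self):
        fit = estimate_fractal_dimension(generate_reference_shape("filled_square", 1024))
        assert fit.dimension_D == pytest.approx(2.0, abs=0.02)
        assert fit.r_squared > 0.999

    def test_single_pixel(self):
        fit = estimate_fractal_dimension(generate_reference_shape("point", 128))
        assert fit.dimension_D == pytest.approx(0.0, abs=0.02)

    def test_line(self):
        fit = estimate_fractal_dimension(generate_reference_shape("hline", 512))
        assert fit.dimension_D == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet_triadic_ladder(self):
        """Level-4 carpet on its natural base-3 ladder follows the exact
        power law N(3^j) = 8^(4-j), so D = log 8 / log 3."""
        mask = generate_reference_shape("sierpinski_carpet", 81, level=4)
        ladder = geometric_epsilons(mask.shape, base=3)
        assert ladder == [81, 27, 9, 3, 1]
        counts = box_counts(mask, ladder)
        assert counts == [8 ** k for k in range(5)]
        fit = estimate_fractal_dimension(mask, FractalConfig(epsilons=tuple(ladder)))
        assert fit.dimension_D == pytest.approx(CARPET_D, abs=0.03)

    def test_empty_mask_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_fractal_dimension(BinaryMask(grid=np.zeros((64, 64), bool)))

    def test_dimension_in_admissible_range_on_random_masks(self, rng):
        for _ in range(10):
            grid = rng.random((128, 128)) < rng.uniform(0.02, 0.6)
            grid[64, 64] = True
            fit = estimate_fractal_dimension(BinaryMask(grid=grid))
            assert 0.0 <= fit.dimension_D <= 2.0

    @pytest.mark.parametrize(
        "shape,kwargs,ladder_base",
        [("disk", {"size": 128}, None), ("hline", {"size": 128}, None),
         ("sierpinski_carpet", {"size": 81, "level": 4}, 3)],
    )
    def test_scale_invariance_under_2x_upscale(self, shape, kwargs, ladder_base):
        """Nearest-neighbour 2× upscaling, with the box ladder scaled along
        with the mask, changes D by < 0.05."""
        mask = generate_reference_shape(shape, **kwargs)
        big = BinaryMask(grid=np.kron(mask.grid, np.ones((2, 2), bool)))
        la = (dyadic_epsilons(mask.shape) if ladder_base is None
              else geometric_epsilons(mask.shape, base=ladder_base))
        lb = [2 * e for e in la]
        fit_a = estimate_fractal_dimension(mask, FractalConfig(epsilons=tuple(la)))
        fit_b = estimate_fractal_dimension(big, FractalConfig(epsilons=tuple(lb)))
        assert abs(fit_a.dimension_D - fit_b.dimension_D) < 0.05

    def test_default_ladder_is_dyadic(self):
        assert dyadic_epsilons((1024, 1024)) == [256, 128, 64, 32, 16, 8, 4, 2]

    def test_audit_fields_consistent(self):
        fit = estimate_fractal_dimension(generate_reference_shape("disk", 256))
        assert len(fit.epsilons) == len(fit.counts) == len(fit.log_points)
        start, stop = fit.segment
        assert 0 <= start < stop <= len(fit.epsilons)
        assert 0.0 <= fit.r_squared <= 1.0
        assert fit.n_iterations >= 1
        assert fit.to_json()  # serializable
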