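import numpy as np
import pytest

from corticad import (
    CorticalMask,
    fit_border_polynomial,
    generate_phantom_pair,
    measure_side,
    upper_border,
    width_profile,
)
from corticad.morphometry import _cv_sse


def band_mask(top_row: int, thickness: int, shape=(128, 128)) -> CorticalMask:
    px = np.zeros(shape, dtype=np.uint8)
    px[top_row : top_row + thickness, :] = 1
    return CorticalMask(px)


class TestUpperBorder:
    def test_full_mask_border_at_row_zero(self):
        points = upper_border(CorticalMask(np.ones((32, 32), dtype=np.uint8)))
        assert points == [(c, 0) for c in range(32)]

    def test_horizontal_band(self):
        points = upper_border(band_mask(100, 20))
        assert points == [(c, 100) for c in range(128)]

    def test_empty_columns_omitted(self):
        px = np.zeros((32, 32), dtype=np.uint8)
        px[10:20, :] = 1
        px[:, 7] = 0
        points = upper_border(CorticalMask(px))
        assert all(c != 7 for c, _ in points)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            upper_border(CorticalMask(np.zeros((32, 32), dtype=np.uint8)))


class TestFitBorderPolynomial:
    def test_exact_quadratic_recovered(self):
        cols = np.arange(100)
        rows = 0.01 * cols**2 + 50
        curve = fit_border_polynomial(list(zip(cols, rows)), (1, 2, 3, 4, 5))
        assert curve.degree == 2
        assert curve.coefficients == pytest.approx((0.01, 0.0, 50.0), abs=1e-6)
        assert curve.sse == pytest.approx(0.0, abs=1e-9)

    def test_collinear_points_select_degree_one(self):
        cols = np.arange(60)
        rows = 0.5 * cols + 10
        curve = fit_border_polynomial(list(zip(cols, rows)), (1, 2, 3, 4, 5))
        assert curve.degree == 1

    def test_insufficient_points_raise(self):
        with pytest.raises(ValueError, match="at least"):
            fit_border_polynomial([(0, 1), (1, 2), (2, 3)], (5,))

    def test_selected_degree_never_beaten_by_rejected_candidate(self, rng):
        cols = np.arange(80)
        rows = 0.002 * cols**2 + 0.3 * cols + 20 + rng.normal(0, 1.0, 80)
        points = list(zip(cols, rows))
        candidates = (1, 2, 3, 4, 5)
        curve = fit_border_polynomial(points, candidates)
        c = np.array([c for c, _ in points], dtype=float)
        r = np.array([row for _, row in points], dtype=float)
        chosen = _cv_sse(c, r, curve.degree)
        for d in candidates:
            assert chosen <= _cv_sse(c, r, d) * (1 + 1e-9) + 1e-9


class TestWidthProfile:
    def test_flat_band_width(self):
        mask = band_mask(100, 20)
        curve = fit_border_polynomial(upper_border(mask), (1, 2, 3, 4, 5))
        profile = width_profile(mask, curve, margin_frac=0.1, step=1)
        widths = profile.widths
        assert np.all(np.abs(widths - 20.0) <= 0.5)
        assert profile.min_width <= profile.avg_width <= profile.max_width

    def test_tilted_band_measures_perpendicular_not_column_height(self, rotated_band):
        """For a 30-degree band of true thickness 20 the column height is
        ~23.1; the tangent-perpendicular construction must return ~20."""
        mask = rotated_band(30, 20)
        curve = fit_border_polynomial(upper_border(mask), (1, 2, 3, 4, 5))
        profile = width_profile(mask, curve, margin_frac=0.1, step=1)
        assert profile.avg_width == pytest.approx(20.0, abs=1.0)
        assert abs(profile.avg_width - 23.1) > 1.5

    @pytest.mark.parametrize("theta", [0, 10, 20, 30, 40])
    @pytest.mark.parametrize("thickness", [10, 20, 30])
    def test_rotated_rectangle_within_five_percent(self, rotated_band, theta, thickness):
        mask = rotated_band(theta, thickness)
        curve = fit_border_polynomial(upper_border(mask), (1, 2, 3, 4, 5))
        profile = width_profile(mask, curve, margin_frac=0.1, step=1)
        assert abs(profile.avg_width - thickness) / thickness <= 0.05

    def test_sparse_profile_raises(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[30:40, 10:16] = 1
        mask = CorticalMask(px)
        curve = fit_border_polynomial(upper_border(mask), (1, 2))
        with pytest.raises(ValueError, match="sparse"):
            # margin excludes nearly all of the 6-px domain
            width_profile(mask, curve, margin_frac=0.49, step=4)


class TestMeasureSide:
    def test_phantom_round_trip_within_ten_percent(self):
        rec = generate_phantom_pair("normal", seed=21)
        true_avg = rec.true_widths["right"][2]
        _, _, avg = measure_side(rec.right_roi, rec.right_mask)
        assert abs(avg - true_avg) / true_avg <= 0.10

    def test_constant_width_band_has_small_spread(self):
        rec = generate_phantom_pair("osteopenia", seed=8)
        mn, mx, avg = measure_side(rec.left_roi, rec.left_mask)
        assert mx - mn <= 2.0

    def test_single_column_mask_raises(self):
        px = np.zeros((64, 64), dtype=np.uint8)
        px[20:40, 30] = 1
        with pytest.raises(ValueError):
            measure_side(None, CorticalMask(px))

    def test_widths_ignore_gray_offset(self):
        rec = generate_phantom_pair("normal", seed=4)
        shifted = np.clip(rec.right_roi.pixels + 20, 0, 255)
        from corticad import RoiImage, Side

        roi2 = RoiImage(pixels=shifted, side=Side.RIGHT)
        assert measure_side(rec.right_roi, rec.right_mask) == measure_side(roi2, rec.right_mask)
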