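"""Unit and property tests for the image-derived assay statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biofilmquant as bq
from biofilmquant.exceptions import FormatError, GeometryError, ValidationError


class TestToGrayscale:
    def test_grayscale_passthrough(self):
        arr = np.arange(12, dtype=float).reshape(3, 4)
        assert np.array_equal(bq.to_grayscale(arr).pixels, arr)

    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 255, 255), 255.0),  # weights sum to 1
            ((100, 200, 50), 0.2126 * 100 + 0.7152 * 200 + 0.0722 * 50),
        ],
    )
    def test_luminance_weights(self, rgb, expected):
        img = np.tile(np.array(rgb, dtype=float), (2, 2, 1))
        assert bq.to_grayscale(img).pixels[0, 0] == pytest.approx(expected, abs=0.5)

    def test_bad_channel_count(self):
        with pytest.raises(FormatError):
            bq.to_grayscale(np.zeros((2, 2, 5)))


class TestExtractProfile:
    def test_constant_column(self):
        img = bq.GrayImage(np.full((10, 5), 42.0))
        prof = bq.extract_profile(img, bq.ProfileLine((2, 0), (2, 9)))
        assert np.allclose(prof.values, 42.0)
        assert prof.max_gray == 42.0
        assert prof.positions[0] == 0 and prof.positions[-1] == pytest.approx(9.0)

    def test_axis_aligned_step(self):
        px = np.zeros((10, 4))
        px[6:, :] = 200.0
        prof = bq.extract_profile(bq.GrayImage(px), bq.ProfileLine((1, 0), (1, 9)))
        assert np.array_equal(prof.values >= 100, np.arange(10) >= 6)

    def test_diagonal_on_linear_gradient_matches_plane(self):
        # plane f(x, y) = 2x + 3y sampled along a diagonal line
        yy, xx = np.mgrid[0:50, 0:50]
        img = bq.GrayImage((2.0 * xx + 3.0 * yy) * (255 / (2 * 49 + 3 * 49)))
        line = bq.ProfileLine((3.0, 5.0), (40.0, 30.0))
        prof = bq.extract_profile(img, line)
        t = prof.positions / line.length
        x = 3.0 + t * 37.0
        y = 5.0 + t * 25.0
        expected = (2.0 * x + 3.0 * y) * (255 / (2 * 49 + 3 * 49))
        assert np.allclose(prof.values, expected, atol=1e-6)

    def test_endpoint_out_of_bounds(self):
        img = bq.GrayImage(np.zeros((5, 5)))
        with pytest.raises(GeometryError):
            bq.extract_profile(img, bq.ProfileLine((0, 0), (10, 0)))


def _profile(values, step=1.0):
    values = np.asarray(values, dtype=float)
    return bq.IntensityProfile(
        positions=np.arange(len(values)) * step, values=values
    )


class TestSettlingRatio:
    def test_constant_positive_profile_crosses_at_origin(self):
        assert bq.settling_ratio(_profile([50.0] * 10)) == 0.0

    def test_linear_ramp_crosses_at_midpoint(self):
        # ramp 0..M over the line: half-max reached exactly half-way
        vals = np.linspace(0.0, 200.0, 101)
        assert bq.settling_ratio(_profile(vals)) == pytest.approx(0.5)

    def test_step_at_80_percent(self):
        vals = np.where(np.arange(101) < 80, 0.0, 200.0)
        assert bq.settling_ratio(_profile(vals)) == pytest.approx(0.80)

    def test_all_zero_profile_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert bq.settling_ratio(_profile([0.0] * 5)) == 0.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            bq.IntensityProfile(positions=np.array([]), values=np.array([]))

    @given(
        boundary=st.integers(min_value=1, max_value=99),
        scale=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, boundary, scale):
        """Uniform intensity scaling leaves the ratio unchanged."""
        vals = np.where(np.arange(100) < boundary, 10.0, 200.0)
        assert bq.settling_ratio(_profile(vals)) == bq.settling_ratio(
            _profile(vals * scale)
        )

    def test_monotone_in_boundary_position(self):
        """Moving the step toward the bottom never decreases the ratio."""
        ratios = [
            bq.settling_ratio(_profile(np.where(np.arange(100) < b, 10.0, 200.0)))
            for b in range(1, 100, 7)
        ]
        assert all(a <= b for a, b in zip(ratios, ratios[1:]))


class TestSettlingScore:
    def test_mean_of_identical_lines(self):
        img = bq.render_settling_image(bq.TubeSpec(cleared_fraction=0.5))
        lines = [bq.ProfileLine((20, 0), (20, 239))] * 3
        meas = bq.settling_score(img, lines)
        assert meas.ratio == meas.per_line_ratios[0]

    def test_arithmetic_mean(self):
        meas = bq.TubeMeasurement(per_line_ratios=(0.2, 0.4, 0.6))
        assert meas.ratio == pytest.approx(0.4)

    def test_empty_line_list_rejected(self):
        img = bq.GrayImage(np.zeros((5, 5)))
        with pytest.raises(ValidationError):
            bq.settling_score(img, [])

    def test_invert_flag_flips_polarity(self):
        spec = bq.TubeSpec(cleared_fraction=0.6)
        img = bq.render_settling_image(spec).inverted()
        lines = [bq.ProfileLine((30, 0), (30, 239))]
        # dense region is now dark; inverting restores the convention
        assert bq.settling_score(img, lines, invert=True).ratio == pytest.approx(
            0.6, abs=0.01
        )


class TestMeasureSpot:
    def test_uniform_image_gives_zero(self):
        img = bq.GrayImage(np.full((20, 20), 37.0))
        m = bq.measure_spot(img, bq.SpotROI(center=(10, 10), radius=4))
        assert m.background == pytest.approx(37.0)
        assert m.corrected == 0.0

    def test_hand_arithmetic(self):
        # A_t=100, I_t=20, A_s=10, I_s=110 -> background (2000-1100)/90 = 10
        px = np.full((10, 10), 10.0)
        px.flat[:10] = 110.0
        mask = np.zeros((10, 10), dtype=bool)
        mask.flat[:10] = True
        m = bq.measure_spot(bq.GrayImage(px), bq.SpotROI(mask=mask))
        assert (m.area_total, m.area_spot) == (100, 10)
        assert m.mean_total == pytest.approx(20.0)
        assert m.mean_spot == pytest.approx(110.0)
        assert m.background == pytest.approx(10.0)
        assert m.corrected == pytest.approx(100.0)

    def test_clamp_case(self):
        # A_t=100, I_t=50, A_s=10, I_s=10 -> background ~54.44, corrected 0
        px = np.full((10, 10), 50.0)
        px.flat[:10] = 10.0
        px.flat[10:] = (5000.0 - 100.0) / 90.0
        mask = np.zeros((10, 10), dtype=bool)
        mask.flat[:10] = True
        m = bq.measure_spot(bq.GrayImage(px), bq.SpotROI(mask=mask))
        assert m.raw_corrected == pytest.approx(10.0 - 4900.0 / 90.0)
        assert m.corrected == 0.0

    def test_background_equals_complement_mean(self, rng):
        """Algebraic identity: the formula background is the pixel mean
        outside the ROI."""
        for _ in range(25):
            px = rng.uniform(0, 255, size=(24, 24))
            mask = np.zeros_like(px, dtype=bool)
            cx, cy = rng.integers(6, 18, size=2)
            yy, xx = np.mgrid[0:24, 0:24]
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= 25
            m = bq.measure_spot(bq.GrayImage(px), bq.SpotROI(mask=mask))
            assert m.background == pytest.approx(px[~mask].mean(), abs=1e-9)

    def test_offset_invariance(self, rng):
        """Adding a constant offset cancels in I_s - background."""
        px = rng.uniform(10, 100, size=(16, 16))
        roi = bq.SpotROI(center=(8, 8), radius=3)
        base = bq.measure_spot(bq.GrayImage(px), roi)
        shifted = bq.measure_spot(bq.GrayImage(px + 50.0), roi)
        assert shifted.raw_corrected == pytest.approx(base.raw_corrected, abs=1e-9)

    def test_full_image_roi_rejected(self):
        img = bq.GrayImage(np.zeros((5, 5)))
        with pytest.raises(ValidationError):
            bq.measure_spot(img, bq.SpotROI(mask=np.ones((5, 5), dtype=bool)))

    def test_empty_roi_rejected(self):
        img = bq.GrayImage(np.zeros((5, 5)))
        with pytest.raises(ValidationError):
            bq.measure_spot(img, bq.SpotROI(mask=np.zeros((5, 5), dtype=bool)))

    def test_roi_outside_image_rejected(self):
        img = bq.GrayImage(np.zeros((10, 10)))
        with pytest.raises(GeometryError):
            bq.measure_spot(img, bq.SpotROI(center=(9, 9), radius=5))


class TestInvasionScore:
    def test_mean_and_identity(self):
        def meas(spot_mean):
            px = np.full((10, 10), 10.0)
            px.flat[:10] = spot_mean
            mask = np.zeros((10, 10), dtype=bool)
            mask.flat[:10] = True
            return bq.measure_spot(bq.GrayImage(px), bq.SpotROI(mask=mask))

        single = meas(110.0)
        assert bq.invasion_score([single]) == pytest.approx(single.corrected)
        trio = [meas(v) for v in (10.0, 60.0, 110.0)]
        assert bq.invasion_score(trio) == pytest.approx(
            np.mean([m.corrected for m in trio])
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            bq.invasion_score([])


class TestDeterminism:
    def test_fixed_image_and_annotation_bit_reproducible(self):
        img = bq.render_settling_image(
            bq.TubeSpec(cleared_fraction=0.37, noise_sd=3, seed=11)
        )
        lines = [bq.ProfileLine((10, 0), (15, 239)), bq.ProfileLine((30, 0), (30, 239))]
        a = bq.settling_score(img, lines)
        b = bq.settling_score(img, lines)
        assert a.per_line_ratios == b.per_line_ratios
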