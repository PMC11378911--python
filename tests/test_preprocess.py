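"""Ratiometric preprocessing: background, registration, ratio, bleach, clip."""

import numpy as np
import pytest
from scipy import ndimage

from edgepulse.movie import Calibration, RatioMovie, TimeLapseMovie
from edgepulse.preprocess import (
    BleachCurve,
    bleach_correct,
    build_background_model,
    clip_percentiles,
    compute_ratio,
    fit_bleach_curve,
    register_channels,
    subtract_background,
)

CAL = Calibration(0.33, 25.0)


def movie_from(arrays: dict) -> TimeLapseMovie:
    return TimeLapseMovie({k: np.asarray(v, float) for k, v in arrays.items()}, CAL)


class TestBackground:
    def test_constant_blank_reproduced(self):
        model = build_background_model({"FRET": [np.full((3, 20, 20), 7.0)]})
        assert np.allclose(model.for_channel("FRET"), 7.0)

    def test_two_blanks_average(self):
        model = build_background_model(
            {"CFP": [np.full((20, 20), 10.0), np.full((20, 20), 30.0)]}
        )
        assert np.allclose(model.for_channel("CFP"), 20.0)

    def test_hot_pixel_spread_matches_disk_mean_oracle(self):
        blank = np.zeros((31, 31))
        blank[15, 15] = 900.0
        model = build_background_model({"m": [blank]}, filter_radius=5)
        # oracle: brute-force mean over the disk footprint centered there
        from skimage.morphology import disk

        k = disk(5).astype(float)
        oracle = 900.0 / k.sum()
        assert model.for_channel("m")[15, 15] == pytest.approx(oracle)
        assert model.for_channel("m")[15, 15] < 900.0

    def test_empty_blank_list_rejected(self):
        with pytest.raises(ValueError):
            build_background_model({"FRET": []})


class TestSubtract:
    def test_frame_equal_to_model_zeroes_out(self):
        frames = np.full((4, 16, 16), 50.0)
        model = build_background_model({"FRET": [np.full((16, 16), 50.0)]})
        out = subtract_background(movie_from({"FRET": frames}), model)
        assert np.allclose(out["FRET"], 0.0)

    def test_offset_preserved(self):
        frames = np.full((2, 16, 16), 150.0)
        model = build_background_model({"FRET": [np.full((16, 16), 50.0)]})
        out = subtract_background(movie_from({"FRET": frames}), model)
        assert np.allclose(out["FRET"], 100.0)

    def test_floor_at_zero(self):
        frames = np.full((2, 16, 16), 10.0)
        model = build_background_model({"FRET": [np.full((16, 16), 50.0)]})
        out = subtract_background(movie_from({"FRET": frames}), model)
        assert np.allclose(out["FRET"], 0.0)

    def test_shape_mismatch_rejected(self):
        model = build_background_model({"FRET": [np.zeros((8, 8))]})
        with pytest.raises(ValueError):
            subtract_background(movie_from({"FRET": np.zeros((2, 16, 16))}), model)


class TestRegister:
    @staticmethod
    def _textured(shape=(96, 96), seed=0):
        # cell-like image: bright textured blob on a dark background
        rng = np.random.default_rng(seed)
        yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
        blob = ((yy - 48) ** 2 + (xx - 48) ** 2 <= 30**2).astype(float)
        img = 1000 * blob + rng.normal(0, 30, shape)
        return ndimage.gaussian_filter(img, 2)

    def test_aligned_channels_report_zero_shift(self):
        base = self._textured()
        movie = movie_from({"CFP": np.stack([base] * 3),
                            "FRET": np.stack([base] * 3)})
        _, shifts = register_channels(movie)
        assert shifts["FRET"] == (0.0, 0.0)

    def test_constructed_shift_recovered(self):
        base = self._textured()
        shifted = ndimage.shift(base, (3, -2), order=1, mode="nearest")
        movie = movie_from({"CFP": np.stack([base] * 3),
                            "FRET": np.stack([shifted] * 3)})
        out, shifts = register_channels(movie)
        assert shifts["FRET"][0] == pytest.approx(-3, abs=0.2)
        assert shifts["FRET"][1] == pytest.approx(2, abs=0.2)
        inner = (slice(8, -8), slice(8, -8))
        assert np.allclose(out["FRET"][0][inner], base[inner], atol=2.0)

    def test_excessive_shift_capped_to_identity(self):
        base = self._textured()
        far = ndimage.shift(base, (30, 0), order=1, mode="nearest")
        movie = movie_from({"CFP": np.stack([base] * 3),
                            "FRET": np.stack([far] * 3)})
        with pytest.warns(UserWarning, match="identity"):
            out, shifts = register_channels(movie, max_shift_px=10)
        assert shifts["FRET"] == (0.0, 0.0)
        assert np.array_equal(out["FRET"], movie["FRET"])

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            register_channels(movie_from({"CFP": np.zeros((2, 8, 8))}))


class TestRatio:
    def test_constant_multiple_gives_constant_ratio(self):
        den = np.full((3, 20, 20), 500.0)
        masks = np.ones((3, 20, 20), bool)
        masks[:, :2, :] = False
        ratio = compute_ratio(movie_from({"n": 2 * den, "d": den}), "n", "d",
                              masks)
        assert np.allclose(ratio.values[ratio.valid], 2.0)
        assert not ratio.valid[0, 0, 0]

    def test_zero_denominator_marked_invalid(self):
        num = np.full((1, 20, 20), 100.0)
        den = np.full((1, 20, 20), 100.0)
        den[0, :, 10:] = 0.0
        masks = np.ones((1, 20, 20), bool)
        ratio = compute_ratio(movie_from({"n": num, "d": den}), "n", "d", masks,
                              smooth_radius=0)
        assert not ratio.valid[0, 5, 15]
        assert np.isfinite(ratio.values[ratio.valid]).all()

    def test_empty_mask_flagged(self):
        masks = np.zeros((2, 10, 10), bool)
        masks[1] = True
        ratio = compute_ratio(
            movie_from({"n": np.ones((2, 10, 10)), "d": np.ones((2, 10, 10))}),
            "n", "d", masks,
        )
        assert ratio.empty_frames == [0]

    def test_background_then_ratio_order_independence(self):
        # a constant-multiple channel pair yields the constant regardless of
        # the background level added to both channels
        rng = np.random.default_rng(1)
        den = ndimage.gaussian_filter(rng.uniform(400, 600, (2, 40, 40)), 2)
        masks = np.zeros((2, 40, 40), bool)
        masks[:, 10:30, 10:30] = True
        for bg in (0.0, 80.0):
            movie = movie_from({"n": 3 * den + bg, "d": den + bg})
            model = build_background_model(
                {"n": [np.full((40, 40), bg)], "d": [np.full((40, 40), bg)]}
            )
            sub = subtract_background(movie, model)
            ratio = compute_ratio(sub, "n", "d", masks)
            inner = ratio.values[:, 14:26, 14:26]
            assert np.allclose(inner, 3.0, rtol=0.02)


class TestBleach:
    @staticmethod
    def _ratio_movie(curve: np.ndarray, noise=0.0, seed=0) -> RatioMovie:
        rng = np.random.default_rng(seed)
        vals = np.ones((curve.size, 12, 12)) * curve[:, None, None]
        if noise:
            vals = vals + rng.normal(0, noise, vals.shape)
        return RatioMovie(vals, np.ones(vals.shape, bool), CAL)

    def test_constant_control_gives_unit_curve(self):
        rm = self._ratio_movie(np.full(20, 1.6))
        curve = fit_bleach_curve([rm])
        assert np.allclose(curve.c, 1.0)

    def test_exponential_rate_recovered_from_generator_taus(self):
        rate = 1 / 3000 - 1 / 6000  # per s, from the two channel taus
        t = np.arange(40) * 25.0
        rm = self._ratio_movie(1.8 * np.exp(-rate * t))
        curve = fit_bleach_curve([rm], kind="exponential")
        assert curve.rate_per_s == pytest.approx(rate, rel=0.02)

    def test_curve_normalized_at_frame_zero(self):
        rng = np.random.default_rng(3)
        rm = self._ratio_movie(np.cumprod(rng.uniform(0.97, 1.0, 30)) * 2.0)
        for kind in ("empirical", "exponential"):
            assert fit_bleach_curve([rm], kind=kind).c[0] == pytest.approx(1.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_bleach_curve([self._ratio_movie(np.ones(4))])

    def test_unit_curve_correction_is_identity(self):
        rm = self._ratio_movie(np.linspace(2, 1, 10))
        curve = BleachCurve(np.ones(10), "empirical", 25.0)
        out = bleach_correct(rm, curve)
        assert np.array_equal(out.values, rm.values)

    def test_round_trip_flattens_ratio(self):
        rate = 1 / 3000 - 1 / 6000
        t = np.arange(40) * 25.0
        rm = self._ratio_movie(1.5 * np.exp(-rate * t))
        curve = fit_bleach_curve([rm], kind="exponential")
        means = bleach_correct(rm, curve).frame_means()
        assert np.std(means) / np.mean(means) < 0.01

    def test_double_correction_differs_from_single(self):
        rate = 1e-4
        t = np.arange(10) * 25.0
        rm = self._ratio_movie(np.exp(-rate * t))
        curve = fit_bleach_curve([rm], kind="exponential")
        once = bleach_correct(rm, curve)
        twice = bleach_correct(once, curve)
        assert not np.allclose(once.values[-1], twice.values[-1])


class TestClip:
    @staticmethod
    def _from_values(vals: np.ndarray) -> RatioMovie:
        arr = np.asarray(vals, float).reshape(1, 1, -1)
        return RatioMovie(arr, np.ones_like(arr, bool), CAL)

    def test_constant_movie_unchanged(self):
        rm = self._from_values(np.full(200, 5.0))
        assert np.allclose(clip_percentiles(rm).values, 5.0)

    def test_order_statistic_limits(self):
        vals = np.arange(1.0, 101.0)
        rm = self._from_values(vals)
        out = clip_percentiles(rm)
        lo, hi = np.percentile(vals, [1, 99])
        assert out.values.min() == pytest.approx(lo)
        assert out.values.max() == pytest.approx(hi)

    def test_outlier_pulled_in(self):
        vals = np.concatenate([np.ones(199), [1e6]])
        out = clip_percentiles(self._from_values(vals))
        assert out.values.max() < 1e6

    def test_median_preserved_for_symmetric_tails(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(3.0, 0.5, 5000)
        rm = self._from_values(vals)
        out = clip_percentiles(rm)
        assert np.median(out.values) == pytest.approx(np.median(vals), abs=1e-9)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            clip_percentiles(self._from_values(np.ones(50)))


class TestSyntheticRoundTrips:
    def test_ratio_recovers_activity_field(self, noiseless_sim):
        # generator oracle: per-pixel FRET/CFP equals the activity field
        rendered, boundary, fields, coupling = noiseless_sim
        model = build_background_model(
            {c: [rendered.blank[c]] for c in rendered.movie.channels}
        )
        sub = subtract_background(rendered.movie, model)
        ratio = compute_ratio(sub, "FRET", "CFP", rendered.masks)
        t = 30
        inside = rendered.masks[t] & ratio.valid[t]
        # erode so the comparison avoids smoothing bleed at the cell edge
        core = ndimage.binary_erosion(inside, iterations=4)
        yy, xx = np.nonzero(core)
        phi = np.mod(np.arctan2(yy - rendered.center_px[0],
                                xx - rendered.center_px[1]), 2 * np.pi)
        rho = np.hypot(yy - rendered.center_px[0], xx - rendered.center_px[1])
        rho_um = rho * 0.33
        r_t = boundary.radius_at(phi, np.full_like(phi, t * 25.0))
        in_band = (r_t - rho_um) <= coupling.activity_depth_um
        expected = np.where(in_band, fields.activity_at(phi, t), 1.0)
        bleach = np.exp(-t * 25.0 * (1 / 3000 - 1 / 6000))
        measured = ratio.values[t][yy, xx]
        # compare away from the band boundary where smoothing mixes levels
        sel = np.abs((r_t - rho_um) - coupling.activity_depth_um) > 1.0
        assert np.allclose(measured[sel], expected[sel] * bleach, rtol=0.05)

    def test_bleach_rate_recovered_from_control_movie(self):
        # control condition: no activity modulation, no noise
        from edgepulse.synthetic import (
            BoundaryParams, CouplingParams, render_timelapse,
            simulate_activity_coupling, simulate_boundary_series,
        )

        params = BoundaryParams(n_events=0, n_frames=40, base_radius=30.0)
        coupling = CouplingParams(noise_sd=0.0, activity_gain=0.0)
        boundary = simulate_boundary_series(params)
        f = simulate_activity_coupling(boundary, coupling)
        rendered = render_timelapse(boundary, f, coupling)
        model = build_background_model(
            {c: [rendered.blank[c]] for c in rendered.movie.channels}
        )
        sub = subtract_background(rendered.movie, model)
        ratio = compute_ratio(sub, "FRET", "CFP", rendered.masks)
        curve = fit_bleach_curve([ratio], kind="exponential")
        expected = 1 / 3000 - 1 / 6000
        assert curve.rate_per_s == pytest.approx(expected, rel=0.02)
        corrected = bleach_correct(ratio, curve)
        means = corrected.frame_means()
        assert np.std(means) / np.mean(means) < 0.01
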