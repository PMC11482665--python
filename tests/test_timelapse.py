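"""Flat-field correction, drift tracking, variance projection, intensity."""

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from tinyscope import synthetic
from tinyscope import timelapse as tl
from tinyscope.frames import Frame, TimelapseSeries
from tinyscope.synthetic import fourier_shift_image, make_drifting_timelapse


def vignette(shape, strength):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
    v = 1.0 - strength * r2 / r2.max()
    return v / v.mean()


class TestFlatField:
    def test_self_correction_yields_constant(self, rng):
        flat = Frame(vignette((128, 128), 0.4) * 150.0)
        out = tl.flat_field_correct(flat, flat)
        assert out.pixels.std() < 1e-9
        assert out.pixels.mean() == pytest.approx(flat.pixels.mean())

    def test_constant_flat_is_identity(self, textured_frame):
        flat = Frame(np.full((128, 128), 180.0))
        np.testing.assert_allclose(
            tl.flat_field_correct(textured_frame, flat).pixels,
            textured_frame.pixels,
        )

    def test_vignetted_scene_restored(self, texture_array):
        v = vignette((128, 128), 0.4)
        corrected = tl.flat_field_correct(
            Frame(np.clip(texture_array * v, 0, 255)), Frame(np.clip(v * 150, 0, 255))
        )
        rms = np.sqrt(np.mean((corrected.pixels - texture_array) ** 2))
        assert rms < 0.01 * 255

    def test_dark_subtraction(self, texture_array):
        dark = Frame(np.full((128, 128), 10.0))
        flat = Frame(np.full((128, 128), 110.0))
        out = tl.flat_field_correct(
            Frame(texture_array), flat, dark
        )
        np.testing.assert_allclose(out.pixels, np.clip(texture_array - 10.0, 0, 255))

    def test_zero_mean_flat_rejected(self, textured_frame):
        with pytest.raises(ValueError):
            tl.flat_field_correct(textured_frame, Frame(np.zeros((128, 128))))


class TestPairShift:
    def test_cyclic_integer_shift_exact(self, texture_array):
        shifted = np.roll(np.roll(texture_array, -2, axis=0), 3, axis=1)
        dx, dy, q = tl.pair_shift(texture_array, shifted)
        assert (dx, dy) == (3.0, -2.0)
        assert q > 2.0

    def test_identity(self, texture_array):
        dx, dy, _ = tl.pair_shift(texture_array, texture_array)
        assert (dx, dy) == (0.0, 0.0)

    def test_subpixel_half_pixel(self, texture_array):
        shifted = fourier_shift_image(texture_array, 0.5, 0.0)
        dx, dy, _ = tl.pair_shift(texture_array, shifted)
        assert abs(dx - 0.5) <= 0.15
        assert abs(dy) <= 0.15

    def test_antisymmetry(self, texture_array):
        shifted = fourier_shift_image(texture_array, 2.3, -1.2)
        fwd = tl.pair_shift(texture_array, shifted)
        rev = tl.pair_shift(shifted, texture_array)
        assert abs(fwd[0] + rev[0]) <= 0.1
        assert abs(fwd[1] + rev[1]) <= 0.1

    def test_constant_frames_rejected(self):
        flat = np.full((64, 64), 3.0)
        with pytest.raises(ValueError):
            tl.pair_shift(flat, flat)

    def test_agrees_with_reference_estimator(self, texture_array):
        """Cross-check against the upsampled-DFT phase correlation in
        scikit-image (note its (row, col) order and opposite sign)."""
        rng = np.random.default_rng(77)
        for _ in range(5):
            dx, dy = rng.uniform(-6, 6, size=2)
            shifted = fourier_shift_image(texture_array, dx, dy)
            ours = tl.pair_shift(texture_array, shifted)
            ref = phase_cross_correlation(
                texture_array, shifted, upsample_factor=50, normalization="phase"
            )[0]
            # 3-point parabola vs upsampled DFT: agree to ~0.2 px, and
            # both within 0.2 px of the generating shift
            assert ours[0] == pytest.approx(-ref[1], abs=0.2)
            assert ours[1] == pytest.approx(-ref[0], abs=0.2)
            assert ours[0] == pytest.approx(dx, abs=0.2)
            assert ours[1] == pytest.approx(dy, abs=0.2)

    def test_raw_correlation_mode(self, texture_array):
        shifted = np.roll(texture_array, 4, axis=1)
        dx, dy, _ = tl.pair_shift_raw(texture_array, shifted)
        assert abs(dx - 4.0) <= 0.2 and abs(dy) <= 0.2


class TestDriftTrack:
    def test_constant_unit_drift(self):
        series = make_drifting_timelapse([(1.0, 0.0)] * 9, noise_sd=0.005, seed=1)
        track = tl.drift_track(series)
        assert track.cumulative[-1][0] == pytest.approx(9.0, abs=0.5)
        assert track.cumulative[-1][1] == pytest.approx(0.0, abs=0.5)

    def test_static_series_zero_track(self):
        series = make_drifting_timelapse([(0.0, 0.0)] * 5, noise_sd=0.005, seed=2)
        track = tl.drift_track(series)
        assert np.abs(track.pairwise).max() <= 0.2

    def test_injected_jump_localized(self):
        shifts = [(0.5, 0.0)] * 8
        shifts[4] = (7.0, -5.0)  # sudden mechanical jump
        series = make_drifting_timelapse(shifts, noise_sd=0.01, seed=3)
        track = tl.drift_track(series)
        magnitudes = np.hypot(track.pairwise[:, 0], track.pairwise[:, 1])
        assert int(np.argmax(magnitudes)) == 4

    def test_cumulative_is_prefix_sum(self):
        series = make_drifting_timelapse(
            [(1.0, 2.0), (-0.5, 0.5), (2.0, -1.0)], noise_sd=0.0, seed=4
        )
        track = tl.drift_track(series)
        np.testing.assert_allclose(
            track.cumulative, np.cumsum(track.pairwise, axis=0)
        )

    def test_concatenation_additivity(self):
        """Total drift of a concatenated series equals the vector sum of
        its parts' totals (same scene, contiguous shifts)."""
        shifts = [(1.5, -1.0)] * 6
        series = make_drifting_timelapse(shifts, noise_sd=0.0, seed=5)
        full = tl.drift_track(series).cumulative[-1]
        first = TimelapseSeries(series.frames[:4], series.timestamps[:4])
        second = TimelapseSeries(series.frames[3:], series.timestamps[3:])
        parts = tl.drift_track(first).cumulative[-1] + tl.drift_track(second).cumulative[-1]
        np.testing.assert_allclose(full, parts, atol=0.1)

    def test_twenty_seeded_recoveries(self):
        """Noise up to 2% full scale, shifts up to +/-8 px/frame:
        max per-pair error at most 0.5 px."""
        worst = 0.0
        for s in range(20):
            rng = np.random.default_rng(s)
            shifts = [tuple(rng.uniform(-8, 8, 2)) for _ in range(9)]
            noise = float(rng.uniform(0.0, 0.02))
            series = make_drifting_timelapse(
                shifts,
                noise_sd=noise,
                vignette_strength=0.2,
                dimming_per_frame=0.001,
                seed=100 + s,
            )
            track = tl.drift_track(series)
            err = np.abs(track.pairwise - np.asarray(shifts)).max()
            worst = max(worst, err)
        assert worst <= 0.5


class TestVarianceProjection:
    def test_constant_series_zero(self):
        frames = [Frame(np.full((64, 64), 50.0)) for _ in range(4)]
        series = TimelapseSeries(frames, [1.0, 2.0, 3.0, 4.0])
        assert np.all(tl.variance_projection(series).pixels == 0)

    def test_moving_particle_trajectory_highlighted(self):
        path = [(20.0 + 8 * i, 40.0 + 4 * i) for i in range(10)]
        series = make_drifting_timelapse(
            [(0.0, 0.0)] * 9,
            moving_particle=path,
            particle_amplitude=0.6,
            noise_sd=0.005,
            seed=6,
        )
        proj = tl.variance_projection(series).pixels
        thresh = np.quantile(proj, 0.99)
        ys, xs = np.nonzero(proj >= thresh)
        # distance from each hot pixel to the nearest path point
        px, py = np.array([p[0] for p in path]), np.array([p[1] for p in path])
        d = np.min(
            np.hypot(xs[:, None] - px[None], ys[:, None] - py[None]), axis=1
        )
        assert np.all(d <= 3.0 + 2 * 2.0)  # path spacing + particle sigma

    def test_order_invariance(self):
        series = make_drifting_timelapse([(1.0, 0.5)] * 4, noise_sd=0.01, seed=7)
        proj = tl.variance_projection(series).pixels
        reordered = TimelapseSeries(series.frames[::-1], series.timestamps)
        np.testing.assert_allclose(
            tl.variance_projection(reordered).pixels, proj
        )


class TestIntensitySeries:
    def test_constant_series_flat(self):
        frames = [
            Frame(np.full((32, 32), 80.0), metadata={"exposure_ms": 10})
            for _ in range(3)
        ]
        df = tl.intensity_series(TimelapseSeries(frames, [1.0, 2.0, 3.0]))
        np.testing.assert_allclose(df["mean_intensity"], 80.0)

    def test_dimming_slope_recovered(self):
        """Battery-discharge model: exponential dimming over 3 days of
        per-minute frames (subsampled); the fitted decay rate matches the
        generator's within 10%."""
        dim = 0.002
        n = 80
        series = make_drifting_timelapse(
            [(0.0, 0.0)] * (n - 1),
            dimming_per_frame=dim,
            noise_sd=0.002,
            exposure_ms=100.0,
            interval_s=3 * 86400 / n,
            seed=8,
        )
        df = tl.intensity_series(series)
        rate = -np.polyfit(np.arange(n), np.log(df["mean_intensity"]), 1)[0]
        assert rate == pytest.approx(-np.log(1 - dim), rel=0.10)
        assert np.polyfit(np.arange(n), df["mean_intensity"], 1)[0] < 0

    def test_two_exposure_groups(self):
        frames = [
            Frame(np.full((32, 32), 40.0), metadata={"exposure_ms": 10}),
            Frame(np.full((32, 32), 200.0), metadata={"exposure_ms": 50}),
            Frame(np.full((32, 32), 41.0), metadata={"exposure_ms": 10}),
            Frame(np.full((32, 32), 201.0), metadata={"exposure_ms": 50}),
        ]
        df = tl.intensity_series(TimelapseSeries(frames, [1.0, 2.0, 3.0, 4.0]))
        sizes = df.groupby("exposure_ms").size()
        assert sizes[10] == 2 and sizes[50] == 2

    def test_missing_exposure_metadata_warns(self):
        frames = [Frame(np.full((32, 32), 9.0)) for _ in range(2)]
        with pytest.warns(RuntimeWarning, match="exposure"):
            df = tl.intensity_series(TimelapseSeries(frames, [1.0, 2.0]))
        assert df["exposure_ms"].nunique() == 1
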