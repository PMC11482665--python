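"""Inline holography: propagator physics and simulate/reconstruct closure."""

import numpy as np
import pytest

from tinyscope import holography as holo
from tinyscope import synthetic
from tinyscope.frames import Frame
from tinyscope.holography import (
    ComplexField,
    Hologram,
    ParticleScene,
    angular_spectrum_propagate,
    normalize_hologram,
    reconstruct,
    simulate_inline,
    z_scan,
)

PITCH = 2.2
WAVELENGTH = 450.0


def gaussian_field(n=256, sigma=20.0):
    r2 = (np.arange(n) - n / 2) ** 2
    g = np.exp(-(r2[:, None] + r2[None, :]) / (2 * sigma**2))
    return ComplexField(g.astype(complex), PITCH)


def centroid_of_minimum(image, cx, cy, half=7):
    """Subpixel dark-spot center: centroid of the depression below the
    local median (robust inside flat absorbing discs)."""
    y0, x0 = int(round(cy)) - half, int(round(cx)) - half
    win = image[y0 : y0 + 2 * half + 1, x0 : x0 + 2 * half + 1].astype(float)
    depth = np.clip(np.median(win) - win, 0, None)
    if depth.sum() == 0:
        return cx, cy
    yy, xx = np.mgrid[0 : win.shape[0], 0 : win.shape[1]]
    return (
        x0 + (depth * xx).sum() / depth.sum(),
        y0 + (depth * yy).sum() / depth.sum(),
    )


class TestNormalize:
    def test_frame_equal_to_background_gives_unit_amplitude(self, textured_frame):
        h = Hologram(textured_frame, background=textured_frame)
        field = normalize_hologram(h)
        np.testing.assert_allclose(np.abs(field.values), 1.0, atol=1e-12)

    def test_constant_frame_without_background(self):
        h = Hologram(Frame(np.full((64, 64), 120.0)))
        np.testing.assert_allclose(np.abs(normalize_hologram(h).values), 1.0)

    def test_simulated_hologram_mean_amplitude_near_unity(self):
        scene = synthetic.make_particle_scene(3, z_um=1500.0, seed=7)
        h = simulate_inline(scene, seed=7)
        field = normalize_hologram(h)
        assert np.abs(field.values).mean() == pytest.approx(1.0, abs=0.01)

    def test_zero_background_pixels_floored_with_warning(self, textured_frame):
        bg = textured_frame.pixels.copy()
        bg[0, 0] = 0.0
        h = Hologram(textured_frame, background=Frame(bg))
        with pytest.warns(RuntimeWarning, match="floored"):
            field = normalize_hologram(h)
        assert field.metadata["floored_background_px"] == 1
        assert np.all(np.isfinite(field.values))


class TestPropagator:
    def test_zero_distance_is_identity(self):
        f = gaussian_field()
        out = angular_spectrum_propagate(f, 0.0, WAVELENGTH)
        assert np.abs(out.values - f.values).max() < 1e-12

    def test_forward_backward_roundtrip(self):
        f = gaussian_field()
        fwd = angular_spectrum_propagate(f, 800.0, WAVELENGTH)
        back = angular_spectrum_propagate(fwd, -800.0, WAVELENGTH)
        rms = np.sqrt(np.mean(np.abs(back.values - f.values) ** 2))
        assert rms < 1e-6

    def test_intensity_conserved(self):
        f = gaussian_field()
        fwd = angular_spectrum_propagate(f, 1500.0, WAVELENGTH)
        assert (np.abs(fwd.values) ** 2).sum() == pytest.approx(
            (np.abs(f.values) ** 2).sum(), rel=1e-6
        )

    def test_linearity(self):
        a = gaussian_field(sigma=15.0)
        rng = np.random.default_rng(4)
        b = ComplexField(
            (rng.normal(size=(256, 256)) + 1j * rng.normal(size=(256, 256)))
            * np.abs(gaussian_field(sigma=40.0).values),
            PITCH,
        )
        alpha, beta = 0.7, -1.3 + 0.2j
        combined = ComplexField(alpha * a.values + beta * b.values, PITCH)
        lhs = angular_spectrum_propagate(combined, 1000.0, WAVELENGTH).values
        rhs = (
            alpha * angular_spectrum_propagate(a, 1000.0, WAVELENGTH).values
            + beta * angular_spectrum_propagate(b, 1000.0, WAVELENGTH).values
        )
        assert np.sqrt(np.mean(np.abs(lhs - rhs) ** 2)) < 1e-9

    def test_fresnel_mode_agrees_in_paraxial_regime(self):
        f = gaussian_field()
        a = angular_spectrum_propagate(f, 800.0, WAVELENGTH).values
        b = angular_spectrum_propagate(f, 800.0, WAVELENGTH, method="fresnel").values
        assert np.sqrt(np.mean(np.abs(a - b) ** 2)) < 1e-6

    def test_aliasing_guard_warns(self):
        f = gaussian_field(n=64)
        with pytest.warns(RuntimeWarning, match="aliasing"):
            angular_spectrum_propagate(f, 10_000_000.0, WAVELENGTH)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            angular_spectrum_propagate(gaussian_field(), 100.0, WAVELENGTH, "kirchhoff")


class TestSimulate:
    def test_empty_scene_gives_flat_hologram(self):
        scene = ParticleScene([], z_um=1500.0)
        h = simulate_inline(scene, noise_sd=0.0, seed=0)
        px = h.frame.pixels
        assert px.std() <= 1.0  # quantization only

    def test_single_disc_shows_fringes_with_flat_corners(self):
        scene = ParticleScene([(560.0, 560.0, 8.0, 1.0)], z_um=1500.0)
        h = simulate_inline(scene, noise_sd=0.0, seed=0)
        px = h.frame.pixels.astype(float)
        center = px[200:310, 200:310]
        corner = px[:40, :40]
        assert center.std() > 10 * max(corner.std(), 0.1)

    def test_same_seed_bit_identical(self):
        scene = synthetic.make_particle_scene(2, z_um=1200.0, seed=5)
        a = simulate_inline(scene, seed=9).frame.pixels
        b = simulate_inline(scene, seed=9).frame.pixels
        np.testing.assert_array_equal(a, b)

    def test_particle_outside_fov_rejected(self):
        scene = ParticleScene([(99999.0, 10.0, 8.0, 1.0)], z_um=1500.0)
        with pytest.raises(ValueError, match="outside"):
            simulate_inline(scene, seed=0)


class TestReconstruct:
    def test_particles_localized_at_true_depth(self):
        scene = synthetic.make_particle_scene(3, z_um=1500.0, seed=7)
        h = simulate_inline(scene, seed=7)
        rec = reconstruct(h, 1500.0)
        for x_um, y_um, _, _ in scene.particles:
            cx, cy = x_um / PITCH, y_um / PITCH
            ex, ey = centroid_of_minimum(rec.pixels, cx, cy)
            assert np.hypot(ex - cx, ey - cy) <= 2.0

    def test_constant_hologram_reconstructs_constant(self):
        h = Hologram(Frame(np.full((128, 128), 100.0)))
        rec = reconstruct(h, 1000.0)
        assert rec.pixels.std() < 1e-6 * rec.max_value

    def test_wrong_depth_loses_contrast(self):
        scene = synthetic.make_particle_scene(3, z_um=1500.0, seed=7)
        h = simulate_inline(scene, seed=7)

        def mean_contrast(rec):
            vals = []
            for x_um, y_um, _, _ in scene.particles:
                cx, cy = int(round(x_um / PITCH)), int(round(y_um / PITCH))
                win = rec.pixels[cy - 7 : cy + 8, cx - 7 : cx + 8]
                vals.append((win.max() - win.min()) / (win.max() + win.min()))
            return np.mean(vals)

        assert mean_contrast(reconstruct(h, 1500.0)) > mean_contrast(
            reconstruct(h, 150.0)
        )

    def test_negative_depth_rejected(self):
        h = Hologram(Frame(np.full((64, 64), 100.0)))
        with pytest.raises(ValueError):
            reconstruct(h, -100.0)

    def test_spherical_source_effective_distance(self):
        h = Hologram(
            Frame(np.full((64, 64), 100.0)), source_distance_mm=80.0
        )
        z_eff = h.effective_distance_um(1500.0)
        assert z_eff == pytest.approx(1500.0 * 80000 / 81500)
        assert z_eff < 1500.0


class TestZScan:
    def test_recovers_depth_within_one_step(self):
        scene = synthetic.make_particle_scene(3, z_um=1500.0, seed=7)
        h = simulate_inline(scene, seed=7)
        best, z_grid, scores = z_scan(h, 500.0, 3000.0, 26)
        step = z_grid[1] - z_grid[0]
        assert abs(best - 1500.0) <= step
        assert scores.shape == (26,)

    def test_empty_hologram_flat_curve_tie_breaks_low(self):
        h = Hologram(Frame(np.full((128, 128), 100.0)))
        best, z_grid, scores = z_scan(h, 500.0, 3000.0, 11)
        assert best == 500.0
        assert np.ptp(scores) < 1e-9

    def test_refinement_never_worsens(self):
        """Doubling the scan density never moves best_z away from truth."""
        for s in range(10):
            z_true = float(np.random.default_rng(40 + s).uniform(800, 2500))
            scene = synthetic.make_particle_scene(3, z_um=z_true, seed=60 + s)
            h = simulate_inline(scene, seed=80 + s)
            coarse, _, _ = z_scan(h, 500.0, 3000.0, 26)
            fine, _, _ = z_scan(h, 500.0, 3000.0, 51)
            assert abs(fine - z_true) <= abs(coarse - z_true) + 1e-9

    def test_degenerate_grid_rejected(self):
        h = Hologram(Frame(np.full((64, 64), 100.0)))
        with pytest.raises(ValueError):
            z_scan(h, 500.0, 3000.0, 2)
        with pytest.raises(ValueError):
            z_scan(h, 3000.0, 500.0, 10)


class TestHologramInvariants:
    def test_wavelength_band_enforced(self, textured_frame):
        with pytest.raises(ValueError):
            Hologram(textured_frame, wavelength_nm=300.0)

    def test_rgb_frame_rejected(self, rng):
        rgb = Frame(rng.uniform(0, 255, size=(64, 64, 3)))
        with pytest.raises(ValueError, match="grayscale"):
            Hologram(rgb)
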