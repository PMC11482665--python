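"""Seeded synthetic fixtures emulating the imaging physics of the devices.

Every generator is a pure function of its parameters and seed: identical
inputs produce bit-identical outputs.  The fixtures emulate what the
hardware produces — defocus blur that grows linearly with distance from
focus, lateral stage drift, radial vignetting, battery-discharge
dimming, diffraction-grating spectra, three-bar resolution targets —
but deliberately not its full optics: defocus is Gaussian (not the true
lens PSF), noise is Gaussian read noise plus optional Poisson shot
noise, and no aberrations are modelled.
"""

from __future__ import annotations

import numpy as np
import scipy.fft
import scipy.ndimage

from tinyscope.frames import Frame, FocusStack, TimelapseSeries
from tinyscope.holography import ParticleScene


# --------------------------------------------------------------------------
# textures and noise


def _texture(shape: tuple[int, int], rng: np.random.Generator, smooth: float = 1.5
             ) -> np.ndarray:
    """Random smooth texture in [0, 1] with broad spatial-frequency content."""
    base = rng.normal(size=shape)
    tex = scipy.ndimage.gaussian_filter(base, smooth)
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / (hi - lo)


def _add_noise(
    img: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
    max_value: float,
    poisson: bool = False,
) -> np.ndarray:
    """Gaussian read noise (sd in full-scale units) + optional shot noise."""
    out = img.astype(float)
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd * max_value, size=img.shape)
    return np.clip(out, 0.0, max_value)


# --------------------------------------------------------------------------
# three-bar resolution target


def make_bar_target(
    line_widths_um: list[float],
    effective_pixel_um: float = 0.55,
    contrast: float = 1.0,
    blur_sigma_um: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    bit_depth: int = 8,
) -> Frame:
    """Render a three-bar resolution target (dark bars, bright field).

    For each line width a group of three bars is drawn in both
    orientations (vertical bars resolving along x, horizontal along y),
    blurred with a Gaussian of ``blur_sigma_um`` and degraded with seeded
    noise.  The frame metadata records, per group, the profile-line
    coordinates that :func:`resolved_linewidth` needs.

    Line widths below the effective pixel size cannot be rendered and
    raise ``ValueError``.
    """
    if not line_widths_um:
        raise ValueError("need at least one line width")
    for w in line_widths_um:
        if w < effective_pixel_um:
            raise ValueError(
                f"line width {w} um below the {effective_pixel_um} um sampling floor"
            )
    widths = sorted(line_widths_um, reverse=True)
    px = effective_pixel_um
    margin = max(8, int(round(2 * widths[0] / px)))
    groups: list[dict] = []
    x_cursor = margin
    height_need = 0
    for w_um in widths:
        w_px = w_um / px
        group_w = 5 * w_px  # 3 bars + 2 gaps
        group_h = 5 * w_px
        groups.append(
            {
                "width_um": w_um,
                "width_px": w_px,
                "x0": x_cursor,
                "group_w": group_w,
                "group_h": group_h,
            }
        )
        x_cursor += int(np.ceil(group_w)) + margin
        height_need = max(height_need, int(np.ceil(group_h)))
    W = x_cursor + margin
    # two rows: vertical-bar groups on top, horizontal-bar groups below
    row_h = height_need + 2 * margin
    H = 2 * row_h
    max_val = float(2**bit_depth - 1)
    hi = max_val
    lo = max_val * (1.0 - contrast)
    img = np.full((H, W), hi)
    yy = np.arange(H)[:, None]
    xx = np.arange(W)[None, :]
    meta_groups = []
    for g in groups:
        w_px = g["width_px"]
        x0 = g["x0"]
        y0v = margin
        # vertical bars: dark where ((x - x0) / w_px) mod 2 in [0, 1)
        in_x = (xx >= x0) & (xx < x0 + g["group_w"])
        in_y = (yy >= y0v) & (yy < y0v + g["group_h"])
        phase = np.floor((xx - x0) / w_px) % 2
        img = np.where(in_x & in_y & (phase == 0), lo, img)
        y0h = row_h + margin
        in_y2 = (yy >= y0h) & (yy < y0h + g["group_h"])
        in_x2 = (xx >= x0) & (xx < x0 + g["group_w"])
        phase_y = np.floor((yy - y0h) / w_px) % 2
        img = np.where(in_x2 & in_y2 & (phase_y == 0), lo, img)
        meta_groups.append(
            {
                "width_um": g["width_um"],
                "width_px": w_px,
                "vertical": {"x0": x0, "y_center": y0v + g["group_h"] / 2},
                "horizontal": {"y0": y0h, "x_center": x0 + g["group_w"] / 2},
            }
        )
    if blur_sigma_um > 0:
        img = scipy.ndimage.gaussian_filter(img, blur_sigma_um / px)
    rng = np.random.default_rng(seed)
    img = _add_noise(img, rng, noise_sd, max_val)
    meta = {
        "kind": "bar_target",
        "effective_pixel_um": px,
        "contrast": contrast,
        "groups": meta_groups,
        "background_level": hi,
        "bar_level": lo,
    }
    return Frame(img, bit_depth=bit_depth, metadata=meta)


def _group_contrast(img: np.ndarray, width_px: float, start: float,
                    line: np.ndarray) -> float:
    """Michelson contrast of a three-bar profile sampled at known positions."""
    bar_centers = start + width_px * np.array([0.5, 2.5, 4.5])
    gap_centers = start + width_px * np.array([1.5, 3.5])
    idx_bar = np.round(bar_centers).astype(int)
    idx_gap = np.round(gap_centers).astype(int)
    idx_bar = np.clip(idx_bar, 0, line.size - 1)
    idx_gap = np.clip(idx_gap, 0, line.size - 1)
    i_min = float(line[idx_bar].mean())
    i_max = float(line[idx_gap].mean())
    if i_max + i_min == 0:
        return 0.0
    return (i_max - i_min) / (i_max + i_min)


def resolved_linewidth(
    frame: Frame, contrast_threshold: float = 0.26
) -> float | None:
    """Smallest bar-target line width resolved in both orientations.

    A group counts as resolved when its three-bar line profile retains a
    Michelson contrast of at least ``contrast_threshold`` in both the
    vertical and the horizontal orientation.  Returns ``None`` when no
    group passes ("unresolved").
    """
    meta = frame.metadata
    if meta.get("kind") != "bar_target" or "groups" not in meta:
        raise ValueError("frame lacks bar-target metadata")
    img = frame.luminance()
    resolved = []
    for g in meta["groups"]:
        w_px = g["width_px"]
        v = g["vertical"]
        row = int(round(v["y_center"]))
        profile_x = img[row, :]
        c_v = _group_contrast(img, w_px, v["x0"], profile_x)
        h_ = g["horizontal"]
        col = int(round(h_["x_center"]))
        profile_y = img[:, col]
        c_h = _group_contrast(img, w_px, h_["y0"], profile_y)
        if min(c_v, c_h) >= contrast_threshold:
            resolved.append(g["width_um"])
    return min(resolved) if resolved else None


# --------------------------------------------------------------------------
# defocus stacks


def make_defocus_stack(
    z_grid_um: np.ndarray | list[float] | None = None,
    z0_um: float = 50.0,
    blur_rate_px_per_um: float = 0.4,
    sigma0_px: float = 0.5,
    noise_sd: float = 0.01,
    shape: tuple[int, int] = (160, 160),
    seed: int = 0,
    bit_depth: int = 8,
) -> FocusStack:
    """A focus stack of one random textured scene, blur growing with |z - z0|.

    Each layer at z is the scene blurred with ``sigma(z) = sigma0 +
    rate * |z - z0|`` pixels plus seeded Gaussian read noise — the
    monotone blur-versus-defocus behavior the sharpness metrics rely on,
    without modelling the true lens PSF.
    """
    if z_grid_um is None:
        z_grid_um = np.arange(0.0, 101.0, 10.0)
    z_grid = np.asarray(z_grid_um, dtype=float)
    if z_grid.size == 0:
        raise ValueError("empty z grid")
    if not (z_grid.min() <= z0_um <= z_grid.max()):
        raise ValueError("z0 must lie within the grid span")
    rng = np.random.default_rng(seed)
    max_val = float(2**bit_depth - 1)
    scene = _texture(shape, rng) * 0.8 * max_val + 0.1 * max_val
    entries = []
    for z in z_grid:
        sigma = sigma0_px + blur_rate_px_per_um * abs(z - z0_um)
        layer = scipy.ndimage.gaussian_filter(scene, sigma) if sigma > 0 else scene
        layer = _add_noise(layer, rng, noise_sd, max_val)
        entries.append(
            (float(z), Frame(layer, bit_depth=bit_depth,
                             metadata={"z_position_um": float(z)}))
        )
    return FocusStack(entries)


# --------------------------------------------------------------------------
# drifting timelapse


def fourier_shift_image(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Cyclic subpixel shift: out(y, x) = in(y - dy, x - dx)."""
    shifted = scipy.ndimage.fourier_shift(scipy.fft.fft2(img), (dy, dx))
    return np.real(scipy.fft.ifft2(shifted))


def make_drifting_timelapse(
    shifts_px: list[tuple[float, float]],
    vignette_strength: float = 0.0,
    dimming_per_frame: float = 0.0,
    moving_particle: list[tuple[float, float]] | None = None,
    particle_sigma_px: float = 2.0,
    particle_amplitude: float = 0.5,
    noise_sd: float = 0.01,
    shape: tuple[int, int] = (128, 128),
    interval_s: float = 60.0,
    exposure_ms: float | None = None,
    seed: int = 0,
    bit_depth: int = 8,
) -> TimelapseSeries:
    """A timelapse of one scene drifting by the given per-frame shifts.

    ``shifts_px[i]`` is the (dx, dy) translation from frame i to frame
    i+1 (n_frames = len(shifts_px) + 1); the scene is shifted
    cumulatively with cyclic Fourier shifts, multiplied by a radial
    vignette of the given strength and a per-frame dimming factor
    ``(1 - dimming_per_frame)**i`` (battery-discharge model), with an
    optional bright Gaussian particle following ``moving_particle`` (one
    (x, y) per frame), and seeded read noise on top.
    """
    n_frames = len(shifts_px) + 1
    rng = np.random.default_rng(seed)
    max_val = float(2**bit_depth - 1)
    scene = _texture(shape, rng) * 0.5 * max_val + 0.2 * max_val
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if vignette_strength > 0:
        cy, cx = (h - 1) / 2, (w - 1) / 2
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
        vignette = 1.0 - vignette_strength * r2
    else:
        vignette = np.ones(shape)
    if moving_particle is not None:
        if len(moving_particle) != n_frames:
            raise ValueError("particle path needs one position per frame")
        for x, y in moving_particle:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"particle path leaves the frame at ({x}, {y})")
    cum = np.cumsum(np.asarray([(0.0, 0.0)] + list(shifts_px), float), axis=0)
    frames = []
    for i in range(n_frames):
        dx, dy = cum[i]
        img = fourier_shift_image(scene, dx, dy) if (dx or dy) else scene.copy()
        img = img * vignette * (1.0 - dimming_per_frame) ** i
        if moving_particle is not None:
            px_, py_ = moving_particle[i]
            blob = np.exp(
                -((xx - px_) ** 2 + (yy - py_) ** 2) / (2 * particle_sigma_px**2)
            )
            img = img + particle_amplitude * max_val * blob
        img = _add_noise(img, rng, noise_sd, max_val)
        meta: dict = {"frame_index": i}
        if exposure_ms is not None:
            meta["exposure_ms"] = exposure_ms
        frames.append(Frame(img, bit_depth=bit_depth, metadata=meta))
    timestamps = np.arange(n_frames) * interval_s + interval_s
    return TimelapseSeries(frames, timestamps)


# --------------------------------------------------------------------------
# spectrometer frames


def wavelength_to_rgb(wavelength_nm: float) -> tuple[float, float, float]:
    """Piecewise linear visible-wavelength to RGB approximation in [0, 1].

    A display-oriented approximation (not a calibrated sensor response):
    violet 380-440, blue 440-490, green 490-580, yellow/orange 580-645,
    red 645-780, with intensity roll-off at both spectrum ends.
    """
    w = wavelength_nm
    if w < 380 or w > 780:
        return (0.0, 0.0, 0.0)
    if w < 440:
        r, g, b = -(w - 440) / 60, 0.0, 1.0
    elif w < 490:
        r, g, b = 0.0, (w - 440) / 50, 1.0
    elif w < 510:
        r, g, b = 0.0, 1.0, -(w - 510) / 20
    elif w < 580:
        r, g, b = (w - 510) / 70, 1.0, 0.0
    elif w < 645:
        r, g, b = 1.0, -(w - 645) / 65, 0.0
    else:
        r, g, b = 1.0, 0.0, 0.0
    if w < 420:
        fade = 0.3 + 0.7 * (w - 380) / 40
    elif w > 700:
        fade = 0.3 + 0.7 * (780 - w) / 80
    else:
        fade = 1.0
    return (r * fade, g * fade, b * fade)


def white_led_lines(
    dispersion_nm_per_px: float = 0.9, origin_nm: float = 380.0
) -> list[tuple[float, float, float]]:
    """Emission lines mimicking a white LED: narrow blue peak at 450 nm
    plus a broad phosphor band around 550-650 nm, with the characteristic
    dip in the green region between them."""

    def pos(lam: float) -> float:
        return (lam - origin_nm) / dispersion_nm_per_px

    return [
        (pos(450.0), 1.0, 9.0),
        (pos(575.0), 0.55, 30.0),
        (pos(615.0), 0.45, 30.0),
    ]


def make_spectrum_frame(
    lines: list[tuple[float, float, float]],
    dispersion_nm_per_px: float = 0.9,
    origin_nm: float = 380.0,
    axis_tilt_deg: float = 0.0,
    stripe_sigma_px: float = 12.0,
    background: float = 0.02,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (240, 640),
    seed: int = 0,
    bit_depth: int = 8,
) -> Frame:
    """Render a dispersed-spectrum camera frame.

    ``lines`` are (position_px along the dispersion axis, amplitude in
    [0, 1], Gaussian width in px).  The dispersion axis runs through the
    frame center at ``axis_tilt_deg``; each line is a Gaussian stripe
    whose RGB color follows the piecewise wavelength map at
    ``origin_nm + dispersion * position``.  Perpendicular to the axis
    the stripe falls off with ``stripe_sigma_px``.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    max_val = float(2**bit_depth - 1)
    theta = np.deg2rad(axis_tilt_deg)
    cy, cx = (h - 1) / 2, (w - 1) / 2
    yy, xx = np.mgrid[0:h, 0:w]
    # coordinate along the tilted axis, measured from the left intercept
    s = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta) + cx
    q = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    perp = np.exp(-(q**2) / (2 * stripe_sigma_px**2))
    img = np.zeros((h, w, 3))
    for pos_px, amp, width_px in lines:
        lam = origin_nm + dispersion_nm_per_px * pos_px
        rgb = wavelength_to_rgb(lam)
        profile = amp * np.exp(-((s - pos_px) ** 2) / (2 * width_px**2)) * perp
        for c in range(3):
            img[..., c] += rgb[c] * profile
    img = (background + img) * max_val
    img = np.clip(img, 0, max_val)
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = _add_noise(img[..., c], rng, noise_sd, max_val)
    meta = {
        "kind": "spectrum_frame",
        "dispersion_nm_per_px": dispersion_nm_per_px,
        "origin_nm": origin_nm,
        "axis_tilt_deg": axis_tilt_deg,
        "lines": [tuple(line) for line in lines],
    }
    return Frame(out, bit_depth=bit_depth, metadata=meta)


# --------------------------------------------------------------------------
# hologram scenes


def make_particle_scene(
    n_particles: int,
    z_um: float,
    shape: tuple[int, int] = (512, 512),
    pixel_pitch_um: float = 2.2,
    radius_range_um: tuple[float, float] = (4.0, 10.0),
    opacity_range: tuple[float, float] = (0.7, 1.0),
    min_separation_um: float | None = None,
    margin_frac: float = 0.25,
    seed: int = 0,
) -> ParticleScene:
    """Random absorbing-disc scene for inline-hologram simulation.

    Particles are placed uniformly inside the central
    ``(1 - 2 * margin_frac)`` region of the field of view with pairwise
    center separation of at least ``min_separation_um`` (default
    3 x pixel pitch, the separability floor for reconstruction), radii
    and opacities drawn uniformly from the given ranges.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    fov_x = w * pixel_pitch_um
    fov_y = h * pixel_pitch_um
    if min_separation_um is None:
        min_separation_um = 3.0 * pixel_pitch_um
    # keep discs well inside so fringes stay in the field
    sep = max(min_separation_um, 2.5 * radius_range_um[1])
    particles: list[tuple[float, float, float, float]] = []
    attempts = 0
    while len(particles) < n_particles:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place particles with the given separation")
        x = rng.uniform(margin_frac * fov_x, (1 - margin_frac) * fov_x)
        y = rng.uniform(margin_frac * fov_y, (1 - margin_frac) * fov_y)
        if any(np.hypot(x - p[0], y - p[1]) < sep for p in particles):
            continue
        r = rng.uniform(*radius_range_um)
        op = rng.uniform(*opacity_range)
        particles.append((float(x), float(y), float(r), float(op)))
    return ParticleScene(particles=particles, z_um=z_um)
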