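"""Inline (lensless) holography: forward simulation and numerical refocus.

In an inline holographic microscope a quasi-point source (a narrow-band
LED behind a pinhole, typically ~80 mm away) illuminates a sample placed
directly on the bare sensor.  Scattered and unscattered waves interfere
on the sensor; the recorded intensity pattern is refocused numerically
by backpropagating the estimated complex field to the sample plane.

The propagator is the band-limited angular spectrum method — exact
scalar diffraction, applied as a unit-modulus transfer function over the
propagating frequency band — with a paraxial single-FFT Fresnel mode
available for cross-checking.  With the sample a distance ``z`` above
the sensor and the source at ``L`` from the sample, the spherical
illumination is equivalent to plane-wave illumination over the effective
distance ``z_eff = z L / (L + z)`` with lateral magnification
``(L + z)/L``; for z of a few mm and L ~ 80 mm this is within a few
percent of z, and plane-wave mode is the default.

The twin image inherent to single-shot inline holograms is *not*
removed: reconstruction is plain backpropagation, no phase retrieval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from tinyscope.frames import Frame

PLANE_WAVE = "plane-wave"


@dataclass
class Hologram:
    """A raw inline hologram plus the optical metadata needed to refocus it.

    ``source_distance_mm`` is the pinhole-to-sample distance in mm, or
    the string ``"plane-wave"`` for collimated illumination (the default
    regime when the sample sits directly on the sensor window).
    """

    frame: Frame
    wavelength_nm: float = 450.0
    pixel_pitch_um: float = 2.2
    source_distance_mm: float | str = PLANE_WAVE
    background: Frame | None = None

    def __post_init__(self) -> None:
        if not 350 <= self.wavelength_nm <= 800:
            raise ValueError("wavelength must be in [350, 800] nm")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.frame.is_rgb:
            raise ValueError("hologram frame must be grayscale")
        if self.background is not None and (
            self.background.pixels.shape != self.frame.pixels.shape
        ):
            raise ValueError("background must match the hologram shape")

    def effective_distance_um(self, z_um: float) -> float:
        """Plane-wave-equivalent propagation distance for depth ``z_um``."""
        if self.source_distance_mm == PLANE_WAVE:
            return z_um
        L_um = float(self.source_distance_mm) * 1000.0
        return z_um * L_um / (L_um + z_um)


@dataclass
class ComplexField:
    """A sampled scalar complex field with its pixel pitch in um."""

    values: np.ndarray
    pitch_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("field must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


@dataclass
class ParticleScene:
    """Absorbing discs at depth z above the sensor.

    ``particles`` is a list of ``(x_um, y_um, radius_um, opacity)`` with
    x/y measured from the field-of-view top-left corner and opacity in
    [0, 1] (1 = fully absorbing).
    """

    particles: list[tuple[float, float, float, float]]
    z_um: float

    def __post_init__(self) -> None:
        if self.z_um <= 0:
            raise ValueError("scene depth must be positive")
        for x, y, r, op in self.particles:
            if not 0 <= op <= 1:
                raise ValueError("opacity must be in [0, 1]")
            if r <= 0:
                raise ValueError("radius must be positive")


def normalize_hologram(h: Hologram, eps: float = 1e-6) -> ComplexField:
    """Estimate the complex field at the sensor from a raw hologram.

    Divides by the background frame (or by the hologram's own mean when
    none is given) to form a contrast image, takes the square root as the
    amplitude estimate, and sets the phase to zero.  Background pixels
    below ``eps`` of full scale are floored; the number floored is
    recorded in the metadata and reported with a warning.
    """
    raw = h.frame.pixels.astype(float)
    floor = eps * h.frame.max_value
    if h.background is not None:
        bg = h.background.pixels.astype(float)
    else:
        bg = np.full_like(raw, max(raw.mean(), floor))
    n_floored = int(np.count_nonzero(bg < floor))
    if n_floored:
        warnings.warn(
            f"{n_floored} background pixels below {eps} of full scale were floored",
            RuntimeWarning,
            stacklevel=2,
        )
        bg = np.maximum(bg, floor)
    contrast = raw / bg
    amplitude = np.sqrt(np.clip(contrast, 0.0, None))
    return ComplexField(
        amplitude.astype(complex),
        h.pixel_pitch_um,
        metadata={"floored_background_px": n_floored},
    )


def _transfer_function(
    shape: tuple[int, int], pitch_um: float, distance_um: float, wavelength_um: float
) -> np.ndarray:
    """Angular-spectrum transfer function; evanescent band zeroed."""
    fy = scipy.fft.fftfreq(shape[0], d=pitch_um)
    fx = scipy.fft.fftfreq(shape[1], d=pitch_um)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    arg = 1.0 / wavelength_um**2 - f2
    prop = arg > 0
    kz = np.sqrt(np.where(prop, arg, 0.0))
    return np.where(prop, np.exp(2j * np.pi * distance_um * kz), 0.0)


def angular_spectrum_propagate(
    field: ComplexField,
    distance_um: float,
    wavelength_nm: float,
    method: str = "angular_spectrum",
) -> ComplexField:
    """Propagate a field by ``distance_um`` (negative = backpropagation).

    The default method multiplies the field's angular spectrum by the
    exact scalar transfer function ``exp(i 2 pi d sqrt(1/lambda^2 - fx^2
    - fy^2))``, zeroing the evanescent band — unitary on the propagating
    band, so intensity is conserved for band-limited input and +z then -z
    is an identity.  ``method="fresnel"`` uses the paraxial quadratic
    phase approximation instead (cross-check mode).

    A warning is emitted when |distance| exceeds the aliasing guard
    ``pitch^2 * N / lambda`` (the transfer function's phase then wraps
    between frequency samples).
    """
    lam_um = wavelength_nm / 1000.0
    n_min = min(field.values.shape)
    guard = field.pitch_um**2 * n_min / lam_um
    if abs(distance_um) > guard:
        warnings.warn(
            f"|distance| {abs(distance_um):.0f} um exceeds the aliasing guard "
            f"{guard:.0f} um for this sampling; expect wraparound artifacts",
            RuntimeWarning,
            stacklevel=2,
        )
    if not np.all(np.isfinite(field.values)):
        raise ValueError("field contains non-finite values")
    spectrum = scipy.fft.fft2(field.values)
    if method == "angular_spectrum":
        H = _transfer_function(field.values.shape, field.pitch_um, distance_um, lam_um)
    elif method == "fresnel":
        fy = scipy.fft.fftfreq(field.values.shape[0], d=field.pitch_um)
        fx = scipy.fft.fftfreq(field.values.shape[1], d=field.pitch_um)
        f2 = fy[:, None] ** 2 + fx[None, :] ** 2
        H = np.exp(2j * np.pi * distance_um / lam_um) * np.exp(
            -1j * np.pi * lam_um * distance_um * f2
        )
    else:
        raise ValueError(f"unknown propagation method {method!r}")
    out = scipy.fft.ifft2(spectrum * H)
    return ComplexField(out, field.pitch_um, metadata=dict(field.metadata))


def _pad_field(
    values: np.ndarray, taper_px: int = 16
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Pad to the next power of two with the border mean, cosine-tapered.

    Returns the padded array and the slices that recover the original
    region.  Tapering blends the field's edges into the pad value so the
    periodic FFT boundary does not introduce a hard edge.
    """
    h, w = values.shape
    H = 1 << (h - 1).bit_length()
    W = 1 << (w - 1).bit_length()
    H, W = max(H, h), max(W, w)
    border = np.concatenate(
        [values[0, :], values[-1, :], values[:, 0], values[:, -1]]
    )
    pad_value = border.mean()
    if taper_px > 0 and min(h, w) > 2 * taper_px:
        win = np.ones(h)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(taper_px) / taper_px))
        wy = win.copy()
        wy[:taper_px] = ramp
        wy[-taper_px:] = ramp[::-1]
        wx = np.ones(w)
        wx[:taper_px] = ramp
        wx[-taper_px:] = ramp[::-1]
        w2d = wy[:, None] * wx[None, :]
        values = pad_value + (values - pad_value) * w2d
    y0 = (H - h) // 2
    x0 = (W - w) // 2
    out = np.full((H, W), pad_value, dtype=complex)
    out[y0 : y0 + h, x0 : x0 + w] = values
    return out, (slice(y0, y0 + h), slice(x0, x0 + w))


def _propagate_padded(
    field: ComplexField,
    distance_um: float,
    wavelength_nm: float,
    method: str = "angular_spectrum",
    taper_px: int = 16,
) -> ComplexField:
    """Propagate with power-of-two padding and edge apodization.

    Used by the hologram pipeline (reconstruction / simulation), where
    the field has a flat unit background that pads naturally.
    """
    padded, crop = _pad_field(field.values, taper_px=taper_px)
    out = angular_spectrum_propagate(
        ComplexField(padded, field.pitch_um), distance_um, wavelength_nm, method
    )
    return ComplexField(out.values[crop], field.pitch_um, metadata=dict(field.metadata))


def reconstruct(
    h: Hologram,
    z_um: float,
    method: str = "angular_spectrum",
    bit_depth: int | None = None,
) -> Frame:
    """Numerically refocus a hologram to the sample plane at depth ``z_um``.

    Normalizes the hologram, backpropagates by the effective distance
    (spherical-source correction applied when a source distance is set),
    and returns the squared modulus rescaled to the output bit depth.
    Absorbing particles appear as local intensity minima; the twin image
    remains as a weak out-of-focus halo.
    """
    if z_um <= 0:
        raise ValueError("sample-to-sensor distance z must be positive")
    field = normalize_hologram(h)
    z_eff = h.effective_distance_um(z_um)
    back = _propagate_padded(field, -z_eff, h.wavelength_nm, method)
    intensity = back.intensity
    depth = bit_depth if bit_depth is not None else h.frame.bit_depth
    max_val = float(2**depth - 1)
    peak = intensity.max()
    scaled = intensity * (max_val / peak) if peak > 0 else intensity
    scaled = np.clip(scaled, 0.0, max_val)
    return Frame(
        scaled,
        bit_depth=depth,
        metadata={"z_um": z_um, "z_eff_um": z_eff, "method": method},
    )


FOCUS_CRITERIA = ("min_amplitude", "variance")


def focus_metric(intensity: np.ndarray, criterion: str = "min_amplitude") -> float:
    """Refocus score of one reconstructed plane (higher = sharper).

    ``"min_amplitude"`` (default) is the integrated-amplitude criterion
    for absorbing objects: the spatial integral of |A| is minimal at the
    in-focus plane, where the object's absorption is most concentrated,
    so the score is ``-mean(|A|)``.  ``"variance"`` is the normalized
    intensity variance ``var/mean^2``; it peaks at focus too but rides on
    a baseline that grows toward the sensor plane (the raw fringe
    contrast), which can swamp the focus peak for sparse weak scenes.
    """
    m = intensity.mean()
    if m == 0:
        return 0.0
    if criterion == "min_amplitude":
        return float(-np.sqrt(np.clip(intensity, 0.0, None)).mean())
    if criterion == "variance":
        return float(intensity.var() / m**2)
    raise ValueError(f"unknown focus criterion {criterion!r}; choose from {FOCUS_CRITERIA}")


def z_scan(
    h: Hologram,
    z_min_um: float,
    z_max_um: float,
    steps: int,
    method: str = "angular_spectrum",
    criterion: str = "min_amplitude",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Refocus over a uniform z grid and pick the sharpest plane.

    Returns ``(best_z_um, z_grid, scores)`` where scores come from
    :func:`focus_metric` per plane; ties go to the smaller z.
    """
    if not 0 < z_min_um < z_max_um:
        raise ValueError("need 0 < z_min < z_max")
    if steps < 3:
        raise ValueError("need at least 3 scan steps")
    z_grid = np.linspace(z_min_um, z_max_um, steps)
    field = normalize_hologram(h)
    padded, crop = _pad_field(field.values)
    pf = ComplexField(padded, field.pitch_um)
    scores = np.empty(steps)
    for i, z in enumerate(z_grid):
        z_eff = h.effective_distance_um(float(z))
        back = angular_spectrum_propagate(pf, -z_eff, h.wavelength_nm, method)
        scores[i] = focus_metric(np.abs(back.values[crop]) ** 2, criterion)
    # ties (within numerical noise of the max) go to the smallest z
    tol = 1e-9 * max(1.0, float(np.abs(scores).max()))
    best = int(np.flatnonzero(scores >= scores.max() - tol)[0])
    return float(z_grid[best]), z_grid, scores


def simulate_inline(
    scene: ParticleScene,
    shape: tuple[int, int] = (512, 512),
    wavelength_nm: float = 450.0,
    pixel_pitch_um: float = 2.2,
    source_distance_mm: float | str = PLANE_WAVE,
    noise_sd: float = 0.01,
    bit_depth: int = 8,
    seed: int | None = None,
) -> Hologram:
    """Forward-simulate an inline hologram of absorbing discs.

    A unit plane wave is multiplied by the scene's transmission mask
    (1 - opacity inside each disc), propagated to the sensor over the
    effective distance, and recorded as the squared modulus plus Gaussian
    read noise (``noise_sd`` in units of the background level), then
    quantized to ``bit_depth``.  Deterministic for a fixed seed.
    """
    h_px, w_px = shape
    mask = np.ones(shape)
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    for x_um, y_um, r_um, opacity in scene.particles:
        if not (0 <= x_um <= w_px * pixel_pitch_um and 0 <= y_um <= h_px * pixel_pitch_um):
            raise ValueError(f"particle at ({x_um}, {y_um}) um outside the field of view")
        if r_um < pixel_pitch_um / 2:
            raise ValueError("particle radius below half the pixel pitch")
        r2 = (xx * pixel_pitch_um - x_um) ** 2 + (yy * pixel_pitch_um - y_um) ** 2
        disc = r2 <= r_um**2
        mask[disc] *= 1.0 - opacity
    field = ComplexField(mask.astype(complex), pixel_pitch_um)
    if source_distance_mm == PLANE_WAVE:
        z_eff = scene.z_um
    else:
        L_um = float(source_distance_mm) * 1000.0
        if scene.z_um > 0.2 * L_um:
            raise ValueError("scene depth must be small compared to the source distance")
        z_eff = scene.z_um * L_um / (L_um + scene.z_um)
    at_sensor = _propagate_padded(field, +z_eff, wavelength_nm, taper_px=0)
    intensity = at_sensor.intensity
    rng = np.random.default_rng(seed)
    noisy = intensity + rng.normal(0.0, noise_sd, size=shape)
    max_val = 2**bit_depth - 1
    # background (unit plane wave) mapped to half scale: headroom for fringes
    counts = np.clip(np.round(noisy * max_val / 2.0), 0, max_val)
    frame = Frame(counts, bit_depth=bit_depth, metadata={"simulated": True})
    return Hologram(
        frame,
        wavelength_nm=wavelength_nm,
        pixel_pitch_um=pixel_pitch_um,
        source_distance_mm=source_distance_mm,
    )
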