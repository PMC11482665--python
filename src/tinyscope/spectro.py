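"""Spectrum extraction and wavelength calibration for a DIY spectrometer.

The instrument is a camera module behind a transmission grating
(~1000 lines/mm, tilted ~35 deg) fed by a pinhole slit: the first
diffraction order lands on the sensor as a stripe of dispersed light.
The user selects the two endpoints of that stripe; the spectrum is the
intensity sampled along the segment, averaged over a perpendicular band.

Pixel positions along the axis are mapped to wavelength with an ordinary
least-squares line fitted to known (position, wavelength) pairs — the
linear model is standard for slit/grating CMOS spectrometers over the
visible range; a quadratic option is exposed for setups where grating
tilt introduces measurable nonlinearity.  Physical layout parameters
(grating pitch, tilt, slit bore, slit-grating distance) are carried as
metadata only and never enter the computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from tinyscope.frames import LUMA_WEIGHTS, Frame


@dataclass(frozen=True)
class DispersionAxis:
    """The user-selected spectral segment: endpoints in (x, y) pixels plus
    the odd width (in px) of the perpendicular averaging band."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    band_width: int = 1

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ValueError("axis endpoints must differ")
        if self.band_width < 1 or self.band_width % 2 == 0:
            raise ValueError("band width must be an odd integer >= 1")


@dataclass
class Spectrum:
    """A 1-D spectrum: position along the dispersion axis (px), one
    intensity array per color channel plus luminance, and an optional
    wavelength axis filled in by :func:`apply_calibration`."""

    position_px: np.ndarray
    channels: dict[str, np.ndarray]
    wavelength_nm: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position_px = np.asarray(self.position_px, dtype=float)
        n = self.position_px.size
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = arr
        if self.wavelength_nm is not None and len(self.wavelength_nm) != n:
            raise ValueError("wavelength axis length mismatch")

    @property
    def luminance(self) -> np.ndarray:
        return self.channels["lum"]


@dataclass(frozen=True)
class WavelengthCalibration:
    """Linear pixel-to-wavelength map lambda = slope * p + intercept."""

    slope_nm_per_px: float
    intercept_nm: float
    rms_residual_nm: float
    n_points: int
    quadratic_nm_per_px2: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if self.slope_nm_per_px == 0:
            raise ValueError("calibration slope must be nonzero")

    def __call__(self, position_px: np.ndarray) -> np.ndarray:
        p = np.asarray(position_px, dtype=float)
        return (
            self.quadratic_nm_per_px2 * p**2
            + self.slope_nm_per_px * p
            + self.intercept_nm
        )


def extract_spectrum(
    frame: Frame,
    axis: DispersionAxis,
    saturation_level: float = 0.99,
) -> Spectrum:
    """Sample the frame along the dispersion axis at 1-px steps.

    Intensities are bilinearly interpolated and averaged over
    ``band_width`` pixels perpendicular to the axis (unweighted mean).
    Saturated pixels (>= ``saturation_level`` of full scale) are excluded
    from the perpendicular mean and counted; band samples falling outside
    the frame are clipped to the border, with a warning giving the count.
    """
    h, w = frame.pixels.shape[:2]
    for px, py in (axis.p0, axis.p1):
        if not (0 <= px <= w - 1 and 0 <= py <= h - 1):
            raise ValueError(f"axis endpoint ({px}, {py}) outside the frame")
    p0 = np.asarray(axis.p0, dtype=float)
    p1 = np.asarray(axis.p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = int(np.floor(length)) + 1
    t = np.arange(n)
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    half = axis.band_width // 2
    offsets = np.arange(-half, half + 1)
    # sample grid: (band, n) coordinates in (x, y)
    xs = p0[0] + t[None, :] * direction[0] + offsets[:, None] * normal[0]
    ys = p0[1] + t[None, :] * direction[1] + offsets[:, None] * normal[1]
    n_outside = int(
        np.count_nonzero((xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1))
    )
    if n_outside:
        warnings.warn(
            f"{n_outside} band samples fall outside the frame and were clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    coords = np.stack([np.clip(ys, 0, h - 1), np.clip(xs, 0, w - 1)])

    def _sample(plane: np.ndarray) -> np.ndarray:
        return scipy.ndimage.map_coordinates(
            plane.astype(float), coords, order=1, mode="nearest"
        )

    if frame.is_rgb:
        bands = {c: _sample(frame.pixels[..., i]) for i, c in enumerate("rgb")}
    else:
        g = _sample(frame.pixels)
        bands = {"r": g, "g": g, "b": g}
    # mask saturated samples out of the perpendicular mean
    sat_thresh = saturation_level * frame.max_value
    lum_band = (
        bands["r"] * LUMA_WEIGHTS[0]
        + bands["g"] * LUMA_WEIGHTS[1]
        + bands["b"] * LUMA_WEIGHTS[2]
    )
    saturated = lum_band >= sat_thresh
    n_saturated = int(np.count_nonzero(saturated))
    weights = np.where(saturated, 0.0, 1.0)
    denom = weights.sum(axis=0)
    all_sat = denom == 0
    denom = np.where(all_sat, axis.band_width, denom)
    weights = np.where(all_sat[None, :], 1.0, weights)
    channels = {
        name: (arr * weights).sum(axis=0) / denom for name, arr in bands.items()
    }
    channels["lum"] = (
        channels["r"] * LUMA_WEIGHTS[0]
        + channels["g"] * LUMA_WEIGHTS[1]
        + channels["b"] * LUMA_WEIGHTS[2]
    )
    return Spectrum(
        t.astype(float),
        channels,
        metadata={
            "band_width": axis.band_width,
            "n_saturated": n_saturated,
            "n_clipped": n_outside,
        },
    )


def fit_calibration(
    pairs: list[tuple[float, float]],
    quadratic: bool = False,
) -> WavelengthCalibration:
    """Least-squares pixel-to-wavelength calibration.

    ``pairs`` are (position_px, wavelength_nm) reference points, e.g.
    known emission lines.  By default fits a line; ``quadratic=True``
    adds a second-order term (needs >= 3 points).
    """
    if len(pairs) < 2:
        raise ValueError("calibration needs at least 2 points")
    p = np.array([x for x, _ in pairs], dtype=float)
    lam = np.array([y for _, y in pairs], dtype=float)
    if np.unique(p).size < 2:
        raise ValueError("calibration needs at least 2 distinct positions")
    deg = 2 if quadratic else 1
    if quadratic and len(pairs) < 3:
        raise ValueError("quadratic calibration needs at least 3 points")
    coeffs = np.polyfit(p, lam, deg)
    fitted = np.polyval(coeffs, p)
    rms = float(np.sqrt(np.mean((lam - fitted) ** 2)))
    if quadratic:
        quad, slope, intercept = coeffs
    else:
        quad = 0.0
        slope, intercept = coeffs
    return WavelengthCalibration(
        slope_nm_per_px=float(slope),
        intercept_nm=float(intercept),
        rms_residual_nm=rms,
        n_points=len(pairs),
        quadratic_nm_per_px2=float(quad),
    )


def apply_calibration(s: Spectrum, cal: WavelengthCalibration) -> Spectrum:
    """Return a copy of the spectrum with its wavelength axis populated."""
    return Spectrum(
        s.position_px.copy(),
        {k: v.copy() for k, v in s.channels.items()},
        wavelength_nm=cal(s.position_px),
        metadata=dict(s.metadata),
    )


def absorbance(
    sample: Spectrum, reference: Spectrum, floor: float = 1e-6
) -> Spectrum:
    """Absorbance A = -log10(I_sample / I_reference), per channel.

    Both spectra must share one position grid.  Intensities are floored
    at ``floor`` times the reference channel's maximum so blank pixels do
    not produce infinities.
    """
    if sample.position_px.shape != reference.position_px.shape or not np.allclose(
        sample.position_px, reference.position_px
    ):
        raise ValueError("sample and reference must share one position grid")
    channels = {}
    for name in sample.channels:
        i_s = sample.channels[name]
        i_r = reference.channels[name]
        scale = max(i_r.max(), 1.0)
        lo = floor * scale
        channels[name] = -np.log10(
            np.maximum(i_s, lo) / np.maximum(i_r, lo)
        )
    # absorbance may be negative where the sample outshines the reference
    return Spectrum(
        sample.position_px.copy(),
        channels,
        wavelength_nm=(
            None if sample.wavelength_nm is None else np.asarray(sample.wavelength_nm)
        ),
        metadata={"kind": "absorbance"},
    )
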