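"""Closed-form optical design calculator for finite-conjugate setups.

Sign convention (Cartesian, light travels left to right): object
distances ``a`` are negative, image distances ``a'`` positive, so the
thin-lens equation reads ``1/f' = 1/a' - 1/a`` and the transverse
magnification ``M = -a'/a`` is positive for a real, inverted,
finite-conjugate image.  A typical pocket-microscope configuration uses
the camera module's own objective (f' ~ 4 mm, f/2.2, 2.2 um pixels)
slightly unscrewed to reach a ~ -4 mm, a' ~ 18 mm, i.e. M ~ 4.5 and an
effective object-side pixel of ~0.5 um.

Each function computes exactly the requested quantity; the calculator
never cross-validates user inputs against each other (published example
values are rounded and mutually inconsistent at the percent level).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalConfig:
    """Static optical parameters of a camera-module microscope.

    Lengths use the units conventional for each quantity: focal length in
    mm, wavelength in nm, pixel pitch in um.
    """

    focal_length_mm: float = 4.0
    f_number: float = 2.2
    wavelength_nm: float = 550.0
    pixel_pitch_um: float = 2.2
    sensor_px: tuple[int, int] = (1600, 1200)

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0:
            raise ValueError("focal length must be positive")
        if self.f_number < 0.5:
            raise ValueError("f-number must be >= 0.5")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if min(self.sensor_px) < 1:
            raise ValueError("sensor must have at least 1x1 pixels")


@dataclass(frozen=True)
class ConjugatePair:
    """Object/image conjugate distances in mm (a < 0 < a' for a real image)."""

    a_mm: float
    a_prime_mm: float

    @property
    def track_length_mm(self) -> float:
        """Total object-to-image distance d = a' - a."""
        return self.a_prime_mm - self.a_mm


def magnification(pair: ConjugatePair) -> float:
    """Transverse magnification M = -a'/a.

    Positive for the standard real-image case a < 0 < a'.
    """
    if pair.a_mm == 0:
        raise ValueError("object distance must be nonzero")
    return -pair.a_prime_mm / pair.a_mm


def lens_solve(
    focal_length_mm: float,
    a_mm: float | None = None,
    a_prime_mm: float | None = None,
) -> ConjugatePair:
    """Solve the thin-lens equation 1/f' = 1/a' - 1/a for the missing distance.

    Exactly one of ``a_mm`` (object side, negative) or ``a_prime_mm``
    (image side, positive) must be given.

    Raises
    ------
    ValueError
        If the known distance puts the conjugate at infinity (object at
        the front focal plane, or image at the back focal plane).
    """
    if focal_length_mm <= 0:
        raise ValueError("focal length must be positive")
    if (a_mm is None) == (a_prime_mm is None):
        raise ValueError("provide exactly one of a_mm or a_prime_mm")
    f = focal_length_mm
    if a_mm is not None:
        if a_mm == 0:
            raise ValueError("object distance must be nonzero")
        if a_mm + f == 0:
            raise ValueError(
                "image at infinity: object sits at the front focal plane "
                f"(a = -f' = {a_mm} mm)"
            )
        # 1/a' = 1/f' + 1/a
        a_prime = f * a_mm / (a_mm + f)
        return ConjugatePair(a_mm=a_mm, a_prime_mm=a_prime)
    assert a_prime_mm is not None
    if a_prime_mm == 0:
        raise ValueError("image distance must be nonzero")
    if a_prime_mm == f:
        raise ValueError(
            "object at infinity: image sits at the back focal plane "
            f"(a' = f' = {a_prime_mm} mm)"
        )
    # 1/a = 1/a' - 1/f'
    a = f * a_prime_mm / (f - a_prime_mm)
    return ConjugatePair(a_mm=a, a_prime_mm=a_prime_mm)


def numerical_aperture(f_number: float) -> float:
    """Image-side NA of a lens approximated as NA = 1/(2 f#)."""
    if f_number <= 0:
        raise ValueError("f-number must be positive")
    return 1.0 / (2.0 * f_number)


def diffraction_limit(wavelength_nm: float, na: float) -> float:
    """Diffraction-limited resolution d = lambda / (2 NA), returned in um."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if not 0 < na <= 1.5:
        raise ValueError("NA must be in (0, 1.5]")
    return wavelength_nm / (2.0 * na) / 1000.0


def effective_pixel(pixel_pitch_um: float, magnification: float) -> float:
    """Object-side (effective) pixel size: sensor pitch / |M|, in um."""
    if pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be positive")
    if magnification == 0:
        raise ValueError("magnification must be nonzero")
    return pixel_pitch_um / abs(magnification)


def nyquist_margin(optical_resolution_um: float, effective_pixel_um: float) -> float:
    """Ratio d / (2 * effective pixel); >= 1 means Nyquist sampling is met.

    Note this disregards the Bayer color mosaic, which halves the
    per-channel sampling rate on single-chip color sensors.
    """
    if optical_resolution_um <= 0 or effective_pixel_um <= 0:
        raise ValueError("both lengths must be positive")
    return optical_resolution_um / (2.0 * effective_pixel_um)


def actuator_step(travel_mm: float, resolution_bits: int) -> float:
    """Smallest axial step of a PWM-driven actuator, in um.

    A voice-coil focuser with ``travel_mm`` of linear motion discretized
    at ``resolution_bits`` yields travel / 2**bits per step (1 mm at
    8 bits -> ~3.9 um).
    """
    if travel_mm <= 0:
        raise ValueError("travel must be positive")
    if resolution_bits < 1:
        raise ValueError("resolution must be at least 1 bit")
    return travel_mm * 1000.0 / (2**resolution_bits)


def design_report(
    config: OpticalConfig,
    pair: ConjugatePair | None = None,
) -> dict[str, float]:
    """Full design chain for one configuration, as a flat dict.

    Includes NA, diffraction-limited resolution, and — when a conjugate
    pair is given — magnification, effective pixel and Nyquist margin.
    """
    na = numerical_aperture(config.f_number)
    d_um = diffraction_limit(config.wavelength_nm, na)
    report: dict[str, float] = {"na": na, "resolution_um": d_um}
    if pair is not None:
        m = magnification(pair)
        eff = effective_pixel(config.pixel_pitch_um, m)
        report.update(
            magnification=m,
            effective_pixel_um=eff,
            nyquist_margin=nyquist_margin(d_um, eff),
            track_length_mm=pair.track_length_mm,
        )
    return report
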