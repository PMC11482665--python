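# Methods

This note records the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would want written down.

## Optical design calculator

Sign convention: Cartesian, light travels left→right; object distances
`a` are negative and image distances `a′` positive, so the thin-lens
equation is `1/f′ = 1/a′ − 1/a` and `M = −a′/a` is positive for the
real, inverted image of a finite-conjugate microscope. Each function
computes only the requested quantity and never cross-validates inputs:
vendor-quoted values for these modules are rounded (`f′ ≈ 4 mm`,
`a ≈ −4 mm`, `a′ ≈ 18 mm` are mutually inconsistent with the lens
equation at the percent level), and silently "correcting" a user's
numbers would hide that. The quoted configuration therefore reports
M = 4.5 exactly, while the conventional data-sheet figure (M ≈ 4,
effective pixel ≈ 0.6 µm) follows from the rounded magnification.

`NA = 1/(2·f#)` is the standard small-angle approximation; it ignores
the reduced effective aperture of the finite-conjugate arrangement and
all aberrations, so computed resolutions are best-case. The actuator
step model is purely geometric: a travel of 1 mm PWM-discretized at
8 bits gives 1000/256 ≈ 3.9 µm per step; no hysteresis or current
nonlinearity is modelled.

## Sharpness metrics and autofocus

Both metrics are *relative*: only rank order within one focus sweep is
meaningful.

* `jpeg_size`: the frame is re-encoded as baseline JPEG (Pillow,
  quality 85, chroma subsampling off) and the byte count is the score.
  JPEG allocates bits to high-frequency DCT coefficients, so defocus
  blur shrinks the file. The encoder settings are fixed and recorded in
  the curve metadata because scores across encoder configurations are
  not commensurable; the metric re-encodes rather than trusting
  whatever compression a camera pipeline applied.
* `dct`: mean over 8×8 blocks of the energy fraction outside the
  top-left 2×2 DCT corner. The DC term (and hence scene brightness)
  sits in the excluded corner, making the score 0 for constant frames
  and monotone in blur on textured scenes. The exact statistic (2×2
  exclusion) is this package's choice among the family of DCT sharpness
  measures.

Autofocus is an exhaustive sweep plus argmax over a recorded stack —
matching how bracketing firmware actually works (store everything,
choose afterwards) — not closed-loop hill climbing. Tie-breaking is
deliberate and documented: equal scores resolve toward the z closest to
the median of the sweep (the nominal focus the bracket was centred on),
then toward smaller z. `count_modes` calls a curve unimodal when it has
exactly one local maximum with prominence above 5% of the curve's
dynamic range; wiggles below that are treated as noise, and edge maxima
count.

The EDOF composite selects, per pixel, the layer maximizing local
luminance variance in a 9×9 window — pure selection, never blending, so
output pixel values are a subset of input values. The window default
balances seam localization against noise; it is exposed as a parameter.

Exposure selection scores each bracket frame by the fraction of pixels
in the [0.1, 0.9] band of full scale, subject to a 1% cap on saturated
pixels (≥ 0.99 full scale); if every frame violates the cap the least
saturated wins, and exact ties resolve to the shorter exposure. The
band and cap are this package's operationalization of "best
illumination" — the deployed instruments' firmware never defines one.
The default acquisition plan (exposure ladder 1/2/5/10/20/50/100/200/
500 ms, one event per 60 s, deep sleep between events) mirrors the
documented submersible-deployment configuration; the focus-bracket
offsets, nowhere enumerated for the original hardware, default to ±2
actuator steps ({−8, −4, 0, +4, +8} µm).

## Inline holography

The propagator is the band-limited angular-spectrum method: multiply
the field's FFT by `exp(i·2π·d·√(1/λ² − f_x² − f_y²))` and zero the
evanescent band. This is exact scalar diffraction, unitary on the
propagating band (so +d then −d is an identity and intensity is
conserved for band-limited fields), and safer than single-FFT Fresnel
at millimetre distances with 2.2 µm sampling; a paraxial `fresnel` mode
exists as a cross-check and agrees to ~1e−7 RMS in its validity regime.
An aliasing warning (not an error) fires when `|d| > pitch²·N/λ`.

Pipeline choices:

* **Normalization** divides the raw hologram by its background frame
  (or its own mean), floors background pixels below 1e−6 of full scale
  (counted, warned), and takes the square root as the amplitude
  estimate with zero phase.
* **Padding**: the hologram pipeline pads to the next power of two
  before the FFT and crops after. The pad value is the border mean and
  a 16-px cosine taper blends the field edge into it, so a unit-
  background contrast field continues smoothly and wraparound artifacts
  stay small. The bare propagator does not pad — keeping it exactly
  unitary — padding belongs to `reconstruct`/`simulate_inline`/`z_scan`.
* **Spherical illumination** from a source at distance L is folded into
  plane-wave propagation over `z_eff = z·L/(L+z)`; with samples a few
  mm above the sensor and L ≈ 80 mm the correction is ≈ 2–4%.
  Plane-wave mode is the default because the intended use places the
  sample directly on the sensor window.
* **No phase retrieval**: the twin image remains, as in the real
  instrument's plain backpropagation display.
* **Depth scoring**: `z_scan` scores each plane with the integrated-
  amplitude criterion for absorbing objects (score = −mean |A|, minimal
  integrated amplitude at focus). Normalized intensity variance is kept
  as an option, but measurements during development showed it is nearly
  conserved under propagation for sparse weak scatterers — the raw
  fringe contrast forms a baseline that rises toward the sensor and can
  exceed the focus peak, sending the argmax to the scan edge — whereas
  the integrated-amplitude criterion recovered the true depth on every
  tested scene. Ties (within 1e−9 of the maximum) resolve to smaller z.

The simulator builds a unit plane wave, multiplies by the scene's
transmission mask (discs of given opacity), propagates to the sensor,
and records the squared modulus with Gaussian read noise (default 1% of
the background level) quantized to 8 bits with the unit background at
half scale. Sampling floor: with 2.2 µm pixels, recovered features
below ~2 pixels are not meaningful, so random scenes enforce a minimum
particle-center separation of 3× the pitch.

## Spectrometry

Extraction samples the frame bilinearly at 1-px steps along the
user-selected segment, averaging an odd-width band perpendicular to it
with an unweighted mean; saturated samples (≥ 0.99 full scale) are
excluded from the mean and counted, and band samples beyond the frame
border are clipped with a warning. The wavelength model is a
least-squares line `λ = s·p + λ₀`: over the visible range a slitted
CMOS grating spectrometer is linear to well within its resolution, and
no geometry calibration is available to justify more; a quadratic term
is available behind a flag for tilted-grating setups (≥ 3 points).
Physical layout parameters (1000 lines/mm grating, 35° tilt, 0.1 mm
slit bore, 40 mm slit–grating distance) are carried as metadata only.
Absorbance floors both intensities at 1e−6 of the reference maximum to
avoid infinities; negative absorbance (sample brighter than reference)
is passed through, not clipped.

## Timelapse analytics

* **Flat-field**: `out = (frame − dark)/((flat − dark)/mean(flat −
  dark))`, clipped to the bit-depth range. Dividing by the unit-mean
  flat preserves mean brightness exactly; correction recovers the
  underlying scene exactly only when the vignetting profile used as
  flat is itself unit-mean (otherwise the output is the scene scaled by
  the flat's mean — inherent to any normalization convention).
* **Drift**: phase correlation (whitened cross-power spectrum) per
  successive pair, integer peak wrapped into ±N/2, refined per axis by
  a 3-point parabolic fit (offsets clipped to ±0.5 px, sub-1e−9 offsets
  snapped to zero so exact integer shifts stay exact). `peak_quality`
  is the peak height over the largest value outside a 5-px exclusion
  zone. Windowing before the FFT is available (`window="hann"`) but off
  by default: on cyclic test fixtures it biases recovered shifts by
  ~0.01 px, and the package's contract keeps noiseless cyclic shifts
  integer-exact; enable it for real, non-periodic frames where the FFT
  boundary correlates spuriously. Successive-pair registration with
  prefix-sum accumulation mirrors how deployment drift is analysed;
  registration errors therefore accumulate as √n random walk, which is
  documented rather than hidden by registering to a fixed reference.
  A plain (unwhitened) cross-correlation mode exists for comparison.
* **Variance projection**: per-pixel temporal variance of luminance,
  min-max rescaled to the output bit depth; order-free by construction.
* **Intensity series**: per-frame mean luminance tagged with timestamp
  and exposure group, as a tidy DataFrame; frames without exposure
  metadata collapse into one group with a warning.

Coordinates everywhere: origin top-left, x = column, y = row, 0-based;
`pair_shift(f1, f2) = (dx, dy)` means f2 ≈ f1 translated by (+dx, +dy).

## Synthetic generators

Every generator is a pure function of (parameters, seed) — identical
inputs are bit-identical outputs. They emulate the features the
analyses depend on and nothing more:

* defocus is Gaussian blur with σ(z) = σ₀ + rate·|z − z₀| (default
  0.4 px/µm on a 0–100 µm grid) — monotone in defocus like a real PSF,
  but without its ringing or asymmetry;
* sensor noise is Gaussian read noise (default 1% of full scale, a
  typical figure for small CMOS sensors at short exposure) with
  optional Poisson shot noise; no fixed-pattern noise, no Bayer mosaic;
* drift fixtures use cyclic Fourier shifts (so ground truth is exact at
  subpixel precision), radial vignetting, exponential per-frame dimming
  `(1 − δ)^i` emulating battery discharge, and an optional moving
  Gaussian particle;
* spectrum frames are sums of Gaussian stripes along a (possibly
  tilted) dispersion axis, colored by a piecewise-linear wavelength→RGB
  approximation (display-oriented, not a calibrated sensor response);
  the white-LED preset is a narrow 450 nm peak plus a broad two-
  component phosphor band, reproducing the characteristic blue/phosphor
  gap near 480 nm;
* bar targets render three-bar groups at specified line widths in both
  orientations; `resolved_linewidth` applies a Michelson-contrast
  threshold (default 0.26, the conventional resolution criterion) to
  line profiles at known bar/gap positions.

Consequently, passing tests demonstrate *algorithmic* correctness —
parameter recovery against known ground truth under controlled noise —
not performance on real frames, which add aberrations, rolling-shutter
and compression artifacts, non-Gaussian noise and non-cyclic borders.

## Problem sizes

The closure studies run at the scale the methods target: holograms at
512×512 (10 scenes, 26-step scans), defocus stacks of 11 layers at
160×160 (20 seeds), timelapses of 10 frames at 128×128 (20 seeds).
These sizes were chosen as the smallest at which each estimator's
behavior is representative (fringe support, blockwise DCT statistics
and correlation peaks all well-resolved); the full suite and the
acceptance script each complete in well under a minute on one CPU.
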