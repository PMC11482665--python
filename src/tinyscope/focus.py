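"""Sharpness metrics, autofocus over focus stacks, EDOF and bracketing.

Autofocus on microcontroller microscopes is an exhaustive sweep: the
firmware steps the lens through a focus bracket, stores every frame, and
the sharpest layer is picked afterwards by maximizing a relative
sharpness metric.  Two metrics are provided:

``jpeg_size``
    The byte count of the frame re-encoded as a baseline JPEG at fixed
    settings.  JPEG spends bytes on high-spatial-frequency DCT
    coefficients, so sharper frames compress to larger files.  Scores
    are rank-meaningful only within one encoder configuration.

``dct``
    The fraction of per-8x8-block DCT energy held by coefficients
    outside the top-left 2x2 low-frequency corner, averaged over blocks.
    Zero for a constant frame, larger for sharper texture.

Exposure bracketing (a ladder of exposure times captured every timelapse
event) is planned by :class:`AcquisitionPlan` and resolved after the
fact by :func:`select_best_exposure`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.ndimage
import scipy.signal
from PIL import Image

from tinyscope.frames import Frame, FocusStack

#: JPEG encoder settings fixed for the jpeg_size metric (baseline, no
#: chroma subsampling).  Scores are only comparable at identical settings.
JPEG_SETTINGS = {"quality": 85, "subsampling": 0}

SHARPNESS_METRICS = ("jpeg_size", "dct")


@dataclass
class SharpnessCurve:
    """Per-layer sharpness scores of a focus stack."""

    z_um: np.ndarray
    scores: np.ndarray
    metric_name: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.z_um.shape != self.scores.shape or self.z_um.ndim != 1:
            raise ValueError("z and scores must be matching 1-D arrays")


@dataclass
class AcquisitionPlan:
    """Timelapse acquisition plan: exposure ladder + focus bracket.

    ``exposure_series_ms`` must be strictly increasing; ``focus_offsets_um``
    are signed lens offsets around the nominal focus swept at every event.
    """

    interval_s: float
    exposure_series_ms: list[float]
    focus_offsets_um: list[float]
    deep_sleep: bool = True

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("interval must be positive")
        exp = np.asarray(self.exposure_series_ms, dtype=float)
        if exp.size == 0 or np.any(exp <= 0) or np.any(np.diff(exp) <= 0):
            raise ValueError("exposures must be strictly increasing and positive")


def default_bracket_plan() -> AcquisitionPlan:
    """The default submersible-deployment plan.

    One bracketing event per minute: a 1/2/5/10/20/50/100/200/500 ms
    exposure ladder at each layer of a +/-2-step focus bracket, with the
    controller deep-sleeping between events.
    """
    return AcquisitionPlan(
        interval_s=60.0,
        exposure_series_ms=[1, 2, 5, 10, 20, 50, 100, 200, 500],
        focus_offsets_um=[-8.0, -4.0, 0.0, 4.0, 8.0],
        deep_sleep=True,
    )


def jpeg_size_sharpness(frame: Frame, quality: int = 85) -> int:
    """Sharpness score = bytes of the frame encoded as baseline JPEG.

    Comparative only: scores from different encoder settings or frame
    shapes are not commensurable.  RGB frames are encoded as RGB with
    chroma subsampling disabled; higher-bit-depth frames are rescaled to
    8 bits first.
    """
    px = frame.to_uint8()
    img = Image.fromarray(px, mode="RGB" if frame.is_rgb else "L")
    buf = _io.BytesIO()
    img.save(buf, format="JPEG", quality=quality, subsampling=0)
    return buf.getbuffer().nbytes


def dct_sharpness(frame: Frame, block: int = 8) -> float:
    """High-frequency DCT energy fraction, averaged over 8x8 blocks.

    Each block's 2-D DCT-II energy is split into the top-left 2x2
    low-frequency corner (including DC) and the rest; the score is the
    mean, over blocks, of the high-frequency share.  Constant frames
    score exactly 0.
    """
    gray = frame.luminance()
    h, w = gray.shape
    if h < block or w < block:
        raise ValueError(f"frame smaller than {block}x{block}")
    hb, wb = h - h % block, w - w % block
    tiles = gray[:hb, :wb].reshape(hb // block, block, wb // block, block)
    tiles = tiles.transpose(0, 2, 1, 3)  # (nby, nbx, block, block)
    coef = scipy.fft.dctn(tiles, type=2, norm="ortho", axes=(2, 3))
    energy = coef**2
    total = energy.sum(axis=(2, 3))
    low = energy[:, :, :2, :2].sum(axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, (total - low) / total, 0.0)
    return float(frac.mean())


def sharpness_curve(stack: FocusStack, metric: str = "dct") -> SharpnessCurve:
    """Score every layer of a focus stack with the named metric."""
    if metric == "jpeg_size":
        scores = [jpeg_size_sharpness(f) for f in stack.frames]
        meta = dict(JPEG_SETTINGS)
    elif metric == "dct":
        scores = [dct_sharpness(f) for f in stack.frames]
        meta = {}
    else:
        raise ValueError(
            f"unknown sharpness metric {metric!r}; choose from {SHARPNESS_METRICS}"
        )
    return SharpnessCurve(stack.z_positions, np.array(scores, float), metric, meta)


def best_focus(curve: SharpnessCurve) -> float:
    """z position of the maximal sharpness score.

    Ties are broken toward the z closest to the median z of the curve
    (the nominal bracket center), then toward smaller z.
    """
    if curve.scores.size == 0:
        raise ValueError("empty sharpness curve")
    if np.all(np.isnan(curve.scores)):
        raise ValueError("all sharpness scores are NaN")
    scores = np.where(np.isnan(curve.scores), -np.inf, curve.scores)
    best = np.flatnonzero(scores == scores.max())
    if best.size == 1:
        return float(curve.z_um[best[0]])
    z = curve.z_um[best]
    z_med = float(np.median(curve.z_um))
    order = np.lexsort((z, np.abs(z - z_med)))
    return float(z[order[0]])


def count_modes(curve: SharpnessCurve, rel_prominence: float = 0.05) -> int:
    """Number of local maxima whose prominence exceeds a fraction of the range.

    A sharpness curve is called unimodal when this returns 1: noise
    wiggles smaller than ``rel_prominence`` times the curve's dynamic
    range do not count as modes.  Maxima at the grid edges are counted.
    A constant curve has zero modes.
    """
    sc = curve.scores
    span = sc.max() - sc.min()
    if span == 0:
        return 0
    padded = np.concatenate([[sc.min() - span], sc, [sc.min() - span]])
    peaks, _ = scipy.signal.find_peaks(padded, prominence=rel_prominence * span)
    return int(len(peaks))


def autofocus(stack: FocusStack, metric: str = "dct") -> tuple[float, SharpnessCurve]:
    """Sweep-and-argmax autofocus: returns (best z, full sharpness curve)."""
    curve = sharpness_curve(stack, metric)
    return best_focus(curve), curve


def edof_composite(stack: FocusStack, window: int = 9) -> Frame:
    """Extended depth-of-field composite by per-pixel sharpest-layer selection.

    Local sharpness is the variance of the luminance in a ``window`` x
    ``window`` neighborhood; each output pixel is copied verbatim from the
    layer maximizing it (pure selection, no blending).
    """
    frames = stack.frames
    lum = np.stack([f.luminance() for f in frames])
    mean = scipy.ndimage.uniform_filter(lum, size=(1, window, window))
    sq = scipy.ndimage.uniform_filter(lum**2, size=(1, window, window))
    local_var = sq - mean**2
    pick = np.argmax(local_var, axis=0)
    stacked = np.stack([f.pixels for f in frames])
    out = np.take_along_axis(
        stacked,
        pick[None, ..., None] if stacked.ndim == 4 else pick[None, ...],
        axis=0,
    )[0]
    meta = {"edof_window": window, "n_layers": len(frames)}
    return Frame(out, bit_depth=frames[0].bit_depth, metadata=meta)


def exposure_scores(
    frames: list[Frame],
    well_exposed_band: tuple[float, float] = (0.1, 0.9),
    saturation_level: float = 0.99,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (well-exposed fraction, saturated fraction).

    Well-exposed = fraction of pixels inside ``well_exposed_band`` of full
    scale; saturated = fraction at or above ``saturation_level`` of full
    scale.
    """
    well = np.empty(len(frames))
    sat = np.empty(len(frames))
    for i, f in enumerate(frames):
        px = f.luminance() / f.max_value
        lo, hi = well_exposed_band
        well[i] = np.mean((px >= lo) & (px <= hi))
        sat[i] = np.mean(px >= saturation_level)
    return well, sat


def select_best_exposure(
    frames: list[Frame],
    saturation_cap: float = 0.01,
) -> int:
    """Pick the best-illuminated frame from an exposure bracket.

    Among frames whose saturated-pixel fraction is at most
    ``saturation_cap``, returns the index maximizing the well-exposed
    fraction; if every frame exceeds the cap, the least-saturated one
    wins.  Ties go to the shorter exposure (metadata ``exposure_ms``,
    falling back to list order).
    """
    if not frames:
        raise ValueError("no frames to select from")
    shapes = {f.pixels.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("frames must share one shape")
    well, sat = exposure_scores(frames)
    exposures = np.array(
        [f.metadata.get("exposure_ms", i) for i, f in enumerate(frames)], float
    )
    ok = sat <= saturation_cap
    if np.any(ok):
        candidates = np.flatnonzero(ok)
        key = well[candidates]
        best = candidates[key == key.max()]
    else:
        best = np.flatnonzero(sat == sat.min())
    order = np.lexsort((best, exposures[best]))
    return int(best[order[0]])
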