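"""Disk formats: PNG/TIFF/JPEG frames, manifest-described stacks and series.

A stack or timelapse on disk is a directory of image files plus a
``manifest.json`` listing, per frame, the filename and its acquisition
metadata (``z_um`` for focus stacks, ``timestamp_s`` / ``exposure_ms``
for timelapses).  Spectra and curves are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from tinyscope.frames import Frame, FocusStack, TimelapseSeries
from tinyscope.spectro import Spectrum

MANIFEST_NAME = "manifest.json"


def read_frame(path: str | Path, metadata: dict | None = None) -> Frame:
    """Load an image file as a Frame; bit depth inferred from the dtype."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read image: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return Frame(arr, bit_depth=bit_depth, metadata=dict(metadata or {}))


def write_frame(frame: Frame, path: str | Path) -> None:
    """Write a Frame as PNG (8-bit), TIFF (8/16-bit) or JPEG (8-bit)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        dtype = np.uint16 if frame.bit_depth > 8 else np.uint8
        tifffile.imwrite(path, np.round(frame.pixels).astype(dtype))
    elif suffix in (".png", ".jpg", ".jpeg"):
        iio.imwrite(path, frame.to_uint8())
    else:
        raise ValueError(f"unsupported image format: {suffix}")


def _read_manifest(directory: Path) -> list[dict]:
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    with open(manifest) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{manifest} must contain a list of frame entries")
    return entries


def load_stack(directory: str | Path) -> FocusStack:
    """Load a focus stack: directory with manifest entries {file, z_um}."""
    directory = Path(directory)
    entries = _read_manifest(directory)
    stack_entries = []
    for e in entries:
        frame = read_frame(directory / e["file"], metadata=e)
        stack_entries.append((float(e["z_um"]), frame))
    stack_entries.sort(key=lambda t: t[0])
    return FocusStack(stack_entries)


def load_series(directory: str | Path) -> TimelapseSeries:
    """Load a timelapse: manifest entries {file, timestamp_s[, exposure_ms]}."""
    directory = Path(directory)
    entries = _read_manifest(directory)
    entries = sorted(entries, key=lambda e: float(e["timestamp_s"]))
    frames = [read_frame(directory / e["file"], metadata=e) for e in entries]
    timestamps = [float(e["timestamp_s"]) for e in entries]
    return TimelapseSeries(frames, timestamps)


def load_frames(directory: str | Path) -> list[Frame]:
    """Load an unordered frame collection (e.g. an exposure bracket)."""
    directory = Path(directory)
    entries = _read_manifest(directory)
    return [read_frame(directory / e["file"], metadata=e) for e in entries]


def save_stack(stack: FocusStack, directory: str | Path, fmt: str = "tiff") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (z, frame) in enumerate(stack.entries):
        name = f"frame_{i:04d}.{fmt}"
        write_frame(frame, directory / name)
        manifest.append({"file": name, "z_um": z})
    with open(directory / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)


def save_series(series: TimelapseSeries, directory: str | Path, fmt: str = "tiff"
                ) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (frame, t) in enumerate(zip(series.frames, series.timestamps)):
        name = f"frame_{i:04d}.{fmt}"
        write_frame(frame, directory / name)
        entry = {"file": name, "timestamp_s": float(t)}
        if "exposure_ms" in frame.metadata:
            entry["exposure_ms"] = frame.metadata["exposure_ms"]
        manifest.append(entry)
    with open(directory / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)


def spectrum_to_csv(spectrum: Spectrum, path: str | Path) -> None:
    cols = {"position_px": spectrum.position_px}
    for name in ("r", "g", "b", "lum"):
        cols[name] = spectrum.channels[name]
    if spectrum.wavelength_nm is not None:
        cols["wavelength_nm"] = spectrum.wavelength_nm
    pd.DataFrame(cols).to_csv(path, index=False)


def spectrum_from_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    channels = {name: df[name].to_numpy() for name in ("r", "g", "b", "lum")}
    wl = df["wavelength_nm"].to_numpy() if "wavelength_nm" in df else None
    return Spectrum(df["position_px"].to_numpy(), channels, wavelength_nm=wl)
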