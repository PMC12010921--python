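"""Receive focusing, delay-and-sum B-mode, display rendering and screenshots.

Coordinates: depth is positive downward with 0 at the array face, lateral 0
at the array center; pixel (0, 0) is the shallowest/leftmost pixel and all
indexing is 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .channel import ChannelData
from .probe import ProbeConfig

__all__ = [
    "DelayTable",
    "BeamformedImage",
    "DisplayImage",
    "ScreenshotRaster",
    "default_depth_grid",
    "receive_delays",
    "apply_delays",
    "das_bmode",
    "render_display",
    "render_screenshot",
    "screenshot_to_intensity",
    "save_png",
]


@dataclass
class DelayTable:
    """Receive delays in (fractional) samples.

    ``delays`` has shape ``(n_depth, n_receive, n_scanlines)``:
    ``delays[n, i, x]`` is the arrival time, in RF samples, of an echo from
    depth ``depth_grid_mm[n]`` on the axis of scan line ``x`` at receive
    element ``i`` of that line's aperture.
    """

    delays: np.ndarray
    depth_grid_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.delays.ndim != 3:
            raise ValueError("delays must be (n_depth, n_receive, n_scanlines)")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")


@dataclass
class BeamformedImage:
    """Pre-normalization, pre-log pixel values on an axial x lateral grid."""

    pixels: np.ndarray  # (n_depth, n_scanlines)
    kind: str  # bmode_envelope | slsc_offline | slsc_realtime
    depth_grid_mm: np.ndarray
    line_x_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("bmode_envelope", "slsc_offline", "slsc_realtime"):
            raise ValueError(f"unknown image kind {self.kind!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")


@dataclass
class DisplayImage:
    """Log-compressed image: dB values in [-dynamic_range, 0], max at 0 dB."""

    pixels_db: np.ndarray
    dynamic_range_db: float
    depth_grid_mm: np.ndarray
    line_x_mm: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ScreenshotRaster:
    """8-bit grayscale surrogate of a clinical screen capture."""

    pixels: np.ndarray  # uint8
    dynamic_range_db: float
    depth_grid_mm: np.ndarray
    line_x_mm: np.ndarray
    meta: dict = field(default_factory=dict)


def default_depth_grid(data: ChannelData, max_depth_mm: float | None = None) -> np.ndarray:
    """One depth pixel per RF sample: ``z_n = n c / (2 f_s)``, trimmed so the
    steered delays stay inside the recorded traces."""
    probe = data.probe
    dz = probe.axial_sample_mm
    aperture_mm = probe.n_receive * probe.pitch_mm
    if max_depth_mm is None:
        extent = data.meta.get("extent_mm")
        max_depth_mm = extent[1][1] if extent is not None else data.n_samples * dz
    # deepest depth whose farthest-element delay still lands in the trace
    z_hi = max_depth_mm
    n_raw = data.n_samples
    while z_hi > 0:
        tau = (z_hi + math.sqrt(z_hi**2 + aperture_mm**2)) / probe.sound_speed_mm_s
        if tau * probe.sampling_frequency_hz < n_raw - 2:
            break
        z_hi -= dz
    n_depth = int(z_hi / dz)
    return (np.arange(n_depth) + 1) * dz


def receive_delays(
    probe: ProbeConfig, depth_grid_mm: np.ndarray, scanline: int | None = None
) -> DelayTable:
    """Geometric receive delays ``(z + sqrt(z^2 + d^2)) / c`` in samples.

    ``d`` is the lateral offset of each receive element from the scan-line
    axis.  ``scanline=None`` returns the table for every line at once.
    """
    depth = np.asarray(depth_grid_mm, dtype=float)
    if depth.ndim != 1 or np.any(np.diff(depth) <= 0) or depth[0] <= 0:
        raise ValueError("depth_grid_mm must be strictly increasing and positive")
    ex = probe.receive_element_x_mm()  # (n_receive, n_lines)
    lx = probe.scanline_x_mm()
    if scanline is not None:
        ex = ex[:, scanline : scanline + 1]
        lx = lx[scanline : scanline + 1]
    d = ex - lx[None, :]  # lateral offsets, (n_receive, n_lines)
    z = depth[:, None, None]
    tau_s = (z + np.sqrt(z**2 + d[None, :, :] ** 2)) / probe.sound_speed_mm_s
    return DelayTable(delays=tau_s * probe.sampling_frequency_hz, depth_grid_mm=depth)


def apply_delays(data: ChannelData, delays: DelayTable) -> ChannelData:
    """Align raw traces by the receive delays (linear interpolation).

    Delays falling beyond the recorded trace are zero-filled and flagged in
    ``meta['zero_filled']``.
    """
    if data.aligned:
        raise ValueError("channel data is already delay-aligned")
    tau = delays.delays
    if tau.shape[1] != data.rf.shape[1] or tau.shape[2] != data.rf.shape[2]:
        raise ValueError("delay table does not match channel-data shape")
    n_raw = data.n_samples
    i0 = np.floor(tau).astype(np.int64)
    frac = tau - i0
    out_of_range = (i0 < 0) | (i0 >= n_raw - 1)
    i0c = np.clip(i0, 0, n_raw - 2)
    e_idx = np.arange(data.rf.shape[1])[None, :, None]
    l_idx = np.arange(data.rf.shape[2])[None, None, :]
    lo = data.rf[i0c, e_idx, l_idx]
    hi = data.rf[i0c + 1, e_idx, l_idx]
    aligned = lo * (1.0 - frac) + hi * frac
    if out_of_range.any():
        aligned[out_of_range] = 0.0
    return data.copy_with(
        rf=aligned,
        aligned=True,
        depth_grid_mm=delays.depth_grid_mm,
        meta={**data.meta, "zero_filled": bool(out_of_range.any())},
    )


def das_bmode(aligned: ChannelData) -> BeamformedImage:
    """Delay-and-sum B-mode: sum across the aperture, then the envelope as
    the magnitude of the analytic signal along depth."""
    if not aligned.aligned:
        raise ValueError("das_bmode requires delay-aligned channel data")
    summed = aligned.rf.sum(axis=1)  # (n_depth, n_lines)
    env = np.abs(hilbert(summed, axis=0))
    return BeamformedImage(
        pixels=env,
        kind="bmode_envelope",
        depth_grid_mm=aligned.depth_grid_mm,
        line_x_mm=aligned.line_x_mm(),
        meta={"focus_depth_mm": aligned.focus_depth_mm, "seed": aligned.seed},
    )


def render_display(img: BeamformedImage, dynamic_range_db: float = 60.0) -> DisplayImage:
    """Normalize to the image maximum and log-compress: ``20 log10(p/max)``
    clipped to ``[-dynamic_range, 0]`` dB."""
    p = img.pixels
    if np.any(p < 0):
        raise ValueError("display rendering expects non-negative pixels")
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("cannot render an all-zero image")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(p / pmax)
    db = np.clip(db, -dynamic_range_db, 0.0)
    return DisplayImage(
        pixels_db=db,
        dynamic_range_db=dynamic_range_db,
        depth_grid_mm=img.depth_grid_mm,
        line_x_mm=img.line_x_mm,
        meta=dict(img.meta, kind=img.kind),
    )


def render_screenshot(disp: DisplayImage) -> ScreenshotRaster:
    """Quantize the dB image linearly to 8 bits: [-DR, 0] dB -> [0, 255],
    rounding half up."""
    dr = disp.dynamic_range_db
    scaled = (disp.pixels_db + dr) / dr * 255.0
    q = np.floor(scaled + 0.5).astype(np.uint8)
    return ScreenshotRaster(
        pixels=q,
        dynamic_range_db=dr,
        depth_grid_mm=disp.depth_grid_mm,
        line_x_mm=disp.line_x_mm,
        meta=dict(disp.meta),
    )


def screenshot_to_intensity(raster: ScreenshotRaster | np.ndarray) -> np.ndarray:
    """Grayscale screenshot values as double precision in [0, 255].

    No inverse log mapping is applied: the quantized display gray levels are
    used directly, matching the pseudo-real-time analysis path.  RGB rasters
    are converted to luma with Rec. 601 weights.
    """
    px = raster.pixels if isinstance(raster, ScreenshotRaster) else np.asarray(raster)
    if px.ndim == 3 and px.shape[-1] == 3:
        px = px @ np.array([0.299, 0.587, 0.114])
    return px.astype(np.float64)


def save_png(raster: ScreenshotRaster, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(raster.pixels, mode="L").save(str(path))
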