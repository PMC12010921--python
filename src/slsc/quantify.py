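"""Elliptical ROI placement and generalized contrast-to-noise ratio (gCNR).

gCNR is one minus the overlap of the pixel-value histograms of a mass ROI
and a matched tissue ROI; it is bounded in [0, 1] and invariant to any
monotone remapping shared by the two regions.  ROI placement follows the
matched-ellipse protocol: the tissue ROI has the same shape, size and depth
as the mass ROI, laterally offset with an edge-to-edge gap of 0.9-8.2 mm,
falling back to an offset in depth (< 5 mm edge gap) when the mass spans
most of the lateral field of view.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .beamform import BeamformedImage, ScreenshotRaster, screenshot_to_intensity
from .synthetic import LesionSpec

__all__ = [
    "Ellipse",
    "ROIPair",
    "place_rois",
    "extract_roi_samples",
    "gcnr",
    "gcnr_for_mass",
    "default_n_bins",
]

#: mass ROI semi-axes as a fraction of the lesion semi-axes ("within the mass")
MASS_ROI_MARGIN = 0.8

LATERAL_GAP_MM = (0.9, 8.2)
DEPTH_GAP_MAX_MM = 5.0


@dataclass(frozen=True)
class Ellipse:
    center_mm: tuple[float, float]  # (lateral, axial)
    semi_axes_mm: tuple[float, float]  # (a lateral, b axial)

    def contains(self, x_mm: np.ndarray, z_mm: np.ndarray) -> np.ndarray:
        cx, cz = self.center_mm
        a, b = self.semi_axes_mm
        return ((x_mm - cx) / a) ** 2 + ((z_mm - cz) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class ROIPair:
    """Matched mass/tissue ellipses of identical shape and size."""

    mass_roi: Ellipse
    tissue_roi: Ellipse
    offset_edge_to_edge_mm: float
    placement_mode: str  # "lateral" | "depth_fallback"

    def __post_init__(self) -> None:
        if self.mass_roi.semi_axes_mm != self.tissue_roi.semi_axes_mm:
            raise ValueError("mass and tissue ROIs must share semi-axes")
        if self.placement_mode not in ("lateral", "depth_fallback"):
            raise ValueError(f"unknown placement mode {self.placement_mode!r}")
        if self.placement_mode == "lateral":
            lo, hi = LATERAL_GAP_MM
            if not (lo <= self.offset_edge_to_edge_mm <= hi):
                raise ValueError("lateral edge gap must lie in [0.9, 8.2] mm")
        elif self.offset_edge_to_edge_mm >= DEPTH_GAP_MAX_MM:
            raise ValueError("depth-fallback edge gap must be < 5 mm")


def place_rois(
    lesion: LesionSpec,
    depth_grid_mm: np.ndarray,
    line_x_mm: np.ndarray,
    rng_seed: int = 0,
    margin: float = MASS_ROI_MARGIN,
) -> ROIPair:
    """Place the matched mass/tissue ellipse pair for a lesion.

    The mass ROI is the lesion ellipse shrunk by ``margin``; the tissue ROI
    is offset laterally (preferring the side with more room) by an
    edge-to-edge gap drawn uniformly from the feasible part of 0.9-8.2 mm,
    or offset in depth by a gap < 5 mm when no lateral placement fits.
    Deterministic for fixed ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    cx, cz = lesion.center_mm
    a = lesion.semi_axes_mm[0] * margin
    b = lesion.semi_axes_mm[1] * margin
    mass = Ellipse((cx, cz), (a, b))
    x_lo, x_hi = float(line_x_mm[0]), float(line_x_mm[-1])
    z_lo, z_hi = float(depth_grid_mm[0]), float(depth_grid_mm[-1])

    # lateral placement: |gap| such that the tissue ellipse stays on the grid
    sides = []
    for sign in (+1, -1):
        if sign > 0:
            room = (x_hi - a) - (cx + 2 * a)  # max gap on the right
        else:
            room = (cx - 2 * a) - (x_lo + a)
        gap_hi = min(LATERAL_GAP_MM[1], room)
        if gap_hi >= LATERAL_GAP_MM[0]:
            sides.append((sign, gap_hi))
    if sides:
        order = rng.permutation(len(sides))
        sign, gap_hi = sides[int(order[0])]
        gap = float(rng.uniform(LATERAL_GAP_MM[0], gap_hi))
        tissue = Ellipse((cx + sign * (2 * a + gap), cz), (a, b))
        return ROIPair(mass, tissue, gap, "lateral")

    # depth fallback
    for sign in (+1, -1):
        if sign > 0:
            room = (z_hi - b) - (cz + 2 * b)
        else:
            room = (cz - 2 * b) - (z_lo + b)
        gap_hi = min(DEPTH_GAP_MAX_MM - 1e-6, room)
        if gap_hi >= 0.2:
            gap = float(rng.uniform(0.2, gap_hi))
            tissue = Ellipse((cx, cz + sign * (2 * b + gap)), (a, b))
            return ROIPair(mass, tissue, gap, "depth_fallback")
    raise ValueError(
        f"no tissue ROI placement fits for lesion at {lesion.center_mm} mm "
        f"with semi-axes {lesion.semi_axes_mm} mm"
    )


def extract_roi_samples(
    img: BeamformedImage | ScreenshotRaster | np.ndarray,
    roi: Ellipse,
    depth_grid_mm: np.ndarray | None = None,
    line_x_mm: np.ndarray | None = None,
) -> np.ndarray:
    """All pixel values whose grid centers fall inside the ellipse.

    Beamformed images yield their pre-normalization, pre-log values;
    screenshots yield double-precision gray levels in [0, 255].
    """
    if isinstance(img, BeamformedImage):
        values, zg, xg = img.pixels, img.depth_grid_mm, img.line_x_mm
    elif isinstance(img, ScreenshotRaster):
        values, zg, xg = screenshot_to_intensity(img), img.depth_grid_mm, img.line_x_mm
    else:
        values = np.asarray(img, dtype=float)
        zg, xg = depth_grid_mm, line_x_mm
    if zg is None or xg is None:
        raise ValueError("grid coordinates are required for raw arrays")
    X = np.asarray(xg)[None, :]
    Z = np.asarray(zg)[:, None]
    mask = roi.contains(X, Z)
    samples = values[mask]
    if samples.size == 0:
        raise ValueError(f"ROI {roi} contains no pixel centers")
    return samples


def default_n_bins(n_mass: int, n_tissue: int) -> int:
    """Histogram bin count: square-root rule on the smaller ROI, capped at 256.

    The cap matches 8-bit-comparable data; the square-root rule keeps the
    histogram-overlap estimate from being dominated by per-bin sampling
    noise when ROIs are small.
    """
    return int(min(256, max(8, math.ceil(math.sqrt(min(n_mass, n_tissue))))))


def gcnr(
    mass_samples: np.ndarray,
    tissue_samples: np.ndarray,
    n_bins: int | None = None,
) -> float:
    """Generalized contrast-to-noise ratio of two sample sets.

    Histograms are built on shared equal-width bins spanning the pooled
    min-max range and normalized to unit sum; the result is
    ``1 - sum_j min(h_mass_j, h_tissue_j)``, in [0, 1].  A degenerate
    pooled range (all values equal) returns 0 with a warning.
    """
    a = np.asarray(mass_samples, dtype=float).ravel()
    b = np.asarray(tissue_samples, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        warnings.warn("degenerate pooled range: all sample values equal; gCNR = 0")
        return 0.0
    if n_bins is None:
        n_bins = default_n_bins(a.size, b.size)
    edges = np.linspace(lo, hi, n_bins + 1)
    ha = np.histogram(a, bins=edges)[0] / a.size
    hb = np.histogram(b, bins=edges)[0] / b.size
    return float(np.clip(1.0 - np.minimum(ha, hb).sum(), 0.0, 1.0))


def gcnr_for_mass(
    images: dict[str, BeamformedImage | ScreenshotRaster],
    roi: ROIPair,
    n_bins: int | None = None,
) -> dict[str, float]:
    """gCNR per pathway using the same ROI pair on every image.

    ``images`` maps pathway names (e.g. ``bmode_offline``, ``slsc_offline``,
    ``slsc_realtime``, ``bmode_screenshot``, ``slsc_screenshot``) to images
    on a common grid.  Returns ``{pathway: gcnr}``.
    """
    grids = {
        (im.depth_grid_mm.shape, im.line_x_mm.shape) for im in images.values()
    }
    if len(grids) > 1:
        raise ValueError("all pathway images must share one grid")
    out = {}
    for pathway, im in images.items():
        mass = extract_roi_samples(im, roi.mass_roi)
        tissue = extract_roi_samples(im, roi.tissue_roi)
        out[pathway] = gcnr(mass, tissue, n_bins=n_bins)
    return out
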