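"""Short-lag spatial coherence (SLSC) imaging, offline and real-time forms.

A pixel of an SLSC image is the receive-aperture spatial coherence of the
delay-aligned channel signals, summed over the first M element separations
("short lags").  Two formulations are implemented and deliberately kept
distinct, because their differences are a study object of this package:

* **offline** — for each pixel and each lag m, the normalized
  cross-correlation over an axial kernel is computed for every one of the
  N - m element pairs, the per-pair coefficients are averaged into the
  coherence function R(m), and the pixel is sum_{m=1..M} R(m).  The kernel
  mean is removed per element per kernel (zero-mean signals), and the
  computation runs on real RF.

* **real-time** — the GPU-style reordering: per lag, the pair-summed
  cross-correlation and the two pair-summed energies are accumulated first
  (on analytic signals, no mean removal), each is then summed over the
  axial kernel, and a single normalized ratio per lag is formed before
  summing lags (sum-then-normalize instead of normalize-then-average).

Negative pixels are clipped to zero in both pathways so that display and
gCNR statistics share one convention.  Element indices are 0-based here;
lag m pairs element i with element i + m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .beamform import BeamformedImage
from .channel import ChannelData
from .probe import ProbeConfig

__all__ = [
    "CoherenceParams",
    "CoherenceFunction",
    "LagSums",
    "coherence_function",
    "slsc_offline",
    "lag_sums",
    "slsc_realtime",
]


@dataclass(frozen=True)
class CoherenceParams:
    """Parameters of SLSC formation.

    ``M`` is the short-lag cutoff (default 7, ten percent of a 64-element
    receive aperture).  ``kernel_samples`` is the axial correlation-kernel
    length k in samples; ``None`` selects one wavelength of two-way RF
    travel, ``round(2 f_s / f_0)`` (6 samples at the default probe).
    """

    M: int = 7
    kernel_samples: int | None = None

    def resolve_kernel(self, probe: ProbeConfig) -> int:
        if self.kernel_samples is not None:
            k = int(self.kernel_samples)
        else:
            k = int(round(2.0 * probe.sampling_frequency_hz / probe.center_frequency_hz))
        if k < 1:
            raise ValueError("kernel_samples must be >= 1")
        return k

    def validate(self, n_elements: int) -> None:
        if not (1 <= self.M < n_elements):
            raise ValueError(f"M must satisfy 1 <= M < N (M={self.M}, N={n_elements})")


@dataclass
class CoherenceFunction:
    """Coherence values R(m), m = 1..M, at a single pixel."""

    values: np.ndarray  # (M,)
    pixel: tuple[int, int]  # (depth index, scan line)

    def short_lag_sum(self) -> float:
        return float(self.values.sum())


@dataclass
class LagSums:
    """Kernel-summed correlation accumulators of the real-time formulation.

    Each array has shape ``(n_depth, M)`` for one scan line: ``c_ij`` is the
    pair-summed lag-m cross-correlation, ``c_ii``/``c_jj`` the pair-summed
    energies of the leading/trailing elements, all already summed over the
    axial kernel.
    """

    c_ij: np.ndarray
    c_ii: np.ndarray
    c_jj: np.ndarray
    scanline: int


def _kernel_bounds(n_depth: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Clipped kernel [n1, n2] centered on each depth sample (inclusive)."""
    n = np.arange(n_depth)
    n1 = np.clip(n - k // 2, 0, n_depth - 1)
    n2 = np.clip(n1 + k - 1, 0, n_depth - 1)
    return n1, n2


def _window_sums(x: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Moving sums of ``x`` along axis 0 over the inclusive windows [n1, n2]."""
    cs = np.concatenate([np.zeros((1,) + x.shape[1:], dtype=x.dtype), np.cumsum(x, axis=0)])
    return cs[n2 + 1] - cs[n1]


def _require_aligned(data: ChannelData) -> None:
    if not data.aligned:
        raise ValueError("SLSC requires delay-aligned channel data")
    if data.rf.shape[1] < 2:
        raise ValueError("need at least 2 receive elements")


def coherence_function(
    aligned: ChannelData, pixel: tuple[int, int], params: CoherenceParams | None = None
) -> CoherenceFunction:
    """Coherence function R(m) at one pixel of the offline pathway.

    For each lag m, the N - m element pairs contribute the normalized
    cross-correlation of their zero-mean kernels, averaged with weight
    1/(N - m).  Pairs whose kernel energy vanishes contribute 0.
    """
    _require_aligned(aligned)
    params = params or CoherenceParams()
    n_depth, n_elem, _ = aligned.rf.shape
    params.validate(n_elem)
    k = params.resolve_kernel(aligned.probe)
    n, x = pixel
    n1 = n - k // 2
    n2 = n1 + k - 1
    if n1 < 0 or n2 >= n_depth:
        raise ValueError(
            f"kernel [{n1}, {n2}] around depth sample {n} falls outside the trace"
        )
    s = aligned.rf[n1 : n2 + 1, :, x].astype(np.float64)
    s = s - s.mean(axis=0, keepdims=True)
    energy = (s**2).sum(axis=0)
    values = np.zeros(params.M)
    for m in range(1, params.M + 1):
        num = (s[:, :-m] * s[:, m:]).sum(axis=0)
        den = np.sqrt(energy[:-m] * energy[m:])
        r = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        values[m - 1] = np.clip(r, -1.0, 1.0).mean()
    return CoherenceFunction(values=values, pixel=pixel)


def slsc_offline(aligned: ChannelData, params: CoherenceParams | None = None) -> BeamformedImage:
    """Offline SLSC image: per pixel, sum of R(m) for m = 1..M, negatives
    clipped to zero.  Pixel values lie in [0, M].

    At the shallow/deep image edges the axial kernel is truncated to the
    samples available (same convention as :func:`coherence_function`
    evaluated at interior pixels).
    """
    _require_aligned(aligned)
    params = params or CoherenceParams()
    n_depth, n_elem, n_lines = aligned.rf.shape
    params.validate(n_elem)
    k = params.resolve_kernel(aligned.probe)
    s = aligned.rf.astype(np.float64, copy=False)
    n1, n2 = _kernel_bounds(n_depth, k)
    klen = (n2 - n1 + 1).astype(np.float64)[:, None, None]
    A = _window_sums(s, n1, n2)  # kernel sums
    Q = _window_sums(s * s, n1, n2)  # kernel energies
    out = np.zeros((n_depth, n_lines))
    for m in range(1, params.M + 1):
        P = _window_sums(s[:, :-m, :] * s[:, m:, :], n1, n2)
        sij = P - A[:, :-m, :] * A[:, m:, :] / klen
        sii = np.clip(Q[:, :-m, :] - A[:, :-m, :] ** 2 / klen, 0.0, None)
        sjj = np.clip(Q[:, m:, :] - A[:, m:, :] ** 2 / klen, 0.0, None)
        den = np.sqrt(sii * sjj)
        r = np.divide(sij, den, out=np.zeros_like(sij), where=den > 0)
        out += np.clip(r, -1.0, 1.0).mean(axis=1)
    return BeamformedImage(
        pixels=np.clip(out, 0.0, None),
        kind="slsc_offline",
        depth_grid_mm=aligned.depth_grid_mm,
        line_x_mm=aligned.line_x_mm(),
        meta={
            "M": params.M,
            "kernel_samples": k,
            "pathway": "offline",
            "focus_depth_mm": aligned.focus_depth_mm,
            "seed": aligned.seed,
        },
    )


def _analytic(aligned: ChannelData) -> np.ndarray:
    rf = aligned.rf
    if np.iscomplexobj(rf):
        return rf
    return hilbert(rf.astype(np.float64, copy=False), axis=0)


def lag_sums(
    aligned: ChannelData, pixel_column: int, params: CoherenceParams | None = None
) -> LagSums:
    """Kernel-summed correlation/energy accumulators of one scan line.

    Traces are converted to analytic signals along depth; per lag m the
    N - m pairs are summed (cross term ``s_i conj(s_{i+m})``, energies
    ``|s_i|^2`` and ``|s_{i+m}|^2``) and then summed over the axial kernel.
    """
    _require_aligned(aligned)
    params = params or CoherenceParams()
    n_depth, n_elem, _ = aligned.rf.shape
    params.validate(n_elem)
    k = params.resolve_kernel(aligned.probe)
    s = _analytic(aligned)[:, :, pixel_column]
    n1, n2 = _kernel_bounds(n_depth, k)
    p2 = np.abs(s) ** 2
    c_ij = np.empty((n_depth, params.M), dtype=complex)
    c_ii = np.empty((n_depth, params.M))
    c_jj = np.empty((n_depth, params.M))
    for m in range(1, params.M + 1):
        c_ij[:, m - 1] = _window_sums((s[:, :-m] * np.conj(s[:, m:])).sum(axis=1), n1, n2)
        c_ii[:, m - 1] = _window_sums(p2[:, :-m].sum(axis=1), n1, n2)
        c_jj[:, m - 1] = _window_sums(p2[:, m:].sum(axis=1), n1, n2)
    return LagSums(c_ij=c_ij, c_ii=c_ii, c_jj=c_jj, scanline=pixel_column)


def slsc_realtime(aligned: ChannelData, params: CoherenceParams | None = None) -> BeamformedImage:
    """Real-time (GPU-formulation) SLSC image.

    Per pixel: ``sum_m Re[ sum_k C_ij / sqrt(sum_k C_ii * sum_k C_jj) ]``
    with the pair sums taken before kernel summation and normalization.
    Zero denominators contribute 0; negative pixels are clipped to match
    the offline display convention.  Pixel values lie in [0, M].
    """
    _require_aligned(aligned)
    params = params or CoherenceParams()
    n_depth, n_elem, n_lines = aligned.rf.shape
    params.validate(n_elem)
    k = params.resolve_kernel(aligned.probe)
    s = _analytic(aligned)
    n1, n2 = _kernel_bounds(n_depth, k)
    p2 = np.abs(s) ** 2
    out = np.zeros((n_depth, n_lines))
    for m in range(1, params.M + 1):
        cij = _window_sums((s[:, :-m, :] * np.conj(s[:, m:, :])).sum(axis=1), n1, n2)
        cii = _window_sums(p2[:, :-m, :].sum(axis=1), n1, n2)
        cjj = _window_sums(p2[:, m:, :].sum(axis=1), n1, n2)
        den = np.sqrt(cii * cjj)
        term = np.divide(cij.real, den, out=np.zeros_like(den), where=den > 0)
        out += np.clip(term, -1.0, 1.0)
    return BeamformedImage(
        pixels=np.clip(out, 0.0, None),
        kind="slsc_realtime",
        depth_grid_mm=aligned.depth_grid_mm,
        line_x_mm=aligned.line_x_mm(),
        meta={
            "M": params.M,
            "kernel_samples": k,
            "pathway": "realtime",
            "focus_depth_mm": aligned.focus_depth_mm,
            "seed": aligned.seed,
        },
    )
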