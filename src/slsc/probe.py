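"""Linear-array probe geometry and acquisition parameters.

The default configuration mirrors a high-frequency breast-imaging linear
array: 128 transducer elements, a walking receive aperture of N = 64
elements, 12.5 MHz center frequency and 40 MHz RF sampling.  The package
default uses a desk-scale grid of 64 scan lines (one line per element
step, centered on the array); :meth:`ProbeConfig.full_scale` restores the
clinical 256-line grid at half-pitch line spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ProbeConfig"]


@dataclass(frozen=True)
class ProbeConfig:
    """Geometry and sampling of a linear array with a walking receive aperture.

    Parameters
    ----------
    n_elements_total:
        Number of physical transducer elements.
    n_receive:
        Size N of the walking receive aperture (elements per scan line).
    pitch_mm:
        Element center-to-center spacing in mm.
    center_frequency_hz, sampling_frequency_hz:
        Pulse center frequency and RF sampling rate.
    sound_speed_m_s:
        Assumed homogeneous sound speed.
    n_scanlines:
        Number of receive scan lines per frame.
    scanline_pitch_mm:
        Lateral spacing of scan lines; ``None`` means one line per element
        pitch, centered on the array.
    """

    n_elements_total: int = 128
    n_receive: int = 64
    pitch_mm: float = 0.3
    center_frequency_hz: float = 12.5e6
    sampling_frequency_hz: float = 40.0e6
    sound_speed_m_s: float = 1540.0
    n_scanlines: int = 64
    scanline_pitch_mm: float | None = None

    def __post_init__(self) -> None:
        if self.n_receive > self.n_elements_total:
            raise ValueError(
                f"n_receive ({self.n_receive}) must not exceed "
                f"n_elements_total ({self.n_elements_total})"
            )
        if self.sampling_frequency_hz <= 2 * self.center_frequency_hz:
            raise ValueError(
                "sampling_frequency_hz must exceed twice center_frequency_hz"
            )
        for name in (
            "n_elements_total",
            "n_receive",
            "pitch_mm",
            "center_frequency_hz",
            "sampling_frequency_hz",
            "sound_speed_m_s",
            "n_scanlines",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scanline_pitch_mm is not None and self.scanline_pitch_mm <= 0:
            raise ValueError("scanline_pitch_mm must be positive")

    # ---- derived quantities -------------------------------------------------

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed_m_s / self.center_frequency_hz * 1e3

    @property
    def sound_speed_mm_s(self) -> float:
        return self.sound_speed_m_s * 1e3

    @property
    def samples_per_wavelength(self) -> float:
        return self.sampling_frequency_hz / self.center_frequency_hz

    @property
    def axial_sample_mm(self) -> float:
        """Depth increment per RF sample for two-way travel."""
        return self.sound_speed_mm_s / (2.0 * self.sampling_frequency_hz)

    @property
    def line_spacing_mm(self) -> float:
        return self.pitch_mm if self.scanline_pitch_mm is None else self.scanline_pitch_mm

    # ---- geometry -----------------------------------------------------------

    def element_x_mm(self) -> np.ndarray:
        """Lateral center of every physical element, 0 at the array center."""
        n = self.n_elements_total
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch_mm

    def scanline_x_mm(self) -> np.ndarray:
        """Lateral position of every scan line, centered on the array."""
        n = self.n_scanlines
        return (np.arange(n) - (n - 1) / 2.0) * self.line_spacing_mm

    def first_element(self) -> np.ndarray:
        """Index of the first physical element of each line's receive aperture.

        The aperture is the block of ``n_receive`` consecutive elements whose
        center is nearest the scan line; at the array edges the block is
        shifted inward (edge truncation by shifting, never by shrinking).
        """
        ex = self.element_x_mm()
        lx = self.scanline_x_mm()
        # fractional element index of each line center
        frac = (lx - ex[0]) / self.pitch_mm
        # floor(x + 0.5) keeps half-integer centers deterministic
        first = np.floor(frac + 0.5).astype(int) - self.n_receive // 2
        return np.clip(first, 0, self.n_elements_total - self.n_receive)

    def receive_element_x_mm(self) -> np.ndarray:
        """Lateral positions of the receive elements, shape (n_receive, n_scanlines)."""
        ex = self.element_x_mm()
        first = self.first_element()
        idx = first[None, :] + np.arange(self.n_receive)[:, None]
        return ex[idx]

    @classmethod
    def full_scale(cls, **overrides) -> "ProbeConfig":
        """Clinical-scale grid: 256 scan lines at half-pitch spacing."""
        base = cls(n_scanlines=256, scanline_pitch_mm=0.15)
        return replace(base, **overrides) if overrides else base
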