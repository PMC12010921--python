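"""Synthetic RF channel data with controllable speckle, lesions and noise.

This module generates the raw inputs the rest of the package consumes:

* random point-scatterer phantoms with fully developed speckle and
  elliptical lesions of controllable echogenicity (``make_phantom``),
* focused-transmit RF channel acquisitions with electronic noise and a
  fully element-coherent clutter component (``simulate_channel_data``),
* delay-aligned Gaussian fixtures with an exactly prescribed receive
  spatial-coherence profile (``make_coherence_fixture``), used to validate
  the coherence estimators against the van Cittert-Zernike expectation,
* randomized lesion cohorts with ground-truth content labels
  (``make_cohort``).

The acoustic model is deliberately desk-scale: each element trace is a sum
of Gaussian-modulated pulses at the two-way delay (transmit time ``z/c``
for a focused beam, receive time from the exact element-scatterer
distance), with transmit weighting by a Gaussian lateral beam profile whose
width narrows linearly from the aperture half-width at the surface to the
diffraction limit at the focus.  There is no attenuation, elevation
dimension or nonlinear propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import fftconvolve

from .channel import ChannelData
from .probe import ProbeConfig

__all__ = [
    "LesionSpec",
    "ScattererField",
    "NoiseSpec",
    "PULSE_FRACTIONAL_BANDWIDTH",
    "resolution_cell_area_mm2",
    "make_phantom",
    "simulate_channel_data",
    "make_coherence_fixture",
    "make_cohort",
]

#: two-way fractional bandwidth of the Gaussian-modulated transmit pulse,
#: typical of high-frequency linear arrays
PULSE_FRACTIONAL_BANDWIDTH = 0.6

#: nominal transmit f-number used for the focal beam width and for the
#: lateral size of the resolution cell
TRANSMIT_F_NUMBER = 1.0

CONTENT_CLASSES = ("fluid", "solid_benign", "solid_malignant", "mixed", "simple_cyst")


@dataclass(frozen=True)
class LesionSpec:
    """An elliptical lesion: center/semi-axes in mm plus content and echogenicity.

    ``echogenicity_gain`` multiplies the scatterer amplitudes inside the
    ellipse; 0 means no backscatter (fluid).  Fluid-like content classes
    force a gain of 0.
    """

    center_mm: tuple[float, float]  # (lateral, axial)
    semi_axes_mm: tuple[float, float]  # (a lateral, b axial)
    content_class: str
    echogenicity_gain: float

    def __post_init__(self) -> None:
        if self.content_class not in CONTENT_CLASSES:
            raise ValueError(f"unknown content_class {self.content_class!r}")
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("semi_axes_mm must be positive")
        if self.echogenicity_gain < 0:
            raise ValueError("echogenicity_gain must be >= 0")
        if self.content_class in ("fluid", "simple_cyst") and self.echogenicity_gain != 0:
            raise ValueError("fluid-like lesions must have echogenicity_gain == 0")

    def contains(self, x_mm: np.ndarray, z_mm: np.ndarray) -> np.ndarray:
        cx, cz = self.center_mm
        a, b = self.semi_axes_mm
        return ((x_mm - cx) / a) ** 2 + ((z_mm - cz) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for a channel acquisition.

    ``electronic_snr_db`` is the per-channel SNR of iid Gaussian noise
    relative to the rms of the clean (tissue) RF.  ``clutter_amplitude_db``
    is the rms of a band-limited interference waveform, identical on every
    element of a scan line (fully coherent in the raw domain), relative to
    the same reference.  Use ``-inf`` dB amplitudes to disable a component.
    """

    electronic_snr_db: float = 10.0
    clutter_amplitude_db: float = -14.0

    def __post_init__(self) -> None:
        if math.isnan(self.electronic_snr_db) or math.isnan(self.clutter_amplitude_db):
            raise ValueError("noise levels must not be NaN")


@dataclass
class ScattererField:
    """Point scatterers of a phantom, with the lesion layout that shaped them."""

    x_mm: np.ndarray
    z_mm: np.ndarray
    amplitude: np.ndarray
    extent_mm: tuple[tuple[float, float], tuple[float, float]]  # ((x0,x1),(z0,z1))
    lesions: tuple[LesionSpec, ...] = ()
    seed: int | None = None

    @property
    def n_scatterers(self) -> int:
        return self.x_mm.size


def resolution_cell_area_mm2(probe: ProbeConfig) -> float:
    """Nominal focal resolution-cell area (axial x lateral extent).

    Axial extent is the pulse length ``c / (2 B)`` with ``B`` the absolute
    bandwidth; lateral extent is the focal beamwidth ``lambda * f#``.
    """
    bw_hz = PULSE_FRACTIONAL_BANDWIDTH * probe.center_frequency_hz
    axial_mm = probe.sound_speed_mm_s / (2.0 * bw_hz)
    lateral_mm = probe.wavelength_mm * TRANSMIT_F_NUMBER
    return axial_mm * lateral_mm


def default_extent_mm(probe: ProbeConfig, depth_mm: float = 25.0):
    """Phantom extent covering the scan lines plus a lateral margin."""
    lx = probe.scanline_x_mm()
    margin = 3.0
    return ((lx[0] - margin, lx[-1] + margin), (0.5, depth_mm))


def make_phantom(
    probe: ProbeConfig,
    lesions: list[LesionSpec] | tuple[LesionSpec, ...] = (),
    density: float = 10.0,
    seed: int = 0,
    extent_mm=None,
) -> ScattererField:
    """Draw a uniform random scatterer field with lesion echogenicity applied.

    ``density`` is the number of scatterers per focal resolution cell and
    must be at least 10 so that the tissue background produces fully
    developed (Rayleigh) speckle.  Amplitudes are zero-mean Gaussian with a
    standard deviation scaled by the lesion echogenicity map (tissue = 1).
    Deterministic for fixed ``seed``.
    """
    if density < 10:
        raise ValueError("density must be >= 10 for fully developed speckle")
    if extent_mm is None:
        extent_mm = default_extent_mm(probe)
    (x0, x1), (z0, z1) = extent_mm
    for i, les in enumerate(lesions):
        cx, cz = les.center_mm
        a, b = les.semi_axes_mm
        if not (x0 <= cx - a and cx + a <= x1 and z0 <= cz - b and cz + b <= z1):
            raise ValueError(
                f"lesion {i} ({les.content_class}, center {les.center_mm} mm) "
                f"does not fit inside the phantom extent {extent_mm}"
            )
    area = (x1 - x0) * (z1 - z0)
    n = int(round(density * area / resolution_cell_area_mm2(probe)))
    rng = np.random.default_rng(seed)
    x = rng.uniform(x0, x1, n)
    z = rng.uniform(z0, z1, n)
    amp = rng.normal(0.0, 1.0, n)
    gain = np.ones(n)
    for les in lesions:  # later lesions override earlier ones (septa in fluid)
        mask = les.contains(x, z)
        gain[mask] = les.echogenicity_gain
    return ScattererField(
        x_mm=x,
        z_mm=z,
        amplitude=amp * gain,
        extent_mm=extent_mm,
        lesions=tuple(lesions),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pulse and band helpers
# ---------------------------------------------------------------------------


def gaussian_pulse(probe: ProbeConfig) -> np.ndarray:
    """Gaussian-modulated sinusoid sampled at the RF rate, centered in the array."""
    f0 = probe.center_frequency_hz
    fs = probe.sampling_frequency_hz
    sigma_f = PULSE_FRACTIONAL_BANDWIDTH * f0 / 2.355  # FWHM -> std of spectrum
    sigma_t = 1.0 / (2.0 * math.pi * sigma_f)
    half = int(math.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(2.0 * math.pi * f0 * t)


def _bandlimit(x: np.ndarray, probe: ProbeConfig) -> np.ndarray:
    """Filter white signals along axis 0 to the probe passband (8-17 MHz band
    for the defaults), with a raised-cosine band edge."""
    n = x.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / probe.sampling_frequency_hz)
    f0 = probe.center_frequency_hz
    lo = f0 * (1.0 - 0.72 * PULSE_FRACTIONAL_BANDWIDTH)
    hi = f0 * (1.0 + 0.72 * PULSE_FRACTIONAL_BANDWIDTH)
    edge = 0.1 * (hi - lo)
    h = np.clip((freqs - (lo - edge)) / edge, 0.0, 1.0) * np.clip(
        ((hi + edge) - freqs) / edge, 0.0, 1.0
    )
    h = 0.5 - 0.5 * np.cos(np.pi * h)  # raised-cosine taper
    X = np.fft.rfft(x, axis=0)
    shape = (h.size,) + (1,) * (x.ndim - 1)
    return np.fft.irfft(X * h.reshape(shape), n=n, axis=0)


# ---------------------------------------------------------------------------
# channel-data simulation
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _deposit_rf(
    out,
    xs,
    zs,
    amp,
    elem_x,
    first_elem,
    line_x,
    sigma_focal,
    sigma_near,
    focus_z,
    inv_c,
    fs,
    uniform_tx,
):  # pragma: no cover - exercised via simulate_channel_data
    n_samp, n_elem, n_lines = out.shape
    trunc = 3.0
    for l in range(n_lines):
        x0 = line_x[l]
        f0e = first_elem[l]
        for s in range(xs.size):
            a = amp[s]
            if a == 0.0:
                continue
            z = zs[s]
            if uniform_tx:
                w = a
            else:
                sig = sigma_focal + (sigma_near - sigma_focal) * abs(z - focus_z) / focus_z
                dx = xs[s] - x0
                if abs(dx) > trunc * sig:
                    continue
                w = a * math.exp(-0.5 * dx * dx / (sig * sig))
            t_tx = z * inv_c
            for e in range(n_elem):
                ex = elem_x[f0e + e]
                dxe = xs[s] - ex
                tau = (t_tx + math.sqrt(dxe * dxe + z * z) * inv_c) * fs
                i0 = int(tau)
                if 0 <= i0 < n_samp - 1:
                    fr = tau - i0
                    out[i0, e, l] += w * (1.0 - fr)
                    out[i0 + 1, e, l] += w * fr


def transmit_sigma_mm(probe: ProbeConfig, focus_depth_mm: float) -> tuple[float, float]:
    """Gaussian transmit-beam lateral std at the focus and at the surface."""
    sigma_focal = probe.wavelength_mm * TRANSMIT_F_NUMBER / 2.355
    aperture_mm = probe.n_receive * probe.pitch_mm
    sigma_near = aperture_mm / 2.0 / 2.355
    return sigma_focal, sigma_near


def simulate_channel_data(
    field: ScattererField,
    probe: ProbeConfig,
    focus_depth_mm: float,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    uniform_transmit: bool = False,
) -> ChannelData:
    """Simulate raw (unaligned) RF channel data for every scan line.

    Per scan line, the walking receive aperture of ``probe.n_receive``
    elements records the sum over scatterers of a Gaussian-modulated pulse
    at the two-way delay ``(z + |r_elem - r_scat|)/c``, with the transmit
    weight of a Gaussian beam focused at ``focus_depth_mm``
    (``uniform_transmit=True`` replaces the beam by uniform insonification,
    useful for depth-uniform speckle statistics).  Electronic noise and the
    element-coherent clutter component are then added per ``noise``.
    """
    (_, _), (z0, z1) = field.extent_mm
    if not (z0 <= focus_depth_mm <= z1):
        raise ValueError(
            f"focus_depth_mm={focus_depth_mm} outside phantom depth range ({z0}, {z1})"
        )
    if noise is None:
        noise = NoiseSpec(electronic_snr_db=-math.inf, clutter_amplitude_db=-math.inf)
    c_mm = probe.sound_speed_mm_s
    fs = probe.sampling_frequency_hz
    aperture_mm = probe.n_receive * probe.pitch_mm
    t_max = (z1 + math.sqrt(z1**2 + aperture_mm**2)) / c_mm
    pulse = gaussian_pulse(probe)
    n_samples = int(math.ceil(t_max * fs)) + pulse.size
    n_lines = probe.n_scanlines

    rf = np.zeros((n_samples, probe.n_receive, n_lines))
    sigma_focal, sigma_near = transmit_sigma_mm(probe, focus_depth_mm)
    if field.n_scatterers:
        _deposit_rf(
            rf,
            np.ascontiguousarray(field.x_mm, dtype=np.float64),
            np.ascontiguousarray(field.z_mm, dtype=np.float64),
            np.ascontiguousarray(field.amplitude, dtype=np.float64),
            probe.element_x_mm(),
            probe.first_element(),
            probe.scanline_x_mm(),
            sigma_focal,
            sigma_near,
            float(focus_depth_mm),
            1.0 / c_mm,
            fs,
            uniform_transmit,
        )
        rf = fftconvolve(rf, pulse[:, None, None], mode="same", axes=0)
        ref_rms = float(np.sqrt(np.mean(rf**2)))
    else:
        ref_rms = 0.0
    if ref_rms == 0.0:
        ref_rms = 1.0  # noise-only acquisitions: unit reference

    ss = np.random.SeedSequence(seed)
    rng_noise, rng_clutter = (np.random.default_rng(s) for s in ss.spawn(2))
    if np.isfinite(noise.electronic_snr_db):
        sigma_n = ref_rms * 10.0 ** (-noise.electronic_snr_db / 20.0)
        rf = rf + rng_noise.normal(0.0, sigma_n, rf.shape)
    if np.isfinite(noise.clutter_amplitude_db):
        sigma_c = ref_rms * 10.0 ** (noise.clutter_amplitude_db / 20.0)
        w = _bandlimit(rng_clutter.normal(0.0, 1.0, (n_samples, n_lines)), probe)
        w *= sigma_c / np.sqrt(np.mean(w**2, axis=0, keepdims=True))
        rf = rf + w[:, None, :]

    return ChannelData(
        rf=rf,
        probe=probe,
        focus_depth_mm=float(focus_depth_mm),
        aligned=False,
        seed=seed,
        meta={
            "ref_rms": ref_rms,
            "noise": noise,
            "uniform_transmit": uniform_transmit,
            "extent_mm": field.extent_mm,
        },
    )


# ---------------------------------------------------------------------------
# analytic coherence fixture
# ---------------------------------------------------------------------------


def make_coherence_fixture(
    profile: np.ndarray,
    n_elements: int = 64,
    n_samples: int = 4000,
    seed: int = 0,
    probe: ProbeConfig | None = None,
) -> ChannelData:
    """Delay-aligned Gaussian element signals with a prescribed coherence profile.

    ``profile[m]`` is the target inter-element correlation at lag ``m``
    (``profile[0]`` must be 1); lags beyond the profile length are taken as
    zero.  The cross-element covariance is the Toeplitz matrix of the
    profile, realized by an eigendecomposition factor applied to iid
    Gaussian samples that are band-limited axially to the probe passband.
    Raises ``ValueError`` naming the smallest eigenvalue when the profile is
    not positive semi-definite.
    """
    if probe is None:
        probe = ProbeConfig(n_receive=n_elements, n_scanlines=1)
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0 or not np.isclose(profile[0], 1.0):
        raise ValueError("profile must start with 1 at lag 0")
    full = np.zeros(n_elements)
    full[: min(profile.size, n_elements)] = profile[:n_elements]
    from scipy.linalg import toeplitz

    cov = toeplitz(full)
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(
            f"profile is not a valid correlation sequence: smallest eigenvalue "
            f"of its Toeplitz matrix is {w.min():.3e}"
        )
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, 1.0, (n_samples, n_elements))
    g = _bandlimit(g, probe)
    g /= g.std(axis=0, keepdims=True)
    x = g @ factor.T  # (n_samples, n_elements), covariance -> cov
    depth = np.arange(n_samples) * probe.axial_sample_mm
    return ChannelData(
        rf=x[:, :, None],
        probe=probe,
        focus_depth_mm=float(depth[n_samples // 2]),
        aligned=True,
        depth_grid_mm=depth,
        seed=seed,
        meta={"profile": full},
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: randomization ranges of the default lesion cohort (mm / linear gain / dB)
COHORT_DEFAULTS = {
    "lateral_center_mm": (-3.0, 3.0),
    "depth_mm": (12.0, 20.0),
    "semi_axis_lat_mm": (2.0, 4.0),
    "semi_axis_ax_mm": (1.5, 3.0),
    "solid_gain": (0.5, 0.8),
    "septa_gain": (0.6, 0.9),
    "focus_offset_mm": (-3.0, 3.0),
    "clutter_jitter_db": (-4.0, 4.0),
}


def _cohort_lesions(kind: str, rng: np.random.Generator) -> list[LesionSpec]:
    d = COHORT_DEFAULTS
    cx = rng.uniform(*d["lateral_center_mm"])
    cz = rng.uniform(*d["depth_mm"])
    a = rng.uniform(*d["semi_axis_lat_mm"])
    b = rng.uniform(*d["semi_axis_ax_mm"])
    if kind == "fluid":
        return [LesionSpec((cx, cz), (a, b), "fluid", 0.0)]
    if kind == "solid":
        cls = "solid_malignant" if rng.uniform() < 0.33 else "solid_benign"
        return [LesionSpec((cx, cz), (a, b), cls, rng.uniform(*d["solid_gain"]))]
    if kind == "mixed":
        lesions = [LesionSpec((cx, cz), (a, b), "mixed", 0.0)]
        for _ in range(rng.integers(1, 4)):
            fa = rng.uniform(0.2, 0.4)
            ox = rng.uniform(-0.5, 0.5) * a
            oz = rng.uniform(-0.5, 0.5) * b
            lesions.append(
                LesionSpec(
                    (cx + ox, cz + oz),
                    (fa * a, fa * b),
                    "mixed",
                    rng.uniform(*d["septa_gain"]),
                )
            )
        return lesions
    raise ValueError(kind)


def iter_cohort(
    n_fluid: int,
    n_solid: int,
    n_mixed: int,
    probe: ProbeConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    density: float = 10.0,
):
    """Yield ``(ChannelData, MassRecord)`` pairs for a randomized lesion cohort.

    One phantom is built per mass; lesion sizes, depths, echogenicity and
    clutter severity are randomized within :data:`COHORT_DEFAULTS`.  The
    ground-truth content class and the generating geometry/seeds are stored
    on each record.  Deterministic for a fixed ``seed``.
    """
    from .evaluate import MassRecord

    if min(n_fluid, n_solid, n_mixed) < 0:
        raise ValueError("cohort counts must be >= 0")
    if probe is None:
        probe = ProbeConfig()
    if noise is None:
        noise = NoiseSpec()
    kinds = ["fluid"] * n_fluid + ["solid"] * n_solid + ["mixed"] * n_mixed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(kinds))
    for i, (kind, child) in enumerate(zip(kinds, children)):
        s_phantom, s_channel, s_geom, s_roi = (
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(4)
        )
        rng = np.random.default_rng(s_geom)
        lesions = _cohort_lesions(kind, rng)
        jitter = rng.uniform(*COHORT_DEFAULTS["clutter_jitter_db"])
        mass_noise = NoiseSpec(
            electronic_snr_db=noise.electronic_snr_db,
            clutter_amplitude_db=noise.clutter_amplitude_db + jitter,
        )
        focus = float(
            np.clip(
                lesions[0].center_mm[1] + rng.uniform(*COHORT_DEFAULTS["focus_offset_mm"]),
                5.0,
                24.0,
            )
        )
        # widen the default extent when a lesion would clip its edge
        (x0, x1), (z0, z1) = default_extent_mm(probe)
        for les in lesions:
            (cx, cz), (a, b) = les.center_mm, les.semi_axes_mm
            x0, x1 = min(x0, cx - a - 1.0), max(x1, cx + a + 1.0)
            z0, z1 = min(z0, cz - b - 1.0), max(z1, cz + b + 1.0)
        phantom = make_phantom(
            probe, lesions, density=density, seed=s_phantom, extent_mm=((x0, x1), (z0, z1))
        )
        data = simulate_channel_data(phantom, probe, focus, mass_noise, seed=s_channel)
        record = MassRecord(
            mass_id=f"mass{i:03d}",
            ground_truth=kind,
            meta={
                "content_class": lesions[0].content_class,
                "lesion": lesions[0],
                "all_lesions": lesions,
                "focus_depth_mm": focus,
                "noise": mass_noise,
                "seed_phantom": s_phantom,
                "seed_channel": s_channel,
                "seed_roi": s_roi,
            },
        )
        yield data, record


def make_cohort(
    n_fluid: int,
    n_solid: int,
    n_mixed: int,
    probe: ProbeConfig | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    density: float = 10.0,
) -> list:
    """Materialized version of :func:`iter_cohort` (list of pairs)."""
    return list(
        iter_cohort(n_fluid, n_solid, n_mixed, probe=probe, noise=noise, seed=seed, density=density)
    )
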