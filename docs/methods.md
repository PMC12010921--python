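# Methods

## Problem and model

Hypoechoic breast masses that are actually benign fluid-filled complicated
cysts are hard to distinguish from solid (possibly malignant) masses on
B-mode ultrasound, largely because acoustic clutter fills anechoic regions
with signal.  Short-lag spatial coherence (SLSC) imaging displays, per
pixel, the spatial coherence of the delay-aligned receive-aperture signals
summed over the first M element separations.  Diffuse scattering from
tissue is spatially coherent at short lags (the van Cittert–Zernike
prediction for an unapodized rectangular aperture at focus is the triangle
1 − m/N); echoes from fluid are dominated by spatially incoherent
electronic noise.  Fluid therefore appears dark in SLSC images regardless
of clutter, and the mass/tissue contrast — quantified by the generalized
contrast-to-noise ratio (gCNR) — separates fluid from solid content.

The package implements the chain

1. synthetic RF channel data (`slsc.synthetic`),
2. receive delays, delay-and-sum B-mode, display rendering and 8-bit
   screenshot surrogates (`slsc.beamform`),
3. SLSC in an offline and a real-time (GPU-style) formulation
   (`slsc.coherence`),
4. matched elliptical ROIs and gCNR (`slsc.quantify`),
5. threshold classification, ROC/AUC, optimal threshold, Fleiss' κ
   (`slsc.evaluate`),
6. a configuration-driven experiment runner and CLI (`slsc.pipeline`,
   `slsc.cli`).

## The two SLSC formulations

**Offline.**  For pixel (n, x), lag m and an axial kernel of k samples
centered on n, every one of the N − m element pairs contributes the
normalized cross-correlation of its zero-mean kernel signals; the pair
average is the coherence function R̂(m), and the pixel is Σ_{m=1..M} R̂(m).
The computation runs on real RF; the kernel mean is removed per element
per kernel.

**Real-time.**  The GPU-style reordering accumulates, per lag, the
pair-summed cross-correlation C_ij and the pair-summed energies C_ii, C_jj
on analytic signals (no mean removal), sums each over the kernel, and only
then forms one normalized ratio per lag (real part), summing ratios over
m.  Sum-then-normalize differs from normalize-then-average, so the two
pathways agree only approximately — that difference is a study object, and
the cohort experiment reports the per-mass |ΔgCNR| between pathways
(median ≈ 0.02 under defaults) and the classification agreement.

Conventions shared by both pathways: negative pixels are clipped to zero
(stated in the source method only for the offline pathway, adopted for
both so that displays and gCNR histograms are comparable); per-lag values
are clipped to [−1, 1] (mathematically guaranteed by Cauchy–Schwarz,
enforced against floating-point overshoot); pairs/denominators with zero
energy contribute 0 rather than NaN.  The default kernel is one wavelength
of two-way RF travel, k = round(2 f_s/f_0) = 6 samples at the default
probe, and M = 7 (10 % of the 64-element receive aperture).  At image
edges the kernel is truncated to the available samples; the naive
reference oracle in the tests implements the identical convention, and the
vectorized production path matches it to 1e-10.

Estimator bias note: the normalized correlation over a 6-sample band-limited
kernel carries a small negative bias (≈ −0.02 per lag on the triangle
fixture), so the recovered short-lag sum on the 1 − m/64 fixture averages
≈ 6.43 against the ideal 6.5625.  This is inherent to the one-wavelength
kernel, not a defect of the implementation.

## Synthetic data

The simulator is deliberately desk-scale, not a full-wave or Field-II-grade
model.  Scatterers are uniform random points with zero-mean Gaussian
amplitudes; lesions are ellipses that scale the amplitude standard
deviation by an echogenicity gain (0 for fluid).  Each element trace is a
sum of Gaussian-modulated pulses (60 % fractional bandwidth — the pulse is
unstated in the source and this value is typical of high-frequency linear
arrays) at the two-way delay: transmit time z/c (focused beam), receive
time from the exact element–scatterer distance, linearly interpolated onto
the 40 MHz sample grid.  The transmit beam is a Gaussian lateral profile
whose standard deviation interpolates linearly between the aperture
half-width at the surface and the λ·f# diffraction width at the focus
(f# = 1); scatterers beyond 3σ of a line's beam are skipped.  There is no
attenuation, TGC, elevation dimension or nonlinear propagation.

Noise has two components, both scaled to the rms of the clean simulated RF:

* electronic noise — iid Gaussian per sample/element/line; default channel
  SNR 10 dB (typical clinical channel SNR).
* clutter — a band-limited waveform identical on every element of a scan
  line (fully coherent in the raw domain); default −14 dB.  After receive
  delays are applied, the per-element shifts decorrelate this component at
  larger lags, which is exactly how reverberation clutter degrades B-mode
  contrast while affecting coherence much less.

Under these defaults the simulated regime matches the clinical premise:
fluid-lesion short-lag coherence < 0.2 (noise-dominated), tissue coherence
monotone decreasing in m, B-mode fluid/solid contrast confounded by
clutter, SLSC contrast not.

**Cohort generator.**  One phantom per mass.  Lesion lateral center
U(−3, 3) mm, depth U(12, 20) mm, semi-axes U(2, 4) × U(1.5, 3) mm; solid
echogenicity gain U(0.5, 0.8) (mildly hypoechoic, coherence-preserving);
fluid gain 0; mixed masses are a fluid ellipse containing 1–3 solid septa
(gain U(0.6, 0.9)) — these emulate clusters of cysts and are excluded from
the binary statistics.  The transmit focus is placed within 3 mm of the
lesion center (the acquisition protocol places it within 1 cm).  Clutter
severity jitters per mass by U(−4, 4) dB.  Scatterer density is 10 per
focal resolution cell (the fully-developed-speckle floor); the
speckle-statistics checks use 20 with uniform insonification because the
effective (receive-only) resolution cell is then smaller than the focal
cell the density is defined on.  All randomness flows from explicit seeds
through `numpy.random.SeedSequence` spawning; identical (config, seed)
gives bit-identical outputs, and the experiment runner's CSVs are
byte-identical across reruns.

**Coherence fixture.**  `make_coherence_fixture` bypasses the acoustic
model entirely: it draws zero-mean Gaussian element signals with
cross-element covariance equal to the Toeplitz matrix of a prescribed
coherence profile (eigendecomposition factor; non-PSD profiles are
rejected naming the smallest eigenvalue), band-limited axially to the
probe passband (≈ 8–17 MHz).  This gives an exact ground truth for
validating Eq.-level estimator behavior independent of the simulator.

**What the generator does not emulate:** real tissue heterogeneity,
aberration, reverberation geometry, attenuation with depth, scanner
post-processing (the screenshot surrogate models only log compression at
60 dB and 8-bit quantization — clinical screenshots include proprietary
nonlinear filters, so absolute screenshot gCNR values are not comparable
to clinical ones).  Passing cohort tests therefore demonstrate internal
consistency of the method chain under the stated statistical model, not
clinical performance; the published clinical AUCs (0.963/0.998 real-time/
offline SLSC) are measured on a 60-mass patient dataset that is not
publicly deposited, and are not reproduced here.

## Quantification

The mass ROI is the lesion ellipse shrunk by a 0.8 margin factor ("within
the mass"); the tissue ROI is the same ellipse laterally offset with an
edge-to-edge gap drawn uniformly from the feasible part of 0.9–8.2 mm,
falling back to a depth offset (< 5 mm gap) when the mass spans most of
the lateral field.  The same ROI pair is applied to every image pathway;
beamformed pathways contribute pre-normalization, pre-log pixel values and
screenshot pathways contribute gray levels in [0, 255].

gCNR = 1 − Σ_j min(h_mass, h_tissue) on shared equal-width bins spanning
the pooled min–max range, histograms normalized to unit sum (probability
normalization is forced by the Σmin ≤ 1 bound).  The default bin count is
min(256, ⌈√min(n_mass, n_tissue)⌉): with desk-scale ROIs (≈ 2×10³
correlated pixels) a fixed 256-bin histogram overlap carries a positive
sampling bias of order √(bins/n_eff) that would dominate the statistic,
while the cap reproduces 256 bins for large-n data.  Bin stability is
property-tested (|gCNR(128) − gCNR(512)| < 0.03 at n = 10⁵).

## Evaluation

A mass is called fluid iff gCNR ≥ threshold (ties → fluid, consistent with
"below threshold → solid").  Default threshold 0.73 (the previously
published SVM-derived operating point); the ROC sweeps 0.00–1.00 in 0.01
steps, points are sorted by 1 − specificity, deduplicated, anchored at
(0,0) and (1,1), and integrated trapezoidally.  The optimal threshold
minimizes the Euclidean distance to (0, 1), ties resolved to the smallest
threshold.  Mixed masses and simple cysts are excluded from
sensitivity/specificity (they mix TP/TN, or are trivially identified on
B-mode, respectively).  Fleiss' κ is computed via statsmodels with the
Landis–Koch interpretation bands (≤0 poor, ≤0.20 slight, ≤0.40 fair,
≤0.60 moderate, ≤0.80 substantial, >0.80 almost perfect); the source's
printed band list has a 0.80–0.81 gap and five labels for six ranges, and
its own worked values (e.g. κ = 0.53 "moderate") match Landis–Koch.

## Problem sizes and numerical choices

The default grid is 64 scan lines at 0.3 mm spacing and 25 mm depth
(`ProbeConfig.full_scale()` restores the clinical 256-line half-pitch
grid), one depth pixel per RF sample (c/2f_s ≈ 19 µm).  The default cohort
is 8 fluid + 16 solid masses; a full run (simulation, five image pathways,
gCNR, ROC) takes a few minutes on one CPU.  Fractional receive delays use
linear interpolation (validated against analytic sinusoids to 1e-3);
envelopes are the magnitude of the depth-axis analytic signal; screenshot
quantization rounds half-up with per-pixel dB error ≤ DR/255/2.  The
single-view-per-mass simplification (the clinical protocol acquires two
orthogonal views) is a deliberate scope reduction; the decision trace
records pathway, gCNR value and threshold per call so the workflow remains
fully reproducible from config + seed.

## Known limitations

* The acoustic model omits attenuation, aberration and elevation focusing;
  absolute coherence profiles of simulated tissue are therefore
  implementation-dependent (the analytic fixture, not the simulator, is
  the ground truth for estimator validation).
* gCNR values depend on ROI pixel counts through histogram sampling noise;
  comparisons across image grids should fix `n_bins` explicitly.
* The real-time formulation is a faithful reimplementation of the
  published signal-processing order, not an actual GPU kernel; frame-rate
  engineering is out of scope.
* Reader behavior (BI-RADS assignment, uncertainty) is not modeled; κ
  utilities operate on externally supplied rating tables.
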