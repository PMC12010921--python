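# slsc — short-lag spatial coherence breast ultrasound analysis

Benign fluid-filled breast masses (complicated cysts) and hypoechoic solid
masses look alike on B-mode ultrasound because acoustic clutter fills
anechoic regions, which drives unnecessary biopsies.  Short-lag spatial
coherence (SLSC) imaging replaces echo amplitude with the spatial
coherence of the receive aperture: fluid (noise-dominated) has low
coherence and appears dark, solid tissue keeps near-tissue coherence.  The
mass/tissue contrast of an SLSC image, measured with the generalized
contrast-to-noise ratio (gCNR), then separates fluid from solid content
objectively.

This package is a complete, synthetic-data implementation of that analysis
chain for researchers working on coherence-based beamforming:

* **Simulation** — point-scatterer speckle phantoms with elliptical
  lesions (fluid / solid / mixed), focused-transmit RF channel data,
  electronic noise and element-coherent clutter; analytic fixtures with an
  exactly prescribed coherence profile.
* **Beamforming** — geometric receive delays, delay-and-sum B-mode with
  analytic-signal envelope, 60 dB log-compressed displays and 8-bit
  screenshot surrogates.
* **SLSC** — both formulations, kept deliberately distinct:

  offline (per pixel, kernel of k samples, N-element aperture)

      R̂(m) = 1/(N−m) Σᵢ Σₙ sᵢ(n) sᵢ₊ₘ(n) / √(Σₙ sᵢ²(n) Σₙ sᵢ₊ₘ²(n)),
      pixel = Σ_{m=1..M} R̂(m),   negatives clipped to 0

  real-time (GPU-style: pair sums C_ij, C_ii, C_jj first, on analytic
  signals, kernel-summed, one ratio per lag)

      pixel = Σ_{m=1..M} Re[ Σ_k C_ij / √(Σ_k C_ii · Σ_k C_jj) ]

* **Quantification** — matched elliptical mass/tissue ROIs (0.9–8.2 mm
  lateral edge gap, depth fallback < 5 mm) and
  gCNR = 1 − Σⱼ min(h_mass, h_tissue).
* **Evaluation** — fluid iff gCNR ≥ threshold (default 0.73), ROC over
  thresholds 0–1 in 0.01 steps with trapezoidal AUC, closest-to-(0,1)
  optimal threshold, Fleiss' κ with agreement bands.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Run the default experiment — a 24-mass synthetic cohort (8 fluid, 16
solid), five image pathways per mass, one shared ROI pair per mass:

```sh
slsc run --seed 1 --outdir out/
```

which prints

```
bmode_offline: AUC = 1.000
slsc_offline: AUC = 1.000
slsc_realtime: AUC = 1.000
bmode_screenshot: AUC = 1.000
slsc_screenshot: AUC = 1.000
artifacts in out/
```

and writes `cohort.csv` (per-mass gCNR per pathway), `roc_<pathway>.csv`
(101 threshold points each), `decisions.csv` (the per-mass workflow calls)
and `report.json`.  From that run's report:

* SLSC-gCNR at the 0.73 threshold: sensitivity 1.00, specificity 1.00 —
  every fluid mass has SLSC gCNR ≥ 0.94, every solid mass ≤ 0.62.  B-mode
  gCNR separates the cohort too (AUC 1.0 at n = 24) but with much smaller
  margins (fluid ≈ 0.69–0.81): clutter fills the fluid lesions in
  amplitude images, while it barely touches coherence.
* The ROC-optimal SLSC threshold is 0.62, and the median per-mass
  difference between real-time-formulation and offline SLSC gCNR is 0.017
  with 100 % classification agreement — the two formulations are
  interchangeable at the decision level on this cohort.

The same steps are available piecewise (`slsc simulate`, `slsc beamform`,
`slsc quantify`, `slsc evaluate`) and as a library:

```python
from slsc import (ExperimentConfig, run_experiment)
result = run_experiment(ExperimentConfig(n_fluid=8, n_solid=16, seed=1))
print(result.report["pathways"]["slsc_offline"]["at_0.73"])
```

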