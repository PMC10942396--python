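# anticiprf

Anticipatory spatial attention reshapes responses across human visual
cortex before a target ever appears: BOLD amplitude rises for cortical
locations representing the cued location and falls elsewhere, and
population receptive field (pRF) centers shift toward the attended target.
`anticiprf` is a tested, reusable reimplementation of the full analysis
pipeline for this kind of concurrent psychophysics + event-related pRF
mapping experiment, together with a ground-truth simulator so that every
stage is validated by parameter recovery.

It is aimed at visual/computational neuroscientists who want to analyze —
or simulate and stress-test — trial-wise attention-cued pRF mapping data:
event-related GLMs on vertex time series, per-condition pRF fits,
attention-field models of center shifts, polar tuning of amplitude
modulation, hemodynamic latency estimation, and signal-detection behavior.

## The models at the core

- **pRF model.** Each vertex responds to mapping stimulus *s* with
  `β_s = g · Σ_px G(x, y, σ) · A_s / Σ_px G`, an isotropic 2D Gaussian
  (center x, y; size σ, one SD, in degrees) overlapped with the binary bar
  aperture and scaled by a gain. Fits minimize the residual sum of squares
  over the 49-stimulus beta profile via an exhaustive coarse grid (gain
  solved in closed form per grid point) followed by bounded refinement;
  R² = 1 − RSS/TSS.
- **GLM.** `y = (Σ_k β_k x_k) * HRF + nuisance`, with 250 indicator columns
  (5 attention conditions × 49 stimuli + 5 target regressors) at 1-s TR,
  per-scan polynomial nuisance, OLS, betas in %BOLD.
- **Attention field.** A Gaussian gain field at the attended target
  multiplies a receptive field; the product's center
  `(σ_a²·c_prf + σ₀²·c_field)/(σ₀² + σ_a²)` predicts toward-target pRF
  shifts, used as exact synthesis ground truth.
- **Amplitude tuning.** Focal-minus-distributed modulation binned by polar
  angle distance from the target and fit with a difference of von Mises
  functions `V(x; μ, κ₁) − V(x; μ, κ₂) + B`; the x-intercepts define the
  attentional spread.
- **Latency.** Event-triggered modulation traces fit limb-wise with
  logistics `1/(1 + e^{−m(t−t50)})`; rise latency `t₁₀ = t50 − ln 9/m`;
  bar-duration (1 s vs 2 s) latency differences, bootstrapped across
  participants, discriminate sustained vs transient vs target-evoked
  accounts, with Bayes factors comparing difference means of 0 s vs 1 s.
- **Behavior.** Equal-variance SDT: `d′ = z(hit) − z(FA)` with a 0.5
  correction, per cue validity × target location; percentile bootstrap CIs.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Simulate an hV4-like vertex whose focal-condition pRF is displaced toward
the attended left target, and recover the displacement from the fitted
centers:

```python
import numpy as np
from anticiprf import design, prf, synth

apertures = design.build_bar_apertures()          # 48 bars + blank, 12.4 deg window
base, sigma = (-7.0, 0.0), 0.5 + 0.35 * 7.0       # hV4 size at 7 deg eccentricity
focal = synth.shifted_center(base, (-6.0, 0.0), 0.3)

betas_dist = prf.predict_beta_profile(prf.PRFParams(*base, sigma, 1.0, np.nan), apertures)
betas_focal = prf.predict_beta_profile(prf.PRFParams(*focal, sigma, 1.0, np.nan), apertures)
fit_d = prf.fit_prf(betas_dist, apertures)
fit_f = prf.fit_prf(betas_focal, apertures)
print(f"distributed center ({fit_d.x:.3f}, {fit_d.y:.3f})")
print(f"focal center       ({fit_f.x:.3f}, {fit_f.y:.3f})")
print(f"center shift       {np.hypot(fit_f.x - fit_d.x, fit_f.y - fit_d.y):.4f} deg")
```

Output:

```
distributed center (-7.000, 0.000)
focal center       (-6.700, -0.000)
center shift       0.3000 deg
```

The fitted centers land on the generating values, so the recovered
focal-vs-distributed center distance equals the imposed 0.3° shift — the
position-shift magnitude typical of hV4, against a 0.04° V1-like shift
where the additive baseline change dominates instead.

An end-to-end synthetic run (simulate → GLM → pRF → ROIs → shifts/tuning/
behavior, with TSV/HDF5/JSON outputs and a seed-stamped manifest):

```python
from anticiprf.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(out_dir="run1", seed=1, n_per_map=20))
```

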