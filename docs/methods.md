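# Methods

## The model

`anticiprf` reimplements, end to end, the analysis of a concurrent
psychophysics–fMRI experiment in which covert spatial attention is cued on
every trial while population receptive fields (pRFs) are mapped with bar
stimuli. The chain is:

1. **Forward model (synthesis).** Each cortical-surface vertex carries an
   isotropic 2D Gaussian pRF with center (x₀, y₀) and size σ₀ (one SD, all
   in degrees of visual angle). The response to mapping stimulus *s* under
   attention condition *c* is

       β_cs = g_c · G · O(x_c, y_c, σ_c; A_s) + b_c

   where O is the unit-peak-Gaussian/aperture overlap normalized by the
   Gaussian's pixel sum (so G is a gain in %BOLD and O ∈ [0, 1] independent
   of pixel resolution), b_c an additive baseline shift, and g_c a
   multiplicative response-gain factor. Attention enters in one of four
   modes: `additive_only` (b_c ≠ 0), `position_only` (the focal-condition
   pRF center is the Gaussian-product of the base pRF with an attention
   field), `both`, or `multiplicative_gain` (g_c ≠ 1, b_c = 0).

2. **Attention field.** A Gaussian field at the attended target (6° on a
   cardinal meridian) with size σ_attn multiplies the receptive field; the
   product is again Gaussian with

       center' = (σ_attn²·center + σ₀²·field) / (σ₀² + σ_attn²)
       σ'      = sqrt(σ₀² σ_attn² / (σ₀² + σ_attn²))

   The center shift is imposed through this closed form so recovery targets
   are exact. σ-shrinkage is optional (`shrink_sigma`, default off): the
   default isolates position shifts, which is what the downstream
   distance-change analyses quantify.

3. **BOLD generation.** The 250-column indicator design (5 conditions × 49
   stimuli + 5 target regressors; 1-s TR) times the true betas gives the
   neural predictor; additive attentional modulation is added as a per-trial
   boxcar placed by one of three temporal accounts (`transient`: the 1 s
   after the cue; `sustained`: cue TR through target TR; `target_evoked`:
   target TR onward). The predictor is convolved per scan with a canonical
   double-gamma HRF (Γ(6,1) − Γ(16,1)/6, unit peak, ~5 s to peak, 50-s
   support), and the series is `baseline · (1 + (signal + drift + noise)/100)`.

4. **GLM.** Ordinary least squares of the HRF-convolved indicators plus
   per-scan Legendre polynomials (default order 2) on the raw series; betas
   are converted to %BOLD by dividing by the vertex's temporal mean × 100.
   Because the mean includes the evoked activation, recovered betas carry a
   common scale factor of order the mean activation percentage (~0.1–1%);
   exact-recovery tests allow 1% relative error for this reason. Variance
   explained is 1 − RSS(full)/RSS(nuisance-only) — the fraction of detrended
   variance captured by the task regressors — which is affine-invariant and
   supports the >5% vertex threshold used downstream.

5. **pRF fit.** Per condition (and for the condition average), the 49-beta
   profile is fit by minimizing RSS between data and gain-scaled overlaps:
   an exhaustive coarse grid (centers 1°-spaced inside the 12.4° window,
   σ log-spaced over [0.25, 8]°, 10 levels) with the gain profiled out in
   closed form at every grid point, then bounded Nelder–Mead refinement of
   (x, y, σ) from the best grid point (centers within ±14°, σ ∈ [0.1, 12]°).
   The refined solution is kept only if it does not increase RSS. R² =
   1 − RSS/TSS with TSS the *uncentered* sum of squares of the data. The
   blank stimulus predicts 0 and is included in the fit by default
   (`FitConfig.include_blank`), anchoring additive offsets into the
   residual rather than the gain.

6. **Analyses.**
   - *Amplitude tuning*: per-vertex focal-minus-distributed modulation
     (averaged over the 49 stimuli) is projected at average-condition pRF
     centers, interpolated to a square grid (0.25° default), rotated so the
     attended location is up, and collapsed into 20°-wide polar-angle bins
     (eccentricity 4–8°, GLM VE > 5%; bin centers are member means). The
     binned curve is fit with a difference of two von Mises functions
     V(x; μ, κ₁) − V(x; μ, κ₂) + B, V = S·exp(κ cos(x − μ))/(2π I₀(κ)),
     with a single shared scalar S (a separate-S variant is available).
     Degrees map linearly onto [−π, π] so the von Mises period matches the
     polar circle. Multi-start nonlinear least squares: μ ∈ {−20, 0, 20}°,
     κ₁ ∈ {2, 6, 12}, κ₂ ∈ {0.3, 1, 3}; S from the curve range, B from its
     minimum; best start by RSS wins. The attentional spread is the distance
     between the curve's x-intercepts, bracketed on [−60, 0] and [0, 60]
     and polished with Brent's method; missing sign changes are flagged
     rather than fabricated.
   - *Latency*: ROI traces (%BOLD, first-order per-scan detrend) are
     averaged over trials whose bar overlapped the target, split by bar
     duration and attend-in / attend-out / distributed, aligned to cue or
     target, over a 10-sample window. The attend-in minus attend-out trace
     is min-max normalized, split at its peak, and each limb fit with a
     logistic 1/(1 + e^{−m(t − t50)}). Rise latency: t₁₀ = t50 − ln(9)/m;
     fall latency: the 10%-decline point (f = 0.9 on the falling limb,
     t50 + ln(9)/m with m < 0). The 2-s minus 1-s latency difference is
     bootstrapped over participants (resample, average, refit; failed
     replicate fits are excluded and counted). Bayes factors compare mean
     differences of 0 s vs 1 s using normal PDFs with SDs derived from the
     bootstrap 95% CI ((hi − lo)/(2·1.96)), multiplied across maps.
   - *Position shifts*: per vertex and target, ‖focal center − target‖ −
     ‖distributed center − target‖ (Euclidean, degrees), averaged over
     vertices within a map and over the four conditions; vertices must have
     eccentricity 0.5–5.5° and pRF R² > 0.25 in all five condition models.
     The shuffled control permutes cue labels across trials, rebuilds the
     design, and re-runs GLM + pRF (one permutation by default). Vector
     graphs bin paired opposite-condition centers over 1° eccentricity rings
     (0.5–6.25°) × 45° sectors, restricted to eccentricity < 6°, keyed on
     the pair-averaged (or, optionally, distributed-condition) center;
     congruence is the sign of the shift along the pair's axis.
   - *Behavior*: d′ = z(hit) − z(FA) with CW arbitrarily "target present";
     the default correction is log-linear (+0.5 to the hit and FA counts and
     +1.0 to the trial counts; a numerator-only variant is available). RTs
     average over correct and incorrect trials. Group statistics use the
     percentile bootstrap over participants (default 1000 resamples, 68% CI).
   - *Gaze*: 1 kHz samples converted from screen pixels to degrees with the
     exact arctangent of the scanner display geometry (1920×1080 px,
     60×36.2 cm, 86.5 cm viewing distance); blink samples removed; per-trial
     means from bar onset to target onset; the median over the 300-ms
     fixation windows is subtracted as a calibration correction; fixation
     breaks are counted at the 2° criterion.

## Trial and scan geometry

Trials follow the protocol's event layout: 300 ms fixation, 300 ms pre-cue,
1- or 2-s bar, jittered ISI (50 ms at 10%, 300/400/500 ms at 30% each),
100 ms target array, 500 ms ISI, and a flexible response window that rounds
each trial to an integer number of 1-s TRs, giving 4 or 5 TRs per trial.
Cue families are sampled independently per trial at the protocol's marginal
probabilities: 80% focal (equiprobable over four locations; 75% valid),
20% distributed; 10% blank bars. The mapping indicator spans the bar's 1 or
2 TRs; the target indicator is a single TR at the (floor-quantized) target
onset. `build_balanced_schedule` additionally provides exhaustive
condition × stimulus coverage for simulation studies, since the paper-style
random schedule only covers all 245 mapping regressors at session scale
(520+ trials); GLM columns with no events are reported as NaN.

Bar apertures: 3°-wide strips intersected with the 12.4°-radius circular
window, 24 positions per orientation (`floor(2·radius/step)`), centers 1°
apart and symmetric about zero (−11.5…+11.5°), so adjacent same-orientation
bars overlap by 2°. A pixel is lit iff its center falls inside both strip
and window (no anti-aliasing, bit-reproducible). Default grid 128×128;
geometric property tests use ≥512.

## What the generator emulates — and what it does not

The simulator reproduces the features the analyses are sensitive to:
pRF structure with size growing linearly with eccentricity (slopes
0.10–0.40 per map, intercept 0.5°, values typical of human retinotopy),
wedge-shaped additive modulation (difference-of-von-Mises profile, defaults
S = 0.2, B = −0.03, κ₁ = 6, κ₂ = 1 → peak ≈ +0.09 %BOLD, far trough ≈
−0.04 %BOLD), attention-field position shifts, equal-variance SDT behavior
(defaults d′ = 4.0 valid / 1.6 neutral / 0.5 invalid; shifted-lognormal RTs
with means 0.30/0.56/0.56 s), and fixational gaze with blink gaps. It does
**not** simulate cortical geometry, spatially correlated noise between
vertices, physiological noise spectra, HRF variability across vertices or
participants, or eye-movement dynamics beyond white jitter. Passing
recovery tests therefore demonstrate the correctness of the estimators
under the stated forward model, not robustness to every property of real
fMRI data.

## Numerical choices and problem sizes

- Noise is white Gaussian on the %BOLD scale plus per-scan polynomial drift;
  AR(1) structure is not modeled (no noise model is specified for the
  original data). The calibrated SNR for the pRF-recovery property is a
  white-noise SD of 10% of the peak beta, where the median center error is
  well under 0.25°; at substantially higher noise the error approaches the
  information limit of a 49-sample profile and grows roughly linearly.
- Constant (additive) offsets on the bar betas are only approximately
  absorbed by the pRF model, which has no offset term: centers move by
  ~0.1° for a +0.2 %BOLD offset at σ = 1.5. The blank-inclusion default
  mitigates this by charging offsets to the residual.
- Degenerate inputs: all-zero beta profiles return a flagged degenerate
  solution (NaN parameters), not an exception; empty ROIs warn; empty
  tuning bins are omitted and counted; failed logistic limbs and missing
  spread intercepts are flagged.
- Test and validation runs use desk-scale problem sizes chosen to keep the
  statistical targets meaningful: 64×64 aperture grids for fitting-heavy
  loops, 24–48 vertices per map, balanced schedules with 1–2 repeats
  (245–490 trials), 8 simulated participants with 1040–2080 trials each for
  behavior/latency group analyses, and 200–1000 bootstrap replicates.
- All randomness flows through seeded `numpy.random.default_rng` streams;
  pipeline outputs are stamped with the config hash and seed, and identical
  configs reproduce identical deterministic outputs.

## Known limitations

- The GLM's variance explained is in-sample (no cross-validation), and the
  participant-specific FIR HRF and data-driven noise regressors of the
  original denoising procedure are replaced by the canonical double-gamma
  HRF (a user-supplied sampled HRF is accepted) and per-scan polynomials.
- The %BOLD conversion divides by the temporal mean, which includes evoked
  activation; betas inherit a common sub-percent scale factor.
- The 10-sample event-triggered window clips the falling limb of slow
  responses; fall-latency estimates from target-evoked generators can fail
  (flagged) because the peak sits at the window edge.
- Repeated-measures ANOVA / mixed-effects inference over the summaries is
  out of scope; the bootstrap utilities provide the package's interval
  estimates.
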