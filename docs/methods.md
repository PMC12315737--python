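# Methods

## Signal model

A gradient-echo voxel's magnitude at echo time TE (ms) is modelled as

    S(TE) = S0 · exp(−TE / T2*)                         (monoexponential)
    S(TE) = sqrt( (S0 · exp(−TE / T2*))² + x0² )        (noise floor)

with S0 the signal at TE = 0, T2\* the effective transverse relaxation time
(ms), and x0 ≥ 0 a TE-independent floor.  The floor is the expected residual
magnitude of rectified complex noise: taking the magnitude of a
zero-mean complex Gaussian with per-channel SD σ yields a Rayleigh
distribution with mean σ·sqrt(π/2), so a voxel whose decaying component has
vanished still reads a positive value.  Where the true signal decays into
that floor — short-T2\* voxels near air–tissue boundaries at the later
echoes — a model without x0 sees an artificially flattened decay curve and
overestimates T2\*.  The noise-floor model absorbs the flattening into x0
and recovers a markedly less biased T2\* (the toolkit's tests measure the
two biases directly; neither is exactly zero because sqrt(ν² + x0²) is an
approximation to the exact Rician mean, good at moderate SNR).

Echo times and T2\* are milliseconds everywhere; nothing converts to
seconds implicitly.

## Estimators

* **Log-linear**: OLS of ln S against TE over all observations; T2\* =
  −1/slope, S0 = exp(intercept).  Exact on noiseless monoexponential data;
  used to initialise the nonlinear fits.  A slope at or above −1/500 ms⁻¹
  (i.e. an implied T2\* beyond the physiologic cap, including constant
  data) flags the voxel as non-decaying.
* **Monoexponential NLS**: bounded least squares of the first model,
  unweighted residuals.
* **Noise-floor fit**: bounded least squares of the second model with
  signal-weighted residuals r_i = (S_i / Σ_j S_j)(Ŝ_i − S_i), the weights
  and the normaliser taken over the voxel's full observation set — all
  echoes of all volumes (5 × 200 = 1000 observations per voxel in the
  default regime), or the per-echo temporal means in fast mode (5
  observations).  Weighting by the observed signal de-emphasises
  observations already down at the floor.

Numerical choices (genuinely open design points, decided here):

* Bounds: T2\* ∈ [1, 500] ms (physiologic range at 3 T plus headroom),
  S0 ∈ (0, 10·max signal], x0 ∈ [0, max signal].  A solution at the T2\*
  bound is reported but marked unconverged.
* Initialisation: (S0, T2\*) from the log-linear fit on the positive
  observations; x0 starts at half the minimum observed signal — the floor
  cannot exceed the smallest magnitude seen, and a mid-range start avoids
  the x0 = 0 boundary.
* Solver: scipy's trust-region-reflective bounded least squares with
  tolerances of 1e−12; the contract is the objective, bounds and
  initialisation, not the solver brand.  Forcing the x0 interval to zero
  width reproduces the weighted monoexponential fit exactly (model
  nesting), which the tests verify.
* Failed voxels (non-decaying or all-zero) keep finite fallback parameters
  — T2\* at the cap, S0 at the first-echo mean — and are recorded in
  `failed_mask`, so downstream weight maps are defined everywhere.

## Echo combination

Per-voxel weights W_TE = TE·exp(−TE/T2\*) / Σ_n TE_n·exp(−TE_n/T2\*).  The
unnormalised weight peaks at TE = T2\*, the echo time at which BOLD
contrast-to-noise is maximal, so short-T2\* voxels draw most of their
combined signal from the early echoes.  Weights come from a single
whole-scan fit and are constant over time; dynamic per-volume reweighting
(e.g. tracking respiratory T2\* fluctuation) is deliberately out of scope.
Failed voxels and voxels outside the fit mask receive equal weights
(1/n_echo) and are listed in `fallback_mask`.  The combined series keeps
the input's native units.

## Synthetic phantom

The generator emulates the data regime this pipeline targets, with every
true parameter recorded:

* Geometry: 24 × 24 × 12 voxels (2.4 mm), four disjoint tissue blocks in
  air.  Default tissue values are illustrative plausible 3 T magnitudes,
  not measured constants: "ofc" S0 800 / T2\* 18 ms and "piriform" 900 /
  30 ms (active, short-T2\* dropout zones), "cortex" 1000 / 45 ms (active),
  "white" 950 / 40 ms (inactive control).
* Timing: 200 volumes at TR 2.041 s, echoes at 10.60 / 22.92 / 35.24 /
  47.56 / 59.88 ms — the temporal structure of a five-echo multiband
  protocol with a short first echo.
* Task: a 24-trial, three-condition (lemon / benzaldehyde / control)
  slow event-related design, 2 s stimuli, ≈17 s mean spacing.  BOLD enters
  as a *fractional R2\** decrease, ΔR2\*(x,t) = R2\*₀(x) · bold_effect ·
  task(x,t), with task(x,t) the unit-peak HRF-convolved regressor of the
  region's driving conditions and bold_effect = 0.02 by default.  Injecting
  the effect in R2\* (not as additive signal) makes the percent signal
  change grow ≈ linearly with TE, the physical signature that separates
  BOLD from artifact.
* Respiration: a 0.3 Hz sinusoid plus Gaussian sniff bursts 0.5 s after
  each event onset, unit-normalised, applied as a multiplicative S0
  modulation (default 1 %).  Because it scales S0, its fractional effect is
  identical at every echo — the TE-independent signature of non-BOLD
  artifact — and because the bursts are event-locked it is confounded with
  the task, which is exactly the failure mode the analysis battery must
  handle.
* Noise: two independent Gaussian channels (σ = 5 by default) with the
  magnitude taken, so the thermal floor is physically realised rather than
  assumed; the expected floor is x0 = σ·sqrt(π/2), which the tests verify
  in the air region to 2 %.
* The canonical HRF is the standard double-gamma (peak ≈ 5 s, undershoot
  ≈ 15 s, ratio 1/6, 32 s support), unit peak; regressors are sampled at
  volume midpoints.
* Motion defaults to zero and, when enabled (random walk plus optional
  spikes), feeds only the nuisance-regression path — no image resampling
  is simulated.

What the phantom does *not* emulate: anatomy, B0 field structure and
geometric distortion, k-space/EPI readout effects, slice timing,
spatially correlated physiological noise, and true motion in image space.
Passing tests therefore demonstrate the estimators' correctness and the
direction and rough magnitude of the pipeline's benefits under the modelled
physics — not performance on real data.

## Statistical battery

* **Respiration regressor**: 250 ms moving average, zero-phase 2nd-order
  Butterworth high-pass at 0.05 Hz, linear detrend, standardise to mean
  0 / SD 1, then sampling at volume midpoints (one value per TR).
* **Sniff metrics**: per-trial volume = peak − trough amplitude within the
  cue window, duration = |t_peak − t_trough|.  They enter the design
  HRF-convolved with mean-centred amplitudes (centring keeps the modulators
  orthogonal to the main condition regressors).
* **Motion**: Power-convention framewise displacement (50 mm rotation
  radius); the 24-parameter expansion is the 6 realignment parameters,
  their squares, backward first differences (zero first element) and
  squared differences; spike columns are one-hot regressors for volumes
  where any raw parameter deviates > 6 SD from its run mean.  Constant
  nuisance columns (e.g. a motionless run) are dropped rather than left to
  collide with the intercept.
* **High-pass**: a discrete-cosine drift basis in the design (cutoff
  128 s, K = floor(2·N·TR/cutoff) components) rather than pre-filtering,
  keeping degrees-of-freedom bookkeeping explicit.
* **GLM**: first-pass OLS, then one global AR(1) coefficient pooled over
  all in-mask voxels.  The raw pooled lag-1 autocorrelation of OLS
  residuals is biased toward zero by the design projection (residuals are
  M·e with M the residual-forming matrix), so the estimate inverts the
  expectation map ρ ↦ tr(L·M·Ω(ρ)·M)/tr(M·Ω(ρ)·M) before prewhitening;
  data and design are then AR(1)-whitened and refit.  Contrast
  t-statistics map to Z through the exact t → normal quantile at the
  residual dof.
* **Variance comparison**: classic (mean-centred) Levene test per voxel on
  whitened residuals, one-sided by half-splitting the two-sided p with a
  direction check, signed Z from the normal quantile.  Because different
  acquisitions live in different native units, series are first scaled to
  percent change of their own temporal mean.
* **FDR**: Benjamini–Hochberg step-up (via statsmodels); NaN entries
  (outside-mask voxels) are ignored, never rejected.
* **Sample size**: smallest n ≥ 2 at which the exact noncentral-t power of
  the one-sample t-test (noncentrality d·√n) reaches the target; a direct
  scan, no approximation.  At α = 0.05 / power 0.80 this gives n = 90, 34,
  15, 10 for d = 0.3, 0.5, 0.8, 1.0, within one of the corrected normal
  approximation ((z_{1−α/2}+z_{power})/d)² + z²_{1−α/2}/2.
* **Smoothing**: separable spatial Gaussian, σ = FWHM/(2√(2 ln 2)) per
  axis, reflective boundaries, time axis untouched; default FWHM 8 mm.

## Problem sizes

Test and acceptance runs use the default phantom (24 × 24 × 12, 864 tissue
voxels, 200 volumes) with the fast per-echo-mean fit for map-level work,
single-voxel 200-volume problems for estimator studies (100 Monte-Carlo
replicates), 5–10 phantom replicates for the sensitivity comparisons, and
10⁴ replicate draws for calibration checks — sizes chosen so the full
battery runs comfortably on one CPU while keeping every Monte-Carlo margin
far from its threshold.

## Known limitations

* The noise-floor model is an SNR-moderate approximation to the exact
  Rician mean; a small residual T2\* bias remains at very low SNR.
* One global AR(1) coefficient (as in classic SPM-style analysis) ignores
  spatial heterogeneity of autocorrelation.
* Echo weights are time-invariant; respiratory-phase T2\* fluctuation is
  not modelled or corrected.
* The ICA-based multi-echo denoising family (TE-dependence component
  classification) is outside this package's scope; the phantom's
  TE-separation of BOLD and S0 artifacts provides the raw material for
  such methods but the classification itself is not implemented.
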