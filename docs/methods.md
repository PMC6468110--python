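# Methods

## Scope and data model

The package analyzes three kinds of data from a two-arm preclinical seizure
trial: chronic single-channel ECoG, per-animal seizure-count tables, and
whole-cell voltage-clamp step-protocol recordings. No raw study data are
bundled; the `synthetic` module generates statistically controlled stand-ins
for each, and every default in that module *is* the study condition the rest
of the package assumes.

Time is measured in seconds from recording start; intervals are half-open
`[onset, offset)`. Count tables are long-format with week −1 = the last
baseline ("Bl") week and week 0 = the first post-treatment week; day indices
share the origin (day 0 = first post-treatment day).

## Synthetic ECoG

Baseline activity is Gaussian white noise shaped to a 1/f power spectrum
(flat below 1 Hz), band-passed to the transmitter passband (0.3–160 Hz)
with a zero-phase 4th-order Butterworth filter, and scaled to
`baseline_sd` (default 50 µV). Seizures superimpose a rhythmic spike-wave
component: a 5 Hz fundamental plus two harmonics, exponentially sharpened
(`sign(x)·(e^{1.5|x|}−1)`) to give spike-like peaks, normalized to RMS
amplitude `seizure_amplitude_ratio × baseline_sd` (default ratio 10), with
5 s linear onset/offset ramps. Event durations default to uniform on
50–200 s, the range typical of the focal neocortical model this emulates.

This generator aims for *feature separability with controlled ground
truth*, not physiological realism: it contains no inter-ictal spikes,
movement/EMG artifacts, electrode drift, state-dependent background
(sleep/wake), or seizure evolution. Passing detector tests therefore show
the pipeline is correct and well-calibrated on signals whose ictal epochs
are separable in band-power/line-length space — they do not certify
performance on real recordings, where emission probabilities will be far
noisier (the HMM machinery is exercised under noisy emissions separately).

## Synthetic trial counts

Counts are drawn at day level and aggregated to weeks. Each animal-day has
rate λ_week/7, where λ_week is `baseline_rate` (default 10/week, the
regime the trial's own power calculation assumed) times the treatment rate
ratio (default 0.6, i.e. the 40% reduction the design targeted) for treated
post-treatment weeks, times `exp(week_trend · week)` for natural abatement
(default 0). Two overdispersion mechanisms are available:

* `dispersion` ≥ 0 multiplies each day's rate by a Gamma(1/d, d) variable
  (gamma-Poisson ⇒ negative binomial marginals);
* `cluster_intensity` c ≥ 0 replaces the Poisson draw with a Neyman–Scott
  burst process — cluster centres Poisson with rate λ/(1+c), cluster sizes
  1 + Geometric(mean c) — preserving the mean while raising the day-level
  Fano factor to 1 + 2c.

Both default to 0 so that the marginal weekly counts are exactly
Poisson(λ), the assumption under which the Lehr formula and the power
simulation are calibrated. Group labels are assigned by seeded
randomization.

## Detection chain

* **Epochs**: contiguous, non-overlapping, 5 s (2560 samples at 512 Hz);
  a trailing partial epoch is discarded. An epoch is labelled seizure when
  ≥ 50% of it overlaps a seizure annotation. Both rules are configurable
  defaults — the epoch length is the only part fixed by the workflow being
  modelled.
* **Features**: band powers (δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–70,
  high-γ 70–120 Hz) from Welch's method (1 s Hann segments, 50% overlap,
  mean removal, PSD integrated over the band); line length Σ|Δx|; variance,
  skewness, kurtosis, max-abs. Standardization (z-score) is fitted on the
  training epochs only and re-applied to held-out data.
* **Classifier**: random forest (200 trees, seeded), evaluated by
  stratified shuffled k-fold (default 5). Out-of-fold predictions — not
  training-set predictions — feed the emission estimate, so emissions
  reflect generalization error.
* **HMM**: states (baseline, seizure); observations are the discrete
  predicted labels. Transition matrix = row-normalized transition counts of
  the annotation sequence; emission matrix = row-normalized confusion
  counts P(predicted | true). A pseudocount of 1 on both keeps rows valid
  when a state or transition is absent. The initial distribution is the
  stationary distribution of the transition matrix. Smoothing uses the
  scaled forward–backward recursions; the scaling constants reproduce the
  exact sequence log-likelihood, and a zero-probability observation
  sequence raises rather than returning NaNs.
* **Events**: epochs with seizure posterior ≥ 0.5 form runs; runs separated
  by ≤ 1 sub-threshold epoch merge; merged runs shorter than 2 epochs
  (10 s) are dropped. Decoding thresholds the smoothed posterior rather
  than running Viterbi, since smoothing is the stated mechanism of the
  workflow being modelled. Event-wise evaluation counts a true seizure as
  detected when predictions cover ≥ 50% of it.

## Count statistics

* **Inclusion**: strict rule — animals with *fewer than* 5 seizures in
  week −1 are excluded; exactly 5 is retained.
* **Normalization**: weekly counts divided by the week −1 count
  (`last_week`, so week −1 maps to exactly 1) or by the mean over baseline
  weeks (`mean_of_baseline`); cumulative daily counts divide by the week −1
  total.
* **Burden**: per-animal sum of post-treatment weekly counts over the
  baseline reference; groups compared by Mann–Whitney U. The U test uses
  0.5 credit for ties and enumerates all C(m+n, n) labelings exactly when
  m + n ≤ 14 (correct under ties); larger samples use the normal
  approximation with tie and continuity corrections.
* **Fano factor**: sample variance (n−1 denominator) over mean of
  per-period counts, daily bins by default. This is the conventional
  variance/mean index (1 under Poisson, > 1 under clustering); the binning
  period is configurable because nothing in the modelled workflow fixes it.
* **Lehr sample size**: n = 4/(√λ₁ − √λ₂)² per group — Lehr's 16/d² rule
  of thumb for 80% power at two-sided α = 0.05 applied on the square-root
  scale, where a Poisson count has variance ≈ 1/4. The companion power
  simulation draws Poisson samples and applies the z-test on √counts with
  per-observation variance exactly 1/4; its closed-form normal
  approximation Φ(δ/SE − z_{α/2}) + Φ(−δ/SE − z_{α/2}) serves as the
  oracle (≈ 0.814 at 10 vs 6, n = 8).
* **Interaction test**: the animal-level OLS slope of
  log(normalized frequency + ε), ε = 0.5, over *all* weeks including the
  baseline anchor; the statistic is the treated−control difference in mean
  slope and the null permutes group labels across animals,
  p = (1 + #as-extreme)/(1 + reps). The baseline week is included
  deliberately: a treatment effect is a change *from baseline*, and without
  the anchor a constant post-treatment rate ratio would shift the level but
  not the slope, leaving the test blind to it. This is a design-free
  substitute for a log-linear mixed model's group × week interaction; the
  `tidy_model_frame` export feeds any external mixed-model routine for the
  parametric version.

## Voltage-clamp analysis

Steady-state current = mean over the last 40 ms of each 200 ms step;
current density subtracts the holding baseline and divides by capacitance.
Conductance divides by the K⁺ driving force V − E_K; steps within 5 mV of
the reversal are excluded from the division (never triggered by the default
protocol, whose closest step is −80 mV vs −91.34). The Boltzmann fit uses
`scipy.optimize.curve_fit` with A₁ = min G, A₂ = max G, V₀.₅ = voltage of
the point nearest mid-conductance, k = 10 mV as the start, k bounded
positive so the curve rises with depolarization; non-convergence returns a
flagged fit with diagnostics. Physical constants use textbook precision
(R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹; RT/F = 25.69 mV at 25 °C), the
convention of the electrophysiology literature. The Nernst temperature
defaults to 298.15 K, consistent with an E_K of −91.34 mV for 4/140 mM.

The Henderson liquid-junction estimate ships with a relative-mobility table
(K⁺ ≡ 1; Na⁺ 0.682, Cl⁻ 1.0388, Ca²⁺ 0.4048, Mg²⁺ 0.361, HEPES⁻ 0.30,
EGTA²⁻ 0.24). Chemistry assumptions: HEPES ≈ 50% anionic at pH 7.35, EGTA
entered as the divalent anion, and solutions taken at their written
composition without adding titrant ions — the convention of
junction-potential calculators. Sign convention: bath minus pipette as seen
at the open tip (the standard KCl pipette against physiological saline
gives ≈ +4 mV because Na⁺ lags K⁺). These chemistry choices dominate the
~1 mV uncertainty of any Henderson estimate.

## Numerical and testing choices

All generators draw from a single `numpy.random.Generator` seeded per call;
identical seed + config is bit-identical. Forward–backward is verified
against exhaustive enumeration over all 2^T hidden sequences for T ≤ 10
(tolerance 1e-10) and against an independent categorical-HMM
implementation on longer sequences. EDF round-trips are held to half a
16-bit quantization step of the declared physical range (the writer uses a
symmetric digital range, −32767…32767, so 0 µV is exact); the flat-binary
format is lossless. Simulation sizes in the test suite (e.g. 10,000
replicate trials for power, 500 trials for permutation type-I calibration,
200 replicate cells for fit recovery, a 100-minute benchmark pair of
recordings with 20 seizures each) were chosen as the smallest runs whose
Monte-Carlo error is well below the margins being asserted.

## Known limitations

* The ECoG generator's seizures are stationary spike-wave rhythms; real
  seizure morphology evolves, and detector performance on the benchmark is
  an upper bound.
* Observations enter the HMM as hard labels; a probability-binning variant
  of the emission model is not currently implemented.
* The Henderson estimate depends on the mobility table and ionization
  assumptions; treat it as accurate to ~1 mV.
* The permutation interaction test targets monotone-in-week divergence
  between groups; non-monotone interactions dilute its power.
* Parametric mixed-model, repeated-measures ANOVA, and Welch/Games–Howell
  analyses are intentionally out of scope; `tidy_model_frame` prepares
  their input.
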