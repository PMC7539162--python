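# Methods

This note documents the models, algorithms, defaults and design
choices behind `vnsdyn`, and what the synthetic-data experiments do and
do not demonstrate.

## Model class

Subject-specific, single-input single-output, discrete-time (1 Hz)
innovations-form state-space models

    x[k+1] = A x[k] + B u[k−τ] + K e[k]
    y[k]   = C x[k] + e[k]

- `u` — stimulus amplitude, a unit-amplitude trapezoid over the 120-s
  administration (a boxcar passed through the same causal 5-point
  moving average applied to the biomarkers; 5-sample ramps 0.2…1.0).
  Device amplitudes vary between subjects but are held fixed within an
  administration, so the input carries timing, not magnitude; the
  per-administration device amplitude is kept as metadata only.
- `y` — biomarker normalized to the day's rest, `(value − rest)/rest`,
  unitless.  Rest is the mean over a designated per-day rest segment
  (default: the first 120 s of the day's recording).
- `τ` — integer dead time in samples (= seconds), the latency between
  an input change and its first measurable effect.
- `D = 0` — no instantaneous feedthrough from stimulus to biomarker.
- Innovations `e` enter the state through the gain `K`; the one-step
  predictor is `x̂[k+1] = A x̂[k] + B u[k−τ] + K (y[k] − C x̂[k])`,
  started from `x̂ = 0` (records are rest-normalized, so zero is the
  shared equilibrium; the predictor state resets to zero at record
  boundaries in multi-record estimation).

Linearity is an explicit modeling assumption: the models are best
linear approximations of dynamics that are in general nonlinear.

## Estimation

1. **Subspace initialization** (PO-MOESP family).  Per training record
   the input is delayed by τ (zero head-padding — the stimulus is zero
   before onset, so the shift is exact), block-Hankel matrices with
   `2i` block rows (`i = max(M+3, 6)`, capped by record length) are
   built and concatenated column-wise across records.  An LQ
   factorization of `[U_f; U_p; Y_p; Y_f]` isolates the part of future
   outputs explained by past data with the future-input contribution
   removed; the SVD of that block gives the extended observability
   matrix, hence `A` (shift invariance) and `C` (first row).  `B` and
   per-record initial states follow by linear least squares on the
   simulated response (initial states discarded); `K` is initialized
   at zero.  Degenerate data (zero-variance input, singular-value gaps
   below 1e−10) raise an estimation error naming the offending record.
2. **Prediction-error minimization.**  The modal-form free parameters
   (real poles 1 slot, complex pairs 2 slots, plus `B`, `C`, `K`; at
   most `5M` slots, matching the parameter budget used for AICc) are
   refined by trust-region least squares on the concatenated one-step
   residuals.  Tolerances 1e−9, up to 400 iterations for final fits
   and 40 during grid scans (the scan only needs the AICc ranking; the
   winning configuration is re-polished at the full budget).  Pole
   magnitudes are projected inside the unit disk (radius 1 − 1e−6) at
   every evaluation; transiently unstable predictor iterates are
   reported as large finite residuals so the step is rejected.  If the
   optimizer fails or does not improve the objective, the
   initialization is returned with a warning.  After estimation the
   predictor matrix `A − KC` is stabilized by shrinking `K` if needed.
3. **Ridge regularization** re-solves the same objective with penalty
   `λ‖θ‖²` on the modal parameter vector.  `λ = 0` returns the model
   unchanged; `λ → ∞` shrinks predictions to the rest baseline.  The
   penalty is on `‖θ‖²` itself; a variant centered on a nominal θ*
   would be a one-line change but is not exposed.

The modal parameterization is over-complete (per-mode scale freedom
between `B` and `C`); the trust-region optimizer and the ridge penalty
handle the flat directions, and a small early-exit skips refinement
when the initialization is already at machine-precision fit
(noise-free fixtures).

## Hyperparameter selection and cross-validation

- **(M, τ) by AICc**, `AICc = N ln(SSE/N) + 2p + 2p(p+1)/(N−p−1)` with
  pooled one-step training SSE across records, `p = 5M` allocated
  modal parameters, scalar-innovation Gaussian form.  Used instead of
  plain AIC because `N/p < 40` for the larger candidate models.
  Exhaustive grid `M ∈ 1…10`, `τ ∈ 0…35 s` (the delay grid is a ~99 %
  interval around previously annotated tcVNS onset delays of 18 s,
  SD 7); ties break toward smaller M, then smaller τ; an exactly-zero
  SSE is clamped to a floor so the parameter penalty still ranks
  noise-free fits.  Orders whose `5M` budget exceeds the
  persistence-of-excitation order of the input (DFT bins above 1e−6 of
  the maximum; ≥ 50 for the 300-s trapezoid, usually ~240) are
  excluded.
- **λ by inner validation.**  Training MSE would always pick λ → 0, so
  λ is scored by leave-one-record-out validation inside the training
  set (fit on 2 records, score one-step MSE on the third), warm-started
  along the ascending λ path, with the winner refit on all records.
  Default grid: 20 log-spaced points on [1e−15, 1e4].
- **Outer leave-one-out CV.**  Each of the subject's 4 administrations
  is the unseen test record exactly once → 4 models, 4 selected
  `(M*, τ*, λ*)` triples and 4 held-out one-step fit percentages per
  subject-biomarker; per-subject quantities are fold averages.
  Shortened (truncated) records participate in both roles.

## Fit metric and baselines

`fit% = (1 − ‖y − ŷ‖/‖y − ȳ‖)·100` with both norms over the same
samples; equivalently `(1 − RMSE/σ)·100` with population normalization
on both sides, which makes the mean predictor score exactly 0 % —
the *mean test* is therefore a test of fit% > 0.  The *naive test*
compares against the previous-value predictor `ŷ_k = y_{k−1}` scored
from the second sample (about −41 % on white noise, close to 100 % on
slow series).  Both baseline tests are one-sided (model > baseline);
the biomarker fit/order comparisons are two-sided; no multiple-testing
correction is applied (reported as such).  Normality of paired
differences is gated by Shapiro–Wilk at α = .05 (paired t vs Wilcoxon
signed-rank); the three-way delay comparison gates sphericity with
Mauchly's test and uses one-way repeated-measures ANOVA with
`(2, 2(n−1))` degrees of freedom and partial η².

## Response curves

Two curve families on a common 250-s grid (10 s pre-onset, 120 s
stimulation, 120 s post), values in % of rest, stimulus support
exactly (10, 130) s:

- **experimental** — the prepared administration windows cut to the
  display grid, averaged per subject across administrations, then mean
  ± SEM across the group (missing tail samples of truncated records
  are excluded per time point; a single-subject group reports SEM 0
  with a flag);
- **simulated** — every cross-validated model solved forward from
  `x = 0` with innovations ignored, guaranteeing identical (zero)
  pre-stimulus behavior for active and sham, per-subject averaged over
  the 4 fold models, then mean ± SEM.  Zero initial state under zero
  input stays at zero, so simulated curves are exactly 0 before
  `10 s + τ`.

## Synthetic cohort: what it emulates, and what it does not

Ground-truth systems are diagonal-A responders: dominant pole
`exp(−1/T)` with time constant `T` drawn from 10–30 s, secondary poles
faster by factors of ~3, input vector scaled for an exact DC gain,
innovation gain a modest fraction (0.1) of the per-mode DC weights.
Cohort defaults (all flagged as stand-ins in `CohortConfig`; real
trials expose no per-subject ground truth): active heart-rate gain
−0.04 of rest and PPG-amplitude gain +0.5 of rest (±25 % inter-subject
jitter), sham gains exactly 0, dead times uniform on {10,…,25} s,
orders 1–2, innovation SD 0.01 (HR) / 0.05 (PPG) in normalized units,
rest HR 60–80 bpm, 4 administrations per subject (2 on day 1, 1 on
each of days 2–3, onsets spaced so 300-s windows never overlap),
per-day rest scale jitter 2 %.  Beat times integrate 60/HR evaluated
at the previous beat (optional jitter, off by default so analytic
fixtures are exact).  Raw waveforms use fixed morphological templates:
Gaussian-like QRS complexes (with small side lobes) at beat times and
an asymmetric fast-rise/slow-fall PPG pulse per beat scaled so the
within-beat max − min equals the requested amplitude; the pulse's
harmonic content is kept inside the 0.4–8 Hz PPG passband so amplitude
survives filtering.  All randomness funnels through one seeded
generator per call.

Not emulated: detailed ECG/PPG morphology, heart-rate variability
spectra, respiration, motion artifacts, arrhythmias, or nonlinear
response components.  Passing tests therefore demonstrate correctness
of the algorithms under the linear-plus-noise generating model, not
performance on real recordings.

## Numerical and signal-processing choices

- FIR filters: Hamming windowed-sinc, odd tap count from a 0.2 Hz
  transition at the low band edge, applied centered (group delay
  compensated) via FFT convolution; output length equals input length.
- R-peak detection: derivative → squaring → 150 ms moving-window
  integration, candidate peaks ≥ 250 ms apart, threshold at 0.4 of the
  median upper-half candidate height, refinement to the local ECG
  maximum within ±50 ms.  Adequate for clean and moderately noisy
  signals; not an arrhythmia-grade detector.
- Beat conventions: HR anchored at the later peak of each R-R pair,
  PPG amplitude anchored at the beat-start peak (causality of the
  later moving average); edge beats with incomplete windows are
  dropped.  The 0.4 Hz PPG highpass leaks adjacent-beat mean steps
  into the within-beat max − min when amplitude jumps ~20 % per beat
  (error up to ~5 %); under the cohort's own slow response dynamics
  (≤ ~5 %/beat) recovery is within 2 %.
- Resampling: linear interpolation onto the integer-second grid
  spanning the beat times, no extrapolation; windows half-open
  `[start, end)` with onset at sample index 60.
- Causal moving average: shrinking window at the head of the series
  (no fabricated zeros biasing early rest samples).

## Problem sizes used in the verification suite

The automated experiments are sized for a desk-scale run as a design
choice: recovery oracles use 20 random systems of order ≤ 3 on
300-sample records; dead-time recovery uses 20 seeded systems
(noise-free: exact in ≥ 18/20; moderate noise: set-level agreement —
mean and median offsets within 2 s, no significant paired difference —
since individual delay estimates at this signal-to-noise ratio scatter
by a few seconds, exactly as onset-delay estimates do in practice);
the end-to-end pipeline experiment runs a 6-subject cohort (3 active)
with reduced selection grids (M ∈ {1, 2}, τ in 5-s steps, 5 λ points).
Results at these sizes are qualitative twins of the full 24-subject
configuration, which the cohort generator produces by default.

## Known limitations

- Single-input single-output models only; outputs are modeled
  separately per biomarker.
- Integer (1 s) dead-time resolution; no continuous-delay estimation.
- The modal structure (real/complex pole layout) is fixed at the
  subspace initialization; a complex pair cannot split into two real
  poles during refinement.
- The trapezoidal stimulus is narrowband compared to ideal system-
  identification inputs; identifiability of fast secondary modes is
  correspondingly limited, and at low signal-to-noise the information
  criterion can trade a fast pole against a few seconds of dead time.
- `ss2tf`-based filtering of the predictor can lose precision for
  orders near the cap (M = 10) with clustered poles.
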