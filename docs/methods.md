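# Methods

## The task and the data model

Two mental conditions are decoded from single EEG trials: predicting a
400 ms interval (T400, label +1) versus a 600 ms interval (T600, label −1)
after a first flash at t = 0; a no-timing condition (NT, label 0) exists for
descriptive metrics only.  Epochs span −500..2500 ms at 200 Hz; sample *i*
lies at `t0_ms + 1000·i/srate`, and every analysis window is half-open
`[start, end)`, which makes window arithmetic exact (500–850 ms at 200 Hz is
exactly 70 samples, and adjacent windows tile without overlap).  Trials are
stored and exchanged as an `EpochSet` (trials × channels × samples,
microvolts) with an on-disk bundle of `metadata.json` + little-endian
float32 `data.bin` (a CSV payload is accepted on read).

## Preprocessing

All filters are 4th-order Butterworth applied forward–backward
(`sosfiltfilt`): zero net phase and an effectively flat passband protect ERP
morphology.  Epochs are short relative to delta-band impulse responses, so
signals are reflection-padded by at least 0.5 s before filtering.  A band
with a 0 Hz lower edge (delta "0–4 Hz", broadband "0–90 Hz") is implemented
as a pure low-pass; DC is later removed by baseline correction (per-trial,
per-channel mean over −100..0 ms).  Downsampling uses zero-phase FIR
anti-aliasing with integer decimation; non-integer ratios require an
explicit opt-in to polyphase resampling.  Whether band-pass filtering
happens before or after epoching is immaterial for ≥3 s epochs with
reflection padding; this package filters epochs.

## Classifiers

**DCPM.**  Class templates are per-class trial means.  The discriminative
spatial projection solves the generalized eigenproblem `Sw⁻¹SB u = λu`
where `SB = (X̂1−X̂2)(X̂1−X̂2)ᵀ` (equivalently `Σ11+Σ22−Σ12−Σ21` of the
template cross-products) and `Sw` is the sum of the two within-class
covariance matrices.  Numerical choices:

* `Sw` is ridged with `1e-6·tr(Sw)/Nc·I` before inversion — 18 channels
  with ≤40 trials can be ill-conditioned.
* Eigenvectors are unit-normalized with the largest-magnitude entry
  positive, a deterministic sign convention across linear-algebra backends.
* The retained dimension defaults to eigenvalues ≥ 1 % of the largest,
  capped at 10.  With two classes `SB` has rank 1, so the default keeps one
  filter; more can be requested explicitly.
* All three pattern-matching features use the reduced projection `Û`
  (a full-rank variant for the first feature is available behind a flag).

The canonical-correlation step is computed **per trial**, between the
DSP-projected template and the DSP-projected trial being classified.  It
uses only that trial and the fitted templates — no other test trials and no
labels — so there is no leakage; the fitted model therefore stores
templates, projection, and read-out, while `(Pk, Qk)` are derived
quantities.  CCA itself is an SVD of the whitened cross-covariance,
performed in the data space (economy SVD of each centered matrix) for
numerical stability; all available canonical pairs are used by default.

**CSP.**  Per-trial covariances are trace-normalized, so absolute amplitude
carries no information — only the *spatial pattern* of variance does.  The
composite ridge `1e-6·tr/Nc` is split half per class mean, which keeps the
whitening identity `P(R̄1+R̄2)Pᵀ = I` and the eigenvalue pairing
`λ1 + λ2 = 1` exact (to 1e-8) for the regularized estimates.  Whitening uses
`λ^(-1/2)Uᵀ` — the inverse square root; a strict mode with `λ^(-1)` exists
for auditing, but only the square-root choice satisfies the identities the
construction relies on.  Features are the normalized log variances of the
2+2 extreme filters; "var" is the population variance of the projected row.
The analysis window is all 140 samples in 100–800 ms at 200 Hz (a further
decimation is configurable but off by default).

**Fisher read-outs and fusion.**  Each route's feature vector is projected
by two-class FDA (`w ∝ Sw_pooled⁻¹(m₊−m₋)`, pooled scatter ridged by the
same rule, bias at the projected midpoint of the class means).  Read-out
training features are computed for the training trials against templates
built from the full training fold — no inner cross-fitting; slightly
optimistic but stable at ≤40 trials per class.  The fused label is
`sign(F1+F2)`; a decision value of exactly 0 resolves deterministically to
+1.  Predictions are invariant to a global positive rescaling of all data.

## Cross-validation harness

Stratified 10-fold with seeded shuffling; fold assignment depends only on
the labels and the seed, so comparisons across bands or methods are paired
on identical folds.  Every component — templates, DSP, CSP banks, both FDA
read-outs — is refit strictly on each training fold.  Band filtering and
baseline correction are per-trial, label-free operations and are applied
once before folding.  With unequal fold sizes the mean accuracy weights
folds by size.  The cohort table reports per-subject accuracies in percent
with Mean and Std summary rows.

## ERP metrics

SNR uses population (1/N) moments: `10·log10(mean² / (mean(A²) − mean²))`
over per-trial window amplitudes; it is invariant to positive rescaling.
The Fisher discriminative ratio (FDR — a separability index, not
false-discovery rate) uses population standard deviations for consistency
(`ddof` configurable).  Fractional-area latency integrates the *rectified*
waveform by default (robust for biphasic windows; signed-positive area is
an option) and interpolates the crossing linearly within a sample.  ERSP
uses Morlet wavelets (7 cycles by default), trial-averaged power divided by
mean baseline power per frequency, in dB — so baseline columns average 0 dB
by construction.

## The synthetic generator

`SimConfig` defines one synthetic subject; `simulate_cohort` derives
per-subject seeds from a base seed.  Per trial, the signal is
`gain_map ⊗ kernel + noise`:

* **Kernel:** flash-locked N1s at 160 ms after each flash (first at 0 ms,
  second at 900 ms — outside every classification window, as it must be);
  a CNV ramp from 200 ms (−6 µV/s, flattening at 1000 ms) common to all
  conditions; and a condition-specific positive deflection (half-cosine
  rise over 150 ms, amplitude 4.5 µV) starting at predicted moment +
  200 ms.  A zero deflection amplitude makes the class kernels identical —
  the null configuration.
* **Suppression:** band-limited 20–60 Hz noise (5 µV rms) multiplied by an
  envelope ramping from 1 to (1 − depth) over 100 ms, so depth *d* reads as
  `20·log10(1−d)` dB in the ERSP (−6.02 dB at the default d = 0.5).  Onset
  and depth are condition-dependent: T400 at 100 ms and full depth, T600 at
  220 ms and 0.7× depth, NT at 300 ms and 0.5× depth.
* **Background:** 1/f^1.7 pink noise (4 µV rms) plus white noise (1 µV rms),
  independent across channels.  The 1.7 spectral slope is EEG-typical and
  keeps the 20–60 Hz background small relative to the planted band noise,
  so the suppression depth is recoverable from the ERSP within ±1 dB.
* **Spatial structure:** a fixed gain map grading from the centro-parietal
  midline (1.0) to temporal sites (0.4) and far channels (0.25).  The
  gradient is essential for the power route: after trace normalization a
  spatially *uniform* power change is invisible to CSP.
* **Single-trial variability:** lognormal amplitude jitter (σ = 0.4),
  deflection-latency jitter (60 ms), suppression-onset jitter (40 ms), and
  optional lognormal between-subject effect-size jitter (σ = 0.25).
  These keep single-trial decodability in the 60–80 % range a real
  timing-prediction study reports, rather than at ceiling.

No µV amplitudes are published for these components, so the defaults above
are this package's own calibration: chosen so that the qualitative pattern
of the real study holds — DCPM informative in delta and uninformative in
mid-gamma, CSP the reverse, fusion above both — while nothing saturates.

What the generator does **not** model: volume-conduction correlation of the
background noise across channels, line noise, ocular/muscle artifacts,
button-press lateralization, non-stationary drifts, or any biophysical
forward model.  Passing tests therefore demonstrate the pipeline's
correctness and calibration on data with the assumed structure, not
performance on any particular real recording.

## Statistical checks

The null-calibration check pools 10-fold accuracy over 60 zero-effect
subjects and tests departure from 50 % with the empirical standard error
across subjects (two-sided t, α = 0.05).  Cross-validated decisions within
a subject are positively correlated, which inflates the sd of per-subject
accuracy to ~7–8.5 % against the 5.6 % a naive binomial would predict
(design effect ≈ 2); a binomial band on pooled decisions would therefore
reject a correctly calibrated pipeline far more often than its nominal 5 %.
Band-order effects (delta vs mid-gamma for DCPM; 20–60 Hz vs delta for CSP)
use an exact one-sided sign test across 20 paired simulated subjects at
α = 0.01.

## Known limitations

* DCPM's per-trial CCA makes prediction O(trials × CCA); fine at this scale,
  but a large-scale application would cache the template-side factorization.
* The FDA read-out is trained on in-fold features of the same trials that
  built the templates; with very small folds this optimism can inflate
  decision-value magnitudes (not fold-test accuracy, which is held out).
* The "80 points" sometimes quoted for a 100–800 ms window at 200 Hz is not
  reproducible (the window holds 140 samples); the full-resolution window is
  used and a decimation factor is left configurable.
* ERSP values within half a wavelet support of the epoch edges are
  attenuated; summaries here use interior windows.
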