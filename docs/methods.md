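# Methods

`beatae` detects atrial fibrillation (AFib) beat by beat from a
single-lead ECG.  This note describes the signal model, the processing
chain, the statistic and the learning machinery, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Problem and signal model

AFib changes a single-lead ECG in two ways: the ventricular response
becomes irregular (erratic RR-intervals) and the atrial signature
changes (P-waves are replaced by low-amplitude fibrillatory f-waves).
The package classifies individual heartbeats as normal sinus rhythm
(NSR) or AFib using the beat's waveform morphology, optionally
complemented by one local rhythm number per beat.

## Preprocessing chain

1. **High-pass filter.** A windowed-sinc FIR high-pass at 0.5 Hz removes
   baseline wander.  The filter is built as a delta minus a unit-DC-gain
   Hamming-windowed low-pass, so DC is rejected to machine precision;
   order is ≈3·fs (odd), giving >20 dB attenuation at 0.2 Hz and <0.1%
   ripple at 10 Hz.  It is applied centered (linear phase, group delay
   compensated), so R-peak locations are untouched.  The details
   (order, window, zero-phase application) are our choices; only the FIR
   family and the 0.5 Hz cut-off are fixed by the method.
2. **QRS detection.** An envelope-and-adaptive-threshold detector in the
   Hamilton family: 8–16 Hz band-pass, differentiation, rectification,
   80 ms moving average, then peak acceptance against running QRS/noise
   height estimates (factor 0.3125) with a 200 ms refractory period.
   Accepted envelope peaks are mapped to the R-peak by the local
   absolute maximum of the filtered signal.  Provided QRS annotations
   (AFDB-style records) are instead *refined* to the local absolute
   maximum within ±50 ms — the refinement rule is a design decision, as
   the published method states only that provided peaks were corrected.
3. **Segmentation.** One fixed-length template per R-peak: 200 ms before
   to 400 ms after, i.e. `pre = round(0.2·fs)` and `post = round(0.4·fs)`
   samples (round half away from zero; 50+100 at 250 Hz, 60+120 at
   300 Hz).  The template length is defined as `pre + post`, never
   `round(0.6·fs)`, so the R index is always exactly `pre`.  Beats whose
   window leaves the signal or crosses a rhythm boundary, and beats in
   `other`-labeled intervals (atrial flutter, AV-junctional, noisy), are
   dropped.
4. **Second-R-peak padding.** When the next RR-interval is shorter than
   the 400 ms post-window, the succeeding beat intrudes into the
   template.  Everything from `pre + rint((RR − 0.07 s)·fs)` to the end
   is zeroed, the 70 ms lead covering the intruder's Q-wave.  The start
   index uses round-half-even (`rint`); padding is idempotent, and a
   computed start before the R-peak clamps to `pre` with a warning.
   Only trailing intruders are padded; a leading intruder would mean
   RR < 200 ms, which the detector's refractory period excludes.
5. **Outlier rejection (DMEAN).** Per recording, the mean template is
   computed and beat *i* is discarded when its cosine distance
   `1 − xᵢ·m/(‖xᵢ‖‖m‖)` exceeds a threshold (default 0.2).  Zero-norm
   beats are always discarded.  At most 30% of a recording's beats may
   be removed; beyond that the lowest-distance beats are kept and a
   warning logged.  The multi-criterion variants of this rule found in
   the literature are deliberately reduced to the cosine-distance core.

## The LCSD rhythm statistic

For R-peaks at times R₁…R_N, the Local Change of Successive Differences
at interior beat *i* (1 < i < N) is

    LCSD(Rᵢ) = |(Rᵢ₊₁ − Rᵢ) − (Rᵢ − Rᵢ₋₁)| / mean-RR,

with mean-RR the average of all N−1 RR-intervals of the recording.  It
is non-negative, dimensionless, and invariant under uniform time
scaling.  Two scope decisions matter:

* the denominator uses the **full detected R series**, including beats
  later discarded as morphological outliers — the statistic is defined
  on the rhythm, not on the surviving templates;
* "the recording" is the whole record for short single-rhythm records;
  for long multi-rhythm records the labeled portion is the natural unit
  (portions are also the train/test unit), and both scopes are
  supported.

Boundary beats have no two adjacent RR-intervals; their LCSD is a
missing value (NaN), never 0.  The pipeline drops such beats for every
model cell — including morphology-only ones — so all cells of a model
comparison share an identical beat population.

## Models

All four archetypes are one dense feed-forward core (plain numpy,
float64, analytic backpropagation):

* **AE** — undercomplete autoencoder `[L, round(0.25·L), L]` (75%
  compression), tanh code, linear output, mean-squared reconstruction
  error.  Inputs are standardized, so a linear output layer is natural.
* **SAE** — the same trunk with an L1 activity penalty on the code,
  `λ·mean(|code|)`, default λ = 1e-4.
* **SupAE** — the SAE plus a classifier head at the bottleneck
  (code [+ LCSD] → 3 tanh units → 1 sigmoid), trained jointly on
  `w_rec·MSE + w_cls·BCE + λ·mean(|code|)` with default weights
  w_rec = w_cls = 1 (the published loss names are fixed; the weights are
  ours).
* **MLP** — the same head used stand-alone on encoded features, and a
  zero-hidden-layer variant (logistic regression) for the LCSD-only
  baseline.

"Three-layer" autoencoder is read as input–code–output with a symmetric
decoder; hidden activations, the head width, and the loss weights are
configuration, since the published appendix with exact layer tables is
not available.  The presets keep total trainable parameters in the low
hundreds, the regime the approach is designed for.  Initialization is
seeded uniform scaled by 1/√fan_in.

**Training protocol.**  Adam (lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8) on
shuffled batches of 32; at most 2000 epochs with early stopping after 50
epochs without a validation-loss decrease; the weights of the
best-validation epoch are kept.  Model instances are selected by k-fold
cross-validation (default 10): one run per fold, the held-out fold
serving both as the early-stopping validation set and for instance
selection (lowest validation loss) — the published protocol does not say
whether validation data came from the fold or a separate carve-out, and
the fold is the simpler choice.

## Evaluation protocol

* **Split.** 80/20 by signal portion (stratified by class; a synthetic
  or CinC-style record is one portion) or by patient.  Stratification of
  the portion split is our choice.  The test set is never balanced.
* **Balancing.** Training only: the majority class is undersampled to
  the minority count (seeded, without replacement).
* **Standardization.** Per-feature zero-mean/unit-sd learned on training
  rows (waveform samples and LCSD jointly); validation and test are
  transformed with the training statistics.  Constant features get sd 1.
* **Threshold.** The operating point maximizes Youden's J on the
  *validation* ROC (the published figures mark a "best threshold"
  without defining it); ties break toward 0.5, and candidates are
  midpoints between distinct scores, so separable scores give a
  threshold inside the gap.
* **Metrics.** Confusion counts at the threshold; accuracy, precision,
  recall, F1 (AFib positive); AUC by the trapezoidal rule over the full
  ROC with tied scores grouped, which makes it exactly the pairwise
  concordance probability with ties counted ½.
* **LCSD validation.** One Mann–Whitney U test per dataset between the
  per-beat NSR and AFib LCSD values (midrank ties, tie-corrected normal
  approximation with continuity correction, two-sided), plus a logistic
  baseline using LCSD alone.  U counts pairs (NSR > AFib) plus
  half-ties, so U = 0 means complete separation in the expected
  direction.  No multiple-testing correction is applied (one test per
  dataset).

Every pipeline run returns a manifest (the fully resolved configuration
with all seeds); re-running the manifest reproduces the evaluation
report bit-identically.

## Synthetic data

The generator emulates exactly the two cues the classifier is built to
separate.  Each beat is a sum of Gaussian kernels (P, Q, R, S, T) with
Lead-I-like default amplitudes/offsets/widths; NSR draws RR from
Normal(0.85 s, 0.02 s), AFib from Normal(0.65 s, 0.15 s) truncated to
[0.35, 1.4] s — overlapping rates, clearly different successive
differences — and AFib beats have P amplitude 0 plus a 6 Hz, 0.05 mV
f-wave sinusoid.  Sinusoidal baseline wander (0.25 Hz, below the
high-pass cut-off) and white noise complete the model.  A short-RR AFib
preset (truncation from 0.30 s) guarantees templates with intruding
second R-peaks.  Everything is generated in millivolts; export to WFDB
integer ADC units (default 200 counts/mV) is the only quantization.

An optional per-patient variation layer draws, once per patient, a
global amplitude scale (log-sd 0.25), a T-wave offset (sd 0.04 s) and an
independent P-amplitude scale (log-sd 0.6).  The last emulates
idiosyncratic atrial morphology: patients with small P-waves blur the
NSR/AFib morphology cue for models that never saw them.

**What the benchmark does not show.**  The generator has no respiratory
modulation, ectopy, pathological QRS morphologies, electrode artifacts
or multi-lead structure, and its class cues (P presence, f-wave, RR
dispersion) are cleaner than in clinical recordings.  Near-perfect
synthetic scores therefore demonstrate that the pipeline machinery is
correct and the features carry the intended information — not that
comparable performance transfers to PhysioNet data, where published
F1-scores for this model family are in the high 0.8s.  The
portion-versus-patient comparison deserves particular caution: with
per-beat cues that largely transfer across patients, the
patient-held-out penalty on synthetic data is small and seed-variable,
so it is assessed by majority vote over three paired seeds (same data,
both split modes) rather than as a fixed margin, and the benchmark gives
every patient two records per class so the portion split genuinely
represents the patient-specific setting.

## Problem sizes and numerics

Benchmarks in the test suite and the acceptance script run at desk
scale: the end-to-end benchmark uses 16 records per class of 60 s at
250 Hz (≈2500 beats, ≥1000 per class) with 10-fold cross-validation
capped at 150 epochs; the model-ordering comparisons use 8–24 records
per class with 3 folds and a 120-epoch cap.  The protocol defaults
(2000 epochs, patience 50) remain in `TrainConfig` for full-scale use.
All training is float64; probabilities are clipped at 1e-12 inside the
cross-entropy; the L1 code penalty uses the sign subgradient at 0.
Degenerate cases are explicit: single-class label sets yield threshold
0.5 with a warning, zero-denominator metrics report 0 with a flag, and
constant features standardize to 0.

## Known limitations

* The WFDB support is a minimal subset (text header, format-16 signal,
  MIT annotation format with SKIP/AUX words) sufficient for round-trips
  and AFDB/CinC2017-style layouts, not a general WFDB implementation.
* The Hamilton-family detector is tuned for clean-to-moderately-noisy
  single-lead signals; heavy artifacts will produce missed or spurious
  beats that only DMEAN partially absorbs.
* Exact published layer tables for the reference models are not
  recoverable; parameter counts match in order of magnitude (low
  hundreds), not exactly.
* `other`-rhythm classes are excluded, mirroring the binary task; no
  multi-class extension is provided.
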