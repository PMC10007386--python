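# beatae

Beat-by-beat atrial-fibrillation detection from single-lead ECG, using
autoencoder-extracted morphology features and a local rhythm statistic.

## The problem

Atrial fibrillation (AFib) shows on a single-lead ECG as an irregular
ventricular rhythm and, morphologically, as the replacement of P-waves
by low-amplitude fibrillatory waves.  Most automatic detectors rely on
rhythm features that need many beats of context; this package implements
a near-real-time alternative that classifies each heartbeat from its own
waveform.  It is aimed at people building or studying lightweight AFib
detectors (wearables, Holter post-processing) and at anyone who wants a
fully seeded, dependency-light reference implementation of the approach.

## The method

Each recording passes through a fixed chain: 0.5 Hz FIR high-pass
(zero-phase) → QRS detection (Hamilton-style adaptive threshold) →
fixed-length templates clipped 200 ms before / 400 ms after each R-peak
→ zero-padding of second R-peaks intruding into the 400 ms window
(from 70 ms before the intruder, covering its Q-wave) → cosine-distance
outlier rejection against the recording's mean beat (DMEAN).

Morphological features come from a sparse autoencoder
`[L, round(0.25·L), L]` with an L1 activity penalty on the code; a small
MLP classifies the code, either trained separately (AE→MLP) or jointly
with the reconstruction as a supervised autoencoder (SupAE), whose loss
is `MSE + BCE + λ·mean(|code|)`.

Rhythm information enters through one number per beat, the Local Change
of Successive Differences: for R-peaks at times R₁…R_N,

    LCSD(Rᵢ) = |(Rᵢ₊₁ − Rᵢ) − (Rᵢ − Rᵢ₋₁)| / mean-RR,   1 < i < N,

i.e. the absolute difference of the two adjacent RR-intervals divided by
the recording's mean RR-interval.

The evaluation protocol: 80/20 split by signal portion or by patient,
majority-class undersampling of the training set, training-set
standardization, 10-fold cross-validated training (Adam, batches of 32,
early stopping on validation loss), operating threshold by Youden's J on
the validation ROC, and confusion-count metrics plus trapezoidal AUC on
the untouched test set.

A seeded synthetic ECG generator (Gaussian P-Q-R-S-T kernels, truncated
normal RR models, f-waves, baseline wander, noise, optional per-patient
morphology offsets) makes the whole pipeline testable without downloads;
a minimal WFDB reader/writer ingests AFDB- and CinC2017-style records
when real data are available.

## Worked example

`examples/04_train_and_evaluate.py` trains the supervised autoencoder
with the LCSD feature on a synthetic dataset (8 records per class, 40 s
each, 250 Hz) and prints:

```
train beats (balanced): 528, test beats: 201
confusion: TP 113  FP 0  TN 88  FN 0
accuracy 1.000  precision 1.000  recall 1.000  F1 1.000  AUC 1.000
operating threshold (Youden on validation ROC): 0.379
LCSD Mann-Whitney p on the pooled beats: 5.99e-97
```

The 201 test beats come from held-out signal portions.  The perfect
score says the pipeline separates the synthetic classes (absent P-wave,
f-waves, irregular RR) — see `docs/methods.md` for why this does not
imply clinical-grade performance.  The tiny Mann–Whitney p-value
confirms the NSR and AFib LCSD distributions differ.  The other
examples cover generation and rhythm inspection (`01`), the
preprocessing chain (`02`), LCSD validation and the LCSD-only logistic
baseline (`03`), and the WFDB round-trip (`05`).

The same runs are available from the shell:

```
beatae train --config config.yaml --out results/
beatae report --results results/
```

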