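# Methods

This note documents the models, parameters and numerical choices behind
`neobp`: what the synthetic cohort emulates, how each pipeline stage is
defined, and what the tests do and do not demonstrate about real
clinical data.

## 1. The synthetic neonatal cohort

### Beat morphology and how pressure is encoded in shape

Each arterial beat is a piecewise template: half-sine systolic upstroke,
exponential diastolic decay toward an end-diastolic shelf, and a
Gaussian dicrotic bump on the descending limb. After construction the
beat is rescaled so its maximum is exactly the beat's SBP and its
minimum exactly its DBP; MAP is defined as the trapezoidal area of the
clean pressure over the closed beat span divided by the beat duration,
so an independent numerical integration reproduces it to rounding.

A calibration-free method can only work if waveform *shape* carries
pressure information, which is the physiological premise of pulse-
contour analysis. The simulator realizes that premise with two smooth
monotone maps chosen so their dynamic range comfortably exceeds the
post-averaging noise floor:

* relative dicrotic-bump height `h = clip(0.04 + 0.005·(SBP − 38), 0.02, 0.30)`;
* end-diastolic shelf `s_end = clip(0.04 + 0.005·(DBP − 15), 0.02, 0.40)`;
* systolic-peak fraction drifts mildly with DBP (sub-sample per mmHg at
  125 Hz — deliberately weak, so timing alone cannot carry the task).

Both informative features are amplitude *ratios* within the beat, so
they survive min–max normalization and any affine sensor transform.

### Trajectories, demographics, noise

* Heart rate: bounded random walk around a per-patient mean drawn from
  115–175 bpm, step 0.5 bpm/beat, plus i.i.d. beat-length jitter
  (σ = 2 samples) emulating normal beat-to-beat heart-rate variability.
  The jitter matters beyond realism: it is what makes the two-stream
  correlation peak unique (see §4).
* BP: per-patient baselines rise with weight
  (SBP ≈ 45 + 7·kg, DBP ≈ 22 + 5·kg, each with a few mmHg of
  between-patient scatter), matching the clinical observation that
  neonatal BP grows with size; within a recording both walk slowly
  (σ = 0.3 mmHg/beat, reflected at ±8 mmHg).
* Demographics: gestational age is sampled by stratum
  (EPT/MPT/FT ≈ 19/47/34 %, every stratum present for n ≥ 3), weight
  tracks gestational age inside 0.55–4.85 kg, ages 1–150 days, 60.5 %
  male.
* Sensor transform: per-channel affine gain (0.5–2.0) and arbitrary
  offset — the "unscaled" sensor — with an optional mild tanh
  saturation for robustness experiments (off by default).
* Noise (amplitudes relative to the channel's pulse amplitude, scaled
  by per-channel coupling 1.0/0.5/0.25/0.12 so best-channel selection
  is meaningful): band-limited baseline drift (≤ 0.05 Hz, 0.5),
  respiratory sinusoid at 0.6 Hz (0.10; same lagged phase as the
  arterial line's 1 mmHg respiratory swing — it is the same breath),
  white noise (0.05), optional HFOV sinusoid in 5–20 Hz, and
  Poisson motion bursts (0.5/min, 2 s, 4× amplitude, band-limited
  0.5–15 Hz plus a baseline jump) designed to defeat the quality gate
  rather than the bandpass. The arterial channel carries 0.3 mmHg
  transducer noise. Dropouts delete sensor samples outright so the
  local-lag refinement is exercised.
* Inter-stream lag: uniform in ±2 s per patient (convention: sensor
  sample *i* aligns with IAL sample *i + lag*).

### What the simulator does not emulate

Arterial-line damping/flush artifacts are reduced to generic noise; the
shape→pressure maps, though physiologically motivated, are far cleaner
than real inter-patient morphology variation; sensor saturation and
contact-pressure dependence are at most caricatured. Passing the
synthetic FDA gate therefore demonstrates that the *pipeline machinery*
(conditioning, gating, alignment, leakage-free learning, agreement
statistics) is correct and self-consistent — not that the accuracy
numbers transfer to clinical recordings.

## 2. Conditioning

Bandpass: order-2 Butterworth, 0.1–20 Hz, applied forward–backward
(`sosfiltfilt`), so the magnitude response is the squared analytic
response and the phase is zero — beat landmarks are not shifted between
streams, which alignment depends on. Tests verify passband gains at
0.5/2/5 Hz against the analytic response within 1 %.

HFOV detection: Welch periodogram (16 s segments); the cardiac
fundamental (strongest line in 1.2–5 Hz) and its harmonic comb are
masked; a detection requires a narrowband peak in 5–20 Hz that (a)
concentrates ≥ 40 % of its 1 Hz-neighbourhood power in ±1 bin, and (b)
either exceeds 3× the masked band's median (off-harmonic) or exceeds
the cardiac fundamental itself (on-harmonic). The pipeline notches only
when at least two channels agree, since ventilator interference reaches
every channel. The notch is a zero-phase IIR notch (Q = 10), applied to
both streams so their in-band content stays comparable.

SNR: beat-synchronous definition — beats resampled to a common length,
ensemble mean = signal, per-beat residual = noise, SNR = power ratio.
Chosen because only the threshold (> 5, strict) is specified by
convention; the definition is stated here because the number is
meaningless without it.

Normalization: per-window min–max to [0, 1]. This removes affine gain
and offset exactly, which *is* the calibration-free property. The
output is quantized to a 1e-6 grid: pushing an affine transform through
floating-point filtering perturbs normalized values at the ~1e-12
level, and quantization collapses those perturbations so downstream
predictions are bit-identical under sensor recalibration. The grid is
six orders below any physiological waveform feature.

## 3. Quality grading and exclusion

The clinical quality score is produced by a CNN trained on thousands of
human-graded waveform pairs that do not exist outside the original
device program. The default grader here is a deterministic rule-based
surrogate on the same 0–5 scale, combining (weights 0.5/0.25/0.25):

* noise score `exp(−3·NSR)` where NSR is the beat-ensemble
  residual-to-template power ratio;
* secondary-peak resolution: curvature prominence of the dicrotic bump
  on the smoothed ensemble beat, multiplied by the noise score so
  spurious bumps in noise earn no credit;
* beat regularity `clip(1 − 5·CV(IBI), 0, 1)`, damped by the noise
  score for the same reason.

The damping terms are what make the score decrease monotonically along
a noise ladder instead of fluctuating once the signal is gone. When a
synchronized arterial window exists, `r` is the Pearson coefficient of
the two normalized windows.

Exclusion gates (first failure reported): q > 2.5 (from the evaluation
gate used with the quality scale), r ≥ 0.8 (no published value; exposed
in config and documented as unpinned), SNR > 5 strict, SBP/MAP/DBP
within (0, 200/175/150] mmHg. Windows with fewer than 5 complete
arterial beats are dropped before gating (the SNR definition needs an
ensemble).

## 4. Synchronization

Global lag: normalized cross-correlation of randomly sampled **30 s**
sensor windows against the arterial stream over ±10 s, median vote.
Thirty seconds, not the 4 s analysis length: a pulse train is nearly
periodic, so a 4 s window correlates almost as well at ±1 beat offset;
over 30 s the accumulated beat-length jitter decorrelates the
whole-beat offsets and leaves a unique peak. Votes require a
correlation peak ≥ 0.2, window quality above a light gate (0.1 — a
window clipped by a motion burst still votes the correct lag), and
two-stream heart-rate agreement within 5 bpm (no tolerance is published
for the "correlating heart rates" idea; 5 bpm rejects whole-beat
mis-locks at neonatal rates). Fewer than 3 usable votes is a sync
failure.

Local lag: per window, argmax of normalized cross-correlation within
global ± 2 s; peaks below 0.5 mark the window unalignable. Dropouts
shift the local lag by exactly the deleted length, which the tests
verify.

Pairing: each window is aligned to its first detected beat onset
(deterministic phase), normalized, locally re-synchronized, graded
against its arterial reference, and gated. Ground truth per window is
the mean of per-beat SBP/DBP/MAP over complete arterial beats in the
aligned span (per-window mean chosen over per-beat labels; beat
boundaries come from the filtered stream, values from the unfiltered
stream — the bandpass removes DC and would destroy absolute pressure).
Up to 5000 windows per patient (seeded subsample beyond that); patients
with fewer than 10 usable windows are excluded.

## 5. The regression model

Input features: the window's time-normalized ensemble-average beat
(each detected beat resampled to a 128-point phase axis, averaged,
re-normalized), the mean beat period in seconds, and the two
covariates (age days, weight kg; min–max scaled with training-fold
statistics only). The ensemble-beat canonicalization puts the
pressure-informative landmarks at stable positions regardless of heart
rate — a fully connected network is not translation-invariant, and
phase-aligning the input is the cheap, deterministic alternative to a
convolutional front end. Rate information is preserved explicitly by
the period feature.

Regressor: scikit-learn `MLPRegressor`, hidden layers (64, 32), ReLU,
Adam, 150 iterations, fixed seed; three outputs trained jointly under
squared error. Predictions are projected onto the physiological
ordering DBP ≤ MAP ≤ SBP by sorting the triplet. The architecture slot
is generic — any fit/predict regressor with the same featurization
drops in (a gradient-boosted baseline is exercised in exploration; the
MLP is the default).

Cross-validation: seeded uniform partition of *patients* into k = 10
folds (sizes differing by ≤ 1); each fold's model trains on the other
nine; reports pool held-out predictions only. A programmatic assertion
inside the training loop guarantees no patient appears on both sides
of a fold.

Model ranking follows the clinical selection rule: worst-component
|bias|, then worst-component SD, then slope distance from 1, then
correlation, compared lexicographically with a 0.05 tolerance per key.

## 6. Agreement analysis

"MAE" throughout is the **signed** mean difference (bias), not mean
absolute error — the reported clinical tables (e.g. a bias of −0.1)
force this reading. The FDA gate is |MAE| ≤ 5 mmHg and SD ≤ 8 mmHg,
inclusive at the boundary (a device reported at exactly 7.9/8.0 passes
the guideline as printed).

Two aggregation modes: *pooled* (every window one observation) and
*per-individual* (differences averaged within patient first, then
bias/SD across patient means — each patient weighted equally regardless
of recording length). With equal per-patient counts and equal
per-patient means the two coincide, which is tested.

Regression fits: unconstrained OLS of predicted on true, zero-intercept
least squares (slope = Σxy/Σx²), and the identity line, each with its
RMS residual.

Tukey–Kramer: all-pairs comparison via the studentized-range
distribution with the Kramer unequal-n standard error
√(MSW/2·(1/nᵢ+1/nⱼ)); with equal n this reduces to Tukey's HSD, which
an independent implementation (statsmodels) cross-checks in the tests.
The compact letter display assigns one letter per maximal clique of the
non-significance graph (Bron–Kerbosch), which makes the display
property structural: two groups share a letter **iff** they are not
significantly different.

## 7. Problem sizes and determinism

The headline experiment uses 24 patients with 10-minute paired
recordings (≈ 14,000 usable windows), individual-grouped 10-fold CV —
large enough that per-individual agreement statistics are stable across
seeds, small enough to re-run routinely; the parameter-recovery
experiment uses 10 noiseless patients. All stochastic stages (cohort
draw, fold assignment, network initialization, subsampling, sync window
sampling) are seeded; identical configurations reproduce identical
manifest counts bit-for-bit and identical reports up to BLAS summation
order.

## 8. Known limitations

* The surrogate quality grader matches the *role*, not the scores, of
  the clinical grader; no inter-rater comparison is possible.
* The r ≥ 0.8 exclusion threshold is a documented guess (no published
  value).
* Streams share one sample clock; clock-drift (rate mismatch)
  correction is out of scope.
* Whether grading should use filtered or raw waveforms is not
  specified anywhere authoritative; graded on filtered by default,
  configurable.
* The synthetic cohort's between-patient shape variation is modest; a
  model trained here will not transfer to real sensors.
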