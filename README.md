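# neobp — calibration-free blood pressure from neonatal pulse waveforms

Continuous blood-pressure monitoring in critically ill neonates today
means an invasive arterial line (IAL) — accurate, but a catheter in a
patient who may weigh 600 g. `neobp` implements a complete,
calibration-free pipeline that estimates systolic, diastolic and mean
arterial pressure (SBP/DBP/MAP) from the *shape* of pulse waveforms
recorded by an unscaled skin sensor, plus two demographic covariates
(age and weight), and validates the estimates the way blood-pressure
devices are validated: Bland–Altman agreement against the arterial
line, an FDA-style accuracy gate, and Tukey–Kramer subgroup comparison.

Because clinical IAL/sensor recordings are restricted, the package
ships a first-class **synthetic neonatal hemodynamics simulator** that
generates paired recordings with exact per-beat ground truth and the
full noise structure the pipeline must survive: baseline drift,
respiratory modulation, broadband noise, high-frequency-oscillatory-
ventilation (HFOV) interference, motion-artifact bursts, inter-stream
lag and sensor dropouts. Every stage is therefore testable end to end
with no data download.

## The method

For each 4 s analysis window (1 s hop, matching a ~1 Hz display
update):

1. **Condition** — order-2 Butterworth bandpass, 0.1–20 Hz, applied
   forward–backward (zero phase); if a narrowband ventilation line is
   detected in 5–20 Hz on multiple channels, a notch at the detected
   frequency removes it.
2. **Select & grade** — the best of the 4 sensor channels is chosen by
   a 0–5 quality score built from beat-ensemble residual power,
   dicrotic-peak resolvability and beat regularity. Windows are
   excluded unless q > 2.5, sensor-vs-IAL correlation r ≥ 0.8, arterial
   SNR > 5, and SBP/MAP/DBP within (0, 200/175/150] mmHg.
3. **Synchronize** — a global sensor→IAL lag (median of per-window
   cross-correlation votes, heart-rate-agreement checked), then local
   per-window refinement that absorbs dropouts.
4. **Pair** — each surviving window is min–max normalized to [0, 1]
   (this removes the sensor's unknown gain and offset *exactly* —
   the calibration-free property) and paired with ground truth
   extracted from the aligned arterial span: SBP from peaks, DBP from
   valleys, MAP from the beat area over duration. Up to 5000 windows
   per patient.
5. **Learn** — a compact neural-network regressor maps the window's
   time-normalized ensemble beat + beat period + age + weight to
   (SBP, DBP, MAP). Evaluation is individual-grouped 10-fold
   cross-validation: folds partition patients, so every reported
   number describes patients the model never saw.
6. **Validate** — signed mean difference ("MAE", i.e. bias) and SD of
   differences, per individual and pooled, against the device gate
   |MAE| ≤ 5 mmHg and SD ≤ 8 mmHg; regression fits (unconstrained,
   zero-intercept, identity); Tukey–Kramer compact-letter subgroup
   comparison for unequal group sizes.

## Worked example

```bash
python examples/train_and_evaluate.py
```

simulates 12 patients (4-minute recordings), trains with 6-fold
grouped CV and prints:

```
patients 12, candidate windows 2844, paired 2585, held-out predictions 2585

per-individual-averaged agreement (each patient weighted equally):
  SBP: bias -0.86 mmHg, SD  4.64 mmHg, limits of agreement [-10.2, +8.4]
  DBP: bias +0.14 mmHg, SD  3.67 mmHg, limits of agreement [-7.2, +7.5]
  MAP: bias -0.48 mmHg, SD  3.37 mmHg, limits of agreement [-7.2, +6.3]

FDA accuracy gate (|bias| <= 5 and SD <= 8 mmHg): {'sbp': True, 'dbp': True, 'map': True}
```

Bias is the average signed error across held-out patients (close to
zero: no systematic over/under-reading); SD measures how much the
per-patient mean error varies, the quantity the 8 mmHg precision bound
constrains. Other example scripts demonstrate the simulator
(`simulate_cohort.py`), conditioning and quality grading
(`signal_quality.py`), synchronization (`synchronize_and_pair.py`) and
the subgroup letter display (`subgroup_analysis.py`). A thin CLI wraps
the same pipeline: `neobp run-all --seed 42 --out runs/demo`.

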