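# Methods

This note documents the models behind pactkit, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests
do and do not demonstrate about real recordings.

## The behavior model

`simulate_behavior` draws one day of latent smoker behavior from a seeded
generator. All randomness flows from `SimConfig.seed` through a single
`numpy` generator (renders use substreams keyed by `(seed, sensor_index)`),
so every output is bit-reproducible.

- **Cigarettes.** The number of smoking sessions is Poisson with mean
  `cigarettes_per_day × duration/86400` (default 11/day, the mean
  self-reported consumption of the study population this scenario
  emulates). Sessions are placed uniformly with enough margin that a
  5-min pre-smoking and 15-min post-smoking window never collides with a
  neighboring session. Each session lasts `cigarette_duration_s`
  (default 300 s) and contains 8–12 puffs (uniform), each a
  1.5–3 s inhalation with the wrist transmitter 5–11 cm from the chest
  receiver — inside the ~11 cm maximum hand-to-mouth distance observed
  for regular smoking gestures.
- **Breathing.** An inhomogeneous renewal process whose rate performs a
  clipped random walk inside 12–20 breaths/min; tidal depths are uniform
  0.4–0.8 of the maximum. A puff replaces the tidal breath that would
  fall inside it by a deep (depth 1.0), longer smoke inhalation at the
  puff time. Breath peaks are kept ≥ 2 s inside the recording ends so no
  bump is truncated into undetectability at the edges.
- **Heart rate.** Piecewise-linear profile: baseline 81.54 bpm, ramping
  to 112.03 bpm within 60 s of lighting, holding for the session, and
  relaxing back to baseline 840 s (14 min) after the session ends —
  i.e., recovered within 15 min of smoking. The two levels are the
  pre-smoking and sitting–smoking means of the emulated study
  population.
- **Steps, route, postures.** Walking bouts of 5–10 min cover
  ~12% of the day at 105 steps/min and 1.4 m/s along random bearings;
  step counts are stored per 13.63-s pedometer buffer window (the time
  the processor's buffer takes to fill). Sitting segments are treated as
  indoors for the GPS model.
- **Spurious lighter presses** are Poisson at 0.5/day outside smoking
  sessions, near the false-lighting rate per subject-day reported for
  free-living wear of such lighters.

## Forward sensor models

- **RIP belt.** Chest circumference is the baseline (default 85.63 cm,
  the emulated population's mean chest size) plus raised-cosine breath
  bumps of `breath_amplitude_cm` (default 1.5 cm; bump width
  2.5 s + 1.5 s × depth). Inductance at a given circumference is a
  monotone piecewise-linear interpolation through the four bench
  calibration points (counts measured at 60/80/100/120 cm, inverted
  through `L = 1/((2πf0)²C)` with C = 110 pF). A least-squares affine
  law was considered and rejected: the four implied inductances (2.197,
  2.488, 2.665, 2.901 µH) have enough curvature that the affine fit
  misreproduces the calibration counts by up to 0.8%, while
  interpolation is exact at the calibration points and stays inside the
  2–3 µH band; the affine fit remains available
  (`RipParams.fit_affine_inductance`) for linearity analyses. The
  renderer reports `floor(f0 × 0.01)` counts per window plus the
  idle-noise draw and refuses to run if the implied `f0` reaches the
  16 MHz sampling cap (half the 32 MHz system clock).
- **Bioimpedance** shares the breath bump train (expansion raises
  impedance, so peaks align with breath peaks); the mV scale is
  arbitrary (5 mV default). Its bench idle noise is 0 mV and the default
  honors that.
- **ECG** integrates the heart-rate profile into R-times
  (`t_{k+1} = t_k + 60/hr(t_k)`; strictly regular R–R when the profile
  is constant) and renders a Gaussian QRS (σ = 8 ms, 1 mV) plus 60 Hz
  interference (0.05 mV), slow baseline wander, and idle noise. Only
  R-peak timing is consumed downstream, so no P/T waves are modeled.
- **RF proximity** uses an exponential amplitude–distance law
  `2800·exp(−d/3.5 cm)` mV: ~2.8 V near contact (the receiver's full
  range), ≥ 121 mV at 11 cm (comfortably above the 70 mV threshold),
  and under the noise floor beyond ~20 cm. The bench curve is published
  only graphically; the calibration points above are this package's
  stand-in, and the law is exposed for recalibration.
- **Hand IMU / chest accelerometer** add half-cosine gesture bumps
  (1.5 g, 90 dps) around each puff over the bench bias-and-noise floor,
  clipping at ±8 g / 2000 dps (hand) and ±2 g (chest). Chest walking
  bounce is a 1.75 Hz sinusoid during walking bouts.
- **GPS** displaces each true route point by a draw of magnitude
  N(15.11 m, 2.639 m) at a uniform bearing; indoor intervals hold the
  last outdoor fix, mimicking a receiver that keeps logging its last
  coordinates when satellites are lost.
- **Clock drift** re-expresses any stream or log on a drifting device
  clock via `t = t0 + f(t_true − t0)`; it is the exact inverse of the
  linear compensation, which the tests verify to 1e-9 s.

## Detector parameters

| parameter | default | rationale |
|---|---|---|
| proximity threshold | 70 mV | ten times the ~7 mV mean receiver noise |
| proximity merge gap | 0.5 s | re-joins split excursions within one gesture |
| min breath interval | 1.0 s | caps breathing at 60/min |
| breath prominence floor | 20% of signal IQR | the zero-phase 0.1 Hz high-pass leaves rebound bumps of ~10% IQR between widely spaced breaths; true breaths exceed 100% IQR, so 20% rejects the artifact with an order-of-magnitude margin |
| min R–R interval | 0.3 s | caps heart rate at 200 bpm |
| R-peak prominence | 40% of the 99.9th amplitude percentile | robust to the sparse-spike amplitude distribution of ECG |
| lighter merge window | 60 s before session start | strikes precede lighting |
| flat-line window / floor | 60 s; 3× idle sd (RIP), 1e-3 mV (bioimpedance) | bioimpedance idle noise is 0 mV, so a small absolute floor replaces the 3× rule there |

Instantaneous heart rate is 60/RR assigned to the RR midpoint — the
window-length-independent reading of "R-peaks per minute"; summaries are
mean ± sd over the session, the 5 min before lighting and the 15 min
after the session end, and a window with fewer than two peaks raises
rather than returning a silent zero.

## Numerical choices

- All IIR filtering is zero-phase (forward–backward) in
  second-order-sections form, so detected event times can be compared
  across sensors without phase bias. The 0.001 Hz high-pass on 1 kHz
  data is the fragile case; the SOS realization is checked for finite
  coefficients and finite output at run time.
- "Average Gaussian filter of N points" is convolution with an N-tap
  normalized Gaussian kernel, σ = N/6 (kernel effectively supported on
  its taps); N = 1 is the identity.
- The notch quality factor is Q = 30 — narrow enough to leave QRS energy
  intact (verified by detector agreement on contaminated vs clean ECG).
- Printed-table frequency conversions truncate (not round) to two
  decimals, matching the published convention (9.619976 MHz prints as
  9.61); the same truncation reproduces the printed 1.78% respiration
  disagreement from the raw 1.7878%.
- The breath-variation statistic uses the inductance-belt total as the
  denominator (the reference sensor).
- Cross-correlation normalizes each lag by the overlapping segments'
  norms (so a shifted copy of a sinusoid scores 1.0) and restricts lags
  to half the shorter series, where tiny overlaps would make the
  coefficient degenerate; a zero-lag Pearson variant is available.
- Great-circle distances use the haversine formula on a sphere of
  radius 6371 km.
- `linearity_r2` returns 0.0 for a flat response (zero total sum of
  squares): a horizontal line explains no variance.

## Problem sizes in the test suite

The full-day recovery tests simulate one seeded 24-h subject and run the
complete chain on the 100-Hz streams (~8.6 M samples); the ECG chain runs
at its native 1 kHz over the window around one smoking session (5 min
before to 15 min after), which contains every quantity the heart-rate
summary needs while keeping the suite's footprint proportionate.
Bioimpedance cross-checks run at reduced rates (100–250 Hz) where only
peak counts matter; the numerically fragile 0.001 Hz high-pass is always
exercised at the native 1 kHz.

## What passing tests do and do not show

The generator produces idealized, piecewise-stationary signals: breath
bumps are smooth and unimodal, QRS complexes are clean Gaussians, motion
artifacts are absent, and the proximity excursions of distinct puffs
never overlap. Perfect recovery on noise-free renders and ~0.1% error at
bench noise levels therefore validate the *plumbing* — calibration,
synchronization, zero-phase conditioning, thresholds, bookkeeping — not
detector robustness to real motion artifacts, electrode pops, belt slip
or gesture confounders (eating, phone use), which real free-living data
contain and this generator deliberately does not. The hand-to-mouth IMU
gesture counter in particular is a documented threshold placeholder
behind a pluggable interface, not a trained classifier; its recovery of
puff counts on clean renders says nothing about IMU-based smoking
detection in the wild.

## Known limitations

- Single linear clock model per device; no temperature-dependent or
  piecewise drift.
- The proximity amplitude–distance calibration and the smoke-inhalation
  waveform shape are stand-ins exposed through configuration, not fits
  to published curves.
- Usability screening relies on respiration flat-lining alone; it will
  not flag a dislodged-but-jittering belt.
- The summary's cigarette estimate groups presses per self-reported
  session, so it cannot exceed the session count; studies where subjects
  merge several cigarettes into one report need the raw press count,
  which the consolidation result preserves.
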