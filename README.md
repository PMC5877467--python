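# pactkit

A tested Python pipeline for multi-sensor wearable monitoring of cigarette
smoking. It covers the full data path of a three-device sensor suite — an
instrumented lighter, a wrist module (6-axis IMU, pedometer, RF
transmitter) and a chest module (respiratory inductance belt, bioimpedance
and ECG front end, accelerometer, RF receiver, GPS) — from raw device logs
to the behavioral and physiological event counts a smoking-topography
study reports: lighting events, cigarettes, hand-to-mouth gestures, smoke
inhalations/breaths, and heart-rate changes around smoking sessions.

Because no raw recordings of such suites are publicly deposited, the
package ships a first-class synthetic-data generator: a latent
smoker-behavior timeline (breaths, cigarettes with individual puffs,
steps, a heart-rate profile, a walking route) rendered through a physical
forward model of every sensor, with bench-characterized noise levels and
per-device clock drift. Every detector in the pipeline is validated
against this generator's ground truth.

## The models at the core

**Respiration belt (RIP).** The belt is the inductor of an LC oscillator:
`f0 = 1 / (2π√(LC))` with C = 110 pF (two 220 pF capacitors in series)
and L ≈ 2–3 µH varying with chest circumference. The microcontroller
counts oscillator pulses per 10 ms window (100 Hz), so inhalation (chest
expansion → larger L → lower `f0`) lowers the count. The
inductance-versus-circumference curve interpolates four bench calibration
points measured at 60–120 cm simulated chest sizes.

**Clock synchronization.** Each device clock drifts up to several seconds
per day. With `t0` the reference time at initialization and
`f = (t_device − t0)/(t_pc − t0)` fitted from one paired read-out at data
extraction, raw timestamps are corrected by the linear compensation
`t_c = (t − t0)/f + t0`.

**Conditioning.** Zero-phase per-sensor chains: first-order Butterworth
high-pass at 0.1 Hz (RIP), 0.001 Hz (bioimpedance) and 1 Hz (ECG);
Gaussian smoothers of 10 / 100 / 50 points (RIP / bioimpedance /
proximity); a 60 Hz notch (ECG); second-order 2 Hz low-pass (IMU).

**Event extraction.** Breaths and R-waves are prominent local maxima;
instantaneous heart rate is 60/RR at each RR midpoint; hand-to-mouth
proximity events are excursions of the RF receiver voltage above 70 mV
(ten times the mean noise amplitude); lighter presses are consolidated
into cigarettes against self-reported smoking sessions, with presses
outside every session reported as false lighting events; flat-line
screening labels recording segments usable / removed / ambiguous before
any counting.

## Worked example

```python
import pactkit as pk

cfg = pk.SimConfig(seed=42, duration_s=3600.0)
tl = pk.simulate_behavior(cfg)
print(f"simulated hour: {len(tl.cigarettes)} cigarettes, {tl.n_puffs} puffs, "
      f"{len(tl.breaths)} breaths, {tl.total_steps} steps")

rip = pk.condition(pk.render_rip(tl, seed=42), "rip")
breaths = pk.detect_breaths(rip)
prox = pk.condition(pk.render_proximity(tl, seed=42), "proximity")
h2m = pk.detect_proximity_events(prox)
res = pk.consolidate_lighter(pk.render_lighter(tl, seed=42), pk.render_self_report(tl))
print(f"detected: {len(breaths)} breaths, {len(h2m)} hand-to-mouth events, "
      f"{res.cigarette_count} cigarettes ({res.false_presses} false lighting events)")

c = tl.cigarettes[0]
ecg = pk.condition(pk.render_ecg(tl, seed=42,
                                 t_start_s=c.t_light_s - 360,
                                 t_end_s=c.t_end_s + 960), "ecg")
hr = pk.summarize_heart_rate(pk.detect_rpeaks(ecg), (c.t_light_s, c.t_end_s))
print(f"heart rate: smoking {hr.smoking_bpm[0]:.1f} bpm, "
      f"pre {hr.pre_bpm[0]:.1f} bpm, post {hr.post_bpm[0]:.1f} bpm")
```

prints

```
simulated hour: 1 cigarettes, 8 puffs, 872 breaths, 827 steps
detected: 873 breaths, 8 hand-to-mouth events, 1 cigarettes (0 false lighting events)
heart rate: smoking 109.5 bpm, pre 81.5 bpm, post 91.5 bpm
```

The detectors recover the simulated ground truth almost exactly: 873 of
872 breaths (+0.1 % under bench-level noise), every puff as one proximity
event, and the one cigarette with no false lighting events. The session
heart rate (109.5 bpm) sits below the configured 112.03 bpm smoking
plateau because the session window includes the one-minute rise from the
81.5 bpm baseline; the post-smoking mean reflects the recovery back to
baseline within fifteen minutes.

The same pipeline is scriptable from the shell:

```sh
pactkit simulate --config scenario.yaml --out raw/
pactkit condition --in raw/ --out cond/
pactkit detect --in cond/ --out events/
pactkit report --events events/ --split 10800 --out report.json
pactkit bench rip-linearity
```

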