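# ocutremor

Ocular microtremor is the smallest fixational eye movement: a low-amplitude
oscillation of gaze, conventionally reported between 70 and 150 Hz. The
critical flicker fusion threshold (CFFT) is the frequency at which a
flickering light source starts to appear continuous. `ocutremor` implements
an analysis pipeline that links the two: it extracts the periodicity of
microtremor from 1 kHz gaze recordings, quantifies how microtremor-band
features separate participants who can and cannot resolve fast flicker, and
classifies a participant's CFFT range (above/below 60 or 120 Hz) from those
features. Because suitable public recordings are not generally available,
the package ships a first-class synthetic-gaze generator that reproduces the
statistical structure the analysis assumes, so every stage is testable
end-to-end.

It is aimed at researchers in oculomotor signal analysis and visual
psychophysics who want a reproducible, tested reference implementation of
this analysis chain.

## The analysis

**Kinematics and the reversal statistic.** Gaze positions (X_t, Y_t) on a
uniform grid with step τ = 1 ms give one-step velocities
v_x(t) = (X_{t+τ} − X_t)/τ (likewise v_y). Three variants feed the
analysis: raw, unit-normalized (direction only), and *fixational* —
restricted to sample pairs labelled as fixation, where microtremor lives.
For two instants the angle φ(t, t′) = arccos(v(t)·v(t′) / ‖v(t)‖‖v(t′)‖) ∈
[0, π] measures direction change; the reversal statistic

  Pr_{φ,k}(τ) = P( φ(t, t+τ) ∈ A_k ),  A_k = [(1 − 1/k)π, π]

is the probability that gaze has (nearly) inverted direction over lag τ.
For an oscillatory component this curve peaks at half the oscillation
period; under isotropic independent directions it equals 1/k, the null
reference.

**Spectral and Hilbert–Huang features.** Each velocity variant's power
spectrum (|FFT|², per contiguous valid segment, length-weighted averaging)
is normalized to unit mass over (0, 500] Hz, giving the cumulative power
spectrum C_X(f′) = ∫₀^{f′} S_X df̃. Separately, empirical mode
decomposition splits each velocity series into intrinsic mode functions
S1, S2, …; the analytic signal of each IMF yields an instantaneous
frequency trace whose empirical cdf over time, cdf_{X,Y}(f) =
∫₀^f ρ_{X,Y} df̃, is the second feature family. All 16 features (4
cumulative spectra + 4 variables × IMFs S1–S3) are cumulative curves in
[0, 1] over frequency.

**Psychophysics and group statistics.** Participants judge which of two
targets (19° apart, 1.4° wide) flickers, 3 trials at each of 30/60/120 Hz;
detecting means ≥ 2 of 3 correct (guessing passes with probability
P(X ≥ 2), X ~ Bin(3, 1/3), = 7/27). For each feature family and threshold
f ∈ {60, 120} Hz, the frequency f* maximizing the group-mean difference
between detectors (P>f) and non-detectors (P<f) is located on a 0.5 Hz
grid and the Mann–Whitney U test at f* reported (`GroupSeparation(...)
.fit()`, a model/results pair with a `summary()` table).

**Classification.** A decision tree predicts the detection group from the
four cumulative-spectrum features evaluated at their f*, with SMOTE
rebalancing inside training folds only and nested stratified 5-fold CV over
feature combinations and the tree hyperparameters (`CfftTreeModel(...)
.fit()`); pooled confusion counts give accuracy, sensitivity, specificity
and precision.

## Worked example

```python
from ocutremor import (ParticipantProfile, SimulationConfig, simulate_recording,
                       fixational_velocity, reversal_probability, reversal_peak,
                       period_to_frequency, chance_probability)

profile = ParticipantProfile("P000", tremor_freq=150.0)
config = SimulationConfig(duration=60.0, seed=1)
rec = simulate_recording(profile, config)          # 60 s at 1 kHz
v = fixational_velocity(rec)
for k in (2, 4, 8):
    tau, pr = reversal_peak(reversal_probability(v, k, range(1, 11)))
    print(f"k={k}: reversal peak at tau = {tau:.0f} ms (Pr = {pr:.2f})")
lo, hi = period_to_frequency((2 * 3, 2 * 4))
print(f"implied tremor band: {lo:.0f}-{hi:.0f} Hz")
print(f"chance level of the 2-of-3 criterion: {chance_probability(3, 1/3, 2):.4f}")
```

prints

```
k=2: reversal peak at tau = 3 ms (Pr = 0.87)
k=4: reversal peak at tau = 3 ms (Pr = 0.58)
k=8: reversal peak at tau = 3 ms (Pr = 0.32)
implied tremor band: 125-167 Hz
chance level of the 2-of-3 criterion: 0.2593
```

The reversal probability of the simulated gaze peaks at 3 ms for every
interval narrowness k — half the period of the 150 Hz tremor the generator
injected. A reversal every 3–4 ms means a full oscillation period of
6–8 ms, i.e. a tremor frequency between 125 and ~167 Hz. The chance level
0.2593 = 7/27 is the probability of passing the detection criterion by
guessing.

The full pipeline (cohort simulation → features → group statistics →
classifier) runs from a YAML config:

```bash
ocutremor run-all --seed 0 --out run_output
```

writing gaze/trial tables, reversal curves, the 16-family feature curves,
the group-separation table, classifier reports and a run manifest.

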