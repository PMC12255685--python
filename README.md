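# nirspeech

Analysis pipeline for functional near-infrared spectroscopy (fNIRS)
studies of **audio-tactile speech processing** — for researchers who want
to test whether vibrotactile speech information (a 230 Hz carrier
modulated by the speech envelope's rate of change) enhances cortical
responses to speech in noise, and for anyone who needs a fully simulated,
ground-truth-bearing fNIRS cohort to validate such a pipeline end to end.

The package covers the complete chain:

1. **Simulation** (`nirspeech.simulate`) — dual-wavelength (760/850 nm)
   raw intensities at 3.9063 Hz for a cohort of participants
   (default 21) × 5 conditions (*auditory speech-in-quiet*,
   *auditory speech-in-noise*, *audio-tactile speech-in-noise*,
   *tactile speech*, silent *control*) × 20 trials, over a montage of
   49 long (2.1–4.3 cm) and 8 short (0.8 cm) channels, with known true
   response amplitudes, physiological oscillations, a shared scalp
   process, drifts, motion artifacts and detector noise.
2. **Preprocessing** (`nirspeech.preprocess`) — optical density; channel
   QC by scalp coupling index (reject SCI < 0.7), windowed cardiac peak
   power (reject if > 50% of 10 s windows below 0.1) and OD SD (> 0.2);
   temporal derivative distribution repair; modified Beer–Lambert law
   (partial pathlength factor 0.1); 0.005–0.25 Hz zero-phase 5th-order
   Butterworth band-pass; correlation-based signal improvement;
   short-channel scalp regression.
3. **Feature extraction** (`nirspeech.features`) — per channel ×
   condition amplitudes by (a) a GLM with the canonical double-gamma HRF
   convolved with stimulus-duration/1.67 boxcars, cosine drifts, and
   AR(5)-prewhitened generalized least squares, and (b) waveform mean
   amplitudes (epochs −5..20 s, linear detrend, baseline correction,
   45 Δµmol/l peak-to-peak rejection, 5–8 s mean).
4. **Data-driven ROI** (`nirspeech.roi`) — per participant the top-ten
   channels per method; per-channel participant counts; ROI = the
   intersection of the two methods' top-count sets.
5. **Group statistics** (`nirspeech.groupstats`) — linear mixed models
   with participant random intercepts: condition activations with
   suppressed intercept and Benjamini–Hochberg FDR (q = 0.05), the
   audio-tactile vs auditory contrast, and the multisensory additivity
   test against the summed unisensory responses.
6. **Stimulus synthesis** (`nirspeech.stimulus`) — the vibrotactile
   encoder: broadband envelope → rate of change → 230 Hz carrier.

## The statistics at the core

For cleaned HbO traces $y_c(t)$ the GLM is

$$y_c(t) = \sum_k \beta_{ck}\,(h * u_k)(t) + \text{drifts} + \varepsilon_c(t),
\qquad \varepsilon_c \sim \mathrm{AR}(5),$$

with $h$ the double-gamma HRF and $u_k$ condition $k$'s boxcar train
(duration = stimulus/1.67). Group inference uses

$$\text{HbO} \sim -1 + \text{condition}(:\text{channel}) + (1\mid\text{participant})$$

with BH-FDR across cells, and the audio-tactile gain is the
`audiotactile_noise` coefficient of an intercept model referenced on
`speech_noise`. The additivity test contrasts the bimodal response with
each participant's `speech_noise + tactile` sum: significantly above →
super-additive, below → sub-additive, otherwise additive.

## Worked example

```python
from nirspeech.simulate import generate_cohort
from nirspeech.analysis import analyze_cohort

cohort = generate_cohort(n_participants=21, seed=42, trials_per_condition=8)
result = analyze_cohort(cohort)
print(result.roi.channels)
for method, c in result.contrast.items():
    print(method, round(c.difference, 3), round(c.percent_change, 1), "%")
for method, c in result.additivity.items():
    print(method, c.direction)
```

prints (seed 42):

```
['S1_D1', 'S2_D8', 'S3_D15', 'S4_D22', 'S5_D5', 'S6_D12']
beta 0.531 23.7 %
waveform 0.458 20.4 %
beta sub-additive
waveform sub-additive
```

The ROI is exactly the six designated temporal channels the simulator
made responsive; the recovered audio-tactile gain (true value
0.6 Δµmol/l before the pipeline's deterministic attenuation) is a ~20%
HbO increase over auditory speech-in-noise; and because the simulator's
bimodal amplitude (3.3) is below the unisensory sum (2.7 + 1.2), the
enhancement is correctly classified sub-additive.

A command-line interface mirrors the shell-usable pieces:

```bash
nirspeech simulate --out data/ --seed 1 --participants 21
nirspeech tactile encode speech.wav tactile.wav --carrier 230 --smooth-ms 50
nirspeech analyze --data data/ --out results/
```

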