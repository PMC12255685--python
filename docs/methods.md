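# Methods

This note records the models, conventions and numerical choices behind
`nirspeech`, in the order data flows through the package.

## Forward model (simulator)

Each long channel's latent oxygenated-hemoglobin trace is

    HbO(t) = Σ_trials A(condition, region) · k(t − onset)
           + cardiac + respiratory + Mayer oscillations
           + g_ch · s(t) + drift(t) + ε(t)

where `k` is the canonical double-gamma HRF convolved with the trial's
full-duration boxcar and peak-normalized, so `A` is the **peak evoked
response in Δµmol/l**. `s(t)` is one shared band-limited (0.04–0.15 Hz)
unit-RMS scalp process per participant, coupled to every channel (long
and short) through channel-specific gains — the minimal structure that
makes short-channel regression both necessary and sufficient. Short
channels carry everything except the neural term.

Deoxygenated hemoglobin couples to all *hemodynamic* components (neural,
oscillations, scalp, drift) at the fixed negative ratio `hbr_ratio`
(default −0.3), with only instrumental noise independent per chromophore.
This matters: correlation-based signal improvement estimates its scaling
α from data SDs, and a forward model whose artifacts couple positively
into HbR would make CBSI systematically shrink true responses.

Concentrations map to optical density through the modified Beer–Lambert
law with a single extinction table (the Gratzer/Prahl compilation at
760/850 nm, converted to natural-log units) shared with the analysis
inverse, so the noiseless round trip intensity → OD → MBLL is exact to
machine precision (up to the per-trace mean, which a log-ratio transform
cannot carry). Motion artifacts — single-sample spikes and baseline
steps, the two classes TDDR targets — are injected in OD, common-mode
across wavelengths; per-wavelength detector noise (default OD SD 5e-5)
is what makes the two wavelengths statistically separable and gives the
scalp-coupling index its discriminative power.

Default amplitudes (Δµmol/l, temporal channels): speech-in-quiet 3.0,
speech-in-noise 2.7, audio-tactile 3.3, tactile 1.2, control 0 — i.e. a
0.6 Δµmol/l audio-tactile gain over a 2.7 reference and a deliberately
sub-additive bimodal response (3.3 < 2.7 + 1.2). Tactile input also
drives left somatosensory cortex (1.5). Noise defaults: cardiac 1.1 Hz /
0.5 Δµmol/l, respiratory 0.25 Hz / 0.2, Mayer 0.095 Hz / 0.3, white
concentration noise 0.6, drift ±1 over the recording, scalp RMS 0.8;
motion 0.3 spikes and 0.1 steps per minute at OD amplitudes 0.01/0.005.
These were fixed once to sit at the scale of group-level auditory fNIRS
responses (1–4 Δµmol/l) and plausible physiological variability; they
are exposed in `GroundTruth` and YAML configs but are not tuned per
experiment. A cohort shares one randomized trial schedule (as in a
fixed-playlist experiment); per-participant seeds derive from the master
seed by a fixed counter scheme, and participant heterogeneity enters as
a normal random offset (SD 0.5) added to every non-zero amplitude — a
genuine random-intercept structure for the group models.

The montage is a fixture: 49 long channels (2.1–4.3 cm) and 8 short
(0.8 cm), with coarse region labels in place of anatomy. Exactly six
long channels (three per hemisphere) are labelled temporal and respond
to speech, so data-driven ROI recovery has a known correct answer.

## Preprocessing

Canonical order: OD → channel QC → TDDR → Beer–Lambert (PPF 0.1) →
band-pass → CBSI (long channels) → short-channel regression. Short
channels pass through TDDR/MBLL/filtering like long ones and are then
consumed, un-CBSI'd, as nuisance regressors (HbO and HbR of every
retained short channel, plus an intercept; minimum-norm solve if
collinear). Each stage appends to the recording's provenance list.

* **QC** is computed on task blocks only: samples within −5..+15 s of
  onsets, with gaps > 30 s between segments excised. SCI is the
  cardiac-band (0.5–1.5 Hz; the upper edge respects the 1.95 Hz Nyquist)
  zero-lag correlation of the two wavelengths. Peak power is, per
  non-overlapping 10 s window, the cardiac-band maximum of
  |X(f)·conj(Y(f))| / (‖X‖‖Y‖) of the band-passed pair — bounded to
  [0, 1] by Cauchy–Schwarz, ≈ 1 for a shared tone, small for independent
  noise. The SD criterion uses OD SD ≤ 0.2, equivalent to a 20%
  intensity coefficient of variation through the log-normal relation.
* **TDDR.** Tukey-biweight weights (tuning constant 4.685, scale
  1.4826·MAD) are estimated iteratively on the temporal derivative as in
  the reference algorithm, but the repair replaces only derivative
  samples whose converged weight is exactly zero (residual beyond 4.685
  robust SD) with the robust mean derivative. Two properties motivated
  this: at 3.9 Hz the reference algorithm's 0.5 Hz low/high split leaves
  single-sample spikes in the untouched high band, and global
  reweighting shrinks clean smooth signals by 5–12% RMS — while also
  injecting per-wavelength step noise whenever ordinary noise samples
  are falsely flagged, which decorrelates HbO/HbR and biases CBSI. With
  the zero-weight cut, clean traces pass through exactly; spikes and
  baseline steps (always far beyond the cut) are removed to ~1–3%
  residual.
* **Band-pass**: 5th-order Butterworth low-pass at 0.25 Hz then
  high-pass at 0.005 Hz, both forward–backward (zero phase; effective
  attenuation is doubled relative to a single pass). The high-pass has a
  ~200 s impulse response, so reflected padding is extended to 1000
  samples to keep edge transients out of the analysis region.
* **CBSI**: α = SD(HbO)/SD(HbR); HbO* = (HbO − α·HbR)/2,
  HbR* = −HbO*/α. Output chromophores are anti-correlated by
  construction; the corrected HbR carries no independent information and
  is retained for visualization only — all statistics use HbO.

## Feature extraction

The canonical HRF is the double-gamma with peak delay 6 s, undershoot
delay 12 s, dispersions 0.9 and undershoot ratio 0.35, peak-normalized
to 1. Convolved with the 3.4 s analysis boxcar it peaks at ≈ 6.9 s,
inside the "around 6.5 s" window that motivates the 5–8 s averaging
window.

*GLM*: one regressor per condition (boxcar duration = trial
duration/1.67, single-trial modelled peak normalized to 1, so betas are
peak response amplitudes in Δµmol/l), cosine drifts with frequencies
k/(2T) up to a cutoff, and a constant. The data-driven cutoff (1 /
longest inter-onset interval of interest) is available; the package's
standard configuration uses 0.01 Hz (100 s period), slow enough to stay
clear of the stimulus-locked band. Estimation is OLS → Yule-Walker
(MLE) AR(5) on the residuals → prewhitening of both sides → least
squares, with normal-reference p-values (traces are thousands of
samples long). Near-noiseless fits skip whitening; estimated AR
polynomials are checked for stationarity.

*Waveform*: epochs −5..20 s, linear detrend over the whole epoch, then
pre-stimulus (−5..0 s) mean subtraction; epochs with HbO peak-to-peak
above 45 Δµmol/l are rejected; the amplitude is the 5–8 s mean of the
average retained epoch. With inter-onset intervals (~21 s) shorter than
the response (~37 s), baselines sit on neighbouring responses and
undershoots: waveform amplitudes therefore carry a small deterministic
overlap bias (≈ +5% on task conditions, ≈ +0.1 Δµmol/l on the control).
The GLM, which models all overlapping responses jointly, does not. In
human data this bias is far below the noise floor; in clean simulations
it can reach statistical significance on the control condition, which is
why recovery tests compare against forward-model predictions rather
than raw amplitudes, and the group-level control check bounds the
estimate rather than its p-value.

*CNR* (used to validate preprocessing choices): per channel, (mean 5–8 s
amplitude of stimulus epochs − mean of control epochs) / SD of
control-epoch amplitudes, averaged over channels.

## ROI consensus and group models

Per participant the ten highest-amplitude channels are taken per method
(stable channel-id tie-break); per channel the number of participants
listing it is counted; from each method's counts the channels holding
the m = 6 largest counts are retained (ties included — the retention
depth is a parameter because only the outcome, a six-channel ROI, is
fixed by convention) and the ROI is their intersection. ROI responses
are unweighted means over ROI channels.

Group models are statsmodels `MixedLM` fits (REML) with a participant
random intercept, run separately per feature method; boundary variance
estimates fall back to zero with a warning. Coefficient tests use a
normal reference on estimate/SE; at 21 participants this inflates the
nominal 5% type-I rate to a measured ~7% — acceptable for the package's
purposes and stated here rather than hidden. BH-FDR at q = 0.05 is
applied within each model across its full set of condition(×channel)
cells. The additivity test forms each participant's auxiliary
`auditory + tactile` sum and contrasts the bimodal condition against it,
labelling super-/sub-additive only at p < 0.05.

## Tactile encoder

Envelope extraction is full-wave rectification followed by a zero-phase
4th-order 10 Hz low-pass (preserving the 4–8 Hz syllable rate); the
modulator is the half-wave-rectified first difference, smoothed by a
50 ms moving average and peak-normalized — both cutoffs are declared
defaults, exposed in the API, since the upstream envelope procedure's
exact parameters are not standardized. The carrier is 230 Hz, where
Pacinian corpuscles are most sensitive; physical displacement
calibration is hardware scope.

## What the simulation does and does not show

The generator reproduces the statistical structure the pipeline relies
on: wavelength-coupled hemodynamics, scalp contamination shared between
short and long channels, motion artifacts of the two TDDR classes,
condition-locked responses with participant heterogeneity, and a
fixed-schedule cohort. It does not model photon transport, 3-D head
geometry, wavelength-dependent differential pathlengths, HbR vascular
delay, serially correlated physiological noise beyond discrete
oscillations, or session/montage variability across participants.
Passing recovery tests therefore demonstrates internal consistency and
correct implementation of every stage at realistic signal scales — not
that the pipeline is robust to everything human data can produce.

## Problem sizes used in the test suite

Monte-Carlo suites run at the study's design scale where that is cheap
(21 participants; 200 seeds for gain recovery and false-positive rates;
100 seeds for additivity classification; 200 seeded channels for QC
sensitivity). Full-pipeline cohort suites use the complete 5 × 20-trial
design for single-cohort checks and 8 trials per condition for the
50-cohort ROI-recovery sweep and the coverage sweep — fewer trials make
per-channel amplitudes noisier, so the ROI-recovery claim is tested
under harder, not easier, conditions. All seeds are fixed.
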