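"""Synthetic fNIRS cohort generator with known ground truth.

The generator emulates the statistical structure of a dual-wavelength
(760/850 nm) continuous-wave recording sampled at 3.9063 Hz during a
passive audio-tactile speech experiment: five conditions (auditory
speech-in-quiet, auditory speech-in-noise, audio-tactile speech-in-noise,
tactile speech, silent control) x 20 trials, trial durations 5.56-5.7 s,
jittered 10-20 s breaks, 49 long + 8 short channels.

Forward model per long channel
------------------------------
latent HbO(t) = sum over trials of A(condition, region) * k(t - onset)
               + cardiac/respiratory/Mayer oscillations
               + g_ch * shared scalp process + drift + white noise,
where k is the canonical HRF convolved with the full stimulus-duration
boxcar, peak-normalized so A is the peak evoked response in delta-umol/l.
latent HbR = hbr_ratio * neural HbO + positively-coupled artifact terms
+ independent noise.  Short channels carry scalp, oscillations and noise
but no neural term.  Chromophore traces map to optical density through
the modified Beer-Lambert relation (shared extinction table, PPF 0.1),
motion spikes and baseline shifts are injected into OD, and intensities
are baseline * exp(-OD).

All randomness flows from a single integer seed; per-participant seeds
are derived by a fixed counter offset so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage, default_montage
from .optics import hemoglobin_to_od

SAMPLE_RATE_HZ = 3.9063
WAVELENGTHS_NM = (760, 850)
PPF = 0.1

CONDITIONS = (
    "speech_quiet",
    "speech_noise",
    "audiotactile_noise",
    "tactile",
    "control",
)

#: conditions entering the group contrasts (everything but the silent control)
TASK_CONDITIONS = CONDITIONS[:4]


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    condition: str
    onset: float  # s
    duration: float  # s


@dataclass
class EventSchedule:
    trials: list[Trial]

    def __post_init__(self) -> None:
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    @property
    def conditions(self) -> list[str]:
        return [t.condition for t in self.trials]

    @property
    def total_duration(self) -> float:
        if not self.trials:
            return 0.0
        last = self.trials[-1]
        return last.onset + last.duration

    def shifted(self, offset: float) -> "EventSchedule":
        return EventSchedule(
            [replace(t, onset=t.onset + offset) for t in self.trials]
        )

    def for_condition(self, condition: str) -> list[Trial]:
        return [t for t in self.trials if t.condition == condition]


def generate_events(
    trials_per_condition: int | dict[str, int] = 20,
    duration_range: tuple[float, float] = (5.56, 5.7),
    gap_range: tuple[float, float] = (10.0, 20.0),
    conditions: tuple[str, ...] = CONDITIONS,
    seed: int = 0,
) -> EventSchedule:
    """Randomized trial schedule: conditions shuffled, jittered breaks.

    Onsets start at 0; downstream consumers add their own pre-roll.  With a
    fixed seed the schedule is reproducible.
    """
    if duration_range[0] <= 0 or gap_range[0] <= 0:
        raise ValueError("durations and gaps must be positive")
    if duration_range[1] < duration_range[0] or gap_range[1] < gap_range[0]:
        raise ValueError("ranges must satisfy low <= high")
    if isinstance(trials_per_condition, int):
        counts = {c: trials_per_condition for c in conditions}
    else:
        counts = {c: trials_per_condition.get(c, 0) for c in conditions}
    if any(n < 0 for n in counts.values()):
        raise ValueError("trials-per-condition must be non-negative")

    rng = np.random.default_rng(seed)
    labels = [c for c in conditions for _ in range(counts[c])]
    rng.shuffle(labels)

    trials: list[Trial] = []
    t = 0.0
    for lab in labels:
        dur = float(rng.uniform(*duration_range))
        trials.append(Trial(lab, t, dur))
        t += dur + float(rng.uniform(*gap_range))
    return EventSchedule(trials)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Physiological and instrumental noise levels.

    Oscillation amplitudes are HbO excursions in delta-umol/l; ``white_sd``
    is concentration-domain broadband noise (delta-umol/l, independent per
    chromophore); ``od_noise_sd`` is per-wavelength detector noise added in
    optical density (dimensionless), the component that makes a channel's
    two wavelengths statistically separable; ``drift_sd`` scales a random
    linear drift (delta-umol/l over the whole recording).
    """

    cardiac_freq: float = 1.1
    cardiac_amp: float = 0.5
    resp_freq: float = 0.25
    resp_amp: float = 0.2
    mayer_freq: float = 0.095
    mayer_amp: float = 0.3
    white_sd: float = 0.6
    od_noise_sd: float = 5e-5
    drift_sd: float = 1.0


@dataclass
class MotionParams:
    spike_rate_per_min: float = 0.3
    spike_amp_od: float = 0.01
    shift_rate_per_min: float = 0.1
    shift_amp_od: float = 0.005


def default_amplitudes() -> dict[tuple[str, str], float]:
    """True peak HbO responses (delta-umol/l) by (condition, region).

    The scale follows typical group-level auditory-cortex responses of
    1-4 delta-umol/l.  Only the six designated temporal channels respond to
    speech; tactile input additionally drives left somatosensory cortex.
    The silent control never evokes a response.
    """
    amp: dict[tuple[str, str], float] = {}
    for region in ("left-temporal", "right-temporal"):
        amp[("speech_quiet", region)] = 3.0
        amp[("speech_noise", region)] = 2.7
        amp[("audiotactile_noise", region)] = 3.3
        amp[("tactile", region)] = 1.2
    amp[("tactile", "left-somatosensory")] = 1.5
    amp[("audiotactile_noise", "left-somatosensory")] = 0.8
    return amp


@dataclass
class GroundTruth:
    """Everything the simulator knows and the pipeline must recover."""

    amplitude_by_condition_region: dict[tuple[str, str], float] = field(
        default_factory=default_amplitudes
    )
    hbr_ratio: float = -0.3
    noise: NoiseParams = field(default_factory=NoiseParams)
    scalp_gain: float = 1.0  # scales per-channel coupling of the shared scalp process
    scalp_amp: float = 0.8  # RMS of the shared scalp process, delta-umol/l
    motion: MotionParams = field(default_factory=MotionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.8 <= self.noise.cardiac_freq <= 1.5:
            raise ValueError("cardiac frequency must lie in [0.8, 1.5] Hz")
        if self.hbr_ratio >= 0:
            raise ValueError("hbr_ratio must be negative")
        for name in ("cardiac_amp", "resp_amp", "mayer_amp", "white_sd",
                     "od_noise_sd", "drift_sd"):
            if getattr(self.noise, name) < 0:
                raise ValueError(f"noise amplitude {name} must be >= 0")

    def amplitude(self, condition: str, region: str) -> float:
        return self.amplitude_by_condition_region.get((condition, region), 0.0)

    def silent(self) -> "GroundTruth":
        """Copy with all noise, scalp and motion terms switched off."""
        return replace(
            self,
            noise=NoiseParams(cardiac_amp=0, resp_amp=0, mayer_amp=0,
                              white_sd=0, od_noise_sd=0, drift_sd=0),
            scalp_gain=0.0,
            motion=MotionParams(0, 0, 0, 0),
        )


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Per-participant dual-wavelength raw intensities plus metadata.

    ``intensity`` has shape (n_channels, 2, n_samples); wavelength axis is
    ordered as ``wavelengths``.  ``latent`` optionally carries the noiseless
    concentration traces (n_channels, 2 chromophores, n_samples) for
    round-trip testing.
    """

    participant: str
    montage: Montage
    sample_rate: float
    wavelengths: tuple[int, int]
    intensity: np.ndarray
    events: EventSchedule
    truth: GroundTruth | None = None
    latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, float)
        if inten.ndim != 3 or inten.shape[1] != 2:
            raise ValueError("intensity must have shape (n_channels, 2, n_samples)")
        if inten.shape[0] != len(self.montage.channels):
            raise ValueError("intensity rows do not match montage channels")
        if not np.all(inten > 0):
            raise ValueError("all intensity samples must be strictly positive")
        self.intensity = inten

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def channel_names(self) -> list[str]:
        return self.montage.channel_names()


def _hrf_kernel(sample_rate: float, duration: float = 32.0) -> np.ndarray:
    # local import avoids a circular dependency at module import time
    from .features import canonical_hrf

    t = np.arange(0.0, duration, 1.0 / sample_rate)
    return canonical_hrf(t)


def evoked_kernel(
    boxcar_duration: float, sample_rate: float = SAMPLE_RATE_HZ
) -> np.ndarray:
    """Canonical HRF convolved with a stimulus boxcar, peak-normalized to 1.

    This is the single-trial response shape the simulator scales by the
    true amplitude, so amplitudes are peak evoked responses in umol/l.
    """
    return _evoked_kernel_cached(round(float(boxcar_duration), 3),
                                 round(float(sample_rate), 6)).copy()


def _evoked_kernel_cached(boxcar_duration: float, sample_rate: float) -> np.ndarray:
    key = (boxcar_duration, sample_rate)
    k = _KERNEL_CACHE.get(key)
    if k is None:
        h = _hrf_kernel(sample_rate)
        n_box = max(1, int(round(boxcar_duration * sample_rate)))
        k = np.convolve(h, np.ones(n_box))
        k /= k.max()
        _KERNEL_CACHE[key] = k
    return k


_KERNEL_CACHE: dict[tuple[float, float], np.ndarray] = {}


def _band_limited_noise(n: int, sample_rate: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS stochastic process restricted to ``band`` (Mayer-range scalp)."""
    from scipy.signal import butter, sosfiltfilt

    x = rng.standard_normal(n + 200)
    sos = butter(2, band, btype="bandpass", fs=sample_rate, output="sos")
    y = sosfiltfilt(sos, x)[100:-100]
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def simulate_participant(
    truth: GroundTruth,
    montage: Montage | None = None,
    events: EventSchedule | None = None,
    participant: str = "P01",
    sample_rate: float = SAMPLE_RATE_HZ,
    pre_roll: float = 30.0,
    post_roll: float = 40.0,
    keep_latent: bool = True,
) -> RawRecording:
    """Simulate one participant's raw dual-wavelength recording.

    ``events`` onsets are interpreted relative to the start of the task
    block; the returned recording's events are shifted by ``pre_roll`` so
    every trial has full epoch support.
    """
    montage = montage if montage is not None else default_montage()
    if events is None:
        events = generate_events(seed=truth.seed)
    rng = np.random.default_rng(truth.seed)

    events = events.shifted(pre_roll)
    total = events.total_duration + post_roll if events.trials else pre_roll + post_roll
    n = int(np.ceil(total * sample_rate))
    t = np.arange(n) / sample_rate

    # per-condition neural drive, shared across channels up to region scaling
    drive: dict[str, np.ndarray] = {}
    for cond in set(events.conditions):
        trials = events.for_condition(cond)
        resp = np.zeros(n)
        for tr in trials:
            k = evoked_kernel(tr.duration, sample_rate)
            i0 = int(round(tr.onset * sample_rate))
            seg = k[: max(0, n - i0)]
            resp[i0:i0 + len(seg)] += seg
        drive[cond] = resp

    nz = truth.noise
    scalp = truth.scalp_amp * _band_limited_noise(n, sample_rate, (0.04, 0.15), rng)
    # shared oscillatory phases per participant
    ph = rng.uniform(0, 2 * np.pi, size=3)
    cardiac = np.sin(2 * np.pi * nz.cardiac_freq * t + ph[0])
    resp_osc = np.sin(2 * np.pi * nz.resp_freq * t + ph[1])
    mayer = np.sin(2 * np.pi * nz.mayer_freq * t + ph[2])

    channels = montage.channels
    n_ch = len(channels)
    scalp_gains = truth.scalp_gain * rng.uniform(0.5, 1.5, size=n_ch)
    osc_jitter = rng.uniform(0.8, 1.2, size=n_ch)
    drift_slopes = rng.normal(0.0, nz.drift_sd, size=n_ch) / max(total, 1.0)

    intensity = np.empty((n_ch, 2, n))
    latent = np.empty((n_ch, 2, n)) if keep_latent else None
    baselines = rng.uniform(0.5, 2.0, size=(n_ch, 2))

    minutes = total / 60.0
    for i, ch in enumerate(channels):
        neural = np.zeros(n)
        if not ch.is_short:
            for cond, resp in drive.items():
                a = truth.amplitude(cond, ch.region)
                if a:
                    neural += a * resp
        # slow oscillations, scalp flow and drift are flow-driven
        # hemodynamics: they couple into HbR at the same (negative) ratio
        # as the neural term.  Cardiac pulsation is a blood-volume
        # oscillation, raising both chromophores together — the positive
        # coupling that makes the scalp-coupling index informative at both
        # wavelengths.  Only instrumental noise (and OD-domain motion) is
        # chromophore-independent / common-mode.
        slow = (
            osc_jitter[i] * (nz.resp_amp * resp_osc + nz.mayer_amp * mayer)
            + scalp_gains[i] * scalp + drift_slopes[i] * t
        )
        card = osc_jitter[i] * nz.cardiac_amp * cardiac
        hbo = neural + slow + card + rng.normal(0, nz.white_sd, n)
        hbr = (
            truth.hbr_ratio * (neural + slow)
            + abs(truth.hbr_ratio) * card
            + rng.normal(0, abs(truth.hbr_ratio) * nz.white_sd, n)
        )
        od = hemoglobin_to_od(hbo, hbr, ch.distance, PPF, WAVELENGTHS_NM)

        # motion artifacts are common-mode across wavelengths, injected in OD
        mot = truth.motion
        n_spikes = rng.poisson(mot.spike_rate_per_min * minutes)
        for _ in range(n_spikes):
            j = rng.integers(0, n)
            od[:, j] += mot.spike_amp_od * rng.normal() * np.array([1.0, 1.0])
        n_shifts = rng.poisson(mot.shift_rate_per_min * minutes)
        for _ in range(n_shifts):
            j = rng.integers(0, n)
            od[:, j:] += mot.shift_amp_od * rng.normal()

        od += rng.normal(0, nz.od_noise_sd, size=od.shape)
        intensity[i] = baselines[i][:, None] * np.exp(-od)
        if keep_latent:
            latent[i, 0] = hbo
            latent[i, 1] = hbr

    return RawRecording(
        participant=participant,
        montage=montage,
        sample_rate=sample_rate,
        wavelengths=WAVELENGTHS_NM,
        intensity=intensity,
        events=events,
        truth=truth,
        latent=latent,
    )


def participant_seed(master_seed: int, index: int) -> int:
    """Splittable counter scheme: deterministic per-participant seed < 2**31."""
    return int((master_seed * 1_000 + 7919 * index + 1) % (2**31 - 1))


def generate_cohort(
    truth: GroundTruth | None = None,
    n_participants: int = 21,
    between_sd: float = 0.5,
    seed: int = 0,
    montage: Montage | None = None,
    events: EventSchedule | None = None,
    trials_per_condition: int = 20,
    keep_latent: bool = False,
) -> list[RawRecording]:
    """Simulate a cohort sharing one trial schedule (as in the study design).

    Each participant's true amplitudes are the cohort amplitudes plus a
    participant-level offset ~ N(0, between_sd) applied to every non-zero
    condition amplitude — a genuine random-intercept structure for the
    group mixed model.
    """
    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    truth = truth if truth is not None else GroundTruth(seed=seed)
    montage = montage if montage is not None else default_montage()
    if events is None:
        events = generate_events(trials_per_condition=trials_per_condition,
                                 seed=participant_seed(seed, 999))
    offset_rng = np.random.default_rng(participant_seed(seed, 0))
    offsets = offset_rng.normal(0.0, between_sd, size=n_participants)

    cohort = []
    for p in range(n_participants):
        amps = {
            key: val + offsets[p] if val != 0 else 0.0
            for key, val in truth.amplitude_by_condition_region.items()
        }
        p_truth = replace(
            truth,
            amplitude_by_condition_region=amps,
            seed=participant_seed(seed, p + 1),
        )
        cohort.append(
            simulate_participant(
                p_truth, montage, events,
                participant=f"P{p + 1:02d}",
                keep_latent=keep_latent,
            )
        )
    return cohort
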