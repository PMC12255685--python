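"""Vibrotactile speech-stimulus synthesis.

The tactile signal is a 230 Hz carrier — the frequency band where
Pacinian corpuscles in glabrous skin are most sensitive — amplitude
modulated by the *rate of change* of the speech broadband envelope:
full-wave rectification, low-pass smoothing, first derivative, moving
average, half-wave rectification, peak rescaling.  Coding the envelope's
positive slope makes the vibration peak at syllable onsets rather than
syllable centers.

Physical displacement calibration (the presentation level, ~3.7 um peak
on the fingertip) is a hardware matter and out of software scope; the
digital modulator is peak-normalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

CARRIER_HZ = 230.0
ENVELOPE_LOWPASS_HZ = 10.0
SMOOTHING_WINDOW_MS = 50.0


@dataclass
class AudioSignal:
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 1:
            raise ValueError("audio must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class Envelope:
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if np.any(self.samples < -1e-12):
            raise ValueError("envelope samples must be non-negative")
        self.samples = np.maximum(self.samples, 0.0)


def read_wav(path) -> AudioSignal:
    """Read a mono WAV (PCM int or float), scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSignal(np.asarray(data, float), float(rate))


def write_wav(path, audio: AudioSignal) -> None:
    wavfile.write(path, int(round(audio.sample_rate)),
                  audio.samples.astype(np.float32))


def write_two_channel_wav(path, audio: AudioSignal, tactile: AudioSignal) -> None:
    """Channel 1 = audio, channel 2 = tactile, in one stereo file."""
    if audio.sample_rate != tactile.sample_rate:
        raise ValueError("audio and tactile must share a sample rate")
    n = max(len(audio.samples), len(tactile.samples))
    buf = np.zeros((n, 2), np.float32)
    buf[: len(audio.samples), 0] = audio.samples
    buf[: len(tactile.samples), 1] = tactile.samples
    wavfile.write(path, int(round(audio.sample_rate)), buf)


def extract_envelope(
    audio: AudioSignal, lowpass_hz: float = ENVELOPE_LOWPASS_HZ
) -> Envelope:
    """Broadband amplitude envelope: full-wave rectify, zero-phase low-pass.

    The 10 Hz default cutoff preserves syllable-rate (~4-8 Hz)
    fluctuations while discarding carrier fine structure.
    """
    if len(audio.samples) == 0:
        raise ValueError("empty audio")
    rect = np.abs(audio.samples)
    if lowpass_hz >= audio.sample_rate / 2:
        raise ValueError("low-pass cutoff at or above Nyquist")
    sos = butter(4, lowpass_hz, btype="lowpass", fs=audio.sample_rate, output="sos")
    env = sosfiltfilt(sos, rect)
    return Envelope(np.maximum(env, 0.0), audio.sample_rate)


def rate_of_change(
    env: Envelope, smoothing_window_ms: float = SMOOTHING_WINDOW_MS
) -> Envelope:
    """Half-wave-rectified, smoothed first derivative, peak-rescaled to 1.

    The first difference (scaled by the sample rate) is smoothed with a
    centered moving average of the stated window, negative values are
    zeroed (only envelope *rises* drive the vibration), and the result is
    rescaled to a maximum of 1 (an all-zero derivative stays zero).
    """
    if len(env.samples) < 2:
        raise ValueError("envelope too short to differentiate")
    win = int(round(smoothing_window_ms * 1e-3 * env.sample_rate))
    if win < 1:
        raise ValueError("smoothing window shorter than one sample")
    d = np.diff(env.samples) * env.sample_rate
    d = np.concatenate([d, [0.0]])  # keep the input length
    kernel = np.ones(win) / win
    smooth = np.convolve(d, kernel, mode="same")
    rect = np.maximum(smooth, 0.0)
    peak = rect.max()
    if peak > 0:
        rect = rect / peak
    return Envelope(rect, env.sample_rate)


def synthesize_tactile(
    modulator: Envelope, carrier_hz: float = CARRIER_HZ
) -> AudioSignal:
    """Modulate a sinusoidal carrier: out(t) = m(t) * sin(2 pi f t)."""
    if modulator.sample_rate <= 2 * carrier_hz:
        raise ValueError(
            f"sample rate {modulator.sample_rate} Hz cannot represent a "
            f"{carrier_hz} Hz carrier"
        )
    if modulator.samples.size and modulator.samples.max() > 1 + 1e-9:
        raise ValueError("modulator must lie in [0, 1]")
    t = np.arange(len(modulator.samples)) / modulator.sample_rate
    return AudioSignal(
        modulator.samples * np.sin(2 * np.pi * carrier_hz * t),
        modulator.sample_rate,
    )


def encode_tactile(
    audio: AudioSignal,
    carrier_hz: float = CARRIER_HZ,
    smoothing_window_ms: float = SMOOTHING_WINDOW_MS,
    envelope_lowpass_hz: float = ENVELOPE_LOWPASS_HZ,
) -> AudioSignal:
    """Full chain: envelope -> rate of change -> carrier modulation."""
    env = extract_envelope(audio, envelope_lowpass_hz)
    mod = rate_of_change(env, smoothing_window_ms)
    return synthesize_tactile(mod, carrier_hz)
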