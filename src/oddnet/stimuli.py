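"""Pure-tone stimulus synthesis and cochleagram (STFT) input features.

The experiment presents pairs of 100-ms pure tones: a first tone that is
either the standard (10 kHz, 80 dB SPL) or one of four deviants
(frequency: +/-2.5 kHz; intensity: +/-10 dB), followed after a 450-ms
offset-to-onset gap by a second, always-standard tone.  Audio is rendered
at 100 kHz and converted to a time-frequency "cochleagram" — the magnitude
of a Hann-windowed short-time Fourier transform evaluated on 0..50 kHz at
0.5-kHz spacing (101 bins), with frames decimated to the 100-Hz grid of the
evoked-potential analysis (111 frames over -0.1..1.0 s).  The cochleagram
is the only input representation the recurrent model ever sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

AUDIO_RATE = 100_000.0
"""Audio sampling rate in Hz."""

FRAME_RATE = 100.0
"""Cochleagram frame rate in Hz (matches the resampled ERP grid)."""

WINDOW = (-0.1, 1.0)
"""Trial window in seconds relative to first-tone onset, inclusive ends."""

N_FRAMES = 111
N_BINS = 101
BIN_SPACING_KHZ = 0.5

STANDARD_FREQ_KHZ = 10.0
STANDARD_LEVEL_DB = 80.0
TONE_DURATION_MS = 100.0
ISI_S = 0.45  # constant offset-to-onset inter-stimulus interval
SECOND_TONE_ONSET_S = TONE_DURATION_MS / 1000.0 + ISI_S  # 0.55 s

CONDITIONS = ("S", "fD1", "fD2", "iD1", "iD2")

#: First-tone (frequency kHz, level dB) for each of the five conditions.
CONDITION_TONES = {
    "S": (10.0, 80.0),
    "fD1": (12.5, 80.0),
    "fD2": (7.5, 80.0),
    "iD1": (10.0, 90.0),
    "iD2": (10.0, 70.0),
}


@dataclass(frozen=True)
class ToneSpec:
    """A single pure tone.

    Parameters
    ----------
    frequency_khz : float
        Tone frequency in kHz; must lie in (0, 50] (the modelled hearing range).
    level_db : float
        Sound level in dB SPL; 80 dB maps to peak amplitude 1.
    duration_ms : float
        Tone duration in milliseconds, > 0.
    onset_s : float
        Tone onset in seconds relative to trial zero (first-tone onset).
    """

    frequency_khz: float
    level_db: float
    duration_ms: float = TONE_DURATION_MS
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency_khz <= 50.0):
            raise ValueError(f"frequency must lie in (0, 50] kHz, got {self.frequency_khz}")
        if not self.duration_ms > 0:
            raise ValueError("duration must be positive")
        if not np.isfinite(self.level_db):
            raise ValueError("level must be finite")


STANDARD_TONE = ToneSpec(STANDARD_FREQ_KHZ, STANDARD_LEVEL_DB, TONE_DURATION_MS, 0.0)


@dataclass
class TrialAudio:
    """Rendered audio for one trial window.

    ``waveform`` holds amplitude samples at 100 kHz on the inclusive grid
    t = -0.1 + k / 100000, k = 0..110000 (110 001 samples).
    """

    waveform: np.ndarray
    condition: str | None = None
    rate: float = AUDIO_RATE
    window: tuple[float, float] = WINDOW

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.waveform.size) / self.rate


@dataclass
class Cochleagram:
    """STFT magnitude features: 101 frequency bins x 111 frames.

    ``magnitudes[k, j]`` is the magnitude at frequency ``k * 0.5`` kHz in the
    frame centred on ``-0.1 + j / 100`` s.  All entries are nonnegative.
    """

    magnitudes: np.ndarray
    frame_rate: float = FRAME_RATE
    bin_frequencies_khz: np.ndarray = field(
        default_factory=lambda: np.arange(N_BINS) * BIN_SPACING_KHZ
    )

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.shape[0] != N_BINS:
            raise ValueError(f"expected {N_BINS} frequency bins, got {self.magnitudes.shape[0]}")

    @property
    def frame_times(self) -> np.ndarray:
        return WINDOW[0] + np.arange(self.magnitudes.shape[1]) / self.frame_rate


def amplitude_from_level(level_db: float) -> float:
    """Linear peak amplitude for a sound level in dB SPL.

    Levels are normalised so that an 80-dB tone has peak amplitude 1, hence
    ``10 ** ((level - 80) / 20)``; strictly increasing in level.
    """
    level_db = float(level_db)
    if not np.isfinite(level_db):
        raise ValueError("level must be finite")
    return float(10.0 ** ((level_db - STANDARD_LEVEL_DB) / 20.0))


def trial_time_grid(rate: float = AUDIO_RATE, window: tuple[float, float] = WINDOW) -> np.ndarray:
    """Inclusive-end sample times for the trial window at ``rate``."""
    n = int(round((window[1] - window[0]) * rate)) + 1
    return window[0] + np.arange(n) / rate


def synthesize_tone(
    spec: ToneSpec, fs: float = AUDIO_RATE, window: tuple[float, float] = WINDOW
) -> np.ndarray:
    """Render a single pure tone into the trial window.

    The tone is a zero-initial-phase sine, ``A sin(2 pi f (t - onset))`` with
    ``A = amplitude_from_level(level)``, nonzero only on
    ``onset <= t < onset + duration``; no onset/offset ramps are applied.
    """
    freq_hz = spec.frequency_khz * 1000.0
    if freq_hz >= fs / 2:
        raise ValueError(f"tone frequency {freq_hz} Hz would alias at fs={fs} Hz")
    t = trial_time_grid(fs, window)
    amp = amplitude_from_level(spec.level_db)
    on = (t >= spec.onset_s - 1e-12) & (t < spec.onset_s + spec.duration_ms / 1000.0 - 1e-12)
    wave = np.zeros_like(t)
    wave[on] = amp * np.sin(2 * np.pi * freq_hz * (t[on] - spec.onset_s))
    return wave


def build_trial_audio(first_tone: ToneSpec, condition: str | None = None) -> TrialAudio:
    """Assemble the two-tone trial: ``first_tone`` at 0 s, then the standard.

    The second tone is always the 10-kHz, 80-dB, 100-ms standard with onset at
    0.55 s (100-ms first tone plus the constant 450-ms offset-to-onset gap).
    """
    if first_tone.onset_s != 0.0:
        raise ValueError("first tone onset must be 0 s")
    second = ToneSpec(
        STANDARD_FREQ_KHZ, STANDARD_LEVEL_DB, TONE_DURATION_MS, SECOND_TONE_ONSET_S
    )
    wave = synthesize_tone(first_tone) + synthesize_tone(second)
    return TrialAudio(waveform=wave, condition=condition)


def condition_trial_audio(condition: str) -> TrialAudio:
    """Two-tone trial audio for one of the five named stimulus conditions."""
    if condition not in CONDITION_TONES:
        raise ValueError(f"unknown condition {condition!r}")
    freq, level = CONDITION_TONES[condition]
    return build_trial_audio(ToneSpec(freq, level, TONE_DURATION_MS, 0.0), condition)


def cochleagram(audio: TrialAudio | np.ndarray, rate: float = AUDIO_RATE) -> Cochleagram:
    """STFT magnitude cochleagram of a trial waveform.

    Hann-windowed 200-sample segments (2 ms at 100 kHz) give frequency bins
    at exact multiples of 0.5 kHz from 0 to 50 kHz (101 bins).  The native
    100-sample hop corresponds to a 1000-Hz frame sequence; frames are
    subsampled by 10 so that frame centres land exactly on the analysis grid
    -0.1, -0.09, ..., 1.0 s (111 frames).  Segments overrunning the signal
    edges are zero-padded.
    """
    if isinstance(audio, TrialAudio):
        if audio.rate != AUDIO_RATE:
            raise ValueError(f"audio must be sampled at {AUDIO_RATE} Hz")
        wave = np.asarray(audio.waveform, dtype=float)
    else:
        if rate != AUDIO_RATE:
            raise ValueError(f"audio must be sampled at {AUDIO_RATE} Hz")
        wave = np.asarray(audio, dtype=float)

    nseg = 200
    half = nseg // 2
    win = hann(nseg, sym=False)
    hop = int(AUDIO_RATE / FRAME_RATE)  # 1000 samples between retained frames
    n_frames = (wave.size - 1) // hop + 1
    padded = np.concatenate([np.zeros(half), wave, np.zeros(half)])
    centres = np.arange(n_frames) * hop
    # windowed segments centred on each retained frame time
    idx = centres[:, None] + np.arange(nseg)[None, :]
    segs = padded[idx] * win
    mags = np.abs(np.fft.rfft(segs, axis=1)).T  # (101, n_frames)
    return Cochleagram(magnitudes=mags)


def condition_cochleagrams() -> dict[str, Cochleagram]:
    """Cochleagrams for all five stimulus conditions, keyed by condition."""
    return {c: cochleagram(condition_trial_audio(c)) for c in CONDITIONS}
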