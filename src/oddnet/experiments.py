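"""Simulated probe experiments on a trained model.

Single pure tones sweeping duration (100-500 ms at 10 kHz / 80 dB),
frequency (5-15 kHz at 100 ms / 80 dB) or intensity (60-100 dB at
100 ms / 10 kHz) are rendered in the standard -0.1..1.0 s window with no
trailing standard, converted to cochleagrams and fed to the model.  From
each output waveform the onset peak (most negative value between tone
onset and 100 ms past tone offset), the offset peak (most positive value
in the 100 ms after tone offset) and the mean over the long-latency
window 0.25-0.55 s are extracted.  Qualitative checks encode the
neurophysiological expectations: offset-peak latency grows with duration,
onset-peak magnitude grows with level, and louder-than-standard tones
drive the long-latency window upward.  The frequency sweep is reported
without assertion — a model trained only on the oddball set has no reason
to generalise across frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rnn_model import TrainedHierarchicalRNN
from .stimuli import (
    STANDARD_FREQ_KHZ,
    STANDARD_LEVEL_DB,
    TONE_DURATION_MS,
    ToneSpec,
    cochleagram,
    synthesize_tone,
)

SWEEP_VALUES = {
    "duration": (100.0, 200.0, 300.0, 400.0, 500.0),  # ms
    "frequency": (5.0, 7.5, 10.0, 12.5, 15.0),  # kHz
    "intensity": (60.0, 70.0, 80.0, 90.0, 100.0),  # dB
}

LONG_LATENCY_WINDOW = (0.25, 0.55)


@dataclass(frozen=True)
class ProbeSweep:
    """One probe family; non-swept parameters stay at the standard tone's."""

    kind: str
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in SWEEP_VALUES:
            raise ValueError(f"kind must be one of {sorted(SWEEP_VALUES)}")
        if not self.values:
            object.__setattr__(self, "values", SWEEP_VALUES[self.kind])

    def tones(self) -> list[ToneSpec]:
        out = []
        for v in self.values:
            freq, level, dur = STANDARD_FREQ_KHZ, STANDARD_LEVEL_DB, TONE_DURATION_MS
            if self.kind == "duration":
                dur = v
            elif self.kind == "frequency":
                freq = v
            else:
                level = v
            out.append(ToneSpec(freq, level, dur, 0.0))
        return out


@dataclass
class ProbeReport:
    """Model responses and extracted features for one sweep.

    ``waveforms`` is (n_probes, 111); ``features`` has one row per probe
    with onset/offset peak amplitudes and latencies and the long-latency
    window mean.
    """

    sweep: ProbeSweep
    waveforms: np.ndarray
    features: pd.DataFrame
    times: np.ndarray = field(repr=False, default=None)


def run_probe_sweep(model: TrainedHierarchicalRNN, sweep: ProbeSweep | str) -> ProbeReport:
    """Present each probe tone alone and extract response features."""
    sweep = ProbeSweep(sweep) if isinstance(sweep, str) else sweep
    waves, rows = [], []
    t = None
    for value, tone in zip(sweep.values, sweep.tones()):
        coch = cochleagram(synthesize_tone(tone))
        y = model.forward(coch.magnitudes)
        t = coch.frame_times
        dur_s = tone.duration_ms / 1000.0
        on_win = (t >= 0) & (t <= dur_s + 0.1)
        off_win = (t > dur_s) & (t <= dur_s + 0.1)
        late = (t >= LONG_LATENCY_WINDOW[0]) & (t <= LONG_LATENCY_WINDOW[1])
        i_on = np.flatnonzero(on_win)[np.argmin(y[on_win])]
        i_off = np.flatnonzero(off_win)[np.argmax(y[off_win])]
        waves.append(y)
        rows.append(
            {"value": value,
             "onset_peak": float(y[i_on]), "onset_latency_s": float(t[i_on]),
             "offset_peak": float(y[i_off]), "offset_latency_s": float(t[i_off]),
             "long_latency_mean": float(y[late].mean())}
        )
    return ProbeReport(
        sweep=sweep, waveforms=np.stack(waves), features=pd.DataFrame(rows), times=t
    )


def qualitative_checks(reports: dict[str, ProbeReport]) -> pd.DataFrame:
    """Evaluate the stereotypical-response expectations on sweep reports.

    Checks (evaluated only when the relevant sweep is present):
    (a) duration: offset-peak latency strictly increasing in duration;
    (b) intensity: onset-peak magnitude nondecreasing in level;
    (c) intensity: long-latency mean for 90 and 100 dB above that for 80 dB.
    The result is reported, not asserted — an untrained model simply fails.
    """
    rows = []
    if "duration" in reports:
        lat = reports["duration"].features["offset_latency_s"].to_numpy()
        rows.append(
            {"check": "offset_latency_increases_with_duration",
             "passed": bool(np.all(np.diff(lat) > 0)),
             "detail": np.array2string(lat, precision=3)}
        )
    if "intensity" in reports:
        feats = reports["intensity"].features
        mag = -feats["onset_peak"].to_numpy()  # onset is negative-going
        rows.append(
            {"check": "onset_magnitude_nondecreasing_with_level",
             "passed": bool(np.all(np.diff(mag) >= 0)),
             "detail": np.array2string(mag, precision=3)}
        )
        late = feats.set_index("value")["long_latency_mean"]
        if {80.0, 90.0, 100.0} <= set(late.index):
            rows.append(
                {"check": "louder_tones_drive_long_latency_positive",
                 "passed": bool((late[90.0] > late[80.0]) and (late[100.0] > late[80.0])),
                 "detail": np.array2string(late.to_numpy(), precision=3)}
            )
    return pd.DataFrame(rows)
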