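"""Epoch pipeline: band-pass filter, baseline correction, resampling,
standard-trial balancing, and assembly of the idealised training set.

The processing order mirrors the recording pipeline: signals are band-pass
filtered between 0.1 and 30 Hz at the native 1000-Hz rate, epochs are
baseline-corrected by subtracting the mean over the 0.1-s pre-stimulus
window, and then resampled to 100 Hz (111 samples over -0.1..1.0 s).  To
balance trial numbers, only standards immediately preceding a deviant are
retained (200 per animal per paradigm), leaving 200 S + 100 D1 + 100 D2
per paradigm.  Averaging corresponding trials across animals and across
the two channels yields the 800-trial "idealised experiment" used to train
the recurrent model, and per-condition grand averages serve as its
evaluation references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfreqz

from .stimuli import CONDITIONS, WINDOW, Cochleagram, condition_cochleagrams
from .synthetic_data import GLOBAL_CONDITION, PARADIGMS, OddballSequence, SyntheticEpochs

DEVIANTS = ("D1", "D2")


@dataclass
class EpochedTrials:
    """Labelled epochs: ``amplitudes[trial, channel, time]``.

    Interchangeable with :class:`~oddnet.synthetic_data.SyntheticEpochs`;
    this alias exists so downstream code can be explicit that preprocessing
    has been applied.
    """

    amplitudes: np.ndarray
    labels: pd.DataFrame
    rate: float
    window: tuple[float, float] = WINDOW

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.amplitudes.shape[-1]) / self.rate


def _as_epochs(trials: SyntheticEpochs | EpochedTrials) -> EpochedTrials:
    return EpochedTrials(trials.amplitudes, trials.labels, trials.rate, trials.window)


def bandpass_filter(
    trials: SyntheticEpochs | EpochedTrials, low: float = 0.1, high: float = 30.0
) -> EpochedTrials:
    """Zero-phase 0.1-30 Hz band-pass with a 4th-order Butterworth response.

    The squared Butterworth magnitude response (the forward-backward
    response of separate 4th-order high- and low-pass designs) is applied
    in the frequency domain after reflecting the epoch at both edges.  On
    1.1-s epochs a forward-backward IIR high-pass at 0.1 Hz is numerically
    pathological — its settling time exceeds the epoch and its padding
    transients *amplify* broadband noise several-fold — whereas the
    frequency-domain form realises the same magnitude response exactly and
    with zero phase at any epoch length.
    """
    if trials.rate <= 2 * high:
        raise ValueError(f"sampling rate {trials.rate} too low for {high} Hz passband edge")
    amp = np.asarray(trials.amplitudes, dtype=float)
    n = amp.shape[-1]
    pad = min(n - 1, int(trials.rate))  # one-second edge reflection
    ext = np.concatenate(
        [amp[..., pad:0:-1], amp, amp[..., -2 : -2 - pad : -1]], axis=-1
    )
    freqs = np.fft.rfftfreq(ext.shape[-1], d=1.0 / trials.rate)
    hp = butter(4, low, btype="high", fs=trials.rate, output="sos")
    lp = butter(4, high, btype="low", fs=trials.rate, output="sos")
    resp = np.ones_like(freqs)
    for sos in (hp, lp):
        _, h = sosfreqz(sos, worN=freqs, fs=trials.rate)
        resp *= np.abs(h) ** 2  # forward-backward: squared magnitude, zero phase
    filtered = np.fft.irfft(np.fft.rfft(ext, axis=-1) * resp, n=ext.shape[-1], axis=-1)
    out = _as_epochs(trials)
    out.amplitudes = filtered[..., pad : pad + n]
    return out


def baseline_correct(trials: SyntheticEpochs | EpochedTrials) -> EpochedTrials:
    """Subtract each trial/channel's mean over the pre-stimulus window (t < 0)."""
    if trials.window[0] >= 0:
        raise ValueError("window must include pre-stimulus samples")
    t = trials.times
    pre = t < 0
    amp = np.asarray(trials.amplitudes, dtype=float)
    amp = amp - amp[..., pre].mean(axis=-1, keepdims=True)
    out = _as_epochs(trials)
    out.amplitudes = amp
    return out


def resample_to(trials: SyntheticEpochs | EpochedTrials, rate: float = 100.0) -> EpochedTrials:
    """Resample to ``rate`` by subsampling; 111 samples over -0.1..1.0 s.

    The native rate must be an integer multiple of ``rate``; output sample k
    is the native sample at t = -0.1 + k / rate.  An exclusive-end native
    grid (missing t = +1.0) repeats its final sample for the last output.
    Plain subsampling is exact for the band-limited signals this pipeline
    produces (the 30-Hz low-pass precedes it).
    """
    ratio = trials.rate / rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"native rate {trials.rate} not an integer multiple of {rate}")
    ratio = int(round(ratio))
    n_in = trials.amplitudes.shape[-1]
    n_out = int(round((trials.window[1] - trials.window[0]) * rate)) + 1
    idx = np.arange(n_out) * ratio
    if n_in == (n_out - 1) * ratio:  # exclusive-end convention
        idx[-1] = n_in - 1
    elif n_in < (n_out - 1) * ratio + 1:
        raise ValueError(f"{n_in} native samples cannot cover the window at {rate} Hz")
    out = _as_epochs(trials)
    out.amplitudes = np.asarray(trials.amplitudes)[..., idx]
    out.rate = rate
    return out


def preprocess(trials: SyntheticEpochs | EpochedTrials, rate: float = 100.0) -> EpochedTrials:
    """Full stage order: band-pass filter, baseline-correct, resample."""
    return resample_to(baseline_correct(bandpass_filter(trials)), rate)


def retained_standard_indices(sequence: OddballSequence) -> np.ndarray:
    """Sequence positions of standards immediately preceding a deviant."""
    labs = sequence.labels
    return np.array(
        [i for i in range(len(labs) - 1) if labs[i] == "S" and labs[i + 1] in DEVIANTS],
        dtype=int,
    )


def select_balanced_standards(
    sequence: OddballSequence, trials: SyntheticEpochs | EpochedTrials
) -> EpochedTrials:
    """Balance one animal/paradigm block: keep deviants plus the standards
    that immediately precede a deviant (200 for the full 800/100/100 design).
    """
    labels = trials.labels
    if len(labels) != len(sequence):
        raise ValueError("sequence and trials are misaligned")
    seq_labels = np.array(sequence.labels)
    if not np.array_equal(labels["local_condition"].to_numpy(), seq_labels):
        raise ValueError("trial labels do not match the sequence")
    keep_std = set(retained_standard_indices(sequence).tolist())
    pos = labels["sequence_index"].to_numpy()
    mask = np.array(
        [lab in DEVIANTS or p in keep_std for lab, p in zip(seq_labels, pos)]
    )
    out = _as_epochs(trials)
    out.amplitudes = trials.amplitudes[mask]
    out.labels = labels.loc[mask].reset_index(drop=True)
    return out


def balance_cohort(cohort: SyntheticEpochs | EpochedTrials) -> EpochedTrials:
    """Apply standard-trial balancing per (animal, paradigm) block.

    The sequence is reconstructed from the ``local_condition`` /
    ``sequence_index`` labels when the epochs object does not carry the
    realised :class:`OddballSequence` objects.
    """
    labels = cohort.labels
    sequences = getattr(cohort, "sequences", None) or {}
    masks = []
    for (animal, paradigm), grp in labels.groupby(["animal", "paradigm"], sort=True):
        seq = sequences.get((animal, paradigm))
        if seq is None:
            order = grp.sort_values("sequence_index")
            seq = OddballSequence(tuple(order["local_condition"]), paradigm)
        keep_std = set(retained_standard_indices(seq).tolist())
        m = grp.apply(
            lambda r: r["local_condition"] in DEVIANTS or r["sequence_index"] in keep_std,
            axis=1,
        )
        masks.append(pd.Series(m.to_numpy(), index=grp.index))
    mask = pd.concat(masks).sort_index().to_numpy()
    out = _as_epochs(cohort)
    out.amplitudes = cohort.amplitudes[mask]
    out.labels = labels.loc[mask].reset_index(drop=True)
    return out


@dataclass
class IdealizedDataset:
    """The 800-trial idealised experiment.

    ``targets[i]`` is the i-th cross-animal, cross-channel average trial
    (111 samples); its input cochleagram is
    ``unique_inputs[input_index[i]]`` — one of the five condition
    cochleagrams.  ``labels`` carries paradigm, condition and the
    within-condition occurrence order used for cross-animal pairing.
    """

    targets: np.ndarray
    labels: pd.DataFrame
    input_index: np.ndarray
    unique_inputs: dict[str, Cochleagram] = field(default_factory=dict)
    conditions: tuple[str, ...] = CONDITIONS
    rate: float = 100.0

    @property
    def n_trials(self) -> int:
        return self.targets.shape[0]

    @property
    def inputs(self) -> np.ndarray:
        """Materialised inputs, shape (n_trials, 101, 111)."""
        stack = np.stack([self.unique_inputs[c].magnitudes for c in self.conditions])
        return stack[self.input_index]


def build_idealized_dataset(
    balanced: EpochedTrials, inputs: dict[str, Cochleagram] | None = None
) -> IdealizedDataset:
    """Average balanced trials across animals and channels into 800 trials.

    Trials are paired across animals by within-(paradigm, condition)
    occurrence order — the only index the animals share.  Every animal must
    contribute the same trial counts.  Inputs are attached by condition
    (the S cochleagram serves both paradigms' standards).
    """
    if balanced.rate != 100.0:
        raise ValueError("idealised dataset expects 100-Hz preprocessed trials")
    labels = balanced.labels
    animals = sorted(labels["animal"].unique())
    amp = np.asarray(balanced.amplitudes, dtype=float).mean(axis=1)  # channel average
    inputs = inputs if inputs is not None else condition_cochleagrams()

    targets: list[np.ndarray] = []
    rows: list[dict] = []
    idx: list[int] = []
    for paradigm in PARADIGMS:
        for local in ("S", "D1", "D2"):
            cond = GLOBAL_CONDITION[(paradigm, local)]
            per_animal = []
            for a in animals:
                sel = labels.index[
                    (labels["animal"] == a)
                    & (labels["paradigm"] == paradigm)
                    & (labels["local_condition"] == local)
                ].to_numpy()
                order = np.argsort(labels.loc[sel, "sequence_index"].to_numpy(), kind="stable")
                per_animal.append(amp[sel[order]])
            counts = {p.shape[0] for p in per_animal}
            if len(counts) != 1:
                raise ValueError(
                    f"unequal {paradigm}/{local} trial counts across animals: {sorted(counts)}"
                )
            mean_trials = np.mean(per_animal, axis=0)  # (n_occ, n_times)
            c_idx = CONDITIONS.index(cond)
            for occ, wave in enumerate(mean_trials):
                targets.append(wave)
                rows.append({"paradigm": paradigm, "condition": cond, "occurrence": occ})
                idx.append(c_idx)
    return IdealizedDataset(
        targets=np.asarray(targets),
        labels=pd.DataFrame(rows),
        input_index=np.asarray(idx, dtype=int),
        unique_inputs=inputs,
        rate=balanced.rate,
    )


@dataclass
class GrandAverage:
    """Per-condition mean waveforms (5 x 111); S pooled across paradigms."""

    waveforms: dict[str, np.ndarray]
    rate: float = 100.0

    def as_array(self) -> np.ndarray:
        return np.stack([self.waveforms[c] for c in CONDITIONS])

    def to_frame(self) -> pd.DataFrame:
        n = next(iter(self.waveforms.values())).size
        t = WINDOW[0] + np.arange(n) / self.rate
        return pd.DataFrame({"time_s": t, **{c: self.waveforms[c] for c in CONDITIONS}})


def grand_average(dataset: IdealizedDataset | EpochedTrials) -> GrandAverage:
    """Condition means of the idealised trials (or of channel-averaged epochs)."""
    if isinstance(dataset, IdealizedDataset):
        amp = dataset.targets
        conds = dataset.labels["condition"].to_numpy()
        rate = dataset.rate
    else:
        amp = np.asarray(dataset.amplitudes, dtype=float).mean(axis=1)
        conds = dataset.labels["condition"].to_numpy()
        rate = dataset.rate
    waveforms = {c: amp[conds == c].mean(axis=0) for c in CONDITIONS}
    return GrandAverage(waveforms=waveforms, rate=rate)


def expected_frame_count(rate: float = 100.0) -> int:
    """Samples on the inclusive -0.1..1.0 s grid (111 at 100 Hz, = N_FRAMES)."""
    return int(round((WINDOW[1] - WINDOW[0]) * rate)) + 1
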