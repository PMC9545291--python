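"""Synthetic oddball sequences and epoched evoked-potential cohorts.

This module stands in for the in-vivo recordings: it generates, per animal
and per oddball paradigm (frequency / intensity), the full 1000-stimulus
sequence (800 standards, 100 increasing deviants D1, 100 decreasing
deviants D2, no two deviants adjacent) and realises every stimulus as an
epoched two-channel trial on the native 1000-Hz grid over -0.1..1.0 s.

Each trial is the condition's noise-free template — a sum of Gaussian
"component" bumps emulating the grand-average morphology (onset
negativity, offset positivity, a long-latency positive "danger" bump for
fD1/fD2/iD1, a late positive bump after the rising-level transition in
iD2, and a subtle negative "safety" dip over 0.6-0.8 s) — scaled by
animal-specific per-component gains, plus an ~10-Hz background oscillation
with random phase and white noise.  Noise is white at the native rate; the
0.1-30 Hz band-pass stage in :mod:`oddnet.preprocessing` band-limits it.

Everything is driven by a single seed through ``numpy.random.Generator``
spawning, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimuli import CONDITIONS, SECOND_TONE_ONSET_S, TONE_DURATION_MS, WINDOW

PARADIGMS = ("frequency", "intensity")

NATIVE_RATE = 1000.0

#: Map (paradigm, local label) -> global condition name.
GLOBAL_CONDITION = {
    ("frequency", "S"): "S",
    ("frequency", "D1"): "fD1",
    ("frequency", "D2"): "fD2",
    ("intensity", "S"): "S",
    ("intensity", "D1"): "iD1",
    ("intensity", "D2"): "iD2",
}


@dataclass(frozen=True)
class OddballSequence:
    """Ordered stimulus labels for one oddball block."""

    labels: tuple[str, ...]
    paradigm: str = "frequency"

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"S", "D1", "D2"}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {k: self.labels.count(k) for k in ("S", "D1", "D2")}


def generate_oddball_sequence(
    n_s: int = 800,
    n_d1: int = 100,
    n_d2: int = 100,
    seed: int | np.random.Generator = 0,
    paradigm: str = "frequency",
) -> OddballSequence:
    """Random oddball sequence with no two deviants adjacent.

    Each deviant is slotted into the position immediately following a
    distinct standard (so the sequence starts with a standard and deviants
    are always separated by at least one standard); slots and D1/D2
    identities are drawn uniformly.  Requires ``n_s >= n_d1 + n_d2``.
    """
    n_d = n_d1 + n_d2
    if n_s < n_d:
        raise ValueError("need at least as many standards as deviants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slots = rng.choice(n_s, size=n_d, replace=False)  # deviant follows standard `slot`
    kinds = np.array(["D1"] * n_d1 + ["D2"] * n_d2)
    rng.shuffle(kinds)
    after = {int(s): k for s, k in zip(slots, kinds)}
    labels: list[str] = []
    for i in range(n_s):
        labels.append("S")
        if i in after:
            labels.append(after[i])
    return OddballSequence(tuple(labels), paradigm)


@dataclass(frozen=True)
class ERPComponentSpec:
    """One Gaussian ERP component.

    ``latency`` (s) is the bump centre, ``width`` (s) its standard
    deviation, ``base_amplitude`` its signed peak in arbitrary units, and
    ``modulation`` maps each of the five global conditions to a gain.
    """

    name: str
    latency: float
    width: float
    base_amplitude: float
    modulation: dict[str, float]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        missing = set(CONDITIONS) - set(self.modulation)
        if missing:
            raise ValueError(f"modulation missing conditions {missing}")


def _onset_gain(condition: str) -> float:
    # obligatory response gain: monotone in level, mildly modulated by frequency
    return {"S": 1.0, "fD1": 1.1, "fD2": 0.9, "iD1": 1.5, "iD2": 0.6}[condition]


def default_component_specs() -> list[ERPComponentSpec]:
    """Default component set reproducing the qualitative evoked morphology.

    Onset negativity peaks 30 ms after each tone onset and offset
    positivity 30 ms after each tone offset; the long-latency positive
    (danger) bump at 0.38 s follows fD1/fD2/iD1; a subtle negative (safety)
    dip at 0.70 s follows the return to the standard after those deviants;
    and the rising-level transition in iD2 (70-dB tone then 80-dB standard)
    adds a late positive bump at 0.88 s.
    """
    on1 = {c: _onset_gain(c) for c in CONDITIONS}
    off1 = dict(on1)
    ones = {c: 1.0 for c in CONDITIONS}
    t_on2 = SECOND_TONE_ONSET_S
    t_off1 = TONE_DURATION_MS / 1000.0
    t_off2 = t_on2 + TONE_DURATION_MS / 1000.0
    return [
        ERPComponentSpec("onset1", 0.03, 0.015, -1.0, on1),
        ERPComponentSpec("offset1", t_off1 + 0.03, 0.015, 0.8, off1),
        ERPComponentSpec("onset2", t_on2 + 0.03, 0.015, -1.0, ones),
        ERPComponentSpec("offset2", t_off2 + 0.03, 0.015, 0.8, ones),
        ERPComponentSpec(
            "danger", 0.38, 0.06, 0.6,
            {"S": 0.0, "fD1": 1.0, "fD2": 0.9, "iD1": 1.1, "iD2": 0.0},
        ),
        ERPComponentSpec(
            "safety", 0.70, 0.05, -0.35,
            {"S": 0.0, "fD1": 0.5, "fD2": 1.0, "iD1": 1.0, "iD2": 0.0},
        ),
        ERPComponentSpec(
            "late_rise", 0.88, 0.07, 0.5,
            {"S": 0.0, "fD1": 0.0, "fD2": 0.0, "iD1": 0.0, "iD2": 1.0},
        ),
    ]


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    ``trial_noise_sd`` is the white-noise SD at the native rate (a.u.);
    after the 0.1-30 Hz band-pass it shrinks to roughly a quarter of this.
    ``animal_effect_sd`` is the SD of the per-animal multiplicative gain
    (mean 1) applied independently to each ERP component.
    ``alpha_amplitude`` is the peak of the ~10-Hz background rhythm
    relative to the unit onset peak.
    """

    n_animals: int = 14
    n_channels: int = 2
    native_rate: float = NATIVE_RATE
    trial_noise_sd: float = 2.5
    animal_effect_sd: float = 0.1
    alpha_amplitude: float = 0.2
    alpha_freq: float = 10.0
    n_standards: int = 800
    n_d1: int = 100
    n_d2: int = 100
    component_specs: list[ERPComponentSpec] = field(default_factory=default_component_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("group statistics need at least 2 animals")
        if min(self.trial_noise_sd, self.animal_effect_sd, self.alpha_amplitude) < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class SyntheticEpochs:
    """Epoched cohort: ``amplitudes[trial, channel, time]`` plus labels.

    ``labels`` has one row per trial with columns ``animal``, ``paradigm``,
    ``condition`` (global: S/fD1/fD2/iD1/iD2), ``local_condition``
    (S/D1/D2) and ``sequence_index``.  ``sequences`` maps
    ``(animal, paradigm)`` to the realised :class:`OddballSequence`.
    """

    amplitudes: np.ndarray
    labels: pd.DataFrame
    rate: float = NATIVE_RATE
    window: tuple[float, float] = WINDOW
    sequences: dict[tuple[int, str], OddballSequence] = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.amplitudes.shape[-1]) / self.rate

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    def select(self, mask: np.ndarray) -> "SyntheticEpochs":
        """Subset of trials; labels keep their original content, reindexed."""
        return replace(
            self,
            amplitudes=self.amplitudes[mask],
            labels=self.labels.loc[np.asarray(mask)].reset_index(drop=True),
        )


def time_grid(rate: float = NATIVE_RATE, window: tuple[float, float] = WINDOW) -> np.ndarray:
    """Inclusive-end time grid over the trial window."""
    n = int(round((window[1] - window[0]) * rate)) + 1
    return window[0] + np.arange(n) / rate


def erp_template(
    condition: str,
    paradigm: str | None = None,
    specs: list[ERPComponentSpec] | None = None,
    rate: float = NATIVE_RATE,
    gains: dict[str, float] | None = None,
) -> np.ndarray:
    """Noise-free single-channel template for one condition.

    The template is the sum of Gaussian bumps
    ``base_amplitude * modulation[condition] * exp(-(t - latency)^2 / (2 width^2))``;
    ``gains`` optionally multiplies each named component (used for
    animal-specific effects).  ``condition`` may be a local label
    (S/D1/D2, with ``paradigm`` given) or a global one.
    """
    if condition not in CONDITIONS:
        condition = GLOBAL_CONDITION[(paradigm, condition)]
    if specs is None:
        specs = default_component_specs()
    t = time_grid(rate)
    wave = np.zeros_like(t)
    for comp in specs:
        g = comp.modulation[condition] * (1.0 if gains is None else gains.get(comp.name, 1.0))
        if g == 0.0:
            continue
        wave += comp.base_amplitude * g * np.exp(-0.5 * ((t - comp.latency) / comp.width) ** 2)
    return wave


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticEpochs:
    """Simulate the full cohort; deterministic given ``config.seed``.

    For each animal and paradigm a fresh oddball sequence is drawn and every
    stimulus becomes one trial:
    ``template(condition; animal gains) + alpha rhythm (shared across the
    two channels, random phase per trial) + white noise (independent per
    channel)``.
    """
    cfg = config or CohortConfig()
    root = np.random.default_rng(cfg.seed)
    # independent child streams: one per (animal, paradigm)
    children = root.spawn(cfg.n_animals * len(PARADIGMS) + cfg.n_animals)
    t = time_grid(cfg.native_rate)
    n_t = t.size

    blocks: list[np.ndarray] = []
    rows: list[dict] = []
    sequences: dict[tuple[int, str], OddballSequence] = {}
    comp_names = [c.name for c in cfg.component_specs]

    for a in range(cfg.n_animals):
        gain_rng = children[cfg.n_animals * len(PARADIGMS) + a]
        gains = {
            name: 1.0 + cfg.animal_effect_sd * gain_rng.standard_normal()
            for name in comp_names
        }
        templates = {
            c: erp_template(c, specs=cfg.component_specs, rate=cfg.native_rate, gains=gains)
            for c in CONDITIONS
        }
        for p_i, paradigm in enumerate(PARADIGMS):
            rng = children[a * len(PARADIGMS) + p_i]
            seq = generate_oddball_sequence(
                cfg.n_standards, cfg.n_d1, cfg.n_d2, rng, paradigm
            )
            sequences[(a, paradigm)] = seq
            n = len(seq)
            conds = [GLOBAL_CONDITION[(paradigm, lab)] for lab in seq.labels]
            base = np.stack([templates[c] for c in conds])  # (n, n_t)
            phases = rng.uniform(0, 2 * np.pi, size=n)
            alpha = cfg.alpha_amplitude * np.sin(
                2 * np.pi * cfg.alpha_freq * t[None, :] + phases[:, None]
            )
            trials = (base + alpha)[:, None, :] + cfg.trial_noise_sd * rng.standard_normal(
                (n, cfg.n_channels, n_t)
            )
            blocks.append(trials.astype(np.float32))
            rows.extend(
                {
                    "animal": a,
                    "paradigm": paradigm,
                    "condition": c,
                    "local_condition": lab,
                    "sequence_index": i,
                }
                for i, (lab, c) in enumerate(zip(seq.labels, conds))
            )

    amplitudes = np.concatenate(blocks, axis=0)
    labels = pd.DataFrame(rows)
    return SyntheticEpochs(
        amplitudes=amplitudes, labels=labels, rate=cfg.native_rate, sequences=sequences
    )
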