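import numpy as np
import pandas as pd
import pytest

from oddnet import preprocessing as pp
from oddnet.preprocessing import (
    EpochedTrials,
    balance_cohort,
    bandpass_filter,
    baseline_correct,
    build_idealized_dataset,
    grand_average,
    resample_to,
    retained_standard_indices,
    select_balanced_standards,
)
from oddnet.synthetic_data import (
    CohortConfig,
    OddballSequence,
    generate_oddball_sequence,
    simulate_cohort,
)


def _epochs(x, rate=1000.0):
    x = np.atleast_3d(np.asarray(x, dtype=float))
    labels = pd.DataFrame(
        {"animal": 0, "paradigm": "frequency", "condition": "S",
         "local_condition": "S", "sequence_index": np.arange(x.shape[0])}
    )
    return EpochedTrials(x, labels, rate)


def _grid(rate=1000.0):
    n = int(round(1.1 * rate)) + 1
    return -0.1 + np.arange(n) / rate


class TestBandpassFilter:
    def test_passband_tone_preserved(self):
        t = _grid()
        y = bandpass_filter(_epochs(np.sin(2 * np.pi * 10 * t)[None, None])).amplitudes[0, 0]
        mid = slice(200, 900)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.1)

    def test_stopband_tone_removed(self):
        t = _grid()
        y = bandpass_filter(_epochs(np.sin(2 * np.pi * 100 * t)[None, None])).amplitudes[0, 0]
        assert np.abs(y[200:900]).max() < 0.1  # >= 90% attenuation

    def test_zero_in_zero_out(self):
        y = bandpass_filter(_epochs(np.zeros((1, 1, 1101)))).amplitudes
        np.testing.assert_allclose(y, 0, atol=1e-12)

    def test_design_attenuation_on_long_signal(self):
        # 20-dB contract points checked where the frequencies are resolvable
        rate = 1000.0
        t = np.arange(int(400 * rate)) / rate
        for freq, limit in ((0.01, 0.1), (60.0, 0.1)):
            x = np.sin(2 * np.pi * freq * t)
            tr = EpochedTrials(x[None, None], pd.DataFrame(), rate, (-0.1, t[-1] - 0.1))
            y = bandpass_filter(tr).amplitudes[0, 0]
            interior = slice(int(100 * rate), int(300 * rate))
            assert np.abs(y[interior]).max() < limit, freq

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_epochs(np.zeros((1, 1, 10)), rate=50.0))


class TestBaselineCorrect:
    def test_constant_shift_invariance(self, rng):
        x = rng.standard_normal((4, 2, 1101))
        shifted = baseline_correct(_epochs(x + 7.3)).amplitudes
        plain = baseline_correct(_epochs(x)).amplitudes
        np.testing.assert_allclose(shifted, plain, atol=1e-10)

    def test_idempotent_and_zero_baseline(self, rng):
        x = rng.standard_normal((4, 2, 1101))
        once = baseline_correct(_epochs(x))
        t = once.times
        assert np.abs(once.amplitudes[..., t < 0].mean(axis=-1)).max() < 1e-10
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.amplitudes, twice.amplitudes, atol=1e-12)


class TestResample:
    def test_inclusive_grid_gives_111_samples(self, rng):
        out = resample_to(_epochs(rng.standard_normal((2, 1, 1101))))
        assert out.amplitudes.shape[-1] == 111
        assert out.rate == 100.0

    def test_exclusive_end_grid_accepted(self, rng):
        out = resample_to(_epochs(rng.standard_normal((2, 1, 1100))))
        assert out.amplitudes.shape[-1] == 111

    def test_constant_preserved(self):
        out = resample_to(_epochs(np.full((1, 1, 1101), 3.5)))
        np.testing.assert_allclose(out.amplitudes, 3.5)

    def test_sine_fidelity(self):
        t = _grid()
        out = resample_to(_epochs(np.sin(2 * np.pi * 5 * t)[None, None]))
        expected = np.sin(2 * np.pi * 5 * out.times)
        assert np.abs(out.amplitudes[0, 0] - expected).max() < 0.05

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            resample_to(_epochs(np.zeros((1, 1, 1101))), rate=300.0)

    def test_stage_order_insensitive_on_smooth_data(self):
        """Baseline-then-resample vs resample-then-baseline agree closely on
        smooth band-limited input (regression guard on the pipeline order)."""
        t = _grid()
        x = np.exp(-0.5 * ((t - 0.3) / 0.05) ** 2)[None, None] + 0.2
        a = resample_to(baseline_correct(_epochs(x))).amplitudes
        b = baseline_correct(resample_to(_epochs(x))).amplitudes
        assert np.abs(a - b).max() < 1e-6


class TestBalancing:
    def test_direct_rule_application(self):
        seq = OddballSequence(("S", "D1", "S", "S", "D2"))
        assert retained_standard_indices(seq).tolist() == [0, 3]

    def test_retained_equals_deviant_count(self):
        seq = generate_oddball_sequence(800, 100, 100, seed=2)
        assert retained_standard_indices(seq).size == 200

    def test_select_balanced_standards(self, rng):
        seq = generate_oddball_sequence(20, 3, 2, seed=4)
        n = len(seq)
        x = rng.standard_normal((n, 2, 111))
        labels = pd.DataFrame(
            {"animal": 0, "paradigm": "frequency",
             "condition": ["S" if l == "S" else f"f{l}" for l in seq.labels],
             "local_condition": list(seq.labels), "sequence_index": np.arange(n)}
        )
        trials = EpochedTrials(x, labels, 100.0)
        out = select_balanced_standards(seq, trials)
        assert (out.labels["local_condition"] != "S").sum() == 5  # deviants untouched
        assert (out.labels["local_condition"] == "S").sum() == 5
        # deviant trial data unchanged
        for _, row in out.labels[out.labels["local_condition"] != "S"].iterrows():
            i = row["sequence_index"]
            np.testing.assert_array_equal(
                out.amplitudes[out.labels["sequence_index"] == i][0], x[i]
            )

    def test_misaligned_labels_rejected(self, rng):
        seq = OddballSequence(("S", "D1", "S"))
        labels = pd.DataFrame(
            {"animal": 0, "paradigm": "frequency", "condition": ["S"] * 3,
             "local_condition": ["S", "S", "S"], "sequence_index": [0, 1, 2]}
        )
        with pytest.raises(ValueError):
            select_balanced_standards(seq, EpochedTrials(rng.standard_normal((3, 1, 5)), labels, 100.0))

    def test_cohort_balancing_counts(self, small_balanced, small_config):
        n_dev = small_config.n_d1 + small_config.n_d2
        counts = small_balanced.labels.groupby(["animal", "paradigm"]).size()
        assert (counts == 2 * n_dev).all()  # retained S + deviants = 2*(d1+d2)


class TestIdealizedDataset:
    def test_composition(self, default_idealized):
        ds = default_idealized
        assert ds.n_trials == 800
        comp = ds.labels.groupby(["paradigm", "condition"]).size().to_dict()
        assert comp[("frequency", "S")] == 200
        assert comp[("frequency", "fD1")] == 100
        assert comp[("intensity", "iD2")] == 100
        assert ds.inputs.shape == (800, 101, 111)

    def test_single_animal_single_channel_identity(self, rng):
        cfg = CohortConfig(
            n_animals=2, n_channels=1, n_standards=8, n_d1=2, n_d2=2,
            trial_noise_sd=0.0, animal_effect_sd=0.0, alpha_amplitude=0.0, seed=1,
        )
        bal = balance_cohort(pp.preprocess(simulate_cohort(cfg)))
        ds = build_idealized_dataset(bal)
        one_animal = bal.amplitudes[bal.labels["animal"] == 0][:, 0]
        # noise-free: every animal's trials equal the template, so the mean does too
        cond0 = ds.labels.iloc[0]
        assert ds.targets.shape[1] == 111
        np.testing.assert_allclose(
            ds.targets[:one_animal.shape[0]].mean(), one_animal.mean(), rtol=1e-6
        )

    def test_noise_reduction_by_averaging(self):
        """Idealised-trial noise shrinks like sigma / sqrt(2 * n_animals)."""
        noisy = CohortConfig(
            n_animals=8, n_standards=20, n_d1=4, n_d2=4, trial_noise_sd=1.0,
            animal_effect_sd=0.0, alpha_amplitude=0.0, seed=3,
        )
        ds8 = build_idealized_dataset(balance_cohort(pp.preprocess(simulate_cohort(noisy))))
        from oddnet.synthetic_data import erp_template

        resid = []
        for cond in ("S", "fD1"):
            sel = (ds8.labels["condition"] == cond) & (ds8.labels["paradigm"] == "frequency")
            r = ds8.targets[sel.to_numpy()] - erp_template(cond)[::10]
            resid.append(r[:, 20:90].std())
        # preprocessed single-trial noise sd measured directly
        pre = pp.preprocess(simulate_cohort(noisy))
        trial_sd = (pre.amplitudes[:, :, 20:90]
                    - np.mean(pre.amplitudes[:, :, 20:90], axis=0)).std()
        expected = trial_sd / np.sqrt(2 * 8)
        assert np.mean(resid) == pytest.approx(expected, rel=0.35)

    def test_unequal_counts_rejected(self, small_balanced):
        crippled = EpochedTrials(
            small_balanced.amplitudes[:-1], small_balanced.labels.iloc[:-1].reset_index(drop=True),
            small_balanced.rate,
        )
        with pytest.raises(ValueError):
            build_idealized_dataset(crippled)


class TestGrandAverage:
    def test_shapes_and_pooling(self, default_idealized):
        ga = grand_average(default_idealized)
        assert ga.as_array().shape == (5, 111)
        # S waveform equals the mean of the pooled standards from both paradigms
        sel = (default_idealized.labels["condition"] == "S").to_numpy()
        np.testing.assert_allclose(
            ga.waveforms["S"], default_idealized.targets[sel].mean(axis=0), atol=1e-12
        )

    def test_weighted_mean_identity(self, default_idealized):
        ds = default_idealized
        ga = grand_average(ds)
        counts = ds.labels["condition"].value_counts()
        weighted = sum(ga.waveforms[c] * counts[c] for c in counts.index) / counts.sum()
        np.testing.assert_allclose(weighted, ds.targets.mean(axis=0), atol=1e-10)

    def test_identical_trials_average_to_any(self):
        cfg = CohortConfig(
            n_animals=2, n_standards=6, n_d1=1, n_d2=1, trial_noise_sd=0.0,
            animal_effect_sd=0.0, alpha_amplitude=0.0, seed=1,
        )
        ds = build_idealized_dataset(balance_cohort(pp.preprocess(simulate_cohort(cfg))))
        ga = grand_average(ds)
        sel = (ds.labels["condition"] == "fD1").to_numpy()
        np.testing.assert_allclose(ga.waveforms["fD1"], ds.targets[sel][0], atol=1e-6)
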