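# Methods

`oddnet` re-implements, as a tested and reusable pipeline, the analysis of
mouse auditory-cortex oddball responses: synthetic epoched evoked
potentials stand in for the in-vivo recordings, and the downstream stages
— time-resolved decoding with cluster-based permutation statistics, and a
hierarchical recurrent network fitted to an "idealised experiment" —
operate on them exactly as they would on real data.

## Stimulus model and cochleagrams

Trials pair two 100-ms pure tones with a constant 450-ms offset-to-onset
gap. The first tone is the standard (10 kHz, 80 dB SPL) or one of four
deviants (±2.5 kHz; ±10 dB); the second is always the standard, so the
five conditions are S, fD1, fD2, iD1, iD2. Levels map to amplitude as
`10^((L−80)/20)` (80 dB ↦ 1). Audio is rendered at 100 kHz on the
inclusive grid −0.1…1.0 s (110 001 samples); tones are un-ramped
zero-phase sines, silent elsewhere.

The model input is the magnitude of a Hann-windowed STFT (200-sample
segments, 100-sample overlap), evaluating 0–50 kHz at 0.5-kHz spacing
(101 bins). The native 1000-Hz frame sequence is subsampled by 10 with
frame centres pinned to −0.1, −0.09, …, 1.0 s, giving exactly 111 frames;
segments overrunning the signal are zero-padded. Magnitudes carry no
normalisation constant — any fixed scaling is absorbed by the network's
input weights. Plain subsampling (not low-pass decimation) keeps the
frame decimation bit-reproducible.

## Synthetic cohort generator

The generator emulates what the downstream analyses assume about the
recordings, not their biophysics. Per animal (default 14) and per
paradigm, a 1000-stimulus oddball sequence (800 S, 100 D1, 100 D2) is
drawn by slotting each deviant directly after a distinct standard, which
enforces the design constraints (no two deviants adjacent, sequence
starts with a standard) and makes the retained-standard count exactly
equal the deviant count.

Each stimulus becomes one two-channel trial on the native 1000-Hz grid:

* a noise-free condition **template**: a sum of Gaussian bumps — onset
  negativity 30 ms after each tone onset (gain increasing with level,
  mildly modulated by frequency), offset positivity 30 ms after each
  offset, a long-latency positive bump at 0.38 s (SD 60 ms) for fD1, fD2
  and iD1, a subtle negative dip at 0.70 s after those same deviants, and
  a late positive bump at 0.88 s in iD2 trials where the following
  standard is a rising-level transition;
* an **animal effect**: one multiplicative gain per component,
  `N(1, 0.1)`, preserving template geometry within animal;
* a ~10-Hz background rhythm (amplitude 0.2 of the unit onset peak,
  random phase per trial, shared by both channels);
* white noise, SD 2.5 at 1000 Hz, independent per channel. After the
  0.1–30 Hz band-pass this leaves a per-trial SD of ≈0.58, i.e. a
  single-trial SNR below 1 for the long-latency component — group-mean
  decoding then peaks around 0.65–0.75, the regime typical of epidural
  oddball recordings.

All randomness flows from one seed through spawned NumPy generators;
identical configs give bit-identical cohorts. What the generator does
**not** model: volume conduction, channel covariance, non-stationarity,
latency jitter, 1/f background spectra. Passing tests therefore
demonstrate correctness and calibration of the *analyses*, not fidelity
of the simulated biology.

## Preprocessing

Stage order: band-pass filter → baseline correction → resample →
balancing. The band-pass has the squared magnitude response of cascaded
4th-order Butterworth high- (0.1 Hz) and low-pass (30 Hz) designs and is
applied in the frequency domain with one-second edge reflection. A
forward-backward IIR high-pass at 0.1 Hz is unusable on 1.1-s epochs —
its settling time exceeds the epoch and the padding transients *amplify*
broadband noise several-fold — whereas the frequency-domain form realises
the same zero-phase response exactly at any epoch length.

Baseline correction subtracts the pre-stimulus (t < 0) mean per trial and
channel. Resampling to 100 Hz takes every 10th native sample on the
inclusive grid (111 samples); the 30-Hz low-pass has already band-limited
the data, so subsampling is alias-free. An exclusive-end native grid
(1100 samples) is accepted by repeating its final sample.

Balancing keeps deviants plus only those standards that immediately
precede a deviant (200 per animal per paradigm). The idealised dataset
averages corresponding trials across animals and both channels, pairing
trials by within-(paradigm, condition) occurrence order — the only index
animals share; the result is 800 trials (2 × (200 S + 100 D1 + 100 D2))
with the five condition cochleagrams attached as inputs. Grand averages
pool S across both paradigms (400 trials), since the model knows a single
S condition.

## Decoding

Per animal, a linear SVM (C = 1, no kernel) classifies two condition sets
from the two channel amplitudes at each time sample. The larger class is
randomly under-sampled to equality; stratified 10-fold cross-validation
is repeated 5 times with fresh under-sampling and fold allocation; the
accuracy is the mean over all fold × repeat cells. Features are z-scored
per time sample with training-fold statistics, which makes accuracies
invariant to common amplitude rescaling. Temporal generalisation
evaluates each trained classifier at every test time within the same
splits, so its diagonal reproduces the time-wise map. Prediction ties
(score exactly 0) go to class A.

The SVM is solved in the package itself: the LinearSVC objective
(L2-regularised squared hinge, bias as an augmented regularised feature)
is minimised by a safeguarded active-set Newton method vectorised over
all 111 time points of a fold at once. The objective is strongly convex
and piecewise quadratic, so a handful of Newton steps reaches machine
precision; a unit test pins the solutions to scikit-learn's LinearSVC.
One scikit-learn fit per time point costs ~3 ms of per-call overhead,
i.e. ~16 s per animal and contrast — two orders of magnitude more than
the whole-fold solve. Seeds ladder from one master seed to
per-(animal, repeat) children, so animals are independent and every map
is reproducible.

## Cluster-based permutation statistics

Group inference on accuracy maps uses one-sample t statistics of
(accuracy − chance) across animals at each grid point. Points with
two-sided p < α (α = 0.05, also the cluster-forming threshold) form
candidate clusters — contiguous runs in 1-D, 4-connected components in
2-D — separately for positive and negative t, with cluster mass the sum
of t inside. The null records the maximal |mass| over both signs for each
of 1000 random sign-flips of the per-animal difference maps, and cluster
p-values use the +1 correction `(1 + #{null ≥ |mass|}) / (1 + n_perm)`,
so p ≥ 1/(n_perm + 1) always. Calibration is verified empirically: on 500
pure-noise cohorts (14 × 111) the family-wise error rate falls in
[0.03, 0.08], and an injected +0.15 accuracy bump over a 16-sample window
is recovered (≥80 % cluster coverage) in ≥95 % of datasets. MNE's
implementation of the same test serves as an independent oracle in the
suite.

## Hierarchical recurrent network

Four stacked simple-recurrent layers of 64 rectified units receive the
101 STFT bins; a single linear recurrent unit produces the output:

    h_t^(l) = relu(W_l x_t^(l) + U_l h_{t−1}^(l) + b_l),  h_0 = 0
    y_t     = w·h_t^(4) + u y_{t−1} + c

The rectifier is chosen because exact-zero "zero units" arise naturally
under it and are implausible under saturating odd activations; the output
unit is linear because evoked-potential targets are signed. Input weights
are Glorot-uniform, recurrent matrices orthogonal (QR of a
standard-normal matrix with sign correction), biases zero.

Training minimises MSE between the 111-sample output and the idealised
targets with Adam (lr 10⁻³, β₁ = 0.9, β₂ = 0.99, ε = 10⁻⁸) over shuffled
minibatches of 32 for 500 epochs (the full protocol); forward pass, BPTT
and Adam are implemented in NumPy, and fixed seeds make training
bit-reproducible. Targets stay in raw amplitude units — no
normalisation. Because the idealised set contains only five distinct
input cochleagrams, each minibatch is grouped by unique input and the
forward/backward pass runs once per unique input with the aggregated
output-error gradient; this is algebraically identical to the per-trial
computation and is what makes CPU training practical (~0.35 s/epoch).

Architecture generalisation is checked by 10-fold cross-validation
stratified by (paradigm, condition) — each fold holds back 10 % of every
stimulus type (80 trials). The reported experiment trains five identical
models with consecutive seeds and selects the one maximising mean r²
(squared Pearson correlation between output and grand-average waveform
per condition), breaking ties by lower mean MSE. On the default synthetic
cohort the winner reaches mean r² ≈ 0.94 after 150 epochs; the acceptance
check runs this 150-epoch setting with its correspondingly relaxed bound
(0.85) to keep the suite inside a desktop time budget.

## Unit taxonomy, PCA and entropy

Each of the 256 hidden units is categorised per condition from its
111-sample activation trace by a fixed cascade: **zero** (identically
zero), **alpha** (global peak before stimulus onset, or a pre-stimulus
sample above trace mean + 3 SD with post-stimulus peak < half the
pre-stimulus peak), **onset** (peak within [0, 0.1] ∪ [0.55, 0.65] s),
**offset** ((0.1, 0.15] ∪ (0.65, 0.7]), **safety** ((0.15, 0.25] ∪
(0.7, 0.8]), **danger** ((0.25, 0.55]), else **other**. Peaks are global
argmaxes (earliest sample on ties); window boundaries belong to the
earlier category; the alpha-rule statistics use the unit's full trace.
The unit's modal label is the most frequent per-condition category, ties
broken by cascade order.

Sample entropy follows Richman–Moorman with m = 2 and tolerance
r × SD(series), r = 0.15 (the bare r is interpreted as a fraction of the
series SD, the standard convention): with B and A the ordered
template-pair counts at lengths m and m + 1 (i ≠ j, both restricted to
the first N − m templates), the estimate is −ln(A/B). Conventions:
constant series → 0 (the unmodified estimator would give
ln((N−m)/(N−m−1)) ≠ 0); A = 0 with B > 0 → the maximal defined value
ln B; B = 0 → 0. The implementation is pinned to a brute-force double
loop to 10⁻¹². Entropy summaries count zero-entropy units per layer ×
condition, average the nonzero-entropy units, and report per-category
mean ± SD with each unit's entropy first averaged over conditions; empty
cells are NaN, never 0.

Three PCA projections (2 components, feature-mean-centred) summarise the
activation tensor: conditions (5 × 28 416), layers (4 × 35 520) and, per
layer, units (64 × 555). A matrix with zero variance (e.g. a model whose
responses are condition-independent) returns zero scores and explained
variance rather than NaN.

## Probe experiments

Probe tones are presented alone (no trailing standard) in the standard
window: durations 100–500 ms (10 kHz, 80 dB), frequencies 5–15 kHz
(100 ms, 80 dB), levels 60–100 dB (100 ms, 10 kHz). From each output
waveform the onset peak (most negative value from tone onset to 100 ms
past offset), offset peak (most positive value in the 100 ms after
offset) and the 0.25–0.55-s window mean are extracted. The qualitative
expectations — offset latency strictly increasing with duration, onset
magnitude non-decreasing with level, louder-than-standard tones driving
the long-latency window positive — are evaluated and reported; the
frequency sweep is reported without assertion, since a model trained only
on the oddball set has no reason to generalise across frequency. On the
default trained model all asserted checks pass.

## Orchestration and reproducibility

The `oddnet` CLI runs the stages (`simulate`, `preprocess`, `decode`,
`stats`, `fit`, `analyze`, `probe`, `all`) from a YAML config; every
output directory carries a `manifest.json` with the master seed and a
hash of the resolved config, and reruns with the same config produce
byte-identical CSV outputs. Problem sizes in the test suite are the
study design sizes except where noted (the ensemble check runs 150
epochs; unit tests use miniature cohorts), chosen so the whole suite
completes comfortably on a single CPU.

## Known limitations

* The generator's noise and effect amplitudes are declared defaults, not
  estimates from the recordings; no claim is made that they match in-vivo
  SNR, and the real-data headline numbers (cross-validation MSE,
  best-model r²/MSE, unit counts, entropy medians) are out of scope.
* The idealised-average pairing by occurrence order is one consistent
  reading of "averaging the trials from all of the animals"; any pairing
  of within-condition trials yields the same grand averages.
* Whether accuracies should be pooled over folds before or after repeats
  is unspecified in the source protocol; the mean over all fold × repeat
  cells is used.
* Layer-exclusivity of danger-category units is logged by the analysis
  but not asserted: with a synthetic cohort it may be architecture- or
  data-driven, and the package does not attempt to settle that.
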