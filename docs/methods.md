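# Methods

## Problem

`eegid` implements closed-set personal identification from short spans of
resting-state EEG. A cohort of O enrolled subjects each contributes one or two
one-minute resting recordings (eyes-open, eyes-closed) of C scalp channels at
a fixed sample rate (160 Hz for the public motor-movement/imagery corpus the
tool targets). The system learns a per-subject signature from sub-second
windows of the raw signal and, at identification time, assigns a 0.5 s probe
to one of the O identities. The same trained classifier doubles as an
authenticator: thresholding the posterior probability of a claimed identity
yields false-acceptance/false-rejection trade-offs and an equal error rate.

## Model

The classifier is a convolutional network whose first stage encodes the
standard blind-source-separation view of scalp EEG. Observed channels are
modelled as an instantaneous linear mixture X = A·S of latent cortical
sources S; a learnable separation matrix W maps each time-point's channel
vector into source space, Y = W·X, and is optimized end-to-end by
backpropagation rather than by a classical ICA contrast (no independence
objective, no whitening — the "ICA stage" is exactly a bias-free linear layer
on the channel axis). The default source count is 64 regardless of the input
montage size.

For an input window of P time-points × C channels (one plane):

| stage | output | details |
|---|---|---|
| channel mix | (1, P, 64) | linear C→64, no bias |
| conv 1 | (32, P/2, 64) | 5×3 kernel, stride (2,1), pad (2,1), ELU |
| pool 1 | (32, P/4, 64) | max 2×1 |
| conv 2 | (32, P/4, 64) | 3×3, stride 1, pad 1, ELU |
| pool 2 | (32, P/4, 32) | max 1×2 |
| conv 3 | (32, P/4, 32) | 3×3, stride 1, pad 1, ELU |
| pool 3 | (32, P/8, 32) | max 2×1 |
| fc 1 | 512 | after flatten (32·(P/8)·32 wide) |
| dropout | 512 | p = 0.5 |
| fc 2 | O | log-softmax output |

P must be divisible by 8 (three temporal halvings). Training minimizes the
mean cross-entropy of the log-normalized scores with Adam (learning rate
3·10⁻³, batch 64, seeded shuffling, no schedule, no early stopping); the
final-epoch weights are the enrolled model. Dropout follows the first fully
connected layer only. The loss is averaged (not summed) over the batch; the
class index of the cross-entropy runs over the O enrolled labels.

The network, backpropagation and Adam are implemented in NumPy. Layers run
channels-last internally; convolution evaluates as one matrix product per
kernel offset (or a single im2col product when the contraction is small),
and the elementwise ELU/Adam inner loops JIT-compile via numba when
available, with an equivalent pure-NumPy fallback. Gradient correctness is
asserted against central differences in the test suite. Weights initialize
uniformly in ±1/√fan_in from a seeded generator; identical seeds reproduce
identical runs on one platform (cross-platform bit-reproducibility is not
promised).

## Preprocessing

No filtering, artifact rejection or re-referencing. The only preprocessing is
per-subject Z-score standardization: μ and σ are pooled over *all* of a
subject's values — every channel, every time-point, and every session
included in the experiment (both sessions under the union protocol, one
otherwise) — and each value becomes (x−μ)/σ. σ is the population
(divide-by-N) standard deviation; at these pool sizes the Bessel correction
is immaterial, but the choice is fixed for reproducibility. By default the
statistics are computed on the full recording before the train/test temporal
split, matching the pipeline order in which preprocessing precedes division;
the mild leakage this admits (two scalar moments) is documented, and
`strict_stats=True` in `run_experiment` restricts the pool to the training
spans instead. A constant (σ = 0) recording is rejected as degenerate.

## Sliding-window augmentation

A window of L seconds with stride S ≤ L slides from offset 0 of each
train/test span; the trailing remainder is discarded, so a span of T samples
yields floor((T−L)/S)+1 windows. S = L gives plain fixed windows; the
"sliding ratio" S/L of 0.5 gives 50% overlap, the setting that drives the
accuracy gains. Each window is stored time-major (P × C) so the convolution
kernels' first axis is temporal. Dense class labels are assigned by
lexicographic subject-id sort for cross-run determinism. Under the reference
protocol (109 subjects, first 48 s at 160 Hz) the window/ratio grid
{0.25, 0.5, 1, 2} s × {0.5, 1} reproduces the documented training-set sizes
(e.g. 20819 for 0.5 s / ratio 0.5) exactly; this is asserted in the tests.

## Protocols

*Hold-out (augmentation grid):* per recording, the first 48 s train and the
last 12 s test. *k-fold cross-validation (channel-selection experiment):*
fold i tests the i-th contiguous 1/k block of every recording (60 s → 12 s
folds at k = 5) and trains on the rest, over eyes-open, eyes-closed, or
their union (both sessions pooled per subject, session kept as metadata).
Folds are contiguous temporal blocks rather than shuffled segments: windows
are cut *after* the split inside each interval, and with overlapping windows
temporal blocks are the only construction that keeps training windows from
covering test samples. A leakage check over the interval arithmetic runs on
every plan. Fold metrics aggregate as mean ± population (ddof = 0) standard
deviation, the convention that reproduces the published per-fold values'
printed aggregate.

Recordings whose header rate differs from the expected 160 Hz are excluded
by default (`off_rate_policy="exclude"`); `"resample"` (polyphase) and
`"keep"` are available, since the public corpus contains a few
irregular-rate subjects and the reference protocol does not specify their
handling.

## Evaluation

*Rank-1*: percent of test windows whose argmax class is the true identity
(ties, a measure-zero event for float scores, break to the lowest class
index). *Authentication*: the claim-score construction is the natural one
for a closed-set softmax classifier — every test window claims every
enrolled identity and the match score is the posterior probability of the
claimed class, giving one genuine and O−1 impostor trials per window. At
threshold θ, FAR(θ) = % impostor scores ≥ θ and FRR(θ) = % genuine scores
< θ; sweeping every distinct score (plus a sentinel above the maximum)
traces the DET curve, and the EER is read at the FAR = FRR crossing with
linear interpolation between the bracketing thresholds. The EER is invariant
to monotone rescaling of the scores and the curves are monotone in θ by
construction; both properties are asserted.

## Synthetic cohorts

The generator emulates the generative assumption the architecture targets:
per subject, n_sources latent sinusoids with subject-specific frequencies
(uniform in 4–30 Hz, the theta/alpha/beta band), amplitudes (uniform
0.5–1.5) and per-session phases, plus per-source broadband noise
(sd 0.1), mixed by a subject-specific Gaussian matrix A into n_channels
observed channels, plus white sensor noise scaled to `noise_sd` × signal
RMS (default 0.25). Identity lives in both A and the source spectra and is
shared across sessions; phases and noise are redrawn per session. All
randomness derives from one master seed via per-(subject, session) seed
sequences, so fixtures are reproducible independently of generation order.

Default cohort: 8 subjects, 14 channels, 60 s at 160 Hz, 6 sources. These
are desk-scale study conditions: with the 0.5 s/0.25 s window and 48 s/12 s
split the pipeline reaches test Rank-1 ≥ 90% and EER ≤ 10% (in practice
100%/0% — the cohort is strongly separable), and mean accuracy over seeds
does not rise as `noise_sd` grows through 0.25/1.0/4.0. Training for that
check uses 10 epochs, fixed from a convergence trace (loss < 10⁻⁴ and
perfect held-out accuracy from the first epochs on this cohort).

What passing on synthetic data does *not* show: real resting EEG is
nonstationary, noisy, artifact-laden and far less linearly separable; the
published 109-subject accuracies require the real corpus and GPU-scale
training (2000 epochs) and are out of scope here. The synthetic check
validates the machinery — preprocessing, windowing, optimization, metrics —
not the real-data performance level. The generator makes no physiological
realism claims (no 1/f background, no artifacts, no inter-session drift).

Cohorts can be exported as EDF through a minimal built-in 16-bit writer
(one-second records, microvolt physical dimension, per-channel ranges
widened 5% so quantization error stays below 0.1% of signal RMS) in the
PhysioNet-style `S001/S001R01.edf` layout, and read back with the
`mne`-based reader, which normalizes the corpus's dotted channel labels
("Fc5." → FC5).

## Montages

`EPOC14` is the 14-electrode consumer-headset layout; `FULL64` is the
64-channel 10-10 set of the public corpus. The 32-channel `FLEX32` list is
documented only as a scalp plot in the source material; the list shipped
here is a standard 32-electrode 10-10 subset satisfying every stated
constraint (exactly 32 labels, includes FT7/TP7/TP8/FT8, subset of the 64)
and should be treated as an approximation. Montage order, not file order,
fixes the network's input-channel assignment.

## Numerical choices and edge cases

- float32 training; float64 for preprocessing statistics and score/EER
  arithmetic (the 10⁻⁹-level moment and sweep guarantees hold in float64).
- Pool ties take the earlier element; argmax ties the lowest index.
- A span shorter than one window yields zero segments with a warning, not an
  error; a non-integer window/stride at the recording's rate is an error.
- Checkpoints (`ICAConvNet.save/load`) restore bit-identical evaluation
  outputs and carry the model config, label map and subject statistics.
- `SegmentedDataset.save/load` round-trips bit-exactly (npz + JSON sidecar).

## Experiment configuration (CLI)

`eegid run-experiment --config cfg.yaml [--out dir]` where the YAML may hold:

```yaml
data:
  edf_dir: path/to/cohort        # or:
  synthetic: {n_subjects: 8, n_channels: 14, seed: 7}
sessions: [EO]                   # subset of EO, EC
protocol: {holdout: {train_s: 48, test_s: 12}}   # or {k: 5}
montage: EPOC14                  # optional; null = use all channels
window: {length_s: 0.5, stride_s: 0.25}
train: {epochs: 50, batch_size: 64, learning_rate: 3.0e-3, seed: 1}
model: {}                        # ModelConfig overrides, e.g. n_sources
strict_stats: false
expected_rate: 160.0
off_rate_policy: exclude
```

`eegid synth` writes a synthetic EDF cohort; `eegid segment-count` prints the
window-count bookkeeping for a protocol.

## Known limitations

- Closed-set only: no open-set rejection, no score normalization, no
  cross-session fusion.
- The 2000-epoch, 109-subject reference training is supported but not
  exercised anywhere in the shipped tests; desk-scale runs use the synthetic
  cohort.
- Single-platform determinism only; BLAS differences across platforms can
  change low-order bits and hence long training trajectories.
- EDF support covers plain 16-bit EDF (no EDF+ annotations or event
  triggers).
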