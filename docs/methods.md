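# Methods

`eegaug` implements an EEG classification pipeline for discriminating
Alzheimer's disease (AD), mild cognitive impairment (MCI), and healthy
controls (HC), with three minority-class data-augmentation strategies.
This note records the models, the parameters that matter, what the
synthetic data does and does not emulate, and the design choices made
where the design was genuinely open.

## Signal model of the synthetic cohort

Real resting-state EEG in AD shows *spectral slowing*: delta (1–4 Hz) and
theta (4–8 Hz) power rise while alpha (8–13 Hz), beta (13–30 Hz) and gamma
(30–50 Hz) power fall, with MCI intermediate. The generator emulates
exactly this. Each channel is a unit-variance Gaussian mixture

```
x(t) = √0.15 · pink(t)  +  Σ_b √(0.60 · s_b · g_b) · n_b(t)  +  √(0.25 · g_α) · a(t)
```

scaled to `amplitude_uv` (default 20 µV RMS), where `pink` is
1/f^a-shaped noise (a = 1), `n_b` is unit-RMS Gaussian noise band-limited
to band *b* by the same Butterworth edges the feature extractor uses,
`s_b` is the band's share of the 1/f integral, `g_b` the class's relative
band-power gain, and `a(t)` a 2 Hz-wide oscillation at the class's alpha
peak (10 / 9.5 / 9 Hz for HC / MCI / AD). Channels share one common
component with convex power weight 0.2, giving weak (~0.2) inter-channel
correlation. Class gains: HC all 1.0; AD delta/theta 1.8, alpha/beta
0.55, gamma 0.7; MCI the per-band geometric midpoint. Every component is
RMS-normalized before weighting, so doubling a gain doubles that band's
power up to estimation error.

Default cohort composition mirrors a severely imbalanced clinical
population (102 HC / 7 MCI / 59 AD at 256 Hz); per-subject seeds derive
deterministically from the cohort seed, so generation is bit-reproducible.

What the generator does **not** emulate: artifacts (blinks, EMG, line
noise), any spatial/topographic structure (channels are statistically
exchangeable), non-stationarity, age/sex/severity covariates, and
inter-subject variability beyond the sampling noise of the mixture. Tests
passing on this cohort therefore demonstrate that the pipeline recovers a
known spectral-slowing effect under class imbalance — not that the
reported real-data accuracies transfer. With the default gains the
synthetic classes are in fact *more* separable than real clinical EEG:
most task/method cells saturate at accuracy 1.0, and the interesting
regime is the minority-class condition (e.g. 40 HC / 5 MCI subjects),
where the unaugmented baseline drops below 1.0 and augmentation shows a
measurable benefit.

## Preprocessing

Zero-phase (forward–backward) Butterworth band-pass at 1–50 Hz, polyphase
rational resampling to 128 Hz, segmentation into consecutive
non-overlapping epochs of 5, 10 or 15 s starting at sample 0 (trailing
remainder discarded), and optional peak-to-peak epoch rejection standing
in for interactive artifact-cleaning tools. The filter order is 8: the
pass is applied forward and backward so the effective magnitude response
is |H|², and order 8 is the smallest standard choice that attenuates a
60 Hz tone below 10 % RMS through the 1–50 Hz band (order 4 leaves ~19 %).
Non-overlapping epochs keep examples statistically independent for the
split logic.

## Features (152 per epoch)

Per channel: average Welch PSD in each of the five canonical bands
(5 × 19 = 95 spectral features) plus mean, population variance, and
zero-crossing rate (3 × 19 = 57 statistical features). Welch uses 2-s
Hann segments at 50 % overlap (0.5 Hz resolution, so delta holds ≥ 6
bins at 128 Hz), constant detrend. Band edges 1/4/8/13/30/50 Hz are
half-open `[lo, hi)` with gamma closed at 50, so the five bands partition
[1, 50] exactly and band-integrated power is conserved to machine
precision. "Band-average PSD" is the arithmetic mean of PSD bins in the
band (the band integral is available separately for the conservation
check). The ZCR counts adjacent sample pairs with strictly opposite sign
over len−1, zeros inheriting the previous nonzero sign; leading zeros
carry no sign and never produce a crossing (for a full sine cycle sampled
at 64 points this counts the single interior crossing, 1/63 — the
boundary crossing at sample 0 has no preceding sample).

## Augmentation

**Noise addition.** An artificial epoch is a uniformly drawn real epoch of
the target class plus zero-mean Gaussian noise. The standalone method
calibrates σ to the class: since band-passed EEG is effectively
zero-mean, the "class mean" is read as the rectified grand mean E|x|
(floored at 10⁻⁶ µV); for a zero-mean Gaussian class this equals
σ·√(2/π). The hybrid method's noise arm instead uses a fixed
σ = 0.001 µV.

**Conditional convolutional VAE.** Implemented directly in NumPy (im2col
convolutions, manual backpropagation, Adam) so training is deterministic
and dependency-free. Epochs are standardized per channel by training-set
statistics. The diagnostic label is appended as one-hot constant channels
(conditioning). Encoder: two temporal convolutions (16 then 32 filters,
kernel 3, stride 4 each) with ReLU, then dense heads for the latent mean
and log-variance (latent dimension 16). The reparameterization trick
samples the latent; the decoder mirrors the encoder (dense →
upsample ×4 + convolution, twice). Temporal (1-D) convolutions with the
19 electrodes as input channels are used rather than 2-D image
convolutions: electrode order carries no meaningful 3-tap spatial
neighborhood, and the 1-D form halves CPU cost.

Loss: per-element mean squared reconstruction error plus β times the
Gaussian KL divergence −½Σ(1 + logσ² − µ² − σ²). Because the
reconstruction term is a per-element *mean* over ~2.4×10⁴ elements, the
ELBO-consistent KL weight is of order 1/n_elements; β defaults to
2.5×10⁻⁴ (sample quality is flat across 10⁻⁵–10⁻³). Defaults: 100
training epochs, batch 32, Adam at 10⁻³; the repeated-trial experiments
use 30 training epochs per trial to keep a 20-trial run in minutes on
one CPU core.

**Variance-calibrated sampling.** MSE-trained decoders under-disperse:
raw prior samples had about a third of the data's RMS, with arbitrary
per-channel scale scatter. Sampling therefore rescales each generated
channel so its standard deviation matches the class-conditional
per-channel standard deviation of the standardized training data (a
two-moment correction using training statistics only), then
de-standardizes back to microvolts. This makes artificial epochs
amplitude-realistic; with it, the mean band-power profile of 100
generated MCI epochs correlates at ~0.88–0.90 with the training profile
across seeds (~0.75–0.81 without).

During development, fixed sinusoidal carrier channels in the decoder and
KL warm-up annealing were evaluated and rejected (no fidelity gain:
time-domain MSE penalizes fixed-phase content), as were finer
convolution strides (they inflate high-band power in samples).

**Hybrid.** Concatenates noise-arm and VAE-arm epochs; when balancing, a
class deficit is split half noise (rounding up), half VAE.

**Balancing policy.** Each minority class is raised to the majority-class
epoch count of the training set; the number of generated examples is
never specified externally. Augmentation runs strictly after splitting
and only ever touches the training set (validation/test content hashes
are logged every trial so this is auditable).

## Evaluation protocol

Subject-level 70:12:18 train/validation/test splits, stratified by
diagnosis with largest-remainder rounding per class (ties to the earlier
set). Stratification is not strictly required by the protocol but
without it small-cohort splits can leave a set with no minority
subjects, making minority-class metrics undefined; epoch-level splitting
is available for a literal per-example reading. A fixed per-class test
composition (the study's 3 MCI / 30 HC / 17 AD subjects) can be forced.
The validation set is reserved (unused by default).

Four tasks: 3-class (MCI vs AD vs HC), MCI vs HC, AD vs MCI, and
AD+MCI vs HC (AD and MCI pooled as one positive class). Classifier:
feature-wise standardization by training statistics, then an RBF-kernel
SVM with C = 1 and kernel width 1/(d·Var) — standard defaults, since the
pipeline's claims are comparative across augmentation methods, not
absolute. Metrics: accuracy and macro-averaged F1 (the unweighted
per-class mean, the natural choice under imbalance; used for the 3-class
task as well). Each experiment repeats over independent re-splits with
trial seeds derived from a master seed; a repeated run with the same
master seed is byte-identical down to the results CSV. Failed cells are
recorded and skipped in aggregation rather than aborting the run.

Problem sizes used by the repeated-trial experiments and the acceptance
script: 60 s per synthetic subject, 10-s epochs, 10 trials for the
balanced 20 HC / 20 AD effect-recovery check and 20 trials for the
40 HC / 5 MCI augmentation-benefit check, with 30 VAE training epochs per
trial — sizes chosen so a full run completes in a few minutes on one CPU
core while keeping ≥ 150 training epochs per trial.

## I/O

Recordings travel as EDF (16-bit; the writer emits one-second data
records with per-channel physical ranges set to the data extremes, so
round trips agree to ≲10⁻³ relative). Reading uses MNE. Between stages
epochs are stored losslessly in a schema-tagged NumPy archive. Results
CSVs render floats at 4 decimals so reruns are byte-identical.

## Known limitations

* The VAE captures the class's second-order (spectral/amplitude)
  structure, not higher-order or transient dynamics; its samples are
  smoother than real epochs.
* No spatial model: generator channels are exchangeable, so
  topography-sensitive behavior is untested.
* The 19-channel montage and band edges are fixed conventions; other
  montages work but the 152-feature count is specific to 19 channels.
* Real-data accuracies from the motivating clinical problem are not
  reproducible here — the pipeline's guarantees are structural and
  directional, established on synthetic cohorts with known ground truth.
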