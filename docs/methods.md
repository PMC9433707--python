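# Methods

This note records the scientific and numerical choices behind `csepnet`:
what each stage computes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Noise vocoder

The vocoder splits speech into `n` bands with geometrically spaced edges
between 200 and 5000 Hz (`(5000/200)^(1/n)` edge ratio). Per band: a
4th-order Butterworth band-pass applied forward–backward (zero phase), an
envelope by full-wave rectification plus a 4th-order 30 Hz zero-phase
low-pass, modulation of a seeded Gaussian white-noise carrier, and a second
pass through the band filter to confine modulation splatter. Bands are
summed and the output is RMS-matched to the input. The filter family and
order, and the vocoder's envelope cutoff, are package defaults (the
procedure is standard but underdetermined); the envelope definition is
shared with the stimulus-feature module so one definition serves both.
Loudness is handled only as digital RMS — there is no dB SPL calibration.

## Stimulus features

* **ENV**: |x| → zero-phase 30 Hz Butterworth low-pass → polyphase
  resampling to 256 Hz; undershoot from zero-phase filtering is clipped at
  zero. Output length is `round(duration × 256)`.
* **PH**: a unit impulse at `round(onset × 256)` per phoneme onset.
  Onset-to-sample rounding is *half away from zero* everywhere.
* **PHENV**: the element-wise product ENV × PH.

Features computed on `[0, duration]` are zero-padded onto the epoch window
(−0.5..2.5 s, 768 samples, onset at sample 128) so they align
sample-for-sample with EEG epochs. Envelopes are computed from the natural
(non-vocoded) audio by default; computing them from the vocoded waveform is
a caller choice, not a flag of the core functions.

Phoneme onsets are read from Praat TextGrids (long or short text form;
first interval tier whose name contains "phon", non-empty interval start
times) or a one-column TSV of seconds; output is sorted and deduplicated.

## EEG pipeline

Downsample to 256 Hz (polyphase; event indices rescaled with floor, so up
to one sample of onset jitter is accepted), subtract the instantaneous
channel mean (average reference), then band-pass 1–57 Hz with a zero-phase
Hamming-windowed sinc FIR designed with 1 Hz (low edge) and 6 Hz (high
edge) transition bands — the EEGLAB-style design, delegated to
`mne.filter.filter_data`. Re-referencing and filtering are both linear and
commute; the test suite asserts this to 1e-6 µV. Epochs are 64 × 768; an
event whose window exceeds the recording is skipped and logged, never
truncated. Component-based ocular artifact removal is out of scope; a
peak-amplitude threshold (default 150 µV) stands in its place.

## CSEP and ERP feature images

The lagged correlation uses the lag grid ℓ ∈ {−128, …, 639} samples
(−0.5 s to +2.496 s), chosen so CSEP images share the 64 × 768 geometry of
the epochs; positive lag means the neural signal trails the stimulus
feature. Each coefficient is the Pearson correlation over the overlapping
samples only; overlaps shorter than 8 samples, or with zero variance,
yield 0 rather than NaN. The implementation is O(N log N) — FFT
cross-products plus cumulative-sum window moments, with both series
globally centred and scaled first (Pearson is affine-invariant, and this
conditions the arithmetic) — and is tested against a direct O(N²) per-lag
oracle to 1e-10.

Bootstrap image generation draws a score class uniformly from the observed
classes (so the corpus is balanced across intelligibility), then a
participant × condition pool with that score, then `n_avg` epochs with
replacement (default 80). Each pool's epochs are split 80/20 *before* any
averaging; train exemplars touch only train-side epochs and test exemplars
only test-side epochs, which the suite verifies by epoch identifier. The
split is at the trial level within each participant × condition — the
alternative (splitting participants) would empty some score classes on one
side; trial-level splitting is a known leakage caveat when interpreting
accuracies as subject generalization.

Rendering min-max scales the 64 × 768 matrix, bilinearly resizes to
size² (299 default), and renormalizes so the rendered minimum is exactly 0
and the maximum exactly 1 (interpolation alone cannot guarantee the
extremes); a constant matrix renders as uniform 0.5. The grayscale plane
is replicated onto 3 identical channels — replication avoids making
results depend on a colormap.

## Augmentation

Three perturbations, one chosen uniformly per copy: Gaussian noise with the
drawn field rescaled so the realized noise-to-signal RMS ratio is *exactly*
0.6 (exact rescaling makes the ratio testable deterministically); a
0.625 s (160-column) temporal cutout refilled with noise matched to the
image's global mean and SD (a constant image uses unit SD so the cutout is
still visible); and zeroing of exactly 12 random electrode rows.
Augmentation operates on the 64 × 768 matrices before rendering so columns
and rows keep their time/channel meaning. Originals are retained: factor
10 yields 800 + 7,200 = 8,000. Labels are never altered.

## Classifier

The network is: Conv(32, 16×16) → LeakyReLU(0.01) → Conv(8, 8×8) →
LeakyReLU → pool(2×2, stride 2) → Conv(8, 4×4) → LeakyReLU → pool(2×2,
stride 1) → Conv(3, 3×3) → LeakyReLU → pool(2×2, stride 1) → batch norm →
dense(38) → softmax. All convolutions are same-padded; the pool strides
(2, 1, 1) are the only setting that yields the 299 → 149 → 148 → 147
spatial progression, and `build_model` audits every layer's analytic output
shape against this table at construction, failing loudly on mismatch.
Batch normalization placed after the final pool (rather than per
convolution) is unusual but intentional; the single dense layer maps
147·147·3 features to 38 logits. Classes absent from a run keep their
output units; metrics are computed over observed classes.

Training: categorical cross-entropy (implied by the softmax classification
head), Adam at lr 0.001, batch 64, 5 epochs, shuffling each epoch, 20 % of
the training images held out for validation. All randomness flows from a
single seed; two runs with equal seeds produce bit-identical histories.

The engine (`csepnet.nn`) is written on numpy. Convolutions are evaluated
in the frequency domain (rfft2 products; FFT size `padded + kernel − 1`,
at which the circular weight-gradient correlation is alias-free over the
kernel support); every layer's backward pass is verified against central
finite differences in float64. Float32 is used for training.

A `small` profile (128 × 128 input, filter counts ÷ 4, minimum 1) exists
for desk-scale validation runs; the full 299 × 299 architecture is the
reference and is what the shape audit certifies.

## Occlusion attribution

Sensitivity is the drop in the true-class softmax probability when a 5 × 5
patch (stride 5) is replaced by 0.5 — the rendered-image midpoint, i.e.
the value a constant image renders to. A 299 × 299 input yields a 60 × 60
grid (`ceil(299/5)`). Aggregation to electrodes partitions the image rows
into 64 equal bands (≈ 4.67 pixel rows each) and distributes each grid row
over the bands it overlaps by *fractional* overlap — an exact partition
(band widths sum to the number of grid rows, and the width-weighted sum of
channel scores equals the grid total) that avoids the dead channels an
integer partition would create when the grid has fewer rows than channels.
Absolute sensitivity is averaged over all lag columns by default (signed
aggregation is available). Ranking is by descending score with ties broken
in montage order. The per-model attribution averages occlusion maps over
correctly classified test images. Topographic maps are rendered on the
packaged 2-D montage (Biosemi-64 labels, azimuthal projection, lowest ring
at radius 1.15).

## Synthetic study generator

The generator emulates the study conditions so the pipeline is testable
without the (non-deposited) recordings:

* **Stimuli** — amplitude-modulated pink noise with 3–6 Hz (syllabic)
  modulation; duration ~ N(1.8, 0.2²) s clipped to [1.2, 2.4]; 17–22
  phoneme onsets per sentence (mean 18.6, SD 3.9); 10 sentences, 100
  repeats, 87 subjects, 6 conditions by default.
* **Scores** — p = logistic(2.967·(log₂(channels) − 1.786)) with
  subject-level logit jitter (SD 0.5), snapped to the allowed 2.5-step
  grid (the three never-observed levels map to their nearest allowed
  neighbours); the natural condition concentrates near 99.6 %. The slope
  and midpoint are a least-squares fit of the condition-mean calibration anchors;
  a 2-parameter logistic reproduces the 2-channel (≈ 8.9 vs 7.5) and
  natural anchors well but underestimates the 3-channel mean (≈ 35 vs 55)
  — a known limitation of this psychometric form.
* **EEG** — epoch = s·(g_env·(k∗ENV) + g_ph·(k∗PH))·w_c·response_scale +
  noise_scale·(1/f noise), where k is a gamma-shaped biphasic response
  kernel (latency 100 ms, width 80 ms), s = score/100 (the simplest
  monotone link), w_c = 1 on a contiguous block of 12 left
  central/temporal electrodes (FC5…P1) and 0 elsewhere, and the response
  components are unit-RMS. With the defaults
  (response_scale = noise_scale = 10 µV) a unit tracking gain means a
  single-trial SNR of 0 dB at score 100 on informative channels. Noise is
  drawn independently of the gains, so runs with equal seeds and
  different gains share the same noise field — which is what makes the
  gain-monotonicity property testable with noise held fixed.

What the generator does **not** emulate: real single-trial envelope
tracking is far weaker (correlations of ~0.1, SNR well below 0 dB),
background noise here is spatially independent across channels (no
volume conduction), there are no blink/EMG artifacts, no inter-subject
latency or topography variability, and the informative set is a hard
binary mask. Passing the end-to-end tests therefore demonstrates that the
pipeline is correct and sensitive, not that comparable accuracies are
attainable on recorded EEG.

Two cautions discovered while testing, kept as documented behavior:
Pearson-normalized CSEPs are invariant to a multiplicative response gain
on noiseless data (graded effects exist only against a fixed noise
floor), and a sample-shuffling null is miscalibrated against 1/f noise —
the suite uses phase-randomized surrogates (spectrum-preserving) for the
non-informative-channel null.

## Validation problem sizes

The scaled validation profile (`csepnet.pipeline.scaled_recovery_run`)
uses 8 subjects × 5 deterministic score levels {0, 25, 50, 75, 100},
2 sentences × 20 repeats per pool, ERP images with 20-epoch averages,
400 train / 100 test exemplars, ×2 augmentation, and the `small` CNN for
5 epochs — sizes chosen so a full run completes in a few minutes on one
CPU core while leaving the task non-trivial (single-trial SNR ≤ 0 dB,
38-way output over 5 observed classes). Class recovery is judged against
5× the 2.63 % chance level and electrode recovery against 80 % of the
12-channel informative set, each by majority over three seeds, since
individual seeds vary substantially at this problem size.

## Known limitations

* The trial-level 80/20 split measures within-subject decoding, not
  generalization to unseen listeners.
* Bootstrap exemplars drawn from the same pool share epochs, so test
  exemplars are correlated with each other (not with training data).
* The micro-averaged confusion accuracy (TN+TP)/(TN+TP+FN+FP) is reported
  alongside plain accuracy; with one-vs-rest counts over 38 classes it is
  a deterministic function of plain accuracy.
* Occlusion attribution at 5-pixel stride on a 128-pixel rendering spans
  ~2.5 electrodes per grid row; neighbouring channels of a truly
  informative electrode inevitably receive some credit.
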