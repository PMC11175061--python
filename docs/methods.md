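# Methods

## Signal model and preprocessing

The pipeline assumes a single-lead ECG sampled at a fixed rate (defaults
target 360 samples/s) with R-peak annotations, either provided (beat-level
tasks) or produced by the built-in detector (record-level tasks).

**Wavelet denoising.** Signals are denoised by discrete wavelet
decomposition, thresholding of the detail coefficients, and
reconstruction. Defaults: Daubechies-6 wavelet, decomposition level 6, the
universal threshold σ·√(2 ln N) with σ estimated as MAD(finest
detail)/0.6745, soft (shrinkage) mode. All four choices are configurable;
an SURE (Stein unbiased risk) per-band threshold is provided. The
universal/soft default is the textbook scheme, but note its known bias:
soft shrinkage subtracts the full threshold from every retained
coefficient, which at deep levels (whose bands carry QRS and T-wave
energy) trades noise suppression against waveform distortion. On the
synthetic bench at 10 dB input SNR the default gains a few tenths of a dB,
while `threshold_rule="sure"` gains ~8 dB; the default is kept for its
canonical status and because the pipeline's classifiers are robust to the
residual noise. Denoising a zero or noise-free signal is a near-identity
(clean-input RMSE is far below 2% of peak-to-peak amplitude).

**R-peak realignment.** Annotated peaks are snapped to the argmax of
|signal| within ±`realign_radius` samples (default 25). Ties break toward
the annotated index (and then toward the earlier sample); peaks that
collide after snapping are deduplicated keeping the first, with a logged
warning. A peak never moves farther than the radius.

**Segmentation.** Each beat is the window of `half_window` samples
(default 250) on both sides of its R peak — 501 samples at the default.
The first `skip_first_beats` beats (default 15) of every record are
discarded as a recording transient; the exclusion is applied per record.
Windows that would overrun the record are skipped, never padded, so every
segment has the exact invariant length; skips are counted in the run log.

**QRS detection.** A derivative-energy detector in the Pan–Tompkins
lineage: 5–15 Hz band-pass (zero-phase second-order Butterworth),
differentiation, squaring, 150 ms moving-window integration, peak picking
at 20% of the 99.5th percentile of the integrated energy with a 250 ms
lockout, then refinement to the local absolute maximum of the band-passed
trace. On the synthetic bench it scores F1 ≈ 0.96–1.0 at 10 dB SNR and
recovers every beat within 10 samples on clean records.

## Neuron model

Discrete-time leaky integrate-and-fire with per-step retention λ ∈ (0, 1]:
the membrane is λ·U + drive, a spike fires iff the membrane **strictly**
exceeds V_th (boundary equality does not fire), after which the membrane
resets to V_r (default 0) — or by threshold subtraction in converted
networks — and an optional refractory countdown holds the membrane and
suppresses output. Defaults for trainable networks: λ = 0.9, V_th = 1,
V_r = 0, no refractory period (refractory dynamics complicate gradients
and are supported in inference only). The drive into a layer is the
weighted sum of presynaptic *spike* outputs, the standard choice that
keeps communication binary and event-like; summing presynaptic membrane
potentials instead is expressible through the functional `lif_run`
interface (any real-valued drive sequence) but is not used by the trained
networks.

A continuous reference model τ·dU/dt = −U + R·I(t), integrated by forward
Euler, validates the discrete update: with λ = 1 − dt/τ and drive
(dt/τ)·R·I the two traces agree to 1e-9 on subthreshold input, and the
Euler error halves when dt halves.

## Encoding

`direct` (default): the analog segment is presented as identical constant
drive at every timestep, and the first spiking layer performs the
analog-to-spike conversion. `rate`: seeded Bernoulli spikes with
probability equal to the min-max-normalized sample value; used mainly for
conversion experiments, where input rates must lie in [0, 1].

## Attention block

Input segments are average-pooled onto `slice_count` time slices (501 → 250
by pool size 2 at the defaults; the pool size is input_length //
slice_count and must divide evenly). Features: conv(1→2 channels, kernel
7, same padding) → ReLU → avg-pool 2 → conv(2→2, kernel 5) → ReLU →
avg-pool 2 → flatten. Each of `n_heads` (default 4) fully independent
heads maps the features to `slice_count` logits; SoftMax puts each head's
vector on the probability simplex; the head average (still on the simplex)
multiplies the sliced input element-wise, broadcast across channels.

Because a simplex weight vector averages 1/slice_count, naive gating
attenuates the drive by that factor and silences the spiking stack. The
network therefore applies a fixed gain of `slice_count` between attention
and the first spiking layer — a pure reparameterization (absorbable into
the first weight matrix) that keeps unit-order variance at initialization.

## Architectures

* **Six-layer spiking model** (`build_snn6` / `AttentionSNNClassifier`):
  the attention block's two convolutions, then four fully connected LIF
  layers of widths 256–128–64–classes. Readout: output-layer spike counts
  over T timesteps (default `spike_count`); `mean_membrane` replaces the
  output layer with a non-spiking leaky integrator and averages its
  membrane. The nominal "six layers" counts the two attention convolutions
  plus the four FC-LIF layers; widths are configurable and the count
  follows the defaults.
* **Twelve-layer baseline** (`build_ann12` / `ConvNetClassifier`):
  conv(8, k7) → pool → conv(16, k5) → pool → conv(32, k3) → pool →
  FC 256 → FC 128 → FC 64 → FC classes, ReLU or LeakyReLU. The descriptor
  list counts the three conv and three pool stages, the four FC layers,
  and the two hidden FC activations — twelve entries; convolution
  activations are folded into their conv entries. The published counts
  come without widths, so the widths here are standard choices and
  config-overridable.
* **Non-spiking twin** (`build_ann6`): the attention block plus the same
  FC stack with ReLU, trainable conventionally and convertible
  layer-for-layer into the spiking model.

## Training

Mini-batch Adam (default learning rate 1e-3, batch 64) with softmax
cross-entropy on the readout logits, default 200 epochs and T = 100 —
the published protocol's values; the test bench uses smaller budgets
(below). Gradients flow through the spike nonlinearity via a surrogate
derivative — arctan-shaped, width parameter α = 2, with a rectangular
alternative — and through time by BPTT with the reset path detached (the
standard recipe; detaching stabilizes training and leaves subthreshold
gradients exact, which the finite-difference tests confirm). Inputs are
z-scored per segment by default. Non-finite loss aborts training with the
epoch index; spike-count logits are bounded by T, so only the
conventional baseline can diverge this way. Runs are bit-reproducible
given `random_state`: all initialization, shuffling and encoding
randomness derives from one generator.

Class imbalance: `class_weight="balanced"` applies inverse-frequency
weights in the loss; off by default.

## ANN→SNN conversion

Threshold balancing: for each layer l, the calibration batch yields the
maximum (or a configurable percentile of the) positive pre-activation
p_l; weights are copied as W_l · (p_{l−1}/p_l) and biases as b_l/p_l
(p_0 = the input maximum, 1 for rate-coded input). Converted layers use
integrate-and-fire neurons (λ = 1, V_th = 1) with reset-by-subtraction,
under which the firing rate of a constantly driven neuron converges to its
drive at O(1/T); firing rates multiplied back by p_l estimate the source
ReLU activations. Reset-to-V_r is the biological default elsewhere in the
package; conversion uses subtraction because rate fidelity is the goal of
the transfer — with reset-to-zero the sub-threshold residue is discarded
at every spike and rates plateau away from the target. Architecture
mismatches between a source and an explicit target are reported naming
the first differing layer. On a toy positive-weight ReLU network, the
converted model matches activations within 10% relative error at T = 512,
with the error decreasing monotonically over T ∈ {32, 128, 512}.

## Synthetic bench

The generator emulates an annotated single-lead recording: quasi-periodic
beats at jittered RR intervals (multiplicative Gaussian jitter truncated
at ±3σ so ordering is preserved), each beat a sum of five Gaussian bumps
(P, Q, R, S, T) with class-specific amplitudes/centres/widths. The
ventricular-ectopic-like class has no P wave, a wide slurred QRS and an
inverted T; supraventricular-, fusion- and unknown-like variants are
provided. Additive terms: white Gaussian noise, a 0.2 Hz baseline-wander
sinusoid, and 50 Hz powerline pickup, all configurable. Annotations are
exact by construction (the stored R index is the clean waveform's local
argmax), and record-level rhythm classes (normal / AF-like irregular
rhythm without P waves / fast ectopic-rich / noisy) support the
record-classification task. Defaults: 360 samples/s, 60 s, 75 bpm, 5% RR
jitter, 90/10 N/V mix.

What it does **not** emulate: real morphology variability within a class,
inter-patient differences, electrode artefacts, non-stationary noise, or
multi-lead structure. Passing tests therefore demonstrate that the
algorithms are implemented correctly and can learn morphological
distinctions at a known SNR — not clinical-grade performance on MIT-BIH or
PhysioNet data, whose published headline accuracies additionally depend on
unpublished architecture widths. The optional WFDB reader exists so the
same pipeline can be pointed at real records when they are available
locally.

## Problem sizes in the test bench

Chosen once as desk-scale study conditions: the end-to-end learnability
check trains the attention-SNN on 2,000 balanced N-vs-V segments at 10 dB
SNR for 50 epochs at T = 8 under the stratified 70:30 split; the timestep
comparison runs ten replicates of 600 segments / 12 epochs at T ∈ {1, 8}.
On this bench the two morphologies are grossly different, so accuracy
saturates even at T = 1 and the T = 8 ≥ T = 1 comparison typically ties —
the asserted property is "longer integration is never worse", not a strict
gain. The acceptance script uses the same sizes.

## Evaluation

Metrics are computed from the confusion matrix by hand: per-class
precision TP/(TP+FP), sensitivity TP/(TP+FN), F1 as their harmonic mean,
overall accuracy as trace/total. Zero-denominator cells are reported as
NaN and the class is listed in `undefined` — never silently coerced to 0
(this deliberately differs from scorers that substitute 0 into F1 when a
component is undefined). Multi-class summaries are macro-averaged by
default, with micro (= accuracy for single-label tasks) and
support-weighted averaging as options, since a single printed F1 for a
multi-class task underdetermines the averaging rule. The random 70:30
split is seeded and stratified by class; the inter-patient protocol
assigns whole records to disjoint sides using the canonical MIT-BIH train
and test record lists exposed in `spikecg.io` (together with the standard
four-record exclusion list, which the reader exposes but does not
enforce as a count).

## Known limitations

* Refractory dynamics are inference-only; training requires
  `refractory_steps=0`.
* Conversion covers fully connected ReLU stacks (optionally behind a
  shared attention block); convolutional conversion is not implemented.
* The universal-soft denoising default is conservative at deep
  decomposition levels (see above).
* The CLI stores checkpoints as Python pickles — portable only across
  matching package versions.
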