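# Methods

## Problem and model

`bcgfusion` estimates instantaneous heart rate from two unobtrusive
bed-sensor modalities: a four-channel ballistocardiogram (BCG), which
records the mechanical recoil of the body to cardiac ejection, and a
single-channel photoplethysmogram (PPG), which records peripheral
blood-volume pulses arriving one pulse-transit-time (PTT) after each beat.
A synchronized ECG provides the reference beat times from which window
labels are derived; the ECG is never an input to the regressor.

The regressor is a dual-branch temporal network. Each branch applies, in
order:

1. **Multi-scale causal convolutions.** Parallel causal convolutions with
   kernel sizes {3, 5, 7} (BCG) or {3, 5} (PPG),
   F(t) = Σᵢ f(i)·x(t−i), channel-concatenated and max-pooled once.
   Multiple kernel widths accommodate variation in the duration of the
   mechanical complexes across subjects.
2. **TCN residual blocks.** Dilated causal convolutions
   F(s) = Σᵢ f(i)·x(s−d·i) with dilations (1, 2, 4, 8) for BCG and
   (1, 2, 4) for PPG, two convolutions per block in a pre-activation
   residual arrangement o = ReLU(skip(x) + F(x)), spatial (whole-channel)
   dropout, and a 1×1 convolution on the skip path when the channel count
   changes. With kernel 3 the four-block BCG stack has a receptive field
   of 1 + Σ 2(k−1)d = 61 samples.
3. **BiLSTM.** Independent forward and backward gate recurrences
   (fₜ, iₜ, oₜ gates, cell state Cₜ, hidden hₜ), outputs concatenated per
   time step to 2H features.
4. **Multi-head self-attention.** headᵢ = softmax(QᵢKᵢᵀ/√d_k)Vᵢ on
   subspaces, concatenated and projected by W^O. The head count is
   adjusted downward to the largest divisor of the feature dimension not
   exceeding the requested count, so d_k is always integral. No positional
   encoding is used; temporal order is already encoded by the
   convolutional and recurrent stages.

Both branch outputs are linearly projected into a shared D_fusion = 128
space (P = W·F + b per time step). Cross-modal attention fusion computes a
row-stochastic T×T similarity matrix S = softmax(P_bcg·P_ppgᵀ/√D) and
mixes the modalities as F_fused = S·P_ppg + (J − S)·P_bcg, with J the
all-ones matrix. The "1 − S" term is read as the all-ones matrix minus S
(the elementwise-complement reading is identical); rows of (J − S) sum to
T − 1 and are deliberately not renormalized. Global average pooling over
time feeds a 128 → 64 → 1 head (ReLU between the dense layers); the scalar
output passes through a sigmoid and is linearly mapped onto
[hr_min, hr_max] = [35, 120] BPM, so raw predictions are always
physiological. Labels are correspondingly mapped to (y − 35)/85 for the
loss.

Ablation switches disable the TCN stack, the BiLSTM, the attention stage,
replace dynamic fusion by concatenation plus a dense reduction, or drop a
modality entirely (in which case the remaining branch's projection feeds
the head directly). Requesting a single modality together with dynamic
fusion is rejected as inconsistent.

## Numerical substrate

The network, its gradients and the Nadam optimiser are implemented
directly on numpy through a small reverse-mode autodiff engine
(`bcgfusion.nn`). Float64 is used throughout; gradient correctness is
verified against central finite differences both per operation and through
the assembled network. Nadam uses β₁ = 0.9, β₂ = 0.999, ε = 1e-8.
Weights are initialised from U(−1/√fan_in, +1/√fan_in) under the model
seed, making construction and eval-mode inference bit-reproducible.

## Training protocol

Huber loss (δ = 1.0 on the [0, 1] label scale), Nadam at 1e-3, batch 32,
at most 100 epochs. The learning rate is halved when the training loss
fails to improve by more than 1e-4 for 5 consecutive epochs; early
stopping monitors validation MAE with patience 15 and restores the best
weights. The two plateau rules intentionally monitor different quantities
(training loss vs validation MAE). Both rules are pure functions of the
loss history and are unit-tested on synthetic histories. Cross-validation
supports subject-disjoint folds (default, since 1 s-stride windows overlap
75% and window-level folds leak) and window-level folds; fold assignment
is deterministic under the seed.

## Preprocessing

Order: linear interpolation of NaN gaps (edges filled with the nearest
valid value) → zero-phase 4th-order Butterworth band-pass at the native
rate (0.3–24 Hz for BCG and PPG, 0.5–40 Hz for ECG) → polyphase
downsampling to 100 Hz → 4 s windows with 1 s stride → exclusion of labels
outside [35, 120] BPM (inclusive bounds) → per-window, per-channel z-score
with population σ (constant channels map to zeros). Interpolation precedes
filtering because a zero-phase IIR filter would smear NaNs across the
whole record. The PPG band is not separately specified upstream of this
package; the BCG band is applied to it. Per-window z-scoring is the
strictest normalization scope and also removes slow session drift; the
scope is a config decision, not a physiological claim.

Labels: R-peaks are detected with a Pan–Tompkins-style chain (band-pass →
derivative → squaring → 150 ms moving integration → 0.5× rolling-maximum
threshold with a 250 ms refractory period), then snapped to the local
maximum of the filtered ECG. `detect_r_peaks` returns integer indices;
label computation refines peak times with a 3-point parabolic fit because
at 100 Hz the 10 ms sample quantization alone would exceed the intended
label accuracy. The window label is 60 / mean(RR) over the peaks inside
the window; windows with fewer than two peaks are dropped and counted.

## Synthetic cohorts

The simulator emulates the *structure* of a bed-sensor dataset, not its
physiology: ECG = unit Gaussian R-spikes (σ = 10 ms); BCG = a three-lobe
I-J-K complex (relative amplitudes −0.4 / +1.0 / −0.6, ~150 ms span)
scaled per channel by configurable gains; PPG = a raised-cosine pulse
(300 ms width) delayed by the subject's PTT (drawn from [0.15, 0.30] s).
Kernels are evaluated analytically at continuous beat times, so beat
instants are not quantized to the sample grid. Beat times follow
RR = 60/HR(t) plus truncated Gaussian jitter (default SD 20 ms, RR clipped
to [0.3, 2.0] s); HR(t) superimposes a slow sinusoidal drift (default
±5 BPM at 0.02 Hz) on the subject's mean rate, emulating resting autonomic
variation and ensuring window labels span a range rather than a single
value per subject.

Noise defaults (per `NoiseSpec`): white sensor noise SD 0.1 (J-wave has
unit amplitude), additive 0.25 Hz respiratory baseline of amplitude 0.3
plus a fixed ±20% amplitude modulation of the BCG complexes, and
Poisson-timed movement artifacts (2/min, 0.5–2 s bursts of Hann-windowed
random-walk noise, amplitude 1.0). The ECG reference receives only
attenuated (×0.1) white noise. PPG noise defaults to the same spec with an
independent stream and can be overridden, e.g. to corrupt PPG selectively
in ablation studies.

What passing tests on these cohorts do **not** show: robustness to real
BCG morphology variation across postures and subjects, to arrhythmias, to
sensor coupling changes, or to genuinely non-stationary noise. The
simulator has no hemodynamic fidelity beyond beat timing, the PTT lag and
gross morphology.

## Desk-scale profiles

Default cohorts are 8 subjects × 120 s at 100 Hz (the full-scale geometry
of a 40-subject bed-sensor study is supported but not the default). The
acceptance runs use a scaled-down network (filters_per_kernel = 8,
tcn_channels = 32, lstm_hidden = 32) with pool_size = 4 (sequence length
100 after pooling) and ≤ 30 training epochs; the full-width default
configuration (32/128/128, pool 2) has ~1.8 M parameters and is exercised
for construction and forward contracts. These sizes are the package's own
desk-scale choices so the full pipeline, including training, runs in
minutes on one CPU.

## Degenerate inputs and tie-breaks

Constant channels z-score to zeros (logged). Flat ECG yields no peaks;
windows with < 2 peaks are unlabeled and dropped. An empty beat process
synthesizes a noise-only record (logged warning). Max-pool ties split the
gradient evenly; `maximum` routes the gradient to the first argument on
exact ties. Softmax subtracts the row maximum before exponentiation.
Improvement thresholds of 1e-4 in both plateau rules guard against float
noise.

## Known limitations

* Backpropagation through time stores the full per-step graph; memory
  grows linearly with sequence length and batch size.
* Training determinism holds for fixed seeds on a given platform; across
  BLAS builds, reductions may differ in the last ulps.
* The cross-modal fusion sum term (J − S)·P_bcg scales with T; the
  downstream dense head absorbs this, but very long sequences would need
  attention to initialisation scale.
* The R-peak detector is tuned for clean reference ECG (as in the intended
  datasets), not for ambulatory ECG with artifacts.
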