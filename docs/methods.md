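# Methods

## The transform

The package uses the 1-level two-dimensional stationary (undecimated)
Haar wavelet transform.  The per-axis analysis filters are the Haar
pair (1/√2, 1/√2) and (1/√2, −1/√2) applied without downsampling, so
the four coefficient planes A, H, V, D keep the input's spatial size
and every entry is a signed half-sum of the 2×2 pixel window anchored
at that position.  Boundary handling is periodic (circular).  This
convention was chosen because it is the unique one under which the
2×2 window algebra holds at every position including the borders, and
it gives exact analytic identities that the tests assert:

* perfect reconstruction — the inverse averages the four redundant
  per-window estimates of each pixel and is exact to ≤1e-8 for 8-bit
  inputs;
* detail planes sum (and average) to exactly zero, because the
  high-pass kernels have zero DC response under circular convolution;
* mean(A) = 2·mean(image); for pixels in [0, 255], A ∈ [0, 510] and
  |H|, |V|, |D| ≤ 255, with the bounds attained at binary corner
  blocks.

Sign and orientation conventions (H = row-difference/column-sum,
V = column-difference/row-sum, D = difference-of-differences) are
pinned down by a brute-force periodic sliding-window oracle test and
cross-checked against PyWavelets' undecimated Haar transform, which
shares the same phase and signs.  Odd-sized images are supported
directly (the undecimated transform
imposes no parity constraint).  Multi-level decomposition and other
wavelet families are out of scope: the method operates at one level
with Haar only.

## The network

Two separated paths predict HR coefficients from LR sub-bands.

* Approximate path (1 channel in): conv 3×3 → ghost extension block →
  conv 1×1 → ghost extension block → conv 3×3 → sub-pixel head.  All
  activations ReLU; He-uniform initialization.
* Detail path (3 channels in, H/V/D stacked in that fixed order):
  conv 3×3 → spatial-attention ghost extension block (or plain ghost in
  the "G+G" ablation) → conv 1×1 → sub-pixel head.  All activations
  Tanh; Glorot-uniform initialization.

A ghost extension block computes F = act(conv(x)) with
`primary_filters` output channels and concatenates φ(F), a bias-free
depthwise 3×3 linear map, for 2×`primary_filters` total channels.  The
attention variant multiplies φ(F) element-wise by a spatial map
obtained by channel-wise average- and max-pooling φ(F), merging the two
pooled maps with a single bias-free 3×3 convolution, and squashing with
the hard sigmoid clamp((x+3)/6, 0, 1) (the MobileNetV3 convention; the
gate is therefore exactly 0 below −3 and exactly 1 above +3).  The
merge convolution is bias-free so that the attention block costs
exactly 2k² parameters and 4k²·H·W FLOPs over the plain ghost block,
matching the closed-form accounting; an optional bias flag exists for
experimentation.

Sub-pixel heads are linear (no activation after the final convolution)
because predicted detail coefficients must span signed values beyond
Tanh saturation; they emit scale²·{1, 3} channels and a periodic pixel
rearrangement maps channels to space.

Pixels are divided by 255 before the transform, so A ∈ [0, 2]
(ReLU-compatible) and the detail planes lie in [−1, 1]
(Tanh-compatible); the division is undone after the inverse transform
and outputs are clipped to [0, 255].

### Residual prediction

The coefficient predictor can be read two ways: emit the HR sub-bands
directly, or emit only their *difference* from an LR-derived anchor.
Both are implemented behind `NetworkConfig.residual`.  The default is the
residual form: the network output is added to an anchor — the
sub-bands of the bicubic-upscaled LR image — and the sub-pixel heads
are zero-initialized, so an untrained model reproduces bicubic
upscaling exactly and optimization only learns corrections.  The
direct form (`residual=False`) predicts coefficients from scratch; at
desk scale (tiny model, minutes of CPU) it converges far too slowly to
be competitive with bicubic upscaling (tens of dB below the anchor
after 20 epochs in our experiments), which is why the residual form is
the default.  Both variants share every other component.

## Complexity accounting

Closed-form parameter and FLOP counts cover three block families:
mini-grid (two dense stages), ghost, and attention ghost.  Conventions,
taken literally from the printed formulas: the "+1" terms are the
biases of the dense stage; the cheap depthwise stage is bias-free; one
multiply-accumulate is 2 FLOPs; pooling is not counted.  The symbol M
(second-stage output channels) is unused for the ghost kinds.  A census
routine enumerates an instantiated network's weight tensors per layer,
and tests assert exact equality between the analytic expressions and
the enumerated block subtotals, including the 2k² / 4k²·H·W attention
differences.

## Training

* Loss: 1/(2N)·Σ(‖ΔA‖² + ‖ΔD‖²) over the batch, in the normalized
  coefficient domain.
* Optimizer: Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) with *global-norm*
  gradient clipping at 0.001 (norm clipping was specified; a
  per-value interpretation is not used).  Because Adam is nearly
  invariant to a uniform gradient rescaling, this aggressive clip
  mostly fixes the gradient direction rather than stalling learning;
  it is configurable.
* Learning rate: the cosine-decay recurrence — at epochs divisible by
  `decay_epoch` the value is multiplied by 0.1, otherwise it is *set*
  to (1−α)·½(1+cos(π·epoch/decay_epoch))+α with α = 1e-4.  That
  expression lives on a [α, 1] scale (≈1 at epoch 1), which cannot
  itself be the learning rate of a run whose initial rate is 0.001;
  the optimizer therefore applies it as a multiplier on `initial_lr`.
  The recurrence itself is exposed (and tested) unmodified.
  `decay_epoch` defaults to 100; 30 is the documented alternative.
* Patching: HR crops of 48 px on a regular grid with stride 24 (the
  stated "48 px overlapping" at size 48 would mean stride 0, which
  degenerates; 50% overlap is used and the stride is configurable).
  LR sides are bicubic 1/scale downsamples of the HR crops — the
  standard degradation protocol; the source does not state its
  operator.  The LR patch side is `patch_size/scale`.
* Validation: the last 10% of the seed-shuffled patch list; mean PSNR
  of reconstructed patches per epoch (infinite values capped at 100 dB
  to keep the mean finite).
* Monitoring: the log carries both the running-mean batch loss of each
  epoch and an end-of-epoch loss on a fixed training subset
  (`epoch_loss`).  The running mean is confounded by shuffle order and
  by the model changing within the epoch; the fixed-subset loss is the
  monitor used when asking whether optimization is actually
  progressing.
* Determinism: one integer seed fixes weight init, shuffling and the
  validation split; two runs with equal seeds produce identical loss
  traces on CPU.
* Divergence (NaN/inf loss) aborts with a diagnostic.

The engine underneath is a small reverse-mode numpy implementation
(dense and depthwise convolution with zero 'same' padding, pixel
shuffle, the three nonlinearities, channel pooling).  Its gradients are
verified against central finite differences in float64 for every
trainable tensor, and its convolutions against an independent
scipy reference.

## The phantom generator

`make_phantom` renders chest-radiograph-like 8-bit images: a smooth
bright background with a gentle gradient and vignette, a bright
mediastinal column, two dark elliptical lung fields with crisp sigmoid
borders, curved periodic rib bands, sparse tapering vessel-like
strokes walked outward from each hilum, and Gaussian noise (σ = 2 by
default, emulating acquisition noise).  One seed fixes geometry jitter,
vessel trees and noise.

The defaults were set so the generated images reproduce the
statistical signature the separation architecture assumes — detail
sub-bands near-zero-mean and sparse (>90% of |D| below 5% of its
maximum in the noise-free image), >95% of coefficient energy in the
approximate band, ≥100 distinct gray levels — and so the ×2 bicubic
baseline on phantom patches lands in the high-30s dB, i.e. the task is
non-trivial in the same sense reported for real chest X-ray sets
(where bicubic sits near the low 30s dB).  The generator does **not**
emulate anatomical variability, pathology, scatter/beam-hardening
physics or detector characteristics; passing tests demonstrate the
pipeline's correctness and its ability to beat bicubic on this image
class, not clinical performance on real radiographs.

## Scaled-down experiment sizes

The training acceptance check uses a tiny configuration chosen to keep
a full 5-seed experiment in the minutes range on one CPU: 8 base
filters, 2000 patch pairs from 25 phantoms, batch 128, 20 epochs,
scale ×2.  Full-size runs (32 filters, hundreds of images, 100 epochs)
use the identical code path.

## Known limitations

* Grayscale only; multi-channel inputs must be converted explicitly.
* One scale per trained model (×2, ×3 or ×4); no multi-scale weights.
* The SSIM statistic can be negative for anticorrelated patches; the
  implementation follows the windowed definition (11×11 Gaussian,
  σ 1.5, c₁=(0.01·255)², c₂=(0.03·255)²) without clamping, so the
  documented [0, 1] range holds only for non-pathological pairs.
* PSNR of identical images is reported as +inf, not capped, except in
  validation averaging.
* The numpy engine is single-threaded-friendly but far slower than a
  GPU framework; it is intended for small models and experiments.
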