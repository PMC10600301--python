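# Methods note

This note records the mathematical conventions, model and generator
parameters, numerical choices and known limitations of the `wavefusion`
package. Every empirical statement here is computed by the test suite or
the acceptance script; nothing is quoted from external experiments.

## 1. Preprocessing

**Epoch window.** Trials are truncated to a 1-s post-onset window and
resampled to 100 Hz with a polyphase anti-aliasing filter
(`scipy.signal.resample_poly`; the rational rate ratio is taken from
`fractions.Fraction.limit_denominator(1000)`).

**Bootstrap trial averaging.** For each subject and condition, surrogate
trials are formed as means of `n_select = 25` trials drawn without
replacement within one surrogate and independently across surrogates;
`n_out = 500` surrogates per condition give 1000 samples per subject.
Averaging suppresses trial noise while the class-dependent band-power
difference survives in expectation.

**STFT dialect.** Window length 80 samples, Hann taper (`fftbins=True`),
hop 10 (75% overlap), symmetric zero boundary padding of 40 samples per
side, magnitude (not power, not dB), keeping FFT bins 1..39 — DC and the
Nyquist bin are dropped. A 100-sample signal pads to 180 samples, giving
(180 − 80)/10 + 1 = 11 frames and a 39 × 11 spectrogram per lead. Bin *k*
sits at *k*·fs/80 Hz (1.25–48.75 Hz). All parameters are configurable
through `StftConfig`.

**Montage.** The packaged 63-lead 10-10 montage stores unit-disk
azimuthal-equidistant coordinates (nasion up). The model consumes the 17
posterior leads `P7 P5 P3 P1 Pz P2 P4 P6 P8 PO7 PO3 POz PO4 PO8 O1 Oz O2`
in that fixed order.

## 2. Model

**Per-lead CNN (one per lead, independent weights).** Input 1 × 39 × 11.

| stage | conv (kernel, stride, pad, out-ch) | after conv | pool | after pool |
|---|---|---|---|---|
| 1 | 5×4, 2×1, 2×1, 16 (ReLU, dropout 0.1) | 16×20×10 | 2×2 max | 16×10×5 |
| 2 | 4×2, 2×1, 0, 16 (ReLU, dropout 0.1, batch-norm) | 16×4×4 | 2×2 max | 16×2×2 |
| 3 | 2×2, 1×1, 0, 32 (no activation, dropout 0.1, batch-norm) | 32×1×1 | — | 32×1×1 |

Stage order is conv → ReLU → pool → dropout → batch-norm; stage 1 has no
batch-norm and stage 3 no ReLU. Batch normalization keeps independent
statistics per (lead, channel) over the (batch, H, W) axes. The full
17-lead network has 152,130 parameters.

**Attention (squeeze-and-excite).** Feature maps are mean-pooled per lead
(here to the 32-vector mean, since the maps are already 1 × 1), passed
through a dense 17 → 5 → 17 bottleneck with ReLU, and squashed by a
temperature-flattened sigmoid

  π_i = σ(a_i / τ_attn),  τ_attn = 1 by default.

Exact properties (verified analytically in the tests): π(0) = 0.5,
π(τ·ln 3) = 0.75, and |π − 0.5| shrinks monotonically to 0 as τ_attn → ∞
for fixed pre-activations — large temperatures flatten all weights toward
0.5, which is the anti-collapse mechanism.

**Fusion and heads.** Attention-scaled features are concatenated
(17 × 32 = 544) and a dense layer yields the 128-d representation *r*.
Pretraining head: dense 128 → 32 followed by row-wise L2 normalization
(embeddings live on the unit sphere). Classification head: dense 128 → 2.

## 3. Losses

**Subject-aware contrastive (SAC) loss.** For anchor *i* with positives
Q(i) (same condition *and* same subject) and negatives
S(i) = N_r(i) ∪ N_a(i) (all opposite-condition views, inter- and
intra-subject):

  L = − Σ_i log[ (1/|Q(i)|) Σ_{q∈Q(i)} exp(z_i·z_q/τ) / Σ_{s∈S(i)} exp(z_i·z_s/τ) ]

Three deliberate conventions: the denominator runs over *negatives only*
(not all non-anchor views), the positive mean sits *inside* the logarithm,
and same-condition views from other subjects appear in neither set.
Anchors lacking a positive or a negative are skipped with a warning; a
batch where every anchor is degenerate raises. τ = 0.25 by default. The
analytic gradient is

  dL/dZ = (C + Cᵀ) Z / τ,  C = softmax_S(sim)⊙S_mask − softmax_Q(sim)⊙Q_mask

restricted to valid anchors; it is verified against 64-bit central
differences and the loss against a nested-loop oracle (200 random batches,
tolerance 1e-6) plus closed forms (identical embeddings → Σ_i log|S(i)|;
orthogonal single positive/negative at τ = 1 → −1 per anchor).

**SupCon baseline.** The conventional supervised contrastive loss:
positives share only the condition, the denominator runs over all
non-anchor views, and the log sits inside the positive mean.

**Batch composition.** Batches are keyed to one (subject, condition):
a fraction of positives from the key, intra-subject negatives (same
subject, other condition) and inter-subject negatives (other subjects,
other condition), each drawn without replacement within its role. The
preset schemes are labelled "Q/N_r/N_a (%)": 50/0/50 (default),
45/5/50, 37.5/12.5/50, 25/25/50, 12.5/37.5/50, 5/45/50. Fractions that
are not integer multiples of 1/batch-size are apportioned by largest
remainder (counts always sum to the batch size); a `strict` flag rejects
them instead.

**Views.** Two augmented views per sample: additive 1/√f-weighted pink
noise (scale 0.1), additive white Gaussian noise (scale 0.1), and
multiplicative input dropout (rate 0.1).

## 4. Training protocol

- **WFP pretraining:** plain SGD, learning rate 0.05, 25 epochs, batch
  500 composed as 50/0/50, τ = 0.25. Each epoch every sample serves in
  the positive role exactly once (per-key shuffled chunking); negatives
  are redrawn per batch. The loss is a sum over anchors; the parameter
  step uses the per-view mean gradient so the learning rate is
  batch-size independent (the trace reports the per-view mean loss).
- **Transfer:** CNN bank, attention and encoder weights are copied
  bit-exactly into a fresh classifier; the projection head is dropped and
  the 2-node head re-initialized.
- **WFC fine-tuning:** Adam (β = 0.9/0.999), learning rate 1e-4, weight
  decay 7e-3 (bias/beta excluded), batch 32, 150 epochs, no augmentation.
  Weight decay can be grid-searched on a validation split (ties go to the
  smallest decay).
- Per-class "accuracy" is reported as per-class recall (the only reading
  under which two classes can score differently on a shared test set),
  alongside per-class F1, overall accuracy and the confusion matrix.

## 5. Synthetic generator

Per trial: x(t) = Σ_f A_lf · g · m_c · sin(2πft + φ) + σ_n · n₁/f(t),
with component frequencies f ∈ {2, 4, …, 30} Hz; A_lf per-subject baseline
amplitudes (1/√f envelope × log-normal heterogeneity, log-sd 0.4);
g per-trial log-normal gain (log-sd 0.2); φ uniform random phases;
m_c = √class_effect on effect leads and in-band components (8–13 Hz) for
class-1 trials so band *power* is multiplied by `class_effect` (default 3);
n₁/f unit-variance pink noise (σ_n = 1 by default). One random stream is
spawned per subject from the master seed, so adding subjects never
perturbs existing draws and identical inputs are bit-identical.

Calibration, computed in the acceptance tests: with `class_effect = 1`
the Welch t-test on log alpha-band power rejects at the nominal 5% rate
(200 replicates, binomial envelope); with the default effect the power
exceeds 0.9 at 100 trials/class.

Scope: the generator reproduces the *statistical* structure the method
relies on (subject fingerprints, band-limited class effect, 1/f noise).
It does not model volume conduction, event-related potentials, artifacts,
or non-stationarity.

## 6. Interpretation outputs

Attention topomaps interpolate per-lead π over the unit disk with
thin-plate-spline RBFs (linear kernel optional), exact at the electrodes,
clipped to the observed value range and masked outside the disk. Class
activation maps use the gradient-weighted scheme at the stage-2 ReLU
(16 × 4 × 4): the final convolution output is 1 × 1, so classic
global-average-pooling CAM is spatially degenerate; channel weights are
spatial gradient means, the weighted sum is rectified, bilinearly
upsampled to 39 × 11 and max-normalized (an identically zero map is
returned as zeros with a warning).

## 7. Numerical choices

- All layers are NumPy with hand-written backpropagation; convolutions
  use im2col plus lead-batched BLAS matmuls; every layer's gradient is
  finite-difference tested.
- Training defaults to float32 (the pipeline) for speed; float64 is used
  wherever gradients are checked. Checkpoints record the dtype.
- Dropout is inverted (scaled at train time); max-pool gradients route to
  the first maximal element of each 2 × 2 window.
- Wave synthesis uses the angle-addition identity (two cosine tables and
  two matmuls over the component axis) rather than evaluating sin on the
  full (trial, lead, component, time) grid.

## 8. Limitations

- Results on real EEG are out of scope here: the directional experiment
  (SAC-pretrained ≥ non-pretrained accuracy; attention concentrated on
  signal-bearing leads, 5 seeds) runs on the synthetic `easy` preset at
  reduced epochs, not on human data, and establishes direction, not
  effect size.
- The scaled-down presets use smaller batches and fewer epochs than the
  full protocol; `paper-scale` implements the full protocol but takes
  CPU-hours.
- Single-process CPU only; no GPU path.
- The binary-condition design is hard-coded in the classifier head and
  the samplers (y1 ∈ {0, 1}); subjects are categorical IDs.
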