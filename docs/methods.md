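# Methods

`microexpr` implements an end-to-end micro-expression recognition (MER)
pipeline built around a double-stream 3-D convolutional network.  This
note records the models, the parameter choices that matter, the design
decisions that were genuinely open, and what the synthetic test bed does
and does not demonstrate.

## Problem setting

A micro-expression is a brief (< 0.5 s), low-intensity, involuntary
facial movement.  Recognising one from video requires (i) isolating the
short temporal neighbourhood of peak motion (the *apex* frame), (ii)
amplifying sub-pixel motion until it is visible to a learned feature
extractor, and (iii) a classifier that uses both appearance and motion.
Because annotated micro-expression corpora are small, training is
augmented with ordinary (*macro*) expression clips from a second domain,
and a domain-adversarial discriminator keeps the learned features from
encoding which corpus a clip came from.

## Preprocessing

**Frame window.**  Exactly 18 frames are taken around the apex: 9 before
and 8 after when both margins exist; the first (or last) 18 frames when
the apex sits too close to the clip start (or end); the first 18 when the
apex is unannotated; and, for clips shorter than 18 frames, all frames
followed by the repeated offset (last) frame.  The rules are mutually
exclusive and exhaustive; a brute-force enumeration oracle in the test
suite confirms the precedence on all small cases.

**Resizing.**  Frames are bilinearly resized to 64x64 (video stream) and
144x120 height x width (flow stream).  144 and 120 are divisible by
2^(levels-1) = 4, which the pyramid decomposition below requires.

**Motion magnification.**  Both resized stacks are processed as whole
18-frame sequences with Eulerian video magnification: each frame is
decomposed into a Laplacian pyramid (5-tap binomial kernel; upsampling is
normalised by the blurred sample comb so constant images are reproduced
exactly at borders, making the round trip exact to machine precision);
each pyramid level's per-pixel time series is band-passed; and the
amplified band is added back, L' = L + alpha * B, before collapsing and
clipping to [0, 1].  Choices:

* *Filter family*: an ideal band-pass applied with the FFT along time.
  Its gain is exactly 1 in-band and 0 out-of-band at DFT bin frequencies,
  which makes the gain properties directly testable.  DC is always
  removed, so static sequences are fixed points for every alpha.
* *Pass-band*: 0.4-3.0 Hz by default (configurable).  Expression-scale
  motion at the frame rates used here falls in this range.
* *Pyramid depth*: 3 levels by default.
* *All levels amplified*, including the low-pass residual, and no
  wavelength-dependent attenuation of alpha.  With this choice a small
  oscillating displacement delta is amplified to (1 + alpha) * delta to
  first order, a prediction the tests verify by sub-pixel centroid
  tracking of a synthetic oscillating blob (within 20% at
  delta = 0.05 px, alpha = 10).
* *Amplification factor*: alpha = 20 by default, the ablation optimum.

**Optical-flow sequence.**  Dense flow is computed between frame pairs at
interval d = 2 over the magnified 144x120 stack: pairs (0,2), (2,4), ...,
(14,16) give 8 two-plane (horizontal, vertical, in pixels) fields,
concatenated into a 144x120x16 volume.  Frame 17 of the window is used
only by the video stream.  The flow engine sits behind a pluggable
`dense_flow` contract; the default engine is scikit-image's iterative
Lucas-Kanade solver (`ilk`), with TV-L1 also registered.  The contract is
what matters and is property-tested: < 0.05 px response on identical
frames, recovery of a 2 px translation within 0.25 px, and antisymmetry
under frame exchange within 0.3 px on textured images.  Flow values are
fed to the network raw (pixels per d-frame interval); a standardisation
flag exists but defaults off.

## Architecture

Two parallel single-channel 3-D convolutional streams:

| stream | input        | convolution                      | pool  | flatten |
|--------|--------------|----------------------------------|-------|---------|
| video  | 64x64x18     | 32 @ 3x3x15, stride (1,1,1)      | 3x3x3 | 12,800  |
| flow   | 144x120x16   | 32 @ 3x3x6,  stride (1,1,2)      | 3x3x3 | 117,312 |

All convolutions are valid (no padding); pooling is non-overlapping
(stride = pool size); dropout 0.5 follows each pool.  The flow stream's
temporal stride of 2 treats each two-plane flow field as one unit.  The
flattened features concatenate to a 130,112-vector feeding

* the **emotion head**: FC(128) -> dropout -> FC(3) + softmax, and
* the **domain discriminator**: gradient-reversal layer ->
  FC(128) -> FC(64) -> FC(32), each with dropout, -> FC(1) + sigmoid.

Totals: 16,660,963 trainable parameters without the discriminator and
33,325,796 with it.  The hidden widths (128; 128, 64, 32) are the unique
integer solutions consistent with those totals given the layer structure;
the discriminator output is read as a 1-unit sigmoid because its loss is
binary cross-entropy on a scalar.  Activations are ReLU (a standard
choice); initialisation is seeded Glorot-uniform.

The network and its backpropagation are implemented directly in NumPy
(`microexpr.nn`): batched im2col convolution, non-overlapping max pooling,
inverted dropout, dense layers, and the gradient-reversal contract.
Gradients of every layer, including the adversarial routing, are verified
against central finite differences in float64 on a reduced architecture.
Max-pool gradients are split equally among tied maxima; ties between
positive activations have measure zero for continuous inputs and ties at
zero are annihilated by the preceding ReLU mask.  Training runs in
float32; float64 is used for verification.

## Training objective

With emotion prediction y_i, one-hot label y_i', domain probability d_i
and domain label d_i' (micro = 0, macro = 1), the per-sample objective is

    L_i = L_y(y_i, y_i') - lambda * L_d(d_i, d_i')

where L_y is categorical cross-entropy, L_d is binary cross-entropy (both
with a 1e-12 floor inside the logarithm), and lambda (default 15, the
ablation optimum) weights the domain-adaptation term.  The saddle
structure — the emotion head and shared features minimise L_y, the
discriminator minimises its own +L_d, and the shared features *maximise*
L_d — is realised by the gradient-reversal layer: identity forward,
gradient multiplied by -lambda backward, with lambda held constant over
training.  Batches (size 8) average the per-sample terms, which only
rescales the learning rate relative to the summed form.  The optimiser is
plain SGD at learning rate 0.01; the reference protocol trains 200
epochs.  Mixed micro/macro batches come from a uniform seeded shuffle of
the combined pool each epoch.  Both domains carry emotion labels
(supervised adaptation).  A non-finite loss aborts training with a
diagnostic rather than being silently repaired.

**Macro-expression reduction.**  Macro clips run onset -> apex, so their
middle frame — taken as the apex, `floor((n-1)/2)` with the even-length
tie broken downward — approximates a micro-expression-scale intermediate
expression.  The standard window rules then apply.

## Evaluation protocol

Leave-one-subject-out cross-validation: one fold per micro-domain
subject; macro samples only ever augment the training side; the model is
re-initialised from the run seed for every fold.  Per-fold confusion
counts are pooled into one matrix before computing

    UF1  = (1/C) sum_c 2 TP_c / (2 TP_c + FP_c + FN_c)
    UAR  = (1/C) sum_c TP_c / n_c
    mAcc = trace / total ,

the unweighted F1 / unweighted average recall convention of the MEGC2019
challenge.  Pooling-first makes the protocol numbers invariant to fold
order; a class with a zero denominator contributes 0, not NaN.
Predictions are the softmax argmax with ties broken toward the lowest
class index.

## Synthetic test bed

Licensed corpora (SAMM, SMIC, CK+) cannot be redistributed, so the
package generates its own clips (`microexpr.fixtures`): a subject-specific
smooth random texture ("face") plus a localised Gaussian patch whose
analytic centre — shifted before rasterisation, so sub-pixel motion is
exact and free of interpolation artifacts — translates downward (class
0), upward (class 1) or as two patches moving horizontally outward
(class 2).  Micro-domain displacement ramps up to a mid-clip apex and
back with ~1 px peak amplitude; the macro domain ramps monotonically to
~6 px at the final frame (onset-to-apex, like posed macro-expression
sequences) and carries no apex annotation.  Gaussian sensor noise
(sigma = 0.01) is added.  Defaults: 12 subjects x 3 balanced clips,
24 frames at 24 fps, 180x148 native frames.

The generator reproduces the features the method depends on — localised
class-dependent sub-pixel motion around an apex, subject-level appearance
variation, a coarser-motion second domain — but not photorealistic faces,
head pose changes, illumination drift, or the correlation structure of
real facial musculature.  Passing the end-to-end tests therefore
demonstrates that the pipeline's machinery (windowing, magnification,
flow, optimisation, protocol) is correct and that the network can exploit
separable motion cues; it says nothing about accuracy on real faces.

## Desk-scale study sizes

The end-to-end learnability study runs LOSOCV over 12 micro subjects (36
clips) with a 4-subject (12-clip) macro pool and 2 training epochs per
fold — training accuracy on this separable data already saturates within
2 epochs, so longer schedules add cost without information.  A
hand-written classifier on onset-to-apex flow direction alone exceeds 90%
on the same data, guaranteeing the learnability bar (pooled UAR > 0.5
against a 1/3 chance level) is meaningful rather than vacuous.

## Known limitations

* **Adversarial instability at large lambda.**  With the gradient-reversal
  constant at the ablation optimum (lambda = 15) and learning rate 0.01,
  the feature extractor receives domain gradients 15x the scale of its
  emotion gradients.  On the synthetic test bed this saddle dynamic is
  prone to positive feedback: runs longer than a few epochs can grow the
  shared weights without bound and abort on a non-finite loss.  The
  reference protocol reports stable training on real corpora; no
  stabiliser that the protocol does not prescribe (gradient clipping,
  lambda annealing, feature normalisation) is added here, so the
  phenomenon is left observable and the acceptance suite records how the
  adapted run compares to the lambda = 0 baseline.
* The ideal temporal filter is non-causal (whole-sequence FFT); streaming
  operation is out of scope.
* Face detection / landmark alignment is a pluggable hook, identity by
  default; inputs are assumed face-aligned.
* The unit-sigmoid discriminator output follows the binary cross-entropy
  loss; implementations that place a softmax over a single unit would
  make the domain branch inert.
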