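# microexpr

Micro-expression recognition with a double-stream 3-D convolutional
network, for researchers studying brief (< 0.5 s), low-intensity facial
movements in high-frame-rate video.

A clip is reduced to an 18-frame window around its apex (peak-motion)
frame; the window is resized and motion-magnified with Eulerian video
magnification (per Laplacian-pyramid level, L' = L + αB with B the
temporally band-passed band); dense optical flow at frame interval d = 2
turns the window into a 144×120×16 motion volume.  Two 3-D convolutional
streams — a 64×64×18 intensity stream (32 filters, 3×3×15) and the flow
stream (32 filters, 3×3×6, temporal stride 2) — concatenate into a
130,112-feature vector feeding a 3-class softmax emotion head and,
optionally, a gradient-reversal domain discriminator that lets
macro-expression clips augment training without letting the features
encode the corpus, via the saddle objective

    L = Σᵢ [ L_y(yᵢ, yᵢ′) − λ · L_d(dᵢ, dᵢ′) ] ,

where L_y is categorical and L_d binary cross-entropy, and λ (default 15)
weights the adversarial term.  Evaluation follows leave-one-subject-out
cross-validation scored with the class-balanced UF1 and UAR of the
MEGC2019 protocol.  The network, including all backpropagation and the
gradient-reversal layer, is implemented in NumPy and verified against
finite differences; licensed corpora are not required — a synthetic clip
generator reproduces the motion structure the method depends on.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from microexpr import (ArchitectureSpec, ConfusionMatrix, EvmConfig,
                       FlowConfig, SynthConfig, build_flow_sequence,
                       build_model, build_window, count_parameters,
                       mean_accuracy, synth_sample, uar, uf1)

model = build_model(ArchitectureSpec(), with_discriminator=True, seed=0)
print("trainable parameters (with discriminator):", count_parameters(model))

sample = synth_sample(class_id=2, subject_id="s000", domain=0,
                      cfg=SynthConfig(seed=7))
window = build_window(sample, EvmConfig(alpha=20.0, fps=sample.fps))
flowseq = build_flow_sequence(window.frames_flowres, FlowConfig(d=2))
print("video stream input:", window.frames_small.shape)
print("flow stream input:", flowseq.volume.shape,
      "from pairs", flowseq.pairs[:3], "...")

cm = ConfusionMatrix(counts=np.array([[8, 1, 1], [2, 6, 2], [0, 0, 10]]))
print(f"UF1 {uf1(cm):.5f}  UAR {uar(cm):.5f}  "
      f"mean accuracy {mean_accuracy(cm):.5f}")
```

prints

```
trainable parameters (with discriminator): 33325796
video stream input: (64, 64, 18)
flow stream input: (144, 120, 16) from pairs [(0, 2), (2, 4), (4, 6)] ...
UF1 0.79182  UAR 0.80000  mean accuracy 0.80000
```

The parameter count is every weight and bias of both streams, the emotion
head and the discriminator (16,660,963 without the discriminator); the
two input shapes are the volumes the streams consume; the metric line is
the class-balanced scoring of a hand-checkable 3-class confusion matrix.

## Command line

The `microexpr` entry point chains the stages:

```
microexpr synth      --subjects 12 --clips 3 --frames 24 --out tree/ --seed 7
microexpr preprocess --in tree/ --out pre/ --alpha 20 --fps 24
microexpr flow       --in pre/ --out flowvols/ --d 2
microexpr losocv     --data tree/ --out results/ --epochs 2 --seed 11
microexpr report     --metrics results/metrics.json
```

`magnify` exposes the motion magnifier on a single image-sequence folder,
`train` fits one model (optionally with `--macro-data` and `--lambda`),
and `evaluate` scores a predictions CSV.  Exit codes: 0 success, 2
configuration error, 3 data error, 4 numerical failure.

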