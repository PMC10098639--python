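"""Supervised domain-adaptation training.

The training objective over N samples is

    L = sum_i [ L_y(y_i, y_i') - lambda * L_d(d_i, d_i') ]

where L_y is categorical cross-entropy on the 3-class emotion prediction,
L_d is binary cross-entropy on the micro/macro domain prediction, and
lambda weights the influence of domain adaptation.  The objective is a
saddle point: the emotion head and the shared features minimise L_y, the
discriminator minimises its own L_d, and the shared features *maximise*
L_d — realised mechanically by the gradient-reversal layer with constant
lambda and a plain +L_d discriminator loss (see :mod:`microexpr.model`).
Batches average the per-sample terms, which only rescales the learning
rate relative to a summed objective.

Macro-expression clips are adapted before windowing by "macro reduction":
the middle frame stands in as the apex, on the assumption that a
micro-expression apex resembles the intermediate phase between a
macro-expression's onset and apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np

from .datasets_io import DOMAIN_MACRO, Sample
from .errors import DataError, NumericalError
from .evm import EvmConfig
from .flow import FlowConfig, build_flow_sequence
from .model import ModelHandle, backward_batch, forward, forward_batch
from .preprocess import build_window

LOG_FLOOR = 1e-12


@dataclass
class TrainConfig:
    """Optimisation settings.

    ``lambda_da`` is the domain-adaptation loss weight (ablation optimum
    15); ``alpha_evm`` is passed through to preprocessing (optimum 20).
    The optimiser is plain SGD at learning rate 0.01, 200 epochs, batch 8.
    """

    lambda_da: float = 15.0
    alpha_evm: float = 20.0
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.lambda_da < 0:
            raise ValueError("lambda_da must be >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid batch size or epoch count")


@dataclass
class LossBatch:
    """Predicted/true emotions and domains for a batch of samples."""

    emotion_probs: Sequence[np.ndarray]
    emotion_true: Sequence[np.ndarray]    # one-hot rows
    domain_probs: Sequence[float]
    domain_true: Sequence[int]


def emotion_loss(y: np.ndarray, y_true: np.ndarray) -> float:
    """Categorical cross-entropy -sum_c y'_c log y_c with a 1e-12 log floor."""
    y = np.clip(np.asarray(y, dtype=np.float64), LOG_FLOOR, None)
    return float(-(np.asarray(y_true) * np.log(y)).sum())


def domain_loss(d: float, d_true: int) -> float:
    """Binary cross-entropy -[d' log d + (1 - d') log(1 - d)], clamped."""
    d = min(max(float(d), LOG_FLOOR), 1.0 - LOG_FLOOR)
    return float(-(d_true * np.log(d) + (1 - d_true) * np.log(1.0 - d)))


def total_loss(batch: LossBatch, lambda_da: float) -> float:
    """Mean over the batch of emotion_loss - lambda * domain_loss."""
    n = len(batch.emotion_probs)
    if n == 0:
        raise DataError("empty loss batch")
    ly = np.mean([emotion_loss(y, t)
                  for y, t in zip(batch.emotion_probs, batch.emotion_true)])
    if batch.domain_probs is not None and len(batch.domain_probs):
        ld = np.mean([domain_loss(d, t)
                      for d, t in zip(batch.domain_probs, batch.domain_true)])
    else:
        ld = 0.0
    return float(ly - lambda_da * ld)


def reduce_macro_sample(sample: Sample) -> Sample:
    """Apply macro-expression reduction: middle frame becomes the apex."""
    if sample.domain != DOMAIN_MACRO:
        raise DataError(
            f"macro reduction applies to macro-domain samples, got domain "
            f"{sample.domain}")
    n = sample.n_frames
    if n < 1:
        raise DataError(f"clip {sample.clip_id} is empty")
    return sample.with_apex((n - 1) // 2)


@dataclass
class PreparedSample:
    """Network-ready tensors plus labels for one clip."""

    clip_id: str
    subject_id: str
    emotion: int
    domain: int
    video: np.ndarray      # (64, 64, 18)
    flow: np.ndarray       # (144, 120, 16)


def prepare_sample(sample: Sample, evm_cfg: EvmConfig,
                   flow_cfg: FlowConfig) -> PreparedSample:
    """Preprocess one clip into the two stream inputs.

    Macro-domain clips get macro reduction first; then the 18-frame window
    is selected, resized, magnified, and the flow volume assembled.
    """
    if sample.domain == DOMAIN_MACRO:
        sample = reduce_macro_sample(sample)
    window = build_window(sample, evm_cfg)
    flowseq = build_flow_sequence(window.frames_flowres, flow_cfg)
    return PreparedSample(clip_id=sample.clip_id, subject_id=sample.subject_id,
                          emotion=sample.emotion, domain=sample.domain,
                          video=window.frames_small.astype(np.float64),
                          flow=flowseq.volume)


def prepare_dataset(samples: Iterable[Sample], evm_cfg: EvmConfig,
                    flow_cfg: FlowConfig) -> List[PreparedSample]:
    return [prepare_sample(s, evm_cfg, flow_cfg) for s in samples]


@dataclass
class FitResult:
    model: ModelHandle
    loss_history: List[float] = field(default_factory=list)


def fit(model: ModelHandle, train_data: Sequence[PreparedSample],
        cfg: TrainConfig) -> FitResult:
    """SGD training loop over the combined micro+macro pool.

    Per epoch the pool is uniformly shuffled (seeded) and consumed in
    batches; gradients are averaged over each batch.  Both domains carry
    emotion labels (supervised adaptation), so every sample contributes to
    the emotion loss, and every sample contributes to the domain loss when
    the model has a discriminator and lambda routing is active.  Returns
    the trained model and the per-epoch mean total loss.
    """
    cfg.validate()
    data = list(train_data)
    if not data:
        raise DataError("cannot fit on an empty training set")
    rng = np.random.default_rng(cfg.seed)
    history: List[float] = []
    use_domain = model.with_discriminator

    videos = np.stack([item.video for item in data]).astype(np.float32)
    flows = np.stack([item.flow for item in data]).astype(np.float32)
    emotions = np.array([item.emotion for item in data], dtype=int)
    domains = np.array([item.domain for item in data], dtype=int)

    for _ in range(cfg.epochs):
        order = rng.permutation(len(data))
        epoch_losses = []
        for start in range(0, len(data), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            res = forward_batch(model, videos[idx], flows[idx],
                                grl_lambda=cfg.lambda_da, train=True, rng=rng)
            grads = backward_batch(model, res, emotions[idx],
                                   domains[idx] if use_domain else None)
            onehot = np.eye(model.spec.n_classes)[emotions[idx]]
            loss = total_loss(
                LossBatch(res.emotion_probs, onehot,
                          res.domain_probs if use_domain else [],
                          domains[idx] if use_domain else []),
                cfg.lambda_da if use_domain else 0.0)
            if not np.isfinite(loss):
                raise NumericalError(
                    f"non-finite loss {loss} at epoch {len(history)}")
            epoch_losses.append(loss)
            scale = cfg.learning_rate / len(idx)
            for k, g in grads.items():
                model.params[k] -= (scale * g).astype(model.params[k].dtype)
        history.append(float(np.mean(epoch_losses)))
    return FitResult(model=model, loss_history=history)


def predict(model: ModelHandle, item: PreparedSample) -> np.ndarray:
    """Inference-mode emotion probabilities for one prepared sample."""
    return forward(model, item.video, item.flow, train=False).emotion_probs
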