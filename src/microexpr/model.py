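"""The double-stream 3-D CNN with emotion head and domain discriminator.

Two single-channel input volumes are processed by parallel 3-D
convolutional streams:

* video stream  — 64x64x18 magnified intensity volume; 32 filters of
  3x3x15, stride (1,1,1), no padding; 3x3x3 max pool (stride = pool);
  dropout 0.5; flatten to 12,800 features.
* flow stream   — 144x120x16 optical-flow volume; 32 filters of 3x3x6,
  stride (1,1,2) because each flow field occupies two temporal planes and
  is treated as one unit; same pool/dropout; flatten to 117,312 features.

The concatenated 130,112-feature vector feeds (i) the emotion head — a
dense layer of width 128, dropout, then a 3-way softmax — and, optionally,
(ii) a domain discriminator — a gradient-reversal layer followed by dense
layers of widths 128, 64, 32 (each with dropout) and a 1-unit sigmoid
output separating micro- from macro-expression samples.  The gradient
reversal is the identity in the forward pass and multiplies gradients by
-lambda on the way back, which makes the shared convolutional features
adversarial to the discriminator.

Parameter totals with the default hyperparameters are 16,660,963 without
and 33,325,796 with the discriminator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import nn
from .errors import DataError

THETA_F = "theta_f"
THETA_Y = "theta_y"
THETA_D = "theta_d"


@dataclass
class ArchitectureSpec:
    """Layer hyperparameters of the two streams and the two heads."""

    video_input: Tuple[int, int, int] = (64, 64, 18)
    video_filters: int = 32
    video_kernel: Tuple[int, int, int] = (3, 3, 15)
    video_stride: Tuple[int, int, int] = (1, 1, 1)

    flow_input: Tuple[int, int, int] = (144, 120, 16)
    flow_filters: int = 32
    flow_kernel: Tuple[int, int, int] = (3, 3, 6)
    flow_stride: Tuple[int, int, int] = (1, 1, 2)

    pool: Tuple[int, int, int] = (3, 3, 3)
    dropout: float = 0.5

    n_classes: int = 3
    head_hidden: int = 128
    disc_hidden: Tuple[int, ...] = (128, 64, 32)

    # -- shape arithmetic (valid convolution, pool stride = pool size) --

    def video_conv_shape(self) -> Tuple[int, int, int]:
        return nn.conv_output_shape(self.video_input, self.video_kernel,
                                    self.video_stride)

    def video_pool_shape(self) -> Tuple[int, int, int]:
        return nn.conv_output_shape(self.video_conv_shape(), self.pool,
                                    self.pool)

    def flow_conv_shape(self) -> Tuple[int, int, int]:
        return nn.conv_output_shape(self.flow_input, self.flow_kernel,
                                    self.flow_stride)

    def flow_pool_shape(self) -> Tuple[int, int, int]:
        return nn.conv_output_shape(self.flow_conv_shape(), self.pool,
                                    self.pool)

    def video_flatten(self) -> int:
        return self.video_filters * int(np.prod(self.video_pool_shape()))

    def flow_flatten(self) -> int:
        return self.flow_filters * int(np.prod(self.flow_pool_shape()))

    def feature_length(self) -> int:
        return self.video_flatten() + self.flow_flatten()

    def validate(self) -> None:
        for shape_fn in (self.video_conv_shape, self.video_pool_shape,
                         self.flow_conv_shape, self.flow_pool_shape):
            if any(s < 1 for s in shape_fn()):
                raise DataError(
                    f"degenerate layer shape from {shape_fn.__name__}")
        if self.n_classes < 2 or self.head_hidden < 1:
            raise DataError("invalid head configuration")


@dataclass
class ModelHandle:
    """Parameter container for the three trainable groups.

    ``theta_f`` holds both convolutional streams, ``theta_y`` the emotion
    head and ``theta_d`` the discriminator.
    """

    spec: ArchitectureSpec
    with_discriminator: bool
    seed: int
    params: Dict[str, np.ndarray] = field(default_factory=dict)

    def group_keys(self, group: Optional[str] = None):
        groups = {
            THETA_F: ["conv_v_W", "conv_v_b", "conv_f_W", "conv_f_b"],
            THETA_Y: ["head_fc_W", "head_fc_b", "head_out_W", "head_out_b"],
            THETA_D: sorted(k for k in self.params if k.startswith("disc_")),
        }
        if group is None:
            keys = groups[THETA_F] + groups[THETA_Y] + groups[THETA_D]
        else:
            keys = groups[group]
        return [k for k in keys if k in self.params]

    @property
    def dtype(self):
        return self.params["conv_v_W"].dtype


def build_model(spec: ArchitectureSpec, with_discriminator: bool, seed: int,
                dtype=np.float32) -> ModelHandle:
    """Instantiate all trainable parameters with seeded Glorot-uniform init.

    float32 is the working precision for training; float64 is available
    for high-precision gradient verification.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    p: Dict[str, np.ndarray] = {}

    for name, filters, kernel in (
            ("conv_v", spec.video_filters, spec.video_kernel),
            ("conv_f", spec.flow_filters, spec.flow_kernel)):
        k = int(np.prod(kernel))
        p[f"{name}_W"] = nn.glorot_uniform(rng, (filters, *kernel), k,
                                           k * filters, dtype)
        p[f"{name}_b"] = np.zeros(filters, dtype=dtype)

    feat = spec.feature_length()
    p["head_fc_W"] = nn.glorot_uniform(rng, (spec.head_hidden, feat), feat,
                                       spec.head_hidden, dtype)
    p["head_fc_b"] = np.zeros(spec.head_hidden, dtype=dtype)
    p["head_out_W"] = nn.glorot_uniform(rng, (spec.n_classes, spec.head_hidden),
                                        spec.head_hidden, spec.n_classes, dtype)
    p["head_out_b"] = np.zeros(spec.n_classes, dtype=dtype)

    if with_discriminator:
        widths = [feat, *spec.disc_hidden, 1]
        for i in range(len(widths) - 1):
            fan_in, fan_out = widths[i], widths[i + 1]
            p[f"disc_fc{i}_W"] = nn.glorot_uniform(rng, (fan_out, fan_in),
                                                   fan_in, fan_out, dtype)
            p[f"disc_fc{i}_b"] = np.zeros(fan_out, dtype=dtype)

    return ModelHandle(spec=spec, with_discriminator=with_discriminator,
                       seed=seed, params=p)


def count_parameters(model: ModelHandle, group: Optional[str] = None) -> int:
    """Total trainable scalars, optionally restricted to one group."""
    return int(sum(model.params[k].size for k in model.group_keys(group)))


@dataclass
class BatchResult:
    """Forward outputs for a batch: probs (B, 3), domain (B,) or None."""

    emotion_probs: np.ndarray
    domain_probs: Optional[np.ndarray]
    cache: dict


@dataclass
class ForwardResult:
    """Single-sample view: probs (3,), scalar domain probability."""

    emotion_probs: np.ndarray
    domain_prob: Optional[float]
    cache: dict


def _stream_forward(x, weight, bias, stride, pool, dropout, train, rng):
    conv, conv_cache = nn.conv3d_forward(x, weight, bias, stride)
    act, relu_mask = nn.relu_forward(conv)
    pooled, pool_cache = nn.maxpool3d_forward(act, pool)
    dropped, drop_mask = nn.dropout_forward(pooled, dropout, train, rng)
    flat = dropped.reshape(dropped.shape[0], -1)
    cache = (conv_cache, relu_mask, pool_cache, drop_mask, dropped.shape)
    return flat, cache


def forward_batch(model: ModelHandle, videos: np.ndarray, flows: np.ndarray,
                  grl_lambda: float = 0.0, train: bool = False,
                  rng: Optional[np.random.Generator] = None) -> BatchResult:
    """Run both streams and heads on a batch.

    ``grl_lambda`` is recorded for the backward pass only; the gradient
    reversal is the identity in forward propagation, so it never changes
    forward values.  Dropout is active only when ``train`` is true, in
    which case ``rng`` drives the masks.
    """
    spec = model.spec
    dtype = model.dtype
    videos = np.asarray(videos, dtype=dtype)
    flows = np.asarray(flows, dtype=dtype)
    if videos.ndim != 4 or videos.shape[1:] != spec.video_input:
        raise DataError(
            f"video stream expects inputs (B, {spec.video_input}), got "
            f"{videos.shape}")
    if flows.ndim != 4 or flows.shape[1:] != spec.flow_input:
        raise DataError(
            f"flow stream expects inputs (B, {spec.flow_input}), got "
            f"{flows.shape}")
    if train and rng is None:
        rng = np.random.default_rng(model.seed)
    p = model.params

    flat_v, cache_v = _stream_forward(videos, p["conv_v_W"], p["conv_v_b"],
                                      spec.video_stride, spec.pool,
                                      spec.dropout, train, rng)
    flat_f, cache_f = _stream_forward(flows, p["conv_f_W"], p["conv_f_b"],
                                      spec.flow_stride, spec.pool,
                                      spec.dropout, train, rng)
    feat = np.concatenate([flat_v, flat_f], axis=1)

    h, fc_cache = nn.dense_forward(feat, p["head_fc_W"], p["head_fc_b"])
    h_act, h_mask = nn.relu_forward(h)
    h_drop, h_drop_mask = nn.dropout_forward(h_act, spec.dropout, train, rng)
    logits, out_cache = nn.dense_forward(h_drop, p["head_out_W"],
                                         p["head_out_b"])
    probs = nn.softmax(logits)

    domain_probs = None
    disc_caches = None
    if model.with_discriminator:
        # gradient-reversal layer: identity here, -lambda in backward
        x = feat
        disc_caches = []
        n_hidden = len(spec.disc_hidden)
        for i in range(n_hidden):
            z, d_cache = nn.dense_forward(x, p[f"disc_fc{i}_W"],
                                          p[f"disc_fc{i}_b"])
            a, d_mask = nn.relu_forward(z)
            x, d_drop = nn.dropout_forward(a, spec.dropout, train, rng)
            disc_caches.append((d_cache, d_mask, d_drop))
        logit_d, d_out_cache = nn.dense_forward(x, p[f"disc_fc{n_hidden}_W"],
                                                p[f"disc_fc{n_hidden}_b"])
        domain_probs = nn.sigmoid(logit_d[:, 0])
        disc_caches.append(d_out_cache)

    cache = {
        "stream_v": cache_v, "stream_f": cache_f,
        "split": flat_v.shape[1],
        "head": (fc_cache, h_mask, h_drop_mask, out_cache),
        "probs": probs, "domain_probs": domain_probs,
        "disc": disc_caches, "grl_lambda": grl_lambda,
    }
    return BatchResult(emotion_probs=probs, domain_probs=domain_probs,
                       cache=cache)


def _stream_backward(dflat, cache):
    conv_cache, relu_mask, pool_cache, drop_mask, dropped_shape = cache
    dpooled = nn.dropout_backward(dflat.reshape(dropped_shape), drop_mask)
    dact = nn.maxpool3d_backward(dpooled, pool_cache)
    dconv = nn.relu_backward(dact, relu_mask)
    return nn.conv3d_backward(dconv, conv_cache, need_dx=False)


def backward_batch(model: ModelHandle, result: BatchResult,
                   emotion_true: np.ndarray,
                   domain_true: Optional[np.ndarray] = None
                   ) -> Dict[str, np.ndarray]:
    """Summed-over-batch gradients of the training objective.

    The emotion head propagates categorical cross-entropy; when domain
    labels are given, the discriminator propagates binary cross-entropy
    into its own parameters unweighted, while the gradient entering the
    shared features is multiplied by ``-grl_lambda`` (the gradient-reversal
    contract), realising the saddle-point update of adversarial domain
    adaptation.
    """
    cache = result.cache
    spec = model.spec
    grads: Dict[str, np.ndarray] = {}
    emotion_true = np.asarray(emotion_true, dtype=int)
    b = emotion_true.shape[0]

    # emotion head: d(CE)/d(logits) = probs - onehot, per row
    dlogits = cache["probs"].copy()
    dlogits[np.arange(b), emotion_true] -= 1.0
    fc_cache, h_mask, h_drop_mask, out_cache = cache["head"]
    dh_drop, grads["head_out_W"], grads["head_out_b"] = \
        nn.dense_backward(dlogits, out_cache)
    dh = nn.relu_backward(nn.dropout_backward(dh_drop, h_drop_mask), h_mask)
    dfeat, grads["head_fc_W"], grads["head_fc_b"] = \
        nn.dense_backward(dh, fc_cache)

    if model.with_discriminator and domain_true is not None:
        disc_caches = cache["disc"]
        n_hidden = len(spec.disc_hidden)
        # d(BCE)/d(logit) = sigmoid(logit) - label, per row
        dlogit_d = (cache["domain_probs"]
                    - np.asarray(domain_true, dtype=model.dtype))[:, None]
        dx, grads[f"disc_fc{n_hidden}_W"], grads[f"disc_fc{n_hidden}_b"] = \
            nn.dense_backward(dlogit_d.astype(model.dtype), disc_caches[-1])
        for i in range(n_hidden - 1, -1, -1):
            d_cache, d_mask, d_drop = disc_caches[i]
            dz = nn.relu_backward(nn.dropout_backward(dx, d_drop), d_mask)
            dx, grads[f"disc_fc{i}_W"], grads[f"disc_fc{i}_b"] = \
                nn.dense_backward(dz, d_cache)
        dfeat = dfeat + nn.grl_backward(dx, cache["grl_lambda"])
    elif model.with_discriminator:
        for k in model.group_keys(THETA_D):
            grads[k] = np.zeros_like(model.params[k])

    split = cache["split"]
    _, grads["conv_v_W"], grads["conv_v_b"] = \
        _stream_backward(np.ascontiguousarray(dfeat[:, :split]),
                         cache["stream_v"])
    _, grads["conv_f_W"], grads["conv_f_b"] = \
        _stream_backward(np.ascontiguousarray(dfeat[:, split:]),
                         cache["stream_f"])
    return grads


def forward(model: ModelHandle, video: np.ndarray, flowseq: np.ndarray,
            grl_lambda: float = 0.0, train: bool = False,
            rng: Optional[np.random.Generator] = None) -> ForwardResult:
    """Single-sample convenience wrapper around :func:`forward_batch`."""
    res = forward_batch(model, np.asarray(video)[None],
                        np.asarray(flowseq)[None], grl_lambda=grl_lambda,
                        train=train, rng=rng)
    domain = None if res.domain_probs is None else float(res.domain_probs[0])
    return ForwardResult(emotion_probs=res.emotion_probs[0],
                         domain_prob=domain, cache=res.cache)


def backward(model: ModelHandle, result: ForwardResult, emotion_true: int,
             domain_true: Optional[int] = None) -> Dict[str, np.ndarray]:
    """Single-sample gradients; see :func:`backward_batch`."""
    batch = BatchResult(
        emotion_probs=np.atleast_2d(result.emotion_probs),
        domain_probs=(None if result.domain_prob is None
                      else np.array([result.domain_prob])),
        cache=result.cache)
    return backward_batch(model, batch, np.array([emotion_true]),
                          None if domain_true is None
                          else np.array([domain_true]))


def save_checkpoint(model: ModelHandle, directory) -> None:
    """Write parameters (.npz) plus a framework-neutral JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **model.params)
    manifest = {
        "with_discriminator": model.with_discriminator,
        "seed": model.seed,
        "spec": {k: v for k, v in vars(model.spec).items()},
        "layers": [
            {"name": k, "shape": list(model.params[k].shape),
             "size": int(model.params[k].size)}
            for k in sorted(model.params)
        ],
        "parameter_counts": {
            "total": count_parameters(model),
            THETA_F: count_parameters(model, THETA_F),
            THETA_Y: count_parameters(model, THETA_Y),
            THETA_D: count_parameters(model, THETA_D),
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(directory) -> ModelHandle:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    spec_kwargs = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["spec"].items()
    }
    spec = ArchitectureSpec(**spec_kwargs)
    data = np.load(directory / "params.npz")
    return ModelHandle(spec=spec,
                       with_discriminator=manifest["with_discriminator"],
                       seed=manifest["seed"],
                       params={k: data[k] for k in data.files})
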