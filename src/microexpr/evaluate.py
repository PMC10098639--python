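"""Leave-one-subject-out cross-validation and class-balanced metrics.

Each fold holds out every clip of one subject; macro-expression samples
only ever augment the training side.  Fold confusion counts are pooled
into a single matrix before computing the metrics (the MEGC2019
convention), which makes the protocol-level numbers invariant to fold
order:

    UF1   = (1/C) sum_c 2 TP_c / (2 TP_c + FP_c + FN_c)
    UAR   = (1/C) sum_c TP_c / n_c
    mAcc  = trace / total

A class with a zero denominator contributes 0 (not NaN) to the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datasets_io import DOMAIN_MICRO, Catalog
from .errors import DataError, ProtocolError
from .evm import EvmConfig
from .flow import FlowConfig
from .model import ArchitectureSpec, build_model
from .train import (PreparedSample, TrainConfig, fit, predict,
                    prepare_dataset)

N_CLASSES = 3


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predictions."""

    counts: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels: Sequence[int], predicted: Sequence[int],
              n_classes: int = N_CLASSES) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if true_labels.shape != predicted.shape:
        raise DataError("label arrays must have equal length")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(true_labels, predicted):
        if not (0 <= t < n_classes and 0 <= p < n_classes):
            raise DataError(f"label out of range: true={t}, predicted={p}")
        counts[t, p] += 1
    return ConfusionMatrix(counts=counts)


def _per_class(cm: ConfusionMatrix):
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    return tp, fp, fn


def uf1(cm: ConfusionMatrix) -> float:
    """Unweighted (macro-averaged) F1 over classes."""
    tp, fp, fn = _per_class(cm)
    denom = 2 * tp + fp + fn
    scores = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    return float(scores.mean())


def uar(cm: ConfusionMatrix) -> float:
    """Unweighted average recall over classes."""
    tp, _, fn = _per_class(cm)
    n_c = tp + fn
    recalls = np.where(n_c > 0, tp / np.where(n_c > 0, n_c, 1), 0.0)
    return float(recalls.mean())


def mean_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of all samples predicted correctly (trace / total)."""
    if cm.total == 0:
        raise DataError("mean accuracy undefined for an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


@dataclass
class MetricsReport:
    uf1: float
    uar: float
    mean_accuracy: float
    pooled_confusion: ConfusionMatrix
    per_fold: List[Dict] = field(default_factory=list)
    predictions: List[Dict] = field(default_factory=list)


def losocv_folds(catalog: Catalog) -> List[Tuple[str, List, List]]:
    """One (test_subject, train_samples, test_samples) triple per subject.

    Folds are defined by the subjects owning micro-domain samples; any
    macro-domain samples in the catalog stay in every fold's training set.
    """
    micro_subjects = []
    for s in catalog.samples:
        if s.domain == DOMAIN_MICRO and s.subject_id not in micro_subjects:
            micro_subjects.append(s.subject_id)
    if len(micro_subjects) < 2:
        raise ProtocolError(
            "leave-one-subject-out needs at least 2 micro-domain subjects")
    folds = []
    for subject in micro_subjects:
        test = [s for s in catalog.samples
                if s.domain == DOMAIN_MICRO and s.subject_id == subject]
        train = [s for s in catalog.samples
                 if s.domain != DOMAIN_MICRO or s.subject_id != subject]
        folds.append((subject, train, test))
    return folds


def predict_labels(model, items: Sequence[PreparedSample]):
    """Argmax predictions (ties break to the lowest class index)."""
    preds, probs = [], []
    for item in items:
        p = predict(model, item)
        preds.append(int(np.argmax(p)))   # np.argmax returns the first maximum
        probs.append(p)
    return preds, probs


def prepare_pool(catalog: Catalog, macro_catalog: Optional[Catalog],
                 evm_cfg: EvmConfig, flow_cfg: FlowConfig) -> Dict[str, PreparedSample]:
    """Preprocess every clip once, keyed by clip id (reusable across runs)."""
    samples = list(catalog.samples)
    if macro_catalog is not None:
        samples = samples + list(macro_catalog.samples)
    return {s.clip_id: p
            for s, p in zip(samples,
                            prepare_dataset(samples, evm_cfg, flow_cfg))}


def run_losocv(catalog: Catalog, macro_catalog: Optional[Catalog],
               train_cfg: TrainConfig, spec: Optional[ArchitectureSpec] = None,
               evm_cfg: Optional[EvmConfig] = None,
               flow_cfg: Optional[FlowConfig] = None,
               with_discriminator: Optional[bool] = None,
               prepared: Optional[Dict[str, PreparedSample]] = None
               ) -> MetricsReport:
    """Full LOSOCV protocol on preprocessed samples.

    All clips are preprocessed once up front; the model is re-initialised
    from the run seed for every fold, trained on the remaining subjects
    (plus all macro samples) and evaluated on the held-out subject.  Fold
    confusion counts are pooled before computing UF1 / UAR / mean accuracy.
    """
    spec = spec or ArchitectureSpec()
    evm_cfg = evm_cfg or EvmConfig(alpha=train_cfg.alpha_evm)
    flow_cfg = flow_cfg or FlowConfig()
    if with_discriminator is None:
        with_discriminator = macro_catalog is not None and len(macro_catalog) > 0

    samples = list(catalog.samples)
    if macro_catalog is not None:
        samples = samples + list(macro_catalog.samples)
    pool = Catalog(samples=samples, class_names=catalog.class_names)

    if prepared is None:
        prepared = prepare_pool(catalog, macro_catalog, evm_cfg, flow_cfg)

    per_fold, predictions = [], []
    pooled = np.zeros((spec.n_classes, spec.n_classes), dtype=int)
    for fold_idx, (subject, train_s, test_s) in enumerate(losocv_folds(pool)):
        model = build_model(spec, with_discriminator, seed=train_cfg.seed)
        fold_cfg = TrainConfig(**{**vars(train_cfg),
                                  "seed": train_cfg.seed + fold_idx})
        fit(model, [prepared[s.clip_id] for s in train_s], fold_cfg)
        test_items = [prepared[s.clip_id] for s in test_s]
        preds, probs = predict_labels(model, test_items)
        truths = [item.emotion for item in test_items]
        cm = confusion(truths, preds, spec.n_classes)
        pooled += cm.counts
        per_fold.append({
            "subject": subject, "n_test": len(test_items),
            "uar": uar(cm), "uf1": uf1(cm),
            "mean_accuracy": mean_accuracy(cm),
        })
        for item, t, pr, pb in zip(test_items, truths, preds, probs):
            predictions.append({
                "clip_id": item.clip_id, "subject": item.subject_id,
                "true": t, "predicted": pr,
                "probabilities": [float(x) for x in pb],
            })
    pooled_cm = ConfusionMatrix(counts=pooled)
    return MetricsReport(uf1=uf1(pooled_cm), uar=uar(pooled_cm),
                         mean_accuracy=mean_accuracy(pooled_cm),
                         pooled_confusion=pooled_cm, per_fold=per_fold,
                         predictions=predictions)
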