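"""Classifier training, AUC-weighted ensembling, thresholding and metrics.

The classifier is an ensemble of CNN backbones trained with transfer
learning in the original method (Xception, ResNet50, VGG19,
EfficientNetB1).  Those four require an optional deep-learning framework
and pretrained weights; the first-class, always-available member here is
the ``tiny`` backbone (a small numpy CNN, see :mod:`strokeface.nn`)
which trains on a CPU in seconds and exposes the same interface.

Per sample, replicate probabilities are averaged; per backbone, the
per-fold held-out AUC weights the ensemble:

    K = 1 / sum_i AUC_i
    final probability = sum_i K * AUC_i * p_i

Samples with final probability >= 0.40 are classified as stroke, and the
binomial normal-approximation interval Int = z * sqrt(Accu(1-Accu)/N)
quantifies accuracy uncertainty (z = 1.96 for a 95% interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from strokeface.dataset import FoldPlan, Replicate, Sample, flip_image
from strokeface.geometry import FaceImagePair
from strokeface.nn import TinyConvNet

NAMED_BACKBONES = ("xception", "resnet50", "vgg19", "efficientnetb1")
DEFAULT_THRESHOLD = 0.40

# fixed affine for the optional 4th (depth) channel: cm -> [0, 1]
_DEPTH_OFFSET_CM = 8.0
_DEPTH_SCALE_CM = 10.0


class OptionalDependencyError(ImportError):
    """A named heavyweight backbone was requested without its framework."""


@dataclass(frozen=True)
class BackboneSpec:
    """One ensemble member.  ``tiny`` is self-contained; the four named
    networks are optional plugins that need a deep-learning framework and
    pretrained weights."""

    name: str = "tiny"
    pretrained: bool = False
    in_channels: int = 3
    conv_channels: tuple[int, int] = (8, 16)
    pooled_size: int = 28

    def __post_init__(self) -> None:
        if self.name not in NAMED_BACKBONES + ("tiny",):
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.in_channels not in (3, 4):
            raise ValueError("in_channels must be 3 or 4")

    def build(self, seed: int = 0) -> TinyConvNet:
        if self.name != "tiny":
            raise OptionalDependencyError(
                f"backbone {self.name!r} requires the optional tensorflow/keras "
                "dependency and pretrained weights; use the 'tiny' backbone for "
                "self-contained CPU runs"
            )
        return TinyConvNet(
            in_channels=self.in_channels,
            conv_channels=self.conv_channels,
            pooled_size=self.pooled_size,
            seed=seed,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  Defaults follow the original protocol
    (Adam, lr 1e-4, binary cross-entropy, 20 epochs); the tiny profile
    used throughout tests is ``TrainConfig.tiny()`` (5 epochs, lr 1e-3)."""

    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 16
    optimizer: str = "adam"
    loss: str = "binary_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")

    @classmethod
    def tiny(cls, seed: int = 0, epochs: int = 5) -> "TrainConfig":
        return cls(epochs=epochs, learning_rate=1e-3, batch_size=16, seed=seed)


@dataclass
class StrokeScore:
    sample_id: str
    per_backbone_probability: Mapping[str, float]
    per_backbone_auc: Mapping[str, float]
    final_probability: float
    predicted_label: str
    fold: int = -1


@dataclass
class MetricReport:
    auc: float
    accuracy: float
    true_positive_rate: float
    false_positive_rate: float
    n: int
    ci_half_width: float
    z: float
    threshold: float


# ---------------------------------------------------------------------------
# Image tensors
# ---------------------------------------------------------------------------

def pair_to_array(pair: FaceImagePair, channels: int = 3) -> np.ndarray:
    """FaceImagePair -> (C, H, W) float32 in [0, 1]; channel 4 is depth."""
    tex = np.transpose(pair.texture, (2, 0, 1)).astype(np.float32) / 255.0
    if channels == 3:
        return tex
    if channels == 4:
        d = np.clip((pair.depth + _DEPTH_OFFSET_CM) / _DEPTH_SCALE_CM, 0.0, 1.0)
        return np.concatenate([tex, d[None].astype(np.float32)], axis=0)
    raise ValueError("channels must be 3 or 4")


def _replicate_array(
    rep: Replicate, images: Mapping[str, FaceImagePair], channels: int
) -> np.ndarray:
    pair = images[rep.sample_id]
    if rep.orientation == "flip":
        pair = flip_image(pair)
    return pair_to_array(pair, channels)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def train_backbone(
    spec: BackboneSpec,
    plan: FoldPlan,
    images: Mapping[str, FaceImagePair],
    labels: Mapping[str, str],
    config: TrainConfig,
    fold: int,
) -> TinyConvNet:
    """Train one backbone on the 9 training folds' replicates of ``fold``."""
    reps = plan.training_replicates(fold)
    if not reps:
        raise ValueError(f"fold {fold} has no training replicates")
    first = images[reps[0].sample_id]
    if spec.in_channels == 4 and first.depth is None:
        raise ValueError("4-channel spec but images carry no depth")
    X = np.stack([_replicate_array(r, images, spec.in_channels) for r in reps])
    y = np.array([1 if labels[r.sample_id] == "stroke" else 0 for r in reps])
    model = spec.build(seed=config.seed)
    model.fit(
        X,
        y,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    return model


def sample_probability(
    model: TinyConvNet,
    replicates: Sequence[np.ndarray],
) -> float:
    """Mean class-1 probability over all augmented replicates of one sample."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    probs = model.predict_proba(np.stack(replicates))[:, 1]
    return float(probs.mean())


def predict_samples(
    model: TinyConvNet,
    plan: FoldPlan,
    images: Mapping[str, FaceImagePair],
    sample_ids: Sequence[str],
    channels: int,
) -> dict[str, float]:
    out = {}
    for sid in sample_ids:
        arrays = [_replicate_array(r, images, channels) for r in plan.replicates[sid]]
        out[sid] = sample_probability(model, arrays)
    return out


# ---------------------------------------------------------------------------
# Ensemble, threshold, metrics
# ---------------------------------------------------------------------------

def ensemble(per_backbone_probs: Sequence[float], per_backbone_aucs: Sequence[float]) -> float:
    """AUC-weighted convex combination of member probabilities."""
    p = np.asarray(per_backbone_probs, dtype=float)
    a = np.asarray(per_backbone_aucs, dtype=float)
    if p.shape != a.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("probability and AUC vectors must be equal-length 1-D")
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("AUCs must lie in [0, 1]")
    total = a.sum()
    if total <= 0:
        raise ValueError("ensemble weights undefined: all AUCs are zero")
    return float((a / total) @ p)


def classify(final_probability: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Stroke iff probability >= threshold (boundary inclusive)."""
    if not 0.0 <= final_probability <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    return "stroke" if final_probability >= threshold else "control"


def confidence_interval(accuracy: float, n: int, z: float = 1.96) -> float:
    """Binomial normal-approximation half-width z * sqrt(Accu(1-Accu)/N)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    return float(z * np.sqrt(accuracy * (1.0 - accuracy) / n))


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with midrank ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: need both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(
    scores: Sequence[StrokeScore],
    labels: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    z: float = 1.96,
) -> MetricReport:
    """ROC AUC plus thresholded accuracy/TPR/FPR with the binomial CI."""
    y = np.array([1 if labels[s.sample_id] == "stroke" else 0 for s in scores])
    p = np.array([s.final_probability for s in scores])
    auc = auc_score(y, p)
    pred = (p >= threshold).astype(int)
    acc = float((pred == y).mean())
    tpr = float(pred[y == 1].mean()) if (y == 1).any() else np.nan
    fpr = float(pred[y == 0].mean()) if (y == 0).any() else np.nan
    return MetricReport(
        auc=auc,
        accuracy=acc,
        true_positive_rate=tpr,
        false_positive_rate=fpr,
        n=len(y),
        ci_half_width=confidence_interval(acc, len(y), z),
        z=z,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

def cross_validate(
    samples: Sequence[Sample],
    images: Mapping[str, FaceImagePair],
    plan: FoldPlan,
    specs: Sequence[BackboneSpec] = (BackboneSpec("tiny"),),
    config: TrainConfig = TrainConfig.tiny(),
    threshold: float = DEFAULT_THRESHOLD,
) -> list[StrokeScore]:
    """Score every sample exactly once, by models that never saw its replicates.

    Within each fold, each backbone trains on the other folds and predicts
    the held-out samples; the backbone's held-out AUC on that fold supplies
    its ensemble weight (configurable choice documented in the methods note).
    """
    labels = {s.sample_id: s.label for s in samples}
    out: list[StrokeScore] = []
    for fold in range(plan.k):
        test_ids = plan.test_samples(fold)
        per_backbone: dict[str, dict[str, float]] = {}
        fold_aucs: dict[str, float] = {}
        for i, spec in enumerate(specs):
            cfg = replace(config, seed=config.seed * 1009 + fold * 31 + i)
            model = train_backbone(spec, plan, images, labels, cfg, fold)
            preds = predict_samples(model, plan, images, test_ids, spec.in_channels)
            key = f"{spec.name}{i}" if specs.count(spec) > 1 else spec.name
            per_backbone[key] = preds
            y = np.array([1 if labels[sid] == "stroke" else 0 for sid in test_ids])
            p = np.array([preds[sid] for sid in test_ids])
            # floor at a tiny value: a fold AUC of exactly 0 (possible at very
            # small fold sizes) must not zero out the ensemble weights
            fold_aucs[key] = max(auc_score(y, p), 1e-3) if len(set(y)) == 2 else 0.5
        for sid in test_ids:
            probs = {k: per_backbone[k][sid] for k in per_backbone}
            final = ensemble(list(probs.values()), [fold_aucs[k] for k in probs])
            out.append(
                StrokeScore(
                    sample_id=sid,
                    per_backbone_probability=probs,
                    per_backbone_auc=dict(fold_aucs),
                    final_probability=final,
                    predicted_label=classify(final, threshold),
                    fold=fold,
                )
            )
    return out
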