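"""Cohort handling: stratified 10-fold split, stroke replication, flip augmentation.

The training scheme replicates each stroke sample three times and adds a
left-right mirrored copy of every image, roughly balancing the effective
training class sizes when controls outnumber strokes three to one.
Augmentation is applied after the fold split, so every replicate of a
sample lives in that sample's fold and nothing leaks across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from strokeface.geometry import FaceImagePair

STROKE_COPIES = 3


@dataclass(frozen=True)
class Sample:
    sample_id: str
    label: str  # "stroke" | "control"
    cohort: str = "synthetic"
    age: float | None = None
    sex: str | None = None


@dataclass(frozen=True)
class Replicate:
    replicate_id: str
    sample_id: str
    copy_index: int
    orientation: str  # "orig" | "flip"


@dataclass
class FoldPlan:
    """Fold index per sample plus the per-sample replicate lists."""

    fold_of: Mapping[str, int]
    replicates: Mapping[str, tuple[Replicate, ...]]
    k: int
    seed: int

    def training_replicates(self, fold: int) -> list[Replicate]:
        return [
            rep
            for sid, reps in self.replicates.items()
            if self.fold_of[sid] != fold
            for rep in reps
        ]

    def test_samples(self, fold: int) -> list[str]:
        return [sid for sid, f in self.fold_of.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": rep.sample_id,
                "fold": self.fold_of[rep.sample_id],
                "replicate_id": rep.replicate_id,
                "orientation": rep.orientation,
            }
            for reps in self.replicates.values()
            for rep in reps
        ]
        return pd.DataFrame(rows)


def make_folds(samples: Sequence[Sample], k: int = 10, seed: int = 0) -> FoldPlan:
    """Random stratified k-fold split followed by replication/augmentation.

    Stroke samples get ``STROKE_COPIES`` copies, every copy in both
    orientations; controls get one copy in both orientations.  Raises if a
    class has fewer than k samples (a fold would lose the class).
    """
    labels = np.array([s.label for s in samples])
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_id values must be unique")
    for cls in ("stroke", "control"):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} samples")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_ix) in enumerate(skf.split(np.zeros(len(samples)), labels)):
        for i in test_ix:
            fold_of[ids[i]] = fold

    replicates: dict[str, tuple[Replicate, ...]] = {}
    for s in samples:
        n_copies = STROKE_COPIES if s.label == "stroke" else 1
        reps = tuple(
            Replicate(
                replicate_id=f"{s.sample_id}_c{c}_{orient}",
                sample_id=s.sample_id,
                copy_index=c,
                orientation=orient,
            )
            for c in range(n_copies)
            for orient in ("orig", "flip")
        )
        replicates[s.sample_id] = reps
    return FoldPlan(fold_of=fold_of, replicates=replicates, k=k, seed=seed)


def flip_image(pair: FaceImagePair) -> FaceImagePair:
    """Left-right mirror of texture, depth and the pixel->vertex mapping."""
    transform = None
    if pair.transform is not None:
        w = pair.shape[1]
        transform = pair.transform.copy()
        transform[1] = -transform[1]
        transform[1, 2] += w - 1
    return FaceImagePair(
        texture=np.ascontiguousarray(pair.texture[:, ::-1]),
        depth=np.ascontiguousarray(pair.depth[:, ::-1]),
        mapping=np.ascontiguousarray(pair.mapping[:, ::-1]),
        transform=transform,
    )


def match_controls(
    samples: Sequence[Sample],
    ratio: float = 3.0,
    age_tolerance: float = 5.0,
    seed: int = 0,
) -> list[Sample]:
    """Utility filter: subsample controls to ~ratio per stroke, matching age/sex.

    Greedy nearest-age matching within the same sex where metadata exists;
    not validated against any clinical cohort — it only exercises the
    matching code path on synthetic metadata.
    """
    rng = np.random.default_rng(seed)
    strokes = [s for s in samples if s.label == "stroke"]
    controls = [s for s in samples if s.label == "control"]
    n_want = min(len(controls), int(round(ratio * len(strokes))))
    pool = list(controls)
    chosen: list[Sample] = []
    for s in strokes * int(np.ceil(ratio)):
        if len(chosen) >= n_want or not pool:
            break
        cand = [c for c in pool if c.sex == s.sex] or pool
        if s.age is not None:
            in_tol = [c for c in cand if c.age is not None and abs(c.age - s.age) <= age_tolerance]
            cand = in_tol or cand
        pick = cand[rng.integers(len(cand))]
        chosen.append(pick)
        pool.remove(pick)
    return strokes + chosen
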