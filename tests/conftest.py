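"""Shared synthetic cohorts, built once per session.

All fixtures are generated programmatically from the synthetic module;
no stored data.  The planted cohort carries both stroke effects (blue
shift and droop); the null cohort carries neither; the color-only cohort
carries only the blue shift (its depth images are signal-free).
"""

from __future__ import annotations

import numpy as np
import pytest

from strokeface.model import pair_to_array
from strokeface.pipeline import CohortRun, build_cohort
from strokeface.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def cohort_planted() -> CohortRun:
    return build_cohort(
        SyntheticConfig(n_stroke=20, n_control=20, blue_effect=40.0, droop_effect=0.3, seed=11)
    )


@pytest.fixture(scope="session")
def cohort_null() -> CohortRun:
    return build_cohort(
        SyntheticConfig(n_stroke=12, n_control=12, blue_effect=0.0, droop_effect=0.0, seed=13)
    )


@pytest.fixture(scope="session")
def cohort_color_only() -> CohortRun:
    return build_cohort(
        SyntheticConfig(n_stroke=20, n_control=20, blue_effect=40.0, droop_effect=0.0, seed=17)
    )


@pytest.fixture(scope="session")
def trained_ensemble_color(cohort_color_only):
    """Four differently-initialized tiny backbones fitted on the color-only
    cohort — the model-averaging setting Grad-CAM interpretation assumes."""
    from strokeface.model import BackboneSpec

    ids = list(cohort_color_only.metadata.sample_id)
    X = np.stack([pair_to_array(cohort_color_only.images[i]) for i in ids])
    y = np.array([1 if cohort_color_only.labels[i] == "stroke" else 0 for i in ids])
    models = []
    for seed in (0, 3, 7, 11):
        m = BackboneSpec("tiny").build(seed=seed)
        m.fit(X, y, epochs=6, learning_rate=1e-3, seed=seed)
        models.append(m)
    return models


@pytest.fixture(scope="session")
def proxy_probabilities(cohort_planted) -> np.ndarray:
    """Stand-in stroke probabilities: normalized masked blue-channel mean.

    A monotone function of the planted signal, used where interpretation
    stages need a probability vector without retraining a model.
    """
    from strokeface.interpret import mask_pixels

    vals = []
    for sid, truth in zip(cohort_planted.metadata.sample_id, cohort_planted.truths):
        pair = cohort_planted.images[sid]
        m = mask_pixels(pair, truth.mask_vertex_indices)
        vals.append(float(pair.texture[..., 2][m].mean()))
    v = np.asarray(vals)
    return (v - v.min()) / (v.max() - v.min())


@pytest.fixture(scope="session")
def trained_tiny(cohort_planted):
    """One tiny backbone fitted on the whole planted cohort (for Grad-CAM)."""
    from strokeface.model import BackboneSpec

    ids = list(cohort_planted.metadata.sample_id)
    X = np.stack([pair_to_array(cohort_planted.images[i]) for i in ids])
    y = np.array([1 if cohort_planted.labels[i] == "stroke" else 0 for i in ids])
    model = BackboneSpec("tiny").build(seed=3)
    model.fit(X, y, epochs=6, learning_rate=1e-3, seed=3)
    return model
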