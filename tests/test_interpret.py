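"""Interpretation stages on planted cohorts: maps, Grad-CAM, landmarks, PLSR."""

import numpy as np
import pytest
from scipy import stats

from strokeface.interpret import (
    LandmarkSet,
    differential_map,
    gradcam_mean,
    landmark_distance_rcc,
    landmarks_from_truth,
    mask_pixels,
    plsr_shape,
    rcc_map,
)


def _pairs_labels(run):
    ids = list(run.metadata.sample_id)
    return [run.images[i] for i in ids], [run.labels[i] for i in ids], ids


# ---------------------------------------------------------------------------
# Differential maps
# ---------------------------------------------------------------------------

def test_differential_map_recovers_planted_mask(cohort_planted):
    pairs, labels, ids = _pairs_labels(cohort_planted)
    dm = differential_map(pairs, labels, channel="b", correction="bonferroni")
    mask = mask_pixels(pairs[0], cohort_planted.truths[0].mask_vertex_indices)
    frac = (dm.significant & (dm.sign > 0))[mask].mean()
    assert frac >= 0.8


def test_differential_map_null_controls_alpha(cohort_planted):
    pairs, labels, _ = _pairs_labels(cohort_planted)
    shuffled = list(np.random.default_rng(0).permutation(labels))
    dm = differential_map(pairs, shuffled, channel="b", correction="bonferroni")
    assert dm.significant.mean() <= 0.05


def test_differential_map_antisymmetry(cohort_planted):
    pairs, labels, _ = _pairs_labels(cohort_planted)
    fwd = differential_map(pairs, labels, channel="b")
    swapped = ["stroke" if l == "control" else "control" for l in labels]
    rev = differential_map(pairs, swapped, channel="b")
    assert np.array_equal(fwd.p, rev.p)
    active = fwd.sign != 0
    assert np.array_equal(fwd.sign[active], -rev.sign[active])


def test_differential_map_sample_order_invariance(cohort_planted):
    pairs, labels, _ = _pairs_labels(cohort_planted)
    order = np.random.default_rng(1).permutation(len(pairs))
    dm1 = differential_map(pairs, labels, channel="b")
    dm2 = differential_map([pairs[i] for i in order], [labels[i] for i in order], channel="b")
    assert np.allclose(dm1.p, dm2.p)
    assert np.array_equal(dm1.sign, dm2.sign)


def test_depth_channel_empty_on_color_only_cohort(cohort_color_only):
    """Blue-only planted effect leaves no significantly differential depth."""
    pairs, labels, _ = _pairs_labels(cohort_color_only)
    dm = differential_map(pairs, labels, channel="depth", correction="bonferroni")
    assert dm.significant.sum() == 0
    # positive control: the blue channel does light up on the same cohort
    # (BH here: at 12 vs 12 the asymptotic Mann-Whitney p cannot clear a
    # 50k-test Bonferroni bar even under perfect separation)
    blue = differential_map(pairs, labels, channel="b", correction="bh")
    assert blue.significant.sum() > 0


def test_constant_pixels_get_p_one():
    """A pixel constant across all samples records p = 1, not an error."""
    from strokeface.geometry import FaceImagePair

    rng = np.random.default_rng(0)
    pairs = []
    for _ in range(8):
        tex = rng.uniform(0, 255, (20, 20, 3)).astype(np.float32)
        tex[:5, :5] = 7.0  # constant corner
        pairs.append(
            FaceImagePair(
                texture=tex,
                depth=np.zeros((20, 20), dtype=np.float32),
                mapping=np.zeros((20, 20), dtype=np.int64),
            )
        )
    labels = ["stroke"] * 4 + ["control"] * 4
    dm = differential_map(pairs, labels, channel="b")
    assert (dm.p[:5, :5] == 1.0).all()
    assert (dm.sign[:5, :5] == 0).all()


def test_q_dominates_p_for_both_corrections(cohort_planted):
    pairs, labels, _ = _pairs_labels(cohort_planted)
    for correction in ("bh", "bonferroni"):
        m = differential_map(pairs, labels, channel="g", correction=correction)
        assert (m.q >= m.p - 1e-12).all()


def test_corrections_match_brute_force():
    """BH and Bonferroni agree with directly-coded reference formulas."""
    rng = np.random.default_rng(0)
    p = rng.uniform(size=1000) ** 2
    from strokeface.interpret import _correct

    bonf = _correct(p, "bonferroni")
    assert np.allclose(bonf, np.minimum(p * 1000, 1.0))
    bh = _correct(p, "bh")
    order = np.argsort(p)
    ref = np.empty_like(p)
    m = len(p)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        ref[i] = running
    assert np.allclose(bh, ref)


# ---------------------------------------------------------------------------
# Correlation maps
# ---------------------------------------------------------------------------

def test_rcc_map_concentrates_in_mask(cohort_planted, proxy_probabilities):
    pairs, _, _ = _pairs_labels(cohort_planted)
    cm = rcc_map(pairs, proxy_probabilities, channel="b")
    mask = mask_pixels(pairs[0], cohort_planted.truths[0].mask_vertex_indices)
    in_frac = (cm.significant & (cm.sign > 0))[mask].mean()
    out_frac = (cm.significant & (cm.sign > 0))[~mask].mean()
    assert in_frac > 0.5
    assert in_frac > 5 * max(out_frac, 1e-9)


def test_rcc_map_null_controls_alpha(cohort_planted):
    pairs, _, _ = _pairs_labels(cohort_planted)
    random_probs = np.random.default_rng(3).uniform(size=len(pairs))
    cm = rcc_map(pairs, random_probs, channel="b")
    assert cm.significant.mean() <= 0.05


def test_rcc_map_rejects_constant_probabilities(cohort_planted):
    pairs, _, _ = _pairs_labels(cohort_planted)
    with pytest.raises(ValueError, match="variance"):
        rcc_map(pairs, np.full(len(pairs), 0.5))


def test_vectorized_spearman_matches_scipy():
    from strokeface.interpret import _spearman_vs_vector

    rng = np.random.default_rng(4)
    imgs = rng.normal(size=(25, 6, 7))
    v = rng.normal(size=25)
    rho, p = _spearman_vs_vector(imgs, v)
    for i in range(6):
        for j in range(7):
            r_ref, p_ref = stats.spearmanr(imgs[:, i, j], v)
            assert rho[i, j] == pytest.approx(r_ref)
            assert p[i, j] == pytest.approx(p_ref, rel=1e-6)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def test_gradcam_mean_focuses_on_mask(cohort_color_only, trained_ensemble_color):
    """Averaged over the model ensemble, CAM mass concentrates where the
    blue-channel effect was planted (ophryon + mouth)."""
    pairs, labels, ids = _pairs_labels(cohort_color_only)
    from strokeface.model import pair_to_array

    X = np.stack([pair_to_array(p) for p in pairs])
    probs = np.mean([m.predict_proba(X)[:, 1] for m in trained_ensemble_color], axis=0)
    heat, n_used = gradcam_mean(trained_ensemble_color, pairs, labels, probs)
    assert heat.shape == (224, 224)
    assert (heat >= 0).all() and heat.max() > 0
    pred = np.where(probs >= 0.4, "stroke", "control")
    assert n_used == int((pred == np.asarray(labels)).sum())
    mask = mask_pixels(pairs[0], cohort_color_only.truths[0].mask_vertex_indices)
    assert heat[mask].mean() > heat[~mask].mean()


def test_gradcam_mean_handles_no_correct_predictions(cohort_planted, trained_tiny):
    pairs, labels, _ = _pairs_labels(cohort_planted)
    from strokeface.model import pair_to_array

    X = np.stack([pair_to_array(p) for p in pairs])
    probs = trained_tiny.predict_proba(X)[:, 1]
    pred = np.where(probs >= 0.4, "stroke", "control")
    wrong = ["control" if p == "stroke" else "stroke" for p in pred]  # all incorrect
    heat, n_used = gradcam_mean([trained_tiny], pairs, wrong, probs)
    assert n_used == 0
    assert not heat.any()


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def _landmark_sets(run):
    out = []
    for sid, truth in zip(run.metadata.sample_id, run.truths):
        res = run.preprocessed[sid]
        out.append(
            landmarks_from_truth(res.corrected.vertices, res.pair, truth.landmark_indices)
        )
    return out


def test_landmark_sets_contract(cohort_planted):
    ls = _landmark_sets(cohort_planted)[0]
    assert len(ls.names) == 72
    d = ls.distance_matrix()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    rows, cols = ls.points2d[:, 0], ls.points2d[:, 1]
    assert (rows > -5).all() and (rows < 229).all()
    assert (cols > -5).all() and (cols < 229).all()


def test_landmark_distances_rigid_motion_invariant(cohort_planted):
    ls = _landmark_sets(cohort_planted)[0]
    from strokeface.synthetic import _random_rotation

    R = _random_rotation(np.random.default_rng(0), 30.0)
    moved = LandmarkSet(
        names=ls.names, points2d=ls.points2d, points3d=ls.points3d @ R.T + np.array([1, 2, 3.0])
    )
    assert np.allclose(ls.distance_matrix(), moved.distance_matrix(), atol=1e-9)


def test_droop_raises_lower_to_upper_distances(cohort_planted, proxy_probabilities):
    sets = _landmark_sets(cohort_planted)
    rcc, logp, order, names = landmark_distance_rcc(sets, proxy_probabilities)
    assert rcc.shape == (72, 72) and sorted(order) == list(range(72))
    lower = [i for i, n in enumerate(names) if n.startswith(("contour", "chin"))]
    upper = [i for i, n in enumerate(names) if n.startswith(("forehead", "ophryon", "brow"))]
    sub = rcc[np.ix_(lower, upper)]
    assert np.median(sub) > 0.3  # lower face drifts away from upper face


def test_landmark_rcc_null(cohort_null):
    sets = _landmark_sets(cohort_null)
    probs = np.random.default_rng(2).uniform(size=len(sets))
    rcc, logp, order, names = landmark_distance_rcc(sets, probs)
    iu = np.triu_indices(72, k=1)
    sig = (10.0 ** (-logp[iu]) < 0.05).mean()
    assert sig <= 0.08


def test_missing_landmark_drops_sample(cohort_null, caplog):
    sets = _landmark_sets(cohort_null)
    broken = LandmarkSet(
        names=sets[0].names,
        points2d=sets[0].points2d,
        points3d=np.where(np.arange(72)[:, None] == 0, np.nan, sets[0].points3d),
    )
    probs = np.random.default_rng(0).uniform(size=len(sets))
    import logging

    with caplog.at_level(logging.WARNING):
        landmark_distance_rcc([broken] + sets[1:], probs)
    assert any("dropping sample" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# PLSR shape model
# ---------------------------------------------------------------------------

def test_plsr_identifies_driving_vertex():
    rng = np.random.default_rng(5)
    V = rng.normal(size=(80, 50, 3))
    probs = 2.0 * V[:, 7, 1] + 0.05 * rng.normal(size=80)
    sm = plsr_shape(V, probs)
    assert sm.coefficients.shape == (50, 3)
    flat = np.abs(sm.coefficients)
    assert np.unravel_index(flat.argmax(), flat.shape) == (7, 1)


def test_plsr_recovers_droop_direction(cohort_planted, proxy_probabilities):
    ids = list(cohort_planted.metadata.sample_id)
    V = np.stack([cohort_planted.preprocessed[i].corrected.vertices for i in ids])
    sm = plsr_shape(V, proxy_probabilities)
    lm = cohort_planted.truths[0].landmark_indices
    for corner in ("mouth_corner_l", "mouth_corner_r", "chin_mid"):
        assert sm.coefficients[lm[corner], 1] < 0  # descends along Y with probability


def test_plsr_rejects_degenerate_inputs():
    V = np.zeros((10, 5, 3))
    with pytest.raises(ValueError, match="variance"):
        plsr_shape(V, np.ones(10))
    with pytest.raises(ValueError, match="mismatch"):
        plsr_shape(V, np.arange(9))
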