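"""Planted-signal benchmarks: the package's self-contained validation runs.

Each function generates fresh synthetic cohorts with known planted
structure, runs the corresponding pipeline stage, and measures recovery.
They are used by both the test suite and the reproduction script, and
their default problem sizes are the package's standard benchmark
conditions (documented in the methods note).
"""

from __future__ import annotations

import numpy as np

from strokeface.geometry import (
    correct_pose,
    detect_nose_tip,
    fit_sphere,
    project_depth,
    FacePointCloud,
)
from strokeface.interpret import differential_map, mask_pixels
from strokeface.pipeline import build_cohort, planted_cohort_auc
from strokeface.synthetic import SyntheticConfig, generate_face, _random_rotation
from strokeface.clinical import cit_test


def planted_auc_over_seeds(
    blue_effect: float,
    seeds: list[int],
    n_stroke: int = 60,
    n_control: int = 60,
    k: int = 10,
    epochs: int = 5,
) -> list[float]:
    """Pooled held-out CV AUC per seed for a given planted blue shift."""
    return [
        planted_cohort_auc(
            n_stroke, n_control, blue_effect, droop_effect=0.0, k=k, epochs=epochs, seed=s
        )
        for s in seeds
    ]


def nose_tip_oracle_agreement(n_clouds: int = 20, seed: int = 0) -> float:
    """Fraction of clouds where the detector equals the brute-force argmin.

    The oracle refits a sphere per vertex with an independent plain
    least-squares path and takes the argmin over the same candidate rule.
    """
    from scipy.spatial import cKDTree

    cfg = SyntheticConfig()
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_clouds):
        cloud, _ = generate_face(cfg, "stroke" if i % 2 == 0 else "control", rng)
        det, _ = detect_nose_tip(cloud)
        V = cloud.vertices
        tree = cKDTree(V)
        neighbors = tree.query_ball_point(V, 1.5)
        best_i, best_loss = -1, np.inf
        for j, nb in enumerate(neighbors):
            if len(nb) < 10:
                continue
            fit = fit_sphere(V[nb])
            if fit.loss < best_loss:
                best_i, best_loss = j, fit.loss
        agree += int(best_i == det)
    return agree / n_clouds


def pose_recovery_rmsd(angle_deg: float = 25.0, n_faces: int = 5, seed: int = 0) -> float:
    """Max RMSD (cm) between canonical faces and re-corrected rotated copies."""
    cfg = SyntheticConfig(pose_jitter_deg=0.0, pose_jitter_cm=0.0)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_faces):
        cloud, truth = generate_face(cfg, "control", rng)
        tip, _ = detect_nose_tip(cloud)
        canonical = correct_pose(cloud, tip)
        R = _random_rotation(np.random.default_rng(seed + 100 + i), angle_deg)
        t = np.random.default_rng(seed + 200 + i).uniform(-2, 2, 3)
        moved = FacePointCloud(
            vertices=canonical.vertices @ R.T + t, colors=canonical.colors
        )
        recovered = correct_pose(moved, tip)
        rmsd = float(
            np.sqrt(((recovered.vertices - canonical.vertices) ** 2).sum(axis=1).mean())
        )
        worst = max(worst, rmsd)
    return worst


def depth_roundtrip_max_error(n_faces: int = 20, seed: int = 0) -> float:
    """Max |depth pixel - source vertex Z| over all mapped native pixels."""
    cfg = SyntheticConfig()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_faces):
        cloud, _ = generate_face(cfg, "stroke" if i % 2 == 0 else "control", rng)
        tip, _ = detect_nose_tip(cloud)
        corrected = correct_pose(cloud, tip)
        pair = project_depth(corrected)
        m = pair.mapping >= 0
        err = np.abs(pair.depth[m] - corrected.vertices[pair.mapping[m], 2].astype(np.float32))
        worst = max(worst, float(err.max()))
    return worst


def differential_recovery(
    n_per_group: int = 100,
    blue_effect: float = 40.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """(mask recovery fraction, label-shuffled null significant fraction).

    Recovery: fraction of central-face mask pixels significant (Bonferroni
    q < alpha) with positive sign in the blue channel at n per group.
    Null: significant fraction anywhere after shuffling the labels.
    """
    cfg = SyntheticConfig(
        n_stroke=n_per_group, n_control=n_per_group, blue_effect=blue_effect,
        droop_effect=0.0, seed=seed,
    )
    run = build_cohort(cfg)
    ids = [s.sample_id for s in run.samples]
    pairs = [run.images[i] for i in ids]
    labels = [run.labels[i] for i in ids]

    dm = differential_map(pairs, labels, channel="b", correction="bonferroni", alpha=alpha)
    # shared topology + common pose: one sample's mask pixel set represents all
    mask_img = mask_pixels(run.images[ids[0]], run.truths[0].mask_vertex_indices)
    recovered = float((dm.significant & (dm.sign > 0))[mask_img].mean())

    rng = np.random.default_rng(seed + 1)
    shuffled = list(rng.permutation(labels))
    dm0 = differential_map(pairs, shuffled, channel="b", correction="bonferroni", alpha=alpha)
    null_frac = float(dm0.significant.mean())
    return recovered, null_frac


def cit_directionality(
    n: int = 500,
    n_seeds: int = 20,
    n_perm: int = 400,
    beta: float = 0.8,
    seed: int = 0,
) -> float:
    """Fraction of seeds where the forward chain triple is retained at
    q < 0.20 while the reverse triple is rejected."""
    noise = float(np.sqrt(1.0 - beta**2))
    wins = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        Y = rng.normal(size=n)
        M = beta * Y + noise * rng.normal(size=n)
        L = beta * (M - M.mean()) / M.std() + noise * rng.normal(size=n)
        fwd = cit_test(L, M, Y, n_perm=n_perm, rng=rng)
        rev = cit_test(M, L, Y, n_perm=n_perm, rng=rng)
        wins += int(fwd.p_omnibus < 0.20 and rev.p_omnibus >= 0.20)
    return wins / n_seeds


def cit_null_retention(
    n: int = 150,
    n_reps: int = 200,
    n_perm: int = 150,
    seed: int = 0,
    fdr_cut: float = 0.20,
) -> float:
    """Fraction of fully-independent triples retained at the FDR cut."""
    retained = 0
    for s in range(n_reps):
        rng = np.random.default_rng(seed + s)
        L, M, Y = rng.normal(size=(3, n))
        retained += int(cit_test(L, M, Y, n_perm=n_perm, rng=rng).p_omnibus < fdr_cut)
    return retained / n_reps
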