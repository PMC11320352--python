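"""Preprocessing oracles: sphere fit, pose convention, rasterization."""

import numpy as np
import pytest

from strokeface.geometry import (
    DegenerateInputError,
    FaceImagePair,
    FacePointCloud,
    correct_pose,
    crop_resize,
    detect_nose_tip,
    fit_sphere,
    preprocess_cloud,
    project_depth,
)
from strokeface.synthetic import SyntheticConfig, generate_face, _random_rotation


def _sphere_patch(n=400, r=2.0, center=(1.0, -2.0, 3.0), seed=0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, np.pi / 3, n)  # cap around the pole
    phi = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack(
        [
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
            r * np.cos(theta),
        ]
    ) + np.asarray(center)
    return pts


def test_sphere_fit_exact_on_perfect_sphere():
    pts = _sphere_patch()
    fit = fit_sphere(pts)
    assert fit.loss < 1e-20
    assert np.allclose(fit.center, (1.0, -2.0, 3.0), atol=1e-8)
    assert np.isclose(fit.radius, 2.0, atol=1e-8)


def test_nose_tip_on_sphere_patch_cloud():
    """On a pure sphere patch every vertex fits perfectly; the detector
    must still return a finite-loss candidate with the true center."""
    pts = _sphere_patch(n=800)
    cloud = FacePointCloud(vertices=pts, colors=np.zeros_like(pts))
    idx, fit = detect_nose_tip(cloud)
    assert fit.loss < 1e-10
    assert np.allclose(fit.center, (1.0, -2.0, 3.0), atol=1e-6)


def test_nose_tip_matches_generator_truth(cohort_planted):
    for sid, truth in zip(cohort_planted.metadata.sample_id, cohort_planted.truths):
        res = cohort_planted.preprocessed[sid]
        cloud_tip = cohort_planted.clouds[
            list(cohort_planted.metadata.sample_id).index(sid)
        ].vertices[res.nose_tip_index]
        assert np.linalg.norm(cloud_tip - truth.nose_tip_posed) < 0.3


def test_nose_tip_equals_brute_force_argmin():
    """Detector argmin equals an independent per-vertex lstsq sweep."""
    from scipy.spatial import cKDTree

    cfg = SyntheticConfig()
    rng = np.random.default_rng(21)
    for i in range(3):
        cloud, _ = generate_face(cfg, "stroke" if i % 2 else "control", rng)
        det, _ = detect_nose_tip(cloud)
        V = cloud.vertices
        neighbors = cKDTree(V).query_ball_point(V, 1.5)
        losses = [
            fit_sphere(V[nb]).loss if len(nb) >= 10 else np.inf for nb in neighbors
        ]
        assert int(np.argmin(losses)) == det


def test_nose_tip_requires_dense_neighborhood():
    rng = np.random.default_rng(0)
    sparse = rng.uniform(0, 100, size=(150, 3))  # ~0 neighbors within 1.5 cm
    cloud = FacePointCloud(vertices=sparse, colors=np.zeros((150, 3)))
    with pytest.raises(DegenerateInputError):
        detect_nose_tip(cloud)


def test_pose_correction_identity_on_canonical():
    cfg = SyntheticConfig(pose_jitter_deg=0.0, pose_jitter_cm=0.0)
    cloud, _ = generate_face(cfg, "control", np.random.default_rng(2))
    tip, _ = detect_nose_tip(cloud)
    canonical = correct_pose(cloud, tip)
    again, R = correct_pose(canonical, tip, return_transform=True)
    assert np.abs(R - np.eye(3)).max() < 1e-6
    assert np.abs(again.vertices - canonical.vertices).max() < 1e-6


def test_pose_correction_recovers_25_degree_jitter():
    cfg = SyntheticConfig(pose_jitter_deg=0.0, pose_jitter_cm=0.0)
    cloud, _ = generate_face(cfg, "control", np.random.default_rng(3))
    tip, _ = detect_nose_tip(cloud)
    canonical = correct_pose(cloud, tip)
    R = _random_rotation(np.random.default_rng(7), 25.0)
    moved = FacePointCloud(
        vertices=canonical.vertices @ R.T + np.array([1.0, -0.5, 2.0]),
        colors=canonical.colors,
    )
    recovered = correct_pose(moved, tip)
    rmsd = np.sqrt(((recovered.vertices - canonical.vertices) ** 2).sum(axis=1).mean())
    assert rmsd < 0.1


def test_pose_iterations_converge_monotonically():
    """The frame change of iteration 2 is no larger than iteration 1."""
    cfg = SyntheticConfig()
    rng = np.random.default_rng(31)
    for i in range(10):
        cloud, _ = generate_face(cfg, "stroke" if i % 2 else "control", rng)
        tip, _ = detect_nose_tip(cloud)
        c1, R1 = correct_pose(cloud, tip, n_iter=1, return_transform=True)
        _, R2 = correct_pose(c1, tip, n_iter=1, return_transform=True)
        d1 = np.abs(R1 - np.eye(3)).max()
        d2 = np.abs(R2 - np.eye(3)).max()
        assert d2 <= d1 + 1e-9


def test_pose_correction_degenerate_region():
    line = np.column_stack([np.linspace(0, 1, 200), np.zeros(200), np.zeros(200)])
    cloud = FacePointCloud(vertices=line, colors=np.zeros((200, 3)))
    with pytest.raises(DegenerateInputError):
        correct_pose(cloud, 0)


def test_zbuffer_keeps_nearest_vertex():
    """Two vertices in one cell: the one with larger Z (closer) wins."""
    base = np.random.default_rng(0).uniform(0, 5, size=(200, 2))
    verts = np.column_stack([base, np.zeros(200)])
    verts = np.vstack([verts, [2.52, 2.52, 1.0], [2.53, 2.53, 2.0]])
    colors = np.zeros((202, 3))
    colors[-2] = [10, 10, 10]
    colors[-1] = [99, 99, 99]
    pair = project_depth(FacePointCloud(vertices=verts, colors=colors), resolution=0.1)
    rc = pair.project_points(np.array([[2.525, 2.525]]))[0]
    r, c = int(round(rc[0])), int(round(rc[1]))
    assert pair.depth[r, c] == 2.0
    assert pair.texture[r, c, 0] == 99


def test_plane_projects_to_constant_depth():
    g = np.linspace(0, 3, 40)
    xx, yy = np.meshgrid(g, g)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(1600, 1.25)])
    pair = project_depth(FacePointCloud(verts, np.zeros((1600, 3))), resolution=0.1)
    m = pair.mapping >= 0
    assert np.allclose(pair.depth[m], 1.25)


def test_depth_roundtrip_exact(cohort_null):
    """Every mapped native pixel carries exactly its source vertex Z."""
    for sid in list(cohort_null.metadata.sample_id)[:6]:
        corrected = cohort_null.preprocessed[sid].corrected
        pair = project_depth(corrected)
        m = pair.mapping >= 0
        src_z = corrected.vertices[pair.mapping[m], 2].astype(np.float32)
        assert np.array_equal(pair.depth[m], src_z)


def test_crop_resize_identity_at_target_size():
    tex = np.random.default_rng(0).uniform(0, 255, (224, 224, 3)).astype(np.float32)
    depth = np.random.default_rng(1).uniform(-5, 1, (224, 224)).astype(np.float32)
    mapping = np.arange(224 * 224, dtype=np.int64).reshape(224, 224)
    pair = FaceImagePair(texture=tex, depth=depth, mapping=mapping)
    out = crop_resize(pair)
    assert np.array_equal(out.texture, tex)
    assert np.array_equal(out.depth, depth)


def test_crop_resize_padding_policy():
    """A 300x200 face box is padded symmetrically to a square, then resized:
    the face occupies the full height and 200/300 of the width, centered."""
    H, W = 300, 200
    tex = np.full((H + 40, W + 40, 3), 0, dtype=np.float32)
    mapping = np.full((H + 40, W + 40), -1, dtype=np.int64)
    tex[20 : 20 + H, 20 : 20 + W] = 100.0
    mapping[20 : 20 + H, 20 : 20 + W] = 1
    depth = np.zeros_like(mapping, dtype=np.float32)
    out = crop_resize(FaceImagePair(texture=tex, depth=depth, mapping=mapping))
    assert out.shape == (224, 224)
    face_cols = (out.mapping >= 0).any(axis=0)
    width_frac = face_cols.mean()
    assert abs(width_frac - W / H) < 0.03
    # centered: symmetric margins
    first, last = np.flatnonzero(face_cols)[[0, -1]]
    assert abs(first - (223 - last)) <= 2


def test_crop_resize_preserves_mean_intensity(cohort_null):
    for sid in list(cohort_null.metadata.sample_id)[:8]:
        corrected = cohort_null.preprocessed[sid].corrected
        native = project_depth(corrected)
        out = crop_resize(native)
        m_in = native.mapping >= 0
        m_out = out.mapping >= 0
        mean_in = native.texture[m_in].mean()
        mean_out = out.texture[m_out].mean()
        assert abs(mean_out - mean_in) / mean_in < 0.02


def test_crop_resize_empty_face_errors():
    pair = FaceImagePair(
        texture=np.zeros((50, 50, 3), dtype=np.float32),
        depth=np.zeros((50, 50), dtype=np.float32),
        mapping=np.full((50, 50), -1, dtype=np.int64),
    )
    with pytest.raises(DegenerateInputError):
        crop_resize(pair)


def test_end_to_end_pose_invariance():
    """Texture of a face and of its re-jittered copy agree after preprocessing."""
    cfg = SyntheticConfig(pose_jitter_deg=0.0, pose_jitter_cm=0.0)
    cloud, _ = generate_face(cfg, "stroke", np.random.default_rng(4))
    p1 = preprocess_cloud(cloud).pair
    R = _random_rotation(np.random.default_rng(8), 20.0)
    moved = FacePointCloud(
        vertices=cloud.vertices @ R.T + np.array([0.5, 1.0, -0.7]), colors=cloud.colors
    )
    p2 = preprocess_cloud(moved).pair
    assert np.abs(p1.texture - p2.texture).mean() < 2.0


def test_empty_cloud_rejected():
    with pytest.raises(ValueError):
        FacePointCloud(vertices=np.zeros((0, 3)), colors=np.zeros((0, 3)))
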