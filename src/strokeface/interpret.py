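"""Model interpretation: pixel statistic maps, Grad-CAM, landmarks, PLSR shape.

Four complementary views of what drives the stroke probability:

* differential pixel maps — per-pixel two-sided Mann-Whitney U between the
  stroke and control groups on one channel (R/G/B/depth), corrected for
  multiple testing (Bonferroni by default, matching the hypothesis-testing
  use; BH-FDR selectable);
* probability-correlation maps — per-pixel Spearman rank correlation (RCC)
  against the ensemble stroke probability, BH-FDR masked;
* Grad-CAM averaging — class-activation maps from each model's last conv
  layer, kept only for correctly predicted samples, averaged over samples
  and models;
* landmark distances and PLSR — pairwise 3D landmark distances correlated
  with probability, and a 2-component partial least squares regression of
  probability on registered vertex coordinates (shared synthetic topology,
  so cross-sample correspondence is the identity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import average as _hc_average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, rankdata
from scipy.stats import distributions as _dists
from skimage.transform import resize as _sk_resize
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from strokeface.geometry import FaceImagePair, IMAGE_SIZE
from strokeface.model import classify, DEFAULT_THRESHOLD

logger = logging.getLogger(__name__)

CHANNELS = {"r": 0, "g": 1, "b": 2, "depth": None}


@dataclass
class PixelStatMap:
    """Per-pixel statistic/p/q/sign for one channel over an image cohort."""

    channel: str
    stat: np.ndarray  # (H, W) test statistic (U or rho)
    p: np.ndarray  # raw two-sided p
    q: np.ndarray  # corrected p
    sign: np.ndarray  # int8; + = higher in stroke (or positive correlation)
    correction: str
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.q < self.alpha


@dataclass
class LandmarkSet:
    """72 named landmarks of one sample: 2D pixel and 3D cm coordinates."""

    names: tuple[str, ...]
    points2d: np.ndarray  # (72, 2) (row, col)
    points3d: np.ndarray  # (72, 3) cm, pose-corrected

    def distance_matrix(self) -> np.ndarray:
        d = np.linalg.norm(self.points3d[:, None] - self.points3d[None], axis=2)
        return d


@dataclass
class ShapeModel:
    """2-component PLSR from registered vertex coordinates to probability."""

    coefficients: np.ndarray  # (n_vertices, 3) x/y/z coefficients
    n_components: int
    model: PLSRegression


def _channel_stack(pairs: Sequence[FaceImagePair], channel: str) -> np.ndarray:
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {sorted(CHANNELS)}")
    if channel == "depth":
        return np.stack([p.depth for p in pairs]).astype(float)
    return np.stack([p.texture[..., CHANNELS[channel]] for p in pairs]).astype(float)


def _correct(p: np.ndarray, method: str) -> np.ndarray:
    flat = p.ravel()
    if method == "bonferroni":
        q = np.minimum(flat * flat.size, 1.0)
    elif method == "bh":
        q = multipletests(flat, method="fdr_bh")[1]
    else:
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    return q.reshape(p.shape)


def differential_map(
    pairs: Sequence[FaceImagePair],
    labels: Sequence[str],
    channel: str = "b",
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> PixelStatMap:
    """Per-pixel Mann-Whitney U map between stroke and control groups.

    Constant pixels across all samples get p = 1 (not an error); the sign
    is the sign of the stroke-minus-control group-mean difference.
    """
    labels = np.asarray(labels)
    imgs = _channel_stack(pairs, channel)
    stroke = imgs[labels == "stroke"]
    control = imgs[labels == "control"]
    if len(stroke) < 2 or len(control) < 2:
        raise ValueError("need at least 2 samples per group")
    res = mannwhitneyu(stroke, control, axis=0, alternative="two-sided")
    p = np.nan_to_num(res.pvalue, nan=1.0)
    sign = np.sign(stroke.mean(axis=0) - control.mean(axis=0)).astype(np.int8)
    return PixelStatMap(
        channel=channel,
        stat=np.asarray(res.statistic, dtype=float),
        p=p,
        q=_correct(p, correction),
        sign=sign,
        correction=correction,
        alpha=alpha,
    )


def _spearman_vs_vector(imgs: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pixel Spearman rho and two-sided t-approximation p."""
    n = len(v)
    rv = rankdata(v)
    ri = rankdata(imgs, axis=0)
    rv_c = rv - rv.mean()
    ri_c = ri - ri.mean(axis=0)
    num = np.tensordot(rv_c, ri_c, axes=(0, 0))
    den = np.sqrt((rv_c**2).sum()) * np.sqrt((ri_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * _dists.t.sf(np.abs(t), n - 2)
    p = np.where(den > 0, np.minimum(p, 1.0), 1.0)
    return rho, p


def rcc_map(
    pairs: Sequence[FaceImagePair],
    final_probabilities: Sequence[float],
    channel: str = "b",
    correction: str = "bh",
    alpha: float = 0.05,
) -> PixelStatMap:
    """Per-pixel Spearman correlation with the ensemble stroke probability."""
    probs = np.asarray(final_probabilities, dtype=float)
    if len(pairs) < 10:
        raise ValueError("need at least 10 samples for a correlation map")
    if probs.std() == 0:
        raise ValueError("probability vector has zero variance")
    imgs = _channel_stack(pairs, channel)
    rho, p = _spearman_vs_vector(imgs, probs)
    return PixelStatMap(
        channel=channel,
        stat=rho,
        p=p,
        q=_correct(p, correction),
        sign=np.sign(rho).astype(np.int8),
        correction=correction,
        alpha=alpha,
    )


def gradcam_mean(
    models: Sequence,
    pairs: Sequence[FaceImagePair],
    labels: Sequence[str],
    final_probabilities: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
    channels: int = 3,
    size: int = IMAGE_SIZE,
) -> tuple[np.ndarray, int]:
    """Mean Grad-CAM heatmap over correctly predicted samples and models.

    Returns (heatmap, n_used).  If no sample is correctly predicted the
    heatmap is all-zero with n_used = 0 and a warning is logged.
    """
    from strokeface.model import pair_to_array

    labels = np.asarray(labels)
    probs = np.asarray(final_probabilities, dtype=float)
    correct = np.array([classify(p, threshold) for p in probs]) == labels
    if not correct.any():
        logger.warning("gradcam_mean: no correctly predicted samples; empty map")
        return np.zeros((size, size)), 0
    X = np.stack([pair_to_array(pairs[i], channels) for i in np.flatnonzero(correct)])
    acc = np.zeros((size, size))
    for model in models:
        cams = model.gradcam(X, class_index=1)
        for cam in cams:
            acc += _sk_resize(cam, (size, size), order=1, preserve_range=True)
    n_used = int(correct.sum())
    return acc / (n_used * len(models)), n_used


def landmark_distance_rcc(
    landmark_sets: Sequence[LandmarkSet],
    final_probabilities: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Spearman RCC between every landmark pair distance and probability.

    Returns (rcc 72x72, -log10 p 72x72, display order from hierarchical
    clustering, landmark names).  Samples with missing (non-finite)
    landmarks are dropped with a log entry.  Clustering is average linkage
    on Euclidean distances between the -log10 p rows.
    """
    probs = np.asarray(final_probabilities, dtype=float)
    names = landmark_sets[0].names
    keep_sets, keep_probs = [], []
    for i, ls in enumerate(landmark_sets):
        if ls.names != names:
            raise ValueError("inconsistent landmark naming across samples")
        if not np.isfinite(ls.points3d).all():
            logger.warning("landmark_distance_rcc: dropping sample %d (missing landmark)", i)
            continue
        keep_sets.append(ls)
        keep_probs.append(probs[i])
    probs = np.asarray(keep_probs)
    n_lm = len(names)
    dists = np.stack([ls.distance_matrix() for ls in keep_sets])  # (n, 72, 72)

    iu = np.triu_indices(n_lm, k=1)
    flat = dists[:, iu[0], iu[1]]
    rho_flat, p_flat = _spearman_vs_vector(flat, probs)
    rcc = np.zeros((n_lm, n_lm))
    pmat = np.ones((n_lm, n_lm))
    rcc[iu] = rho_flat
    rcc.T[iu] = rho_flat
    pmat[iu] = p_flat
    pmat.T[iu] = p_flat
    logp = -np.log10(np.maximum(pmat, 1e-300))
    np.fill_diagonal(logp, 0.0)

    link = _hc_average(pdist(logp))
    order = np.asarray(leaves_list(link))
    return rcc, logp, order, names


def landmarks_from_truth(
    corrected_vertices: np.ndarray,
    pair: FaceImagePair,
    landmark_indices: Mapping[str, int],
) -> LandmarkSet:
    """Build a LandmarkSet from generator ground-truth vertex indices.

    On synthetic cohorts the 72 landmarks are template vertex indices, so
    their 3D coordinates come from the pose-corrected cloud and their 2D
    pixel coordinates through the image pair's recorded affine — the same
    mapping-file route an external 2D detector's output would take in
    reverse.
    """
    names = tuple(landmark_indices)
    idx = np.array([landmark_indices[n] for n in names])
    p3 = corrected_vertices[idx]
    p2 = pair.project_points(p3[:, :2])
    return LandmarkSet(names=names, points2d=p2, points3d=p3)


def plsr_shape(
    vertices_by_sample: np.ndarray,
    final_probabilities: Sequence[float],
    n_components: int = 2,
) -> ShapeModel:
    """Fit the 2-component PLSR of stroke probability on vertex coordinates.

    ``vertices_by_sample`` is (n_samples, n_vertices, 3) on a shared
    topology.  The per-vertex x/y/z coefficients describe how the face
    shape moves as the predicted probability rises (e.g. mouth-corner
    descent along -Y for the planted droop).
    """
    V = np.asarray(vertices_by_sample, dtype=float)
    probs = np.asarray(final_probabilities, dtype=float)
    if V.ndim != 3 or V.shape[2] != 3:
        raise ValueError("vertices_by_sample must be (n_samples, n_vertices, 3)")
    if len(V) != len(probs):
        raise ValueError("sample count mismatch between vertices and probabilities")
    if probs.std() == 0:
        raise ValueError("probability vector has zero variance")
    n, nv, _ = V.shape
    X = V.reshape(n, nv * 3)
    pls = PLSRegression(n_components=n_components)
    pls.fit(X, probs)
    coef = np.asarray(pls.coef_).reshape(-1)[: nv * 3].reshape(nv, 3)
    return ShapeModel(coefficients=coef, n_components=n_components, model=pls)


def mask_pixels(pair: FaceImagePair, mask_vertex_indices: np.ndarray) -> np.ndarray:
    """Boolean (H, W) image mask of pixels mapped to the given vertex set."""
    lookup = np.zeros(pair.mapping.max() + 2, dtype=bool)
    lookup[mask_vertex_indices] = True
    return np.where(pair.mapping >= 0, lookup[pair.mapping], False)
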