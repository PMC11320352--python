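"""Synthetic face-scan and clinical-marker generator with planted stroke effects.

Every downstream stage (geometry, CNN training, interpretation maps,
clinical causal analysis) is exercised against cohorts produced here,
because real patient scans cannot be shared.  The generator plants two
facial stroke effects whose ground truth is recorded exactly:

* a blue-channel intensity shift of ``blue_effect`` (0–255 scale) over a
  central-face vertex mask (ophryon + mouth areas), emulating the
  central-cyanosis signature of restricted blood flow, and
* a downward displacement of lower-contour / mouth-corner vertices by
  ``droop_effect`` cm, emulating neuromuscular lower-face droop.

Faces are built on a fixed parametric template (superellipsoid head with
a spherical-cap nose, brow/chin/mouth bumps), so every sample shares the
same vertex topology: cross-sample vertex correspondence is the identity,
which the PLSR shape stage relies on.  Clinical markers are drawn from
declared linear structural chains driver -> mediator -> stroke score so
the causal-inference stage has a known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from strokeface.geometry import FacePointCloud

# Template grid: 73 x 73 vertices over a 14 x 18 cm frontal face patch.
_GRID_N = 73
_HALF_WIDTH = 7.0  # cm
_HALF_HEIGHT = 9.0  # cm
# head ellipsoid semi-axes (cm); larger than the patch so depth stays positive.
# The ellipsoid center sits _HEAD_Y0 above the nose so the surface falls away
# faster below the nose than above it — that vertical asymmetry (and the
# stronger horizontal curvature from the narrow A axis) is what makes the
# pose-correction axis convention deterministic.
_HEAD_A, _HEAD_B, _HEAD_C, _HEAD_Y0 = 9.5, 17.0, 6.0, 2.0
# nose: spherical cap so the tip neighborhood is an exact sphere
_NOSE_Y = -0.5
_NOSE_R = 1.4
_NOSE_DROP = 0.35  # sphere center sits this far behind the local face surface

_BASE_COLOR = np.array([200.0, 160.0, 140.0])  # skin tone; blue kept spatially flat


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig field is invalid; names the field."""


@dataclass(frozen=True)
class CausalChain:
    """Linear structural chain ``driver -> mediator -> stroke score``.

    Generation is conditional on the realized score: the mediator is drawn
    around the standardized score with coefficient ``beta_mediator``, the
    driver around the standardized mediator with ``beta_driver``; both get
    independent Gaussian noise of sd ``noise_sd``.  This realizes exactly
    the conditional-independence structure of a chain with the driver at
    the far end (driver independent of score given mediator).
    """

    driver: str
    mediator: str
    beta_driver: float = 0.8
    beta_mediator: float = 0.8
    noise_sd: float = 0.6


def _default_marker_graph() -> tuple[CausalChain, ...]:
    return (
        CausalChain("fdp", "d_dimer", 0.8, 0.8, 0.6),
        CausalChain("glucose", "neutrophil_pct", 0.7, 0.7, 0.714),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    ``blue_effect`` (delta) and ``droop_effect`` (gamma) are the planted
    stroke effects; ``pose_jitter_deg`` / ``pose_jitter_cm`` bound the
    random rigid pose applied before saving; ``noise_sd`` is per-vertex
    color noise (0-255 scale); ``vertex_noise_sd`` is positional noise in
    cm (scanner-level).
    """

    n_stroke: int = 60
    n_control: int = 60
    blue_effect: float = 30.0
    droop_effect: float = 0.3
    pose_jitter_deg: float = 15.0
    pose_jitter_cm: float = 2.0
    noise_sd: float = 8.0
    vertex_noise_sd: float = 0.003
    marker_graph: tuple[CausalChain, ...] = field(default_factory=_default_marker_graph)
    null_markers: tuple[str, ...] = ("albumin", "creatinine")
    marker_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_stroke", "n_control"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("blue_effect", "droop_effect", "pose_jitter_deg",
                     "pose_jitter_cm", "noise_sd", "vertex_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.marker_missing_rate < 1.0:
            raise ConfigurationError("marker_missing_rate must be in [0, 1)")
        for chain in self.marker_graph:
            if chain.noise_sd < 0:
                raise ConfigurationError("marker_graph: noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-sample generation record used as oracle by the test suite."""

    label: str  # "stroke" | "control"
    nose_tip_index: int
    nose_tip_posed: np.ndarray  # (3,) posed coordinates of the true tip
    rotation: np.ndarray  # (3,3) applied pose rotation, det +1
    translation: np.ndarray  # (3,)
    landmark_indices: Mapping[str, int]  # 72 named template vertex indices
    mask_vertex_indices: np.ndarray  # central-face (ophryon+mouth) vertex set

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("nose_tip_posed", "rotation", "translation", "mask_vertex_indices"):
            d[k] = np.asarray(d[k]).tolist()
        d["landmark_indices"] = dict(self.landmark_indices)
        return json.dumps(d)


# ---------------------------------------------------------------------------
# Template geometry
# ---------------------------------------------------------------------------

def _template_grid() -> tuple[np.ndarray, np.ndarray]:
    u = np.linspace(-1.0, 1.0, _GRID_N)
    uu, vv = np.meshgrid(u, u, indexing="xy")
    x = (_HALF_WIDTH * uu).ravel()
    y = (_HALF_HEIGHT * vv).ravel()
    return x, y


def _gauss(x, y, x0, y0, sx, sy):
    return np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2)))


def _base_depth(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    arg = 1.0 - (x / _HEAD_A) ** 2 - ((y - _HEAD_Y0) / _HEAD_B) ** 2
    z = _HEAD_C * np.sqrt(np.clip(arg, 0.0, None))
    # soft-tissue features (cm): brows, forehead/ophryon, chin, mouth ridge,
    # eye sockets, plus a faint skin-texture ripple that keeps every region
    # except the nose measurably aspherical (so the sphere-fit argmin has a
    # unique, well-separated optimum at the nose apex)
    feat = 0.35 * (_gauss(x, y, -2.2, 2.6, 1.3, 1.3) + _gauss(x, y, 2.2, 2.6, 1.3, 1.3))
    feat += 0.25 * _gauss(x, y, 0.0, 3.4, 1.8, 1.8)
    feat += 0.45 * _gauss(x, y, 0.0, -7.2, 1.6, 1.6)
    feat += 0.30 * _gauss(x, y, 0.0, -4.3, 1.9, 0.55)
    feat -= 0.25 * (_gauss(x, y, -2.6, 1.6, 0.9, 0.9) + _gauss(x, y, 2.6, 1.6, 0.9, 0.9))
    feat += 0.03 * np.sin(2 * np.pi * x / 2.1) * np.sin(2 * np.pi * y / 2.7)
    # taper every feature to zero around the nose cap so the cap stays an
    # exact sphere for the tip detector
    d_nose = np.sqrt(x**2 + (y - _NOSE_Y) ** 2)
    s = np.clip((d_nose - 1.5) / 1.3, 0.0, 1.0)
    return z + (s * s * (3.0 - 2.0 * s)) * feat


def _add_nose(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace the nose region with a protruding near-spherical cap.

    Inside the cap the surface is a sphere of radius ``_NOSE_R`` minus a
    small 4th-order radial taper.  At the apex the neighborhood is almost
    exactly spherical (sphere-fit loss ~ vertex noise); moving off the apex
    picks up the asymmetric taper, so the fit loss rises strictly and the
    tip detector has a unique, well-separated optimum.
    """
    z0 = _base_depth(np.array([0.0]), np.array([_NOSE_Y]))[0]
    zc = z0 - _NOSE_DROP
    d2 = (x - 0.0) ** 2 + (y - _NOSE_Y) ** 2
    inside = d2 < _NOSE_R**2
    sphere_z = np.full_like(z, -np.inf)
    sphere_z[inside] = zc + np.sqrt(_NOSE_R**2 - d2[inside]) - 0.04 * d2[inside] ** 2
    z_new = np.maximum(z, sphere_z)
    tip = int(np.argmax(np.where(inside, sphere_z, -np.inf)))
    return z_new, tip


def template_face() -> tuple[np.ndarray, int]:
    """Canonical (un-posed) template vertices (N,3) and the nose-tip index."""
    x, y = _template_grid()
    z = _base_depth(x, y)
    z, tip = _add_nose(x, y, z)
    return np.column_stack([x, y, z]), tip


def _nearest_vertex(x: np.ndarray, y: np.ndarray, px: float, py: float) -> int:
    return int(np.argmin((x - px) ** 2 + (y - py) ** 2))


def landmark_template() -> dict[str, int]:
    """72 named landmarks as template vertex indices (shared topology)."""
    x, y = _template_grid()
    pts: dict[str, tuple[float, float]] = {}

    # lower face contour (15): jawline ellipse from left temple to right
    t = np.linspace(np.pi * 1.15, np.pi * 1.85, 15)
    for i, a in enumerate(t):
        pts[f"contour_{i}"] = (6.2 * np.cos(a), 8.3 * np.sin(a) + 0.4)
    # forehead arc (5), center point is the ophryon
    for i, fx in enumerate(np.linspace(-3.6, 3.6, 5)):
        name = "ophryon" if i == 2 else f"forehead_{i}"
        pts[name] = (fx, 3.6 if i == 2 else 4.6)
    # brows (2 x 4)
    for side, s in (("l", -1), ("r", 1)):
        for i, fx in enumerate(np.linspace(1.0, 3.4, 4)):
            pts[f"brow_{side}_{i}"] = (s * fx, 2.7)
    # eyes (2 x 6): corners + upper/lower lid points
    for side, s in (("l", -1), ("r", 1)):
        pts[f"eye_{side}_inner"] = (s * 1.6, 1.6)
        pts[f"eye_{side}_outer"] = (s * 3.6, 1.6)
        pts[f"eye_{side}_top_in"] = (s * 2.2, 2.0)
        pts[f"eye_{side}_top_out"] = (s * 3.0, 2.0)
        pts[f"eye_{side}_bot_in"] = (s * 2.2, 1.2)
        pts[f"eye_{side}_bot_out"] = (s * 3.0, 1.2)
    # nose (7)
    pts["nose_tip"] = (0.0, _NOSE_Y)
    pts["nose_dorsum"] = (0.0, 0.2)
    pts["nose_bridge"] = (0.0, 1.0)
    pts["glabella"] = (0.0, 2.2)
    pts["nose_ala_l"] = (-1.0, -1.0)
    pts["nose_ala_r"] = (1.0, -1.0)
    pts["nose_base_l"] = (-0.5, -1.5)
    pts["nose_base_r"] = (0.5, -1.5)
    # mouth (14)
    pts["mouth_corner_l"] = (-2.2, -4.3)
    pts["mouth_corner_r"] = (2.2, -4.3)
    for i, fx in enumerate(np.linspace(-1.4, 1.4, 6)):
        pts[f"mouth_top_{i}"] = (fx, -3.8)
    for i, fx in enumerate(np.linspace(-1.4, 1.4, 6)):
        pts[f"mouth_bot_{i}"] = (fx, -4.8)
    # cheeks (2 x 2) and temples (2)
    for side, s in (("l", -1), ("r", 1)):
        pts[f"cheek_{side}_up"] = (s * 4.6, 0.0)
        pts[f"cheek_{side}_low"] = (s * 4.0, -2.4)
        pts[f"temple_{side}"] = (s * 5.4, 3.2)
    # chin (3)
    pts["chin_mid"] = (0.0, -7.6)
    pts["chin_l"] = (-1.8, -7.0)
    pts["chin_r"] = (1.8, -7.0)
    # philtrum
    pts["philtrum"] = (0.0, -2.6)

    out = {name: _nearest_vertex(x, y, px, py) for name, (px, py) in pts.items()}
    assert len(out) == 72, f"landmark template defines {len(out)} points, expected 72"
    return out


def central_face_mask() -> np.ndarray:
    """Vertex indices of the central-face mask: ophryon + mouth areas."""
    x, y = _template_grid()
    ophryon = ((x / 2.2) ** 2 + ((y - 2.2) / 1.8) ** 2) <= 1.0
    mouth = ((x / 2.4) ** 2 + ((y + 4.3) / 1.2) ** 2) <= 1.0
    return np.flatnonzero(ophryon | mouth)


def _droop_weights(y: np.ndarray) -> np.ndarray:
    # smooth 0->1 transition below y = -3.5 cm: mouth corners get ~0.7,
    # chin and jawline ~1.0
    return 1.0 / (1.0 + np.exp((y + 3.5) / 0.8))


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    if max_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# Face generation
# ---------------------------------------------------------------------------

def generate_face(
    config: SyntheticConfig,
    label: str,
    rng: np.random.Generator,
) -> tuple[FacePointCloud, GroundTruth]:
    """Generate one posed face scan with per-vertex color and its ground truth.

    Stroke samples get the blue-channel shift over the central-face mask and
    the lower-face droop; the cloud is then rotated/translated by a recorded
    random pose.
    """
    config.validate()
    if label not in ("stroke", "control"):
        raise ValueError(f"label must be 'stroke' or 'control', got {label!r}")

    vertices, tip = template_face()
    vertices = vertices.copy()
    x, y = vertices[:, 0], vertices[:, 1]

    colors = np.tile(_BASE_COLOR, (len(vertices), 1))
    # mild smooth red variation on the cheeks (blue kept flat so the planted
    # in-mask vs out-of-mask blue contrast equals blue_effect exactly)
    cheek = _gauss(x, y, -4.0, -1.0, 2.0, 2.0) + _gauss(x, y, 4.0, -1.0, 2.0, 2.0)
    colors[:, 0] += 12.0 * cheek

    mask = central_face_mask()
    if label == "stroke":
        colors[mask, 2] += config.blue_effect
        vertices[:, 1] -= config.droop_effect * _droop_weights(y)

    if config.noise_sd > 0:
        colors = colors + rng.normal(0.0, config.noise_sd, colors.shape)
    colors = np.clip(colors, 0.0, 255.0)
    if config.vertex_noise_sd > 0:
        vertices = vertices + rng.normal(0.0, config.vertex_noise_sd, vertices.shape)

    R = _random_rotation(rng, config.pose_jitter_deg)
    tvec = rng.uniform(-config.pose_jitter_cm, config.pose_jitter_cm, 3)
    posed = vertices @ R.T + tvec

    cloud = FacePointCloud(vertices=posed, colors=colors)
    truth = GroundTruth(
        label=label,
        nose_tip_index=tip,
        nose_tip_posed=posed[tip].copy(),
        rotation=R,
        translation=tvec,
        landmark_indices=landmark_template(),
        mask_vertex_indices=mask,
    )
    return cloud, truth


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[FacePointCloud], list[GroundTruth], pd.DataFrame]:
    """Generate a full labeled cohort plus a sample metadata table.

    Age/sex/cohort metadata exercise matching and splitting code paths; the
    planted facial signal does not depend on them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clouds, truths, rows = [], [], []
    labels = ["stroke"] * config.n_stroke + ["control"] * config.n_control
    for i, label in enumerate(labels):
        cloud, truth = generate_face(config, label, rng)
        clouds.append(cloud)
        truths.append(truth)
        rows.append(
            {
                "sample_id": f"s{i:04d}",
                "label": label,
                "age": float(np.round(np.clip(rng.normal(68.0, 10.0), 30, 95), 1)),
                "sex": "F" if rng.uniform() < 0.5 else "M",
                "cohort": "synthetic",
            }
        )
    return clouds, truths, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical-marker generation
# ---------------------------------------------------------------------------

def _check_acyclic(chains: Sequence[CausalChain]) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for c in chains:
        if c.driver == c.mediator:
            raise ValueError(f"cyclic chain spec: driver == mediator ({c.driver!r})")
        g.add_edge(c.driver, c.mediator)
        g.add_edge(c.mediator, "__score__")
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("cyclic chain spec: marker graph contains a cycle")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_markers(
    config: SyntheticConfig,
    scores: np.ndarray,
    rng: np.random.Generator,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw a clinical-marker table from the declared causal chains.

    ``scores`` are the per-sample stroke probabilities the chains feed into
    (any real-valued vector works).  The returned table contains one column
    per chain variable plus the declared null (independent) markers, indexed
    by ``sample_id``.
    """
    config.validate()
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) == 0:
        raise ValueError("scores must be a non-empty 1-D array")
    _check_acyclic(config.marker_graph)

    n = len(scores)
    z = _zscore(scores)
    cols: dict[str, np.ndarray] = {}
    for chain in config.marker_graph:
        mediator = chain.beta_mediator * z + chain.noise_sd * rng.normal(size=n)
        driver = chain.beta_driver * _zscore(mediator) + chain.noise_sd * rng.normal(size=n)
        cols[chain.mediator] = mediator
        cols[chain.driver] = driver
    for name in config.null_markers:
        cols[name] = rng.normal(size=n)

    df = pd.DataFrame(cols)
    if config.marker_missing_rate > 0:
        miss = rng.uniform(size=df.shape) < config.marker_missing_rate
        df = df.mask(miss)
    df.index = (
        pd.Index(sample_ids, name="sample_id")
        if sample_ids is not None
        else pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id")
    )
    return df
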