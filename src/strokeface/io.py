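"""File formats: PLY point clouds, PNG image pairs, tables and manifests.

Scans travel as ASCII PLY with uchar per-vertex colors (via trimesh);
aligned image pairs as 8-bit RGB texture PNG plus 16-bit depth PNG with a
recorded scale, and the pixel->vertex mapping as a compressed ``.npz``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from strokeface.geometry import FaceImagePair, FacePointCloud

DEPTH_SCALE = 1000.0  # depth PNG stores cm * 1000 + 32768 as uint16


def write_ply(cloud: FacePointCloud, path: str | Path) -> None:
    colors = np.clip(np.round(cloud.colors), 0, 255).astype(np.uint8)
    rgba = np.column_stack([colors, np.full(len(colors), 255, dtype=np.uint8)])
    pc = trimesh.PointCloud(cloud.vertices, colors=rgba)
    pc.export(str(path), encoding="ascii")


def read_ply(path: str | Path) -> FacePointCloud:
    loaded = trimesh.load(str(path))
    vertices = np.asarray(loaded.vertices, dtype=float)
    colors = np.asarray(loaded.colors, dtype=float)[:, :3]
    return FacePointCloud(vertices=vertices, colors=colors)


def write_image_pair(pair: FaceImagePair, stem: str | Path) -> None:
    """Write <stem>_texture.png (8-bit RGB), <stem>_depth.png (16-bit),
    and <stem>_mapping.npz (pixel->vertex indices + transform)."""
    import imageio.v3 as iio

    stem = Path(stem)
    tex = np.clip(np.round(pair.texture), 0, 255).astype(np.uint8)
    iio.imwrite(stem.with_name(stem.name + "_texture.png"), tex)
    d16 = np.clip(pair.depth * DEPTH_SCALE + 32768.0, 0, 65535).astype(np.uint16)
    iio.imwrite(stem.with_name(stem.name + "_depth.png"), d16)
    np.savez_compressed(
        stem.with_name(stem.name + "_mapping.npz"),
        mapping=pair.mapping.astype(np.int32),
        transform=pair.transform if pair.transform is not None else np.full((2, 3), np.nan),
        depth_scale=np.array([DEPTH_SCALE]),
    )


def read_image_pair(stem: str | Path) -> FaceImagePair:
    import imageio.v3 as iio

    stem = Path(stem)
    tex = iio.imread(stem.with_name(stem.name + "_texture.png")).astype(np.float32)
    d16 = iio.imread(stem.with_name(stem.name + "_depth.png")).astype(np.float64)
    data = np.load(stem.with_name(stem.name + "_mapping.npz"))
    depth = ((d16 - 32768.0) / float(data["depth_scale"][0])).astype(np.float32)
    transform = data["transform"]
    if np.isnan(transform).any():
        transform = None
    return FaceImagePair(
        texture=tex, depth=depth, mapping=data["mapping"].astype(np.int64), transform=transform
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int) -> None:
    from strokeface import __version__

    write_json(
        {
            "package_version": __version__,
            "seed": seed,
            "config_hash": config_hash(config),
            "config": config,
        },
        path,
    )


def scores_to_frame(scores) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"sample_id": s.sample_id, "fold": s.fold}
        for k, v in s.per_backbone_probability.items():
            row[f"p_{k}"] = v
        row["final_probability"] = s.final_probability
        row["predicted_label"] = s.predicted_label
        rows.append(row)
    return pd.DataFrame(rows)
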