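"""3D face preprocessing: nose-tip detection, pose correction, rasterization.

The pipeline turns a posed, colored 3D face point cloud into an aligned
pair of 224 x 224 texture (RGB) and depth images:

1. nose-tip detection — for every vertex, a least-squares sphere is fitted
   to its <= 1.5 cm neighborhood; the vertex with the lowest mean squared
   radial residual is the nose tip;
2. pose correction — principal axes of the <= 5 cm nose region define a
   new orthonormal frame; vertices are rotated into it with the nose tip
   at the origin, iterated a few times;
3. z-buffer projection onto the X-Y plane at 0.1 cm resolution, keeping
   per cell the vertex nearest the viewer (largest Z);
4. crop of the unmapped background to the face bounding box, padding to a
   square, and bilinear resize to 224 x 224.

Conventions (fixed; the printed method leaves them open): after
correction the face looks along +Z (larger Z = closer to the viewer) and
the face-up direction is +Y.  Pixel grids are 0-based, row 0 at top,
X maps to columns and Y to rows (image convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.transform import resize as _sk_resize

IMAGE_SIZE = 224


class DegenerateInputError(ValueError):
    """Raised when a cloud cannot support the requested operation."""


@dataclass
class FacePointCloud:
    """Colored 3D scan: ``vertices`` (N,3) in cm, ``colors`` (N,3) RGB in [0,255]."""

    vertices: np.ndarray
    colors: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.colors = np.asarray(self.colors, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.colors.shape != self.vertices.shape:
            raise ValueError("colors must match vertices shape (N, 3)")
        if len(self.vertices) < 100:
            raise ValueError("need at least 100 vertices")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class SphereFit:
    """Least-squares sphere: center (cm), radius (cm), mean squared radial residual."""

    center: np.ndarray
    radius: float
    loss: float


@dataclass
class FaceImagePair:
    """Aligned texture (H,W,3) and depth (H,W, cm) images.

    ``mapping`` holds, per pixel, the index of the contributing vertex
    (-1 = background).  Wherever mapping is set at native resolution, the
    depth pixel is exactly that vertex's Z.  ``transform`` is the 2x3
    affine taking pose-corrected (x, y) cm to (row, col) pixels.
    """

    texture: np.ndarray
    depth: np.ndarray
    mapping: np.ndarray
    transform: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.texture.ndim != 3 or self.texture.shape[2] != 3:
            raise ValueError("texture must be (H, W, 3)")
        if self.depth.shape != self.texture.shape[:2]:
            raise ValueError("depth must match texture (H, W)")
        if self.mapping.shape != self.depth.shape:
            raise ValueError("mapping must match depth shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    def is_standard(self) -> bool:
        return self.shape == (IMAGE_SIZE, IMAGE_SIZE)

    def project_points(self, xy: np.ndarray) -> np.ndarray:
        """Map pose-corrected (x, y) cm coordinates to (row, col) pixels."""
        if self.transform is None:
            raise ValueError("pair carries no coordinate transform")
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ones = np.ones((len(xy), 1))
        return np.hstack([xy, ones]) @ self.transform.T


# ---------------------------------------------------------------------------
# Step 1: nose-tip detection
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> SphereFit:
    """Algebraic least-squares sphere fit (expand |v - O|^2 = r^2).

    Solves the linear system A c = b with A = [2x, 2y, 2z, 1] and
    b = x^2 + y^2 + z^2; the reported loss is the geometric mean squared
    radial residual, which is what ranks nose-tip candidates.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise DegenerateInputError("sphere fit needs at least 4 points")
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        return SphereFit(center=center, radius=0.0, loss=np.inf)
    r = float(np.sqrt(r2))
    d = np.linalg.norm(pts - center, axis=1)
    return SphereFit(center=center, radius=r, loss=float(np.mean((d - r) ** 2)))


def _batched_sphere_losses(
    V: np.ndarray, neighbors: list[np.ndarray], min_neighbors: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-vertex sphere fits over padded neighbor lists.

    Returns (loss, center, radius) arrays; loss = inf where a vertex has
    fewer than ``min_neighbors`` neighbors or the fit is degenerate.
    """
    n = len(V)
    counts = np.array([len(ix) for ix in neighbors])
    kmax = counts.max()
    idx = np.zeros((n, kmax), dtype=np.int64)
    mask = np.zeros((n, kmax), dtype=bool)
    for i, ix in enumerate(neighbors):
        idx[i, : len(ix)] = ix
        mask[i, : len(ix)] = True

    P = V[idx]  # (n, k, 3)
    w = mask.astype(float)[..., None]
    A = np.concatenate([2.0 * P, np.ones((n, kmax, 1))], axis=2) * np.sqrt(w)
    b = (P**2).sum(axis=2) * np.sqrt(mask.astype(float))
    At = A.transpose(0, 2, 1)
    M = At @ A
    rhs = (At @ b[..., None])[..., 0]
    # tiny ridge keeps near-coplanar neighborhoods solvable; their loss is
    # large anyway so they never win the argmin
    M = M + 1e-9 * np.eye(4)
    sol = np.linalg.solve(M, rhs[..., None])[..., 0]
    center = sol[:, :3]
    r2 = sol[:, 3] + (center**2).sum(axis=1)
    radius = np.sqrt(np.clip(r2, 0.0, None))

    diff = P - center[:, None, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    resid2 = (d - radius[:, None]) ** 2 * mask
    loss = resid2.sum(axis=1) / np.maximum(counts, 1)
    loss[(counts < min_neighbors) | (r2 <= 0)] = np.inf
    return loss, center, radius


def detect_nose_tip(
    cloud: FacePointCloud,
    neighborhood_radius: float = 1.5,
    min_neighbors: int = 10,
) -> tuple[int, SphereFit]:
    """Find the nose tip as the vertex whose neighborhood best fits a sphere.

    Every vertex with at least ``min_neighbors`` neighbors within
    ``neighborhood_radius`` cm is a candidate; the candidate minimizing
    the sphere-fit loss wins (exhaustive argmin).
    """
    V = cloud.vertices
    tree = cKDTree(V)
    neighbors = tree.query_ball_point(V, neighborhood_radius)
    loss, center, radius = _batched_sphere_losses(V, neighbors, min_neighbors)
    if not np.isfinite(loss).any():
        raise DegenerateInputError(
            f"no vertex has >= {min_neighbors} neighbors within {neighborhood_radius} cm"
        )
    best = int(np.argmin(loss))
    return best, SphereFit(center=center[best], radius=float(radius[best]), loss=float(loss[best]))


# ---------------------------------------------------------------------------
# Step 2: pose correction
# ---------------------------------------------------------------------------

def _orient_frame(region: np.ndarray, tip: np.ndarray, eigvecs: np.ndarray) -> np.ndarray:
    """Resolve eigenvector sign/order ambiguity into a fixed convention.

    Axes are ordered by descending eigenvalue: the largest-spread axis is
    the face-up direction Y, the smallest-spread axis the viewing normal Z.
    Y's sign points toward the denser side above the nose tip; Z's sign
    makes the nose tip protrude toward the viewer; X = Y x Z closes a
    right-handed frame (det +1).
    """
    z_ax = eigvecs[:, 0]
    y_ax = eigvecs[:, 2]
    centered = region - tip
    # +Z: tip is extremal toward the viewer relative to the region centroid
    if (tip - region.mean(axis=0)) @ z_ax < 0:
        z_ax = -z_ax
    # +Y: more face above the nose tip than below
    above = int(np.sum(centered @ y_ax > 0))
    below = len(region) - above
    if above < below:
        y_ax = -y_ax
    elif above == below and y_ax[np.argmax(np.abs(y_ax))] < 0:
        y_ax = -y_ax  # lexicographic tie-break
    x_ax = np.cross(y_ax, z_ax)
    return np.column_stack([x_ax, y_ax, z_ax])


def correct_pose(
    cloud: FacePointCloud,
    nose_tip: int,
    region_radius: float = 5.0,
    n_iter: int = 3,
    return_transform: bool = False,
):
    """Rotate the cloud into the principal-axes frame of the nose region.

    The region is every vertex within ``region_radius`` cm of the nose tip;
    its covariance eigenvectors define the new base vectors; the nose tip is
    translated to the origin.  Iterating refines the frame because the
    region membership changes slightly after each rotation.
    """
    V = cloud.vertices.copy()
    R_total = np.eye(3)
    t_total = np.zeros(3)
    for _ in range(max(1, n_iter)):
        tip = V[nose_tip]
        region = V[np.linalg.norm(V - tip, axis=1) < region_radius]
        if len(region) < 3:
            raise DegenerateInputError("fewer than 3 points within the nose region")
        cov = np.cov((region - region.mean(axis=0)).T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        if eigvals[1] < 1e-12 * max(eigvals[2], 1e-300):
            raise DegenerateInputError("nose-region covariance is rank deficient")
        R = _orient_frame(region, tip, eigvecs)
        V = (V - tip) @ R
        R_total = R_total @ R
        t_total = (t_total - tip) @ R if np.any(t_total) or np.any(tip) else t_total
    out = FacePointCloud(vertices=V, colors=cloud.colors.copy())
    if return_transform:
        return out, R_total
    return out


# ---------------------------------------------------------------------------
# Step 3: z-buffer projection
# ---------------------------------------------------------------------------

def project_depth(
    cloud: FacePointCloud,
    resolution: float = 0.1,
    hole_fill_cells: int = 3,
) -> FaceImagePair:
    """Rasterize a pose-corrected cloud onto the X-Y plane.

    Grid cells of ``resolution`` cm cover the X-Y bounding box; each cell
    keeps the vertex nearest the viewer (largest Z).  The texture pixel
    takes that vertex's RGB and the depth pixel its Z.  Unmapped cells
    within ``hole_fill_cells`` of a mapped cell copy their nearest mapped
    neighbor (mapping follows); farther cells stay background (0, -1).
    """
    V = cloud.vertices
    if len(V) == 0:
        raise DegenerateInputError("empty cloud")
    x, y, z = V[:, 0], V[:, 1], V[:, 2]
    xmin, ymax = x.min(), y.max()
    cols = np.floor((x - xmin) / resolution).astype(np.int64)
    rows = np.floor((ymax - y) / resolution).astype(np.int64)
    H, W = int(rows.max()) + 1, int(cols.max()) + 1

    # z-buffer: stable sort by (cell, z); the last entry per cell has max z
    cell = rows * W + cols
    order = np.lexsort((z, cell))
    cell_sorted = cell[order]
    last = np.flatnonzero(np.r_[cell_sorted[1:] != cell_sorted[:-1], True])
    keep = order[last]

    texture = np.zeros((H, W, 3), dtype=np.float32)
    depth = np.zeros((H, W), dtype=np.float32)
    mapping = np.full((H, W), -1, dtype=np.int64)
    rk, ck = rows[keep], cols[keep]
    texture[rk, ck] = cloud.colors[keep]
    depth[rk, ck] = z[keep]
    mapping[rk, ck] = keep

    unmapped = mapping < 0
    if unmapped.any() and hole_fill_cells > 0:
        dist, (ir, ic) = ndimage.distance_transform_edt(unmapped, return_indices=True)
        fill = unmapped & (dist <= hole_fill_cells)
        texture[fill] = texture[ir[fill], ic[fill]]
        depth[fill] = depth[ir[fill], ic[fill]]
        mapping[fill] = mapping[ir[fill], ic[fill]]

    # affine cm -> pixel: row = (ymax - y)/res - 0.5, col = (x - xmin)/res - 0.5
    transform = np.array(
        [[0.0, -1.0 / resolution, ymax / resolution - 0.5],
         [1.0 / resolution, 0.0, -xmin / resolution - 0.5]]
    )
    return FaceImagePair(texture=texture, depth=depth, mapping=mapping, transform=transform)


# ---------------------------------------------------------------------------
# Step 4: crop and resize
# ---------------------------------------------------------------------------

def crop_resize(pair: FaceImagePair, size: int = IMAGE_SIZE) -> FaceImagePair:
    """Crop the unmapped margin to the face bounding box and resize to 224 x 224.

    Padding policy: the cropped box is padded symmetrically with background
    to a square before the bilinear resize, so the face keeps its aspect
    ratio.  Depth is resized with the same bilinear transform; the mapping
    uses nearest-neighbor so pixel -> vertex lookups stay valid.
    """
    mapped = pair.mapping >= 0
    if not mapped.any():
        raise DegenerateInputError("face bounding box is empty")
    rows = np.flatnonzero(mapped.any(axis=1))
    cols = np.flatnonzero(mapped.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1

    tex = pair.texture[r0:r1, c0:c1]
    dep = pair.depth[r0:r1, c0:c1]
    mp = pair.mapping[r0:r1, c0:c1]
    h, w = dep.shape
    side = max(h, w)
    pt, pl = (side - h) // 2, (side - w) // 2
    if side != h or side != w:
        tex = np.pad(tex, ((pt, side - h - pt), (pl, side - w - pl), (0, 0)))
        dep = np.pad(dep, ((pt, side - h - pt), (pl, side - w - pl)))
        mp = np.pad(mp, ((pt, side - h - pt), (pl, side - w - pl)), constant_values=-1)

    if side == size:
        tex_r, dep_r, mp_r = tex, dep, mp
    else:
        tex_r = _sk_resize(tex, (size, size), order=1, preserve_range=True,
                           anti_aliasing=False).astype(np.float32)
        dep_r = _sk_resize(dep, (size, size), order=1, preserve_range=True,
                           anti_aliasing=False).astype(np.float32)
        src = np.minimum((np.arange(size) + 0.5) * side / size, side - 1).astype(np.int64)
        mp_r = mp[np.ix_(src, src)]

    transform = None
    if pair.transform is not None:
        scale = size / side
        shift = np.array([pt - r0, pl - c0], dtype=float)
        A = pair.transform.copy()
        A[:, 2] += shift
        # resize maps source pixel centers: out = (in + 0.5) * scale - 0.5
        A = A * scale
        A[:, 2] += 0.5 * scale - 0.5
        transform = A
    return FaceImagePair(texture=np.ascontiguousarray(tex_r),
                         depth=np.ascontiguousarray(dep_r),
                         mapping=np.ascontiguousarray(mp_r),
                         transform=transform)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    pair: FaceImagePair
    corrected: FacePointCloud
    nose_tip_index: int
    sphere_fit: SphereFit
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))


def preprocess_cloud(
    cloud: FacePointCloud,
    neighborhood_radius: float = 1.5,
    region_radius: float = 5.0,
    n_iter: int = 3,
    resolution: float = 0.1,
    size: int = IMAGE_SIZE,
) -> PreprocessResult:
    """Run the full preprocessing chain on a raw posed scan."""
    tip, fit = detect_nose_tip(cloud, neighborhood_radius)
    corrected, R = correct_pose(cloud, tip, region_radius, n_iter, return_transform=True)
    pair = project_depth(corrected, resolution=resolution)
    pair = crop_resize(pair, size=size)
    return PreprocessResult(pair=pair, corrected=corrected, nose_tip_index=tip,
                            sphere_fit=fit, rotation=R)
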