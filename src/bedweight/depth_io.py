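"""Depth-frame and point-cloud handling: the preprocessing chain.

A top-view depth camera observes a patient lying in bed.  The chain
converts the 16-bit depth map to a metric point cloud by pinhole
back-projection, isolates the bed+patient region by depth thresholding
and lattice clustering, optionally segments the patient from the bed
plane (for the uncovering targets), and mean-centers the cloud before
voxelization.

Camera convention: x right, y down (along the image rows), z along the
optical axis; the stored depth is the z coordinate, not the ray length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "DepthFrame",
    "PointCloud",
    "EmptySceneError",
    "SegmentationError",
    "depth_to_cloud",
    "extract_bed_region",
    "segment_patient_from_bed",
    "fit_plane_ransac",
    "mean_center",
    "save_depth_png",
    "load_depth_png",
    "save_ply",
    "load_ply",
]


class EmptySceneError(RuntimeError):
    """No sufficiently large cluster of scene points was found."""


class SegmentationError(RuntimeError):
    """Robust bed-plane fitting failed (too few planar inliers)."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass
class DepthFrame:
    """A rectangular grid of metric depths (meters) with intrinsics.

    Invalid pixels (depth <= 0 or non-finite) are never back-projected.
    """

    depths: np.ndarray
    intrinsics: CameraIntrinsics
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.float64)
        if self.depths.ndim != 2:
            raise ValueError("depths must be a 2D array")
        if self.valid is None:
            self.valid = np.isfinite(self.depths) & (self.depths > 0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & np.isfinite(self.depths) & (self.depths > 0)


@dataclass
class PointCloud:
    """N metric 3D points in the camera frame with acquisition metadata.

    ``pixels`` optionally records the (row, col) of origin of each point
    so lattice-based clustering can operate on back-projected clouds.
    """

    points: np.ndarray
    metadata: dict = field(default_factory=dict)
    pixels: np.ndarray | None = None
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
            if len(self.pixels) != len(self.points):
                raise ValueError("pixels and points must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask, preserving metadata and pixel links."""
        return PointCloud(
            points=self.points[mask],
            metadata=dict(self.metadata),
            pixels=self.pixels[mask] if self.pixels is not None else None,
            frame_shape=self.frame_shape,
        )


def depth_to_cloud(frame: DepthFrame, metadata: dict | None = None) -> PointCloud:
    """Back-project every valid pixel through the pinhole model.

    ``x = (u - cx) z / fx``, ``y = (v - cy) z / fy``, ``z = depth``, with
    u the column and v the row index.  An all-invalid frame yields an
    empty cloud (not an error).
    """
    K = frame.intrinsics
    rows, cols = np.nonzero(frame.valid)
    z = frame.depths[rows, cols]
    x = (cols - K.cx) * z / K.fx
    y = (rows - K.cy) * z / K.fy
    return PointCloud(
        points=np.column_stack([x, y, z]),
        metadata=dict(metadata or {}),
        pixels=np.column_stack([rows, cols]),
        frame_shape=frame.depths.shape,
    )


def extract_bed_region(
    cloud: PointCloud,
    depth_interval: tuple[float, float],
    min_cluster_size: int = 50,
    cluster_radius: float = 0.05,
) -> PointCloud:
    """Keep points in the depth interval, then the largest spatial cluster.

    For back-projected clouds that carry pixel indices, clustering is
    8-connected components on the pixel lattice; otherwise a radius graph
    (``cluster_radius`` meters) is used.  Raises :class:`EmptySceneError`
    if no cluster reaches ``min_cluster_size``.
    """
    lo, hi = depth_interval
    if not lo < hi:
        raise ValueError(f"empty depth interval [{lo}, {hi}]")
    if len(cloud) == 0:
        raise EmptySceneError("empty point cloud")
    in_band = (cloud.points[:, 2] >= lo) & (cloud.points[:, 2] <= hi)
    banded = cloud.select(in_band)
    if len(banded) == 0:
        raise EmptySceneError("no points in the depth interval")

    if banded.pixels is not None and banded.frame_shape is not None:
        from scipy import ndimage

        mask = np.zeros(banded.frame_shape, dtype=bool)
        mask[banded.pixels[:, 0], banded.pixels[:, 1]] = True
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            raise EmptySceneError("no clusters found")
        point_labels = labels[banded.pixels[:, 0], banded.pixels[:, 1]]
        counts = np.bincount(point_labels, minlength=n + 1)
        counts[0] = 0
        best = int(np.argmax(counts))
        keep = point_labels == best
    else:
        from scipy.sparse.csgraph import connected_components
        from scipy.spatial import cKDTree

        tree = cKDTree(banded.points)
        graph = tree.sparse_distance_matrix(tree, cluster_radius, output_type="coo_matrix")
        n, comp = connected_components(graph.tocsr(), directed=False)
        counts = np.bincount(comp)
        keep = comp == int(np.argmax(counts))

    if int(keep.sum()) < min_cluster_size:
        raise EmptySceneError(
            f"largest cluster has {int(keep.sum())} points (< {min_cluster_size})"
        )
    return banded.select(keep)


def fit_plane_ransac(
    points: np.ndarray,
    tolerance: float = 0.02,
    iterations: int = 1000,
    seed: int = 0,
    min_inlier_fraction: float = 0.25,
    score_subsample: int = 4000,
) -> tuple[np.ndarray, float]:
    """Robust plane fit: seeded RANSAC refined by least squares on inliers.

    Returns ``(unit normal n, offset d)`` with the plane ``n . p + d = 0``
    and the normal oriented toward the camera origin (``d < 0`` for a
    plane in front of the camera).  Raises :class:`SegmentationError` when
    fewer than ``min_inlier_fraction`` of the points are within tolerance.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise SegmentationError("need at least 3 points to fit a plane")
    rng = np.random.default_rng(seed)
    score_pts = pts
    if len(pts) > score_subsample:
        score_pts = pts[rng.choice(len(pts), score_subsample, replace=False)]

    tri = rng.integers(0, len(pts), size=(iterations, 3))
    p1, p2, p3 = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    normals = np.cross(p2 - p1, p3 - p1)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-12
    normals = normals[ok] / norms[ok, None]
    offsets = -np.einsum("ij,ij->i", normals, p1[ok])
    if len(normals) == 0:
        raise SegmentationError("all sampled triplets were degenerate")
    dists = np.abs(score_pts @ normals.T + offsets)  # (n_score, n_hyp)
    counts = (dists <= tolerance).sum(axis=0)
    best = int(np.argmax(counts))
    n, d = normals[best], offsets[best]

    # least-squares refinement on full-cloud inliers (two rounds)
    for _ in range(2):
        inliers = np.abs(pts @ n + d) <= tolerance
        if inliers.sum() < 3:
            break
        sub = pts[inliers]
        centroid = sub.mean(axis=0)
        _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
        n = vt[2]
        d = -float(n @ centroid)

    inliers = np.abs(pts @ n + d) <= tolerance
    if inliers.sum() < min_inlier_fraction * len(pts):
        raise SegmentationError(
            f"plane fit found only {int(inliers.sum())}/{len(pts)} inliers"
        )
    # orient the normal toward the camera origin: signed distance of the
    # origin, n.0 + d = d, must be negative
    if d > 0:
        n, d = -n, -d
    return n, float(d)


def segment_patient_from_bed(
    cloud: PointCloud,
    tolerance: float = 0.02,
    iterations: int = 1000,
    seed: int = 0,
) -> PointCloud:
    """Remove the bed plane; return the patient's off-plane points.

    Fits the dominant plane robustly, then discards plane inliers
    (within ``tolerance``) and everything on the far side of the plane
    (below the bed surface as seen from the camera).  What remains is the
    patient's volumetric surface above the bed.
    """
    n, d = fit_plane_ransac(cloud.points, tolerance=tolerance, iterations=iterations, seed=seed)
    signed = cloud.points @ n + d  # negative on the camera side of the plane
    keep = signed < -tolerance
    return cloud.select(keep)


def mean_center(cloud: PointCloud, center: np.ndarray | None = None) -> PointCloud:
    """Translate a cloud so its centroid is the origin (an isometry).

    If ``center`` is given it is subtracted instead of the cloud's own
    centroid — used to shift a target cloud into the frame of its paired
    input cloud.  The applied offset is recorded in the metadata.
    """
    if len(cloud) == 0:
        raise ValueError("cannot mean-center an empty cloud")
    offset = cloud.points.mean(axis=0) if center is None else np.asarray(center, dtype=np.float64)
    out = cloud.select(np.ones(len(cloud), dtype=bool))
    out.points = cloud.points - offset
    out.metadata["center_offset"] = offset.tolist()
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def save_depth_png(frame: DepthFrame, path) -> None:
    """Write depths as a 16-bit PNG in millimeters (0 = invalid)."""
    import imageio.v3 as iio

    mm = np.where(frame.valid, np.round(frame.depths * 1000.0), 0.0)
    iio.imwrite(str(path), np.clip(mm, 0, 65535).astype(np.uint16))


def load_depth_png(path, intrinsics: CameraIntrinsics) -> DepthFrame:
    import imageio.v3 as iio

    mm = np.asarray(iio.imread(str(path)))
    return DepthFrame(depths=mm.astype(np.float64) / 1000.0, intrinsics=intrinsics)


def save_ply(cloud: PointCloud, path) -> None:
    """Write points as a binary little-endian PLY."""
    import trimesh

    trimesh.PointCloud(cloud.points).export(str(path), file_type="ply", encoding="binary_little_endian")


def load_ply(path, metadata: dict | None = None) -> PointCloud:
    import trimesh

    loaded = trimesh.load(str(path), process=False)
    return PointCloud(points=np.asarray(loaded.vertices, dtype=np.float64), metadata=dict(metadata or {}))
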