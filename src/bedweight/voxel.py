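"""Binary voxelization of point clouds into a fixed cuboid grid.

Both networks consume occupancy volumes over the same cuboid: a voxel is
1 iff it contains at least one point of the (mean-centered) cloud.  The
default cuboid is 1.7 m x 2.4 m x 0.7 m discretized into 48 x 96 x 32
voxels (edge lengths 3.5 cm x 2.5 cm x 2.2 cm), centered on the origin
so it covers mean-centered in-bed clouds: x across the bed, y along the
bed, z vertical (the camera's optical axis).

Voxels are half-open boxes ``[lo, hi)`` per axis; points exactly on the
cuboid's maximum face are out of bounds.  Out-of-cuboid points are
discarded and tallied on the returned grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .depth_io import PointCloud

__all__ = ["GridSpec", "VoxelGrid", "voxelize", "voxel_centers", "save_nifti", "load_nifti"]

DEFAULT_EXTENT = (1.7, 2.4, 0.7)
DEFAULT_RESOLUTION = (48, 96, 32)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the voxelization cuboid.

    ``extent`` is the physical size (meters) along (x, y, z); ``resolution``
    the voxel counts (h, w, d); ``origin`` the minimum corner.  By default
    the cuboid is centered on the origin, matching mean-centered clouds.
    """

    extent: tuple[float, float, float] = DEFAULT_EXTENT
    resolution: tuple[int, int, int] = DEFAULT_RESOLUTION
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if any(e <= 0 for e in self.extent):
            raise ValueError(f"extents must be positive, got {self.extent}")
        if any(int(r) != r or r <= 0 for r in self.resolution):
            raise ValueError(f"resolution must be positive integers, got {self.resolution}")
        if self.origin is None:
            object.__setattr__(self, "origin", tuple(-e / 2 for e in self.extent))

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (meters) along (x, y, z)."""
        return np.asarray(self.extent, dtype=float) / np.asarray(self.resolution, dtype=float)

    def to_dict(self) -> dict:
        return {
            "extent": list(self.extent),
            "resolution": list(self.resolution),
            "origin": list(self.origin),  # type: ignore[arg-type]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            extent=tuple(d["extent"]),
            resolution=tuple(int(r) for r in d["resolution"]),
            origin=tuple(d["origin"]) if d.get("origin") is not None else None,
        )


@dataclass
class VoxelGrid:
    """Occupancy volume over a :class:`GridSpec`.

    ``occupancy`` is binary {0,1} for observed grids and real-valued in
    [0, 1] for network outputs.  ``n_discarded`` tallies the points that
    fell outside the cuboid during voxelization.
    """

    occupancy: np.ndarray
    spec: GridSpec
    n_discarded: int = 0

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy)
        if tuple(self.occupancy.shape) != tuple(self.spec.resolution):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} does not match spec resolution {self.spec.resolution}"
            )

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.occupancy, (0, 1)).all())

    def binarize(self, threshold: float = 0.5) -> "VoxelGrid":
        return VoxelGrid((self.occupancy > threshold).astype(np.uint8), self.spec)


def voxelize(cloud: PointCloud, spec: GridSpec | None = None) -> VoxelGrid:
    """Bin a point cloud into a binary occupancy grid.

    A voxel is set to 1 iff at least one point falls inside its half-open
    box.  Points outside the cuboid are discarded and counted in the
    returned grid's ``n_discarded``.  An empty cloud yields an all-zero grid.
    """
    spec = spec if spec is not None else GridSpec()
    occ = np.zeros(spec.resolution, dtype=np.uint8)
    pts = cloud.points
    if len(pts) == 0:
        return VoxelGrid(occ, spec)
    origin = np.asarray(spec.origin, dtype=float)
    res = np.asarray(spec.resolution)
    idx = np.floor((pts - origin) / spec.voxel_size).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < res), axis=1)
    # guard against points exactly on the max face that floor just inside
    on_max_face = np.any(pts >= origin + np.asarray(spec.extent), axis=1)
    inside &= ~on_max_face
    kept = idx[inside]
    occ[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return VoxelGrid(occ, spec, n_discarded=int((~inside).sum()))


def voxel_centers(grid: VoxelGrid) -> PointCloud:
    """One point per occupied voxel, at the voxel center.

    Inverse of :func:`voxelize` in the sense that re-voxelizing the
    centers reproduces the binary grid exactly.
    """
    if not grid.is_binary:
        raise ValueError("voxel_centers requires a binary grid")
    idx = np.argwhere(grid.occupancy > 0)
    origin = np.asarray(grid.spec.origin, dtype=float)
    pts = origin + (idx + 0.5) * grid.spec.voxel_size
    return PointCloud(points=pts.astype(np.float64))


def save_nifti(grid: VoxelGrid, path) -> None:
    """Write a volume as NIfTI with voxel sizes (mm) in the header."""
    import nibabel as nib

    affine = np.diag(list(grid.spec.voxel_size * 1000.0) + [1.0])
    affine[:3, 3] = np.asarray(grid.spec.origin) * 1000.0
    img = nib.Nifti1Image(np.asarray(grid.occupancy, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path, spec: GridSpec | None = None) -> VoxelGrid:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if spec is None:
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float) / 1000.0
        origin = np.asarray(img.affine[:3, 3], dtype=float) / 1000.0
        extent = tuple(zooms * np.asarray(data.shape))
        spec = GridSpec(extent=extent, resolution=tuple(data.shape), origin=tuple(origin))
    if np.isin(data, (0.0, 1.0)).all():
        data = data.astype(np.uint8)
    return VoxelGrid(data, spec)
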