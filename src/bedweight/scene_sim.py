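"""Synthetic paired covered/uncovered in-bed depth scenes with known weight.

The simulator stands in for recordings of real patients in bed under
three cover conditions (none / thin ~1 mm / thick ~3 mm).  Each subject
is a union of 11 ellipsoids (head, torso, pelvis, two-segment arms and
legs) whose total volume — and therefore weight, via a configurable
density — is known in closed form:

* primitive pairs that are allowed to overlap (upper/lower limb
  segments) share semi-axes and orientation, so an affine map turns both
  into unit spheres and the intersection is an exact sphere-sphere lens;
* every other pair is kept disjoint by construction and certified by a
  separating-slab test on the ellipsoids' support functions;
* pose changes (limb spread, whole-body roll into lateral positions,
  shifts on the bed) are rigid motions and leave the volume untouched.

Scenes are rendered with a top-view pinhole camera: the bed plane,
floor and body are ray-traced analytically (z-buffer of nearest hits),
while the blanket is a draped height field — morphological closing
bridges concavities (creating the hollow space a real blanket leaves
over a body), Gaussian smoothing rounds the drape, and the cover
thickness is added on top.  Covered and uncovered renders of a pair
differ only where the blanket lies; optional Gaussian depth noise is
applied last and shared within a pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .depth_io import CameraIntrinsics, DepthFrame, PointCloud, depth_to_cloud

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "Ellipsoid",
    "BodySpec",
    "SceneParams",
    "PairedSample",
    "sample_body",
    "render_depth",
    "body_height_field",
    "drape_blanket",
    "generate_dataset",
    "write_dataset",
]


class ConfigurationError(ValueError):
    """Invalid scene or distribution parameters."""


class GenerationError(RuntimeError):
    """A sampled scene violates a geometric invariant."""


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    """An ellipsoid in bed coordinates (x across, y along, z up from bed).

    ``rotation`` maps the principal frame into bed coordinates; points p
    are inside iff ``(p-c)^T M^{-1} (p-c) <= 1`` with
    ``M = R diag(a^2, b^2, c^2) R^T``.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=np.float64).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        if np.any(self.semi_axes <= 0):
            raise ConfigurationError(f"semi-axes must be positive, got {self.semi_axes}")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return float(4.0 / 3.0 * np.pi * a * b * c)

    @property
    def shape_matrix(self) -> np.ndarray:
        d2 = np.diag(self.semi_axes**2)
        return self.rotation @ d2 @ self.rotation.T

    def support(self, u: np.ndarray) -> float:
        """Support radius along unit direction u: max of u.(p - c) over the surface."""
        return float(np.sqrt(u @ self.shape_matrix @ u))

    def rotated(self, rot: np.ndarray, pivot: np.ndarray) -> "Ellipsoid":
        """Rigidly rotate about a pivot point (an isometry)."""
        pivot = np.asarray(pivot, dtype=np.float64)
        return Ellipsoid(rot @ (self.center - pivot) + pivot, self.semi_axes.copy(), rot @ self.rotation)

    def translated(self, t: np.ndarray) -> "Ellipsoid":
        return Ellipsoid(self.center + np.asarray(t, dtype=np.float64), self.semi_axes.copy(), self.rotation.copy())

    def lowest_z(self) -> float:
        return float(self.center[2] - np.sqrt(self.shape_matrix[2, 2]))


def lens_overlap_volume(e1: Ellipsoid, e2: Ellipsoid) -> float:
    """Exact intersection volume of two equal-shape, co-oriented ellipsoids.

    The affine map to the common principal frame turns both into unit
    spheres; the intersection is a sphere-sphere lens whose volume maps
    back with the Jacobian a*b*c.
    """
    if not np.allclose(e1.semi_axes, e2.semi_axes, rtol=0, atol=1e-12):
        raise ConfigurationError("analytic overlap requires equal semi-axes")
    if not np.allclose(e1.rotation, e2.rotation, rtol=0, atol=1e-9):
        raise ConfigurationError("analytic overlap requires equal orientation")
    delta_unit = (e1.rotation.T @ (e2.center - e1.center)) / e1.semi_axes
    d = float(np.linalg.norm(delta_unit))
    if d >= 2.0:
        return 0.0
    h = 1.0 - d / 2.0  # cap height on a unit sphere
    lens_unit = 2.0 * np.pi * h * h * (3.0 - h) / 3.0
    return float(lens_unit * np.prod(e1.semi_axes))


def _certify_disjoint(e1: Ellipsoid, e2: Ellipsoid) -> bool:
    """Sufficient separating-slab test: a direction u with
    u.(c2 - c1) > h1(u) + h2(u) proves the ellipsoids do not intersect."""
    dc = e2.center - e1.center
    candidates = [dc, np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])]
    candidates += [e1.rotation[:, k] for k in range(3)]
    candidates += [e2.rotation[:, k] for k in range(3)]
    for u in candidates:
        norm = np.linalg.norm(u)
        if norm < 1e-12:
            continue
        u = u / norm
        if abs(u @ dc) > e1.support(u) + e2.support(u) + 1e-12:
            return True
    return False


@dataclass
class BodySpec:
    """A synthetic subject: primitives, pose, density, and exact weight.

    ``overlap_pairs`` indexes the primitive pairs that intentionally
    overlap (limb joints); all other pairs are disjoint, so the analytic
    volume is inclusion-exclusion truncated at pairwise terms — which is
    exact here, not an approximation.
    """

    primitives: list[Ellipsoid]
    overlap_pairs: list[tuple[int, int]]
    pose: str  # supine | lateral-left | lateral-right
    pose_params: dict
    density: float
    weight: float
    subject_id: int = 0

    def analytic_volume(self) -> float:
        vol = sum(e.volume for e in self.primitives)
        vol -= sum(lens_overlap_volume(self.primitives[i], self.primitives[j]) for i, j in self.overlap_pairs)
        return float(vol)

    def validate(self) -> None:
        overlap_set = {tuple(sorted(p)) for p in self.overlap_pairs}
        n = len(self.primitives)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in overlap_set:
                    continue
                if not _certify_disjoint(self.primitives[i], self.primitives[j]):
                    raise GenerationError(f"primitives {i} and {j} could not be certified disjoint")
        if any(e.lowest_z() < -1e-9 for e in self.primitives):
            raise GenerationError("a primitive extends below the bed plane")
        if not np.isclose(self.weight, self.density * self.analytic_volume(), rtol=1e-9):
            raise GenerationError("stored weight disagrees with the analytic volume")


# ---------------------------------------------------------------------------
# Scene parameters
# ---------------------------------------------------------------------------

@dataclass
class SceneParams:
    """Everything that determines a generated dataset (given a seed).

    Lengths in meters.  The camera looks straight down at the bed from
    ``camera_height`` above the bed surface; image rows run along the
    bed (y), columns across it (x).
    """

    bed_extent: tuple[float, float] = (1.2, 2.2)  # (width x, length y)
    bed_height: float = 0.6  # bed surface above the floor
    camera_height: float = 2.2  # camera above the bed surface
    image_shape: tuple[int, int] = (160, 128)  # (rows, cols)
    intrinsics: CameraIntrinsics = field(default_factory=lambda: CameraIntrinsics(140.0, 140.0, 63.5, 79.5))
    blanket_thickness: float = 0.003
    thin_thickness: float = 0.001
    thick_thickness: float = 0.003
    blanket_coverage: float = 0.75  # fraction of bed length, from the foot end
    closing_radius: float = 0.08
    smoothing_sigma: float = 0.03
    heightfield_step: float = 0.01
    depth_noise_std: float = 0.005
    # body-size distribution
    weight_mean: float = 68.0
    weight_std: float = 12.7
    weight_range: tuple[float, float] = (45.0, 104.0)
    length_std: float = 0.05
    length_range: tuple[float, float] = (0.88, 1.12)
    density: float = 1000.0
    p_lateral: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("bed_height", "camera_height", "heightfield_step", "density",
                     "weight_mean", "weight_std", "length_std", "thin_thickness", "thick_thickness"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.blanket_thickness <= 0:
            raise ConfigurationError("blanket thickness must be positive for covered renders")
        if not 0.0 <= self.blanket_coverage <= 1.0:
            raise ConfigurationError("blanket coverage must be in [0, 1]")
        if self.depth_noise_std < 0:
            raise ConfigurationError("depth noise std must be nonnegative")
        if not self.weight_range[0] < self.weight_range[1]:
            raise ConfigurationError("invalid weight range")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "intrinsics"}
        d["bed_extent"] = list(self.bed_extent)
        d["image_shape"] = list(self.image_shape)
        d["weight_range"] = list(self.weight_range)
        d["length_range"] = list(self.length_range)
        d["intrinsics"] = [self.intrinsics.fx, self.intrinsics.fy, self.intrinsics.cx, self.intrinsics.cy]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        fx, fy, cx, cy = d.pop("intrinsics")
        return cls(
            intrinsics=CameraIntrinsics(fx, fy, cx, cy),
            bed_extent=tuple(d.pop("bed_extent")),
            image_shape=tuple(d.pop("image_shape")),
            weight_range=tuple(d.pop("weight_range")),
            length_range=tuple(d.pop("length_range")),
            **d,
        )


# ---------------------------------------------------------------------------
# Body sampling
# ---------------------------------------------------------------------------

# Template proportions for a ~1.9 m reference body; all lengths scale with
# the sampled length factor (y) and girth factor (x, z).
_TEMPLATE_LENGTH = 1.90


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _template(g: float, l: float, folded_arms: bool = False) -> tuple[list[Ellipsoid], list[tuple[int, int]], dict]:
    """Axis-aligned supine template; x/z scale with girth g, y with length l.

    ``folded_arms`` places the arms on the chest instead of beside the
    torso — used for lateral poses, where a body rolled onto its side
    rests on the torso rather than on an outstretched arm.  Returns
    primitives, the designated overlapping (joint) pairs and the joint
    pivots used for limb-spread rotations.
    """
    S = np.array([g, l, g])

    def ell(cx, cy, cz, ax, ay, az):
        return Ellipsoid(np.array([cx, cy, cz]) * S, np.array([ax, ay, az]) * S)

    prims = [
        ell(0.0, 0.11, 0.100, 0.085, 0.110, 0.095),   # 0 head
        ell(0.0, 0.56, 0.105, 0.155, 0.320, 0.100),   # 1 torso
        ell(0.0, 1.02, 0.100, 0.160, 0.120, 0.100),   # 2 pelvis
    ]
    arm = dict(ax=0.042, ay=0.145, az=0.042)
    arm_x, arm_z = (0.100, 0.255) if folded_arms else (0.245, 0.080)
    for side in (-1.0, 1.0):
        x = side * arm_x
        prims.append(ell(x, 0.40, arm_z, **arm))      # 3/5 upper arm (L/R)
        prims.append(ell(x, 0.66, arm_z, **arm))      # 4/6 forearm
    leg = dict(ax=0.068, ay=0.200, az=0.068)
    for side in (-1.0, 1.0):
        x = side * 0.090
        prims.append(ell(x, 1.36, 0.085, **leg))      # 7/9 thigh (L/R)
        prims.append(ell(x, 1.70, 0.085, **leg))      # 8/10 shank
    pairs = [(3, 4), (5, 6), (7, 8), (9, 10)]
    pivots = {
        "shoulder_left": np.array([-arm_x, 0.26, arm_z]) * S,
        "shoulder_right": np.array([arm_x, 0.26, arm_z]) * S,
        "hip_left": np.array([-0.090, 1.16, 0.085]) * S,
        "hip_right": np.array([0.090, 1.16, 0.085]) * S,
    }
    return prims, pairs, pivots


def base_weight(density: float = 1000.0) -> float:
    """Analytic weight of the unscaled template at the given density."""
    prims, pairs, _ = _template(1.0, 1.0)
    body = BodySpec(prims, pairs, "supine", {}, density, 0.0)
    return density * body.analytic_volume()


def _truncated_normal(rng: np.random.Generator, mean: float, std: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, std)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_body(rng: np.random.Generator, params: SceneParams, subject_id: int = 0) -> BodySpec:
    """Draw a subject with an exactly known weight and a random pose.

    The target weight is drawn from a truncated normal matching the
    configured mean/std and range; the girth factor is then solved so
    the analytic weight equals the target exactly (volume scales as
    girth^2 x length).  Pose = limb spread + optional lateral roll +
    a small shift on the bed, all rigid motions.
    """
    if params.weight_std <= 0 or params.length_std <= 0:
        raise ConfigurationError("distribution scales must be positive")
    w_target = _truncated_normal(rng, params.weight_mean, params.weight_std, *params.weight_range)
    l = _truncated_normal(rng, 1.0, params.length_std, *params.length_range)
    w0 = base_weight(params.density)
    g = float(np.sqrt(w_target / (w0 * l)))

    lateral = rng.uniform() < params.p_lateral
    prims, pairs, pivots = _template(g, l, folded_arms=lateral)

    # limb spread: rotate whole limbs (both segments rigidly) about the
    # vertical axis through the joint; rigid => volume preserved.
    # folded arms get only a small swing so they stay over the chest
    arm_max = 5.0 if lateral else 16.0
    arm_l = rng.uniform(np.deg2rad(1), np.deg2rad(arm_max))
    arm_r = rng.uniform(np.deg2rad(1), np.deg2rad(arm_max))
    leg_l = rng.uniform(0.0, np.deg2rad(8))
    leg_r = rng.uniform(0.0, np.deg2rad(8))
    for idx, ang, pivot in (
        ((3, 4), +arm_l, pivots["shoulder_left"]),
        ((5, 6), -arm_r, pivots["shoulder_right"]),
        ((7, 8), +leg_l, pivots["hip_left"]),
        ((9, 10), -leg_r, pivots["hip_right"]),
    ):
        rot = _rot_z(ang)
        for i in idx:
            prims[i] = prims[i].rotated(rot, pivot)

    # position: supine or a lateral roll about the body's long axis
    roll = 0.0
    if lateral:
        side = "lateral-left" if rng.uniform() < 0.5 else "lateral-right"
        roll = rng.uniform(np.deg2rad(55), np.deg2rad(90))
        if side == "lateral-right":
            roll = -roll
        axis_point = np.array([0.0, 0.0, 0.10 * g])
        rot = _rot_y(roll)
        prims = [e.rotated(rot, axis_point) for e in prims]
        pose = side
    else:
        pose = "supine"

    # rest the body on the bed plane and center it on the bed
    body_len = _TEMPLATE_LENGTH * l
    min_z = min(e.lowest_z() for e in prims)
    dy = -body_len / 2.0 + rng.uniform(-0.04, 0.04)
    dx = rng.uniform(-0.04, 0.04)
    shift = np.array([dx, dy, 0.005 - min_z])
    prims = [e.translated(shift) for e in prims]

    body = BodySpec(
        primitives=prims,
        overlap_pairs=pairs,
        pose=pose,
        pose_params={
            "arm_spread": [arm_l, arm_r],
            "leg_spread": [leg_l, leg_r],
            "roll": roll,
            "shift": [dx, dy],
            "girth": g,
            "length": l,
        },
        density=params.density,
        weight=w_target,
        subject_id=subject_id,
    )
    body.validate()
    return body


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _pixel_dirs(params: SceneParams) -> np.ndarray:
    """Unnormalized ray directions (dx, dy, 1) for every pixel, flattened."""
    K = params.intrinsics
    rows, cols = params.image_shape
    v, u = np.mgrid[0:rows, 0:cols]
    dx = (u - K.cx) / K.fx
    dy = (v - K.cy) / K.fy
    return np.stack([dx.ravel(), dy.ravel(), np.ones(rows * cols)], axis=1)


def _scene_depth(body: BodySpec, params: SceneParams) -> np.ndarray:
    """Z-buffer depth of bed + floor + body (no blanket), per pixel."""
    H = params.camera_height
    dirs = _pixel_dirs(params)
    # bed plane at depth H inside the bed rectangle, floor elsewhere
    bx, by = dirs[:, 0] * H, dirs[:, 1] * H
    on_bed = (np.abs(bx) <= params.bed_extent[0] / 2) & (np.abs(by) <= params.bed_extent[1] / 2)
    depth = np.where(on_bed, H, H + params.bed_height)

    # ray-ellipsoid intersections in the camera frame
    S = np.diag([1.0, 1.0, -1.0])  # bed frame (z up) -> camera frame (z down)
    for e in body.primitives:
        c_cam = np.array([e.center[0], e.center[1], H - e.center[2]])
        M_cam = S @ e.shape_matrix @ S
        A = np.linalg.inv(M_cam)
        a = np.einsum("ij,jk,ik->i", dirs, A, dirs)
        Ac = A @ c_cam
        b = -2.0 * dirs @ Ac
        c0 = float(c_cam @ Ac) - 1.0
        disc = b * b - 4.0 * a * c0
        hit = disc >= 0
        t = np.full(len(dirs), np.inf)
        sq = np.sqrt(np.clip(disc, 0, None))
        t_near = (-b - sq) / (2.0 * a)
        t[hit & (t_near > 0)] = t_near[hit & (t_near > 0)]
        depth = np.minimum(depth, t)  # dz = 1, so depth along z equals t
    return depth.reshape(params.image_shape)


def body_height_field(body: BodySpec, params: SceneParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-surface elevation of the body over the bed, on a regular grid.

    Returns ``(heights, x_nodes, y_nodes)``; heights are 0 where only
    the bed is present.  Evaluated analytically from vertical-line /
    ellipsoid intersections.
    """
    step = params.heightfield_step
    hx = params.bed_extent[0] / 2.0
    hy = params.bed_extent[1] / 2.0
    x_nodes = np.arange(-hx, hx + step / 2, step)
    y_nodes = np.arange(-hy, hy + step / 2, step)
    X, Y = np.meshgrid(x_nodes, y_nodes, indexing="ij")
    h = np.zeros_like(X)
    for e in body.primitives:
        A = np.linalg.inv(e.shape_matrix)
        px, py = X - e.center[0], Y - e.center[1]
        # (q + z ez)^T A (q + z ez) = 1 with q = (px, py, -cz)
        a = A[2, 2]
        b = 2.0 * (A[0, 2] * px + A[1, 2] * py) - 2.0 * a * e.center[2]
        qx, qy, qz = px, py, -e.center[2]
        c = (A[0, 0] * qx * qx + A[1, 1] * qy * qy + A[2, 2] * qz * qz
             + 2 * A[0, 1] * qx * qy + 2 * A[0, 2] * qx * qz + 2 * A[1, 2] * qy * qz - 1.0)
        disc = b * b - 4 * a * c
        hit = disc > 0
        z_top = np.where(hit, (-b + np.sqrt(np.clip(disc, 0, None))) / (2 * a), 0.0)
        h = np.maximum(h, np.where(hit, z_top, 0.0))
    return h, x_nodes, y_nodes


def drape_blanket(height_field: np.ndarray, params: SceneParams,
                  thickness: float | None = None,
                  y_nodes: np.ndarray | None = None) -> np.ndarray:
    """Drape a blanket over a body height field.

    Inside the coverage region (a bed-length fraction measured from the
    foot end) the cover is ``max(smooth(close(h)), h) + thickness``: the
    morphological closing (disk footprint) bridges concavities — the
    hollow space under a real blanket — Gaussian smoothing rounds the
    drape outward, and the elementwise max with the closed field
    guarantees the cover never sags below the bridged surface (and so
    never below the body).  Outside the region the field is unchanged.
    """
    h = np.asarray(height_field, dtype=np.float64)
    t = params.blanket_thickness if thickness is None else thickness
    if t <= 0:
        raise ConfigurationError("blanket thickness must be positive")
    if params.blanket_coverage <= 0:
        return h.copy()
    step = params.heightfield_step
    if y_nodes is None:
        hy = params.bed_extent[1] / 2.0
        y_nodes = np.arange(-hy, hy + step / 2, step)
        if len(y_nodes) != h.shape[1]:  # pragma: no cover - shape guard
            y_nodes = np.linspace(-hy, hy, h.shape[1])

    r_px = max(1, int(round(params.closing_radius / step)))
    yy, xx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    disk = (xx * xx + yy * yy) <= r_px * r_px
    closed = ndimage.grey_closing(h, footprint=disk, mode="nearest")
    smooth = ndimage.gaussian_filter(closed, sigma=params.smoothing_sigma / step, mode="nearest")
    covered = np.maximum(smooth, closed) + t

    y_min = params.bed_extent[1] / 2.0 - params.blanket_coverage * params.bed_extent[1]
    region = y_nodes >= y_min  # along the second axis (y)
    out = h.copy()
    out[:, region] = covered[:, region]
    return out


def _blanket_depth(body: BodySpec, params: SceneParams, thickness: float) -> np.ndarray:
    """Per-pixel depth of the draped blanket surface (inf where absent).

    The blanket is a single-valued height field; each pixel ray is
    marched downward in height with bilinear field sampling and the
    crossing is refined by linear interpolation.
    """
    h_body, x_nodes, y_nodes = body_height_field(body, params)
    h_cov = drape_blanket(h_body, params, thickness=thickness, y_nodes=y_nodes)
    y_min = params.bed_extent[1] / 2.0 - params.blanket_coverage * params.bed_extent[1]

    # field to march against: blanket height inside the region, else "absent"
    field = np.where(y_nodes[None, :] >= y_min, h_cov, -1.0)
    H = params.camera_height
    step = params.heightfield_step
    dirs = _pixel_dirs(params)
    dxy = dirs[:, :2]

    def sample(px: np.ndarray, py: np.ndarray) -> np.ndarray:
        ix = (px - x_nodes[0]) / step
        iy = (py - y_nodes[0]) / step
        inside = (ix >= 0) & (ix <= len(x_nodes) - 1) & (iy >= 0) & (iy <= len(y_nodes) - 1)
        ix = np.clip(ix, 0, len(x_nodes) - 1 - 1e-9)
        iy = np.clip(iy, 0, len(y_nodes) - 1 - 1e-9)
        i0, j0 = ix.astype(int), iy.astype(int)
        fx_, fy_ = ix - i0, iy - j0
        f = (field[i0, j0] * (1 - fx_) * (1 - fy_) + field[i0 + 1, j0] * fx_ * (1 - fy_)
             + field[i0, j0 + 1] * (1 - fx_) * fy_ + field[i0 + 1, j0 + 1] * fx_ * fy_)
        return np.where(inside, f, -1.0)

    z_top = float(h_cov.max()) + step
    n_steps = int(np.ceil(z_top / step)) + 1
    zs = np.linspace(z_top, 0.0, n_steps)

    depth = np.full(len(dirs), np.inf)
    prev_f = None
    prev_z = zs[0]
    for z in zs:
        pxy = dxy * (H - z)
        f = sample(pxy[:, 0], pxy[:, 1]) - z
        if prev_f is not None:
            cross = (prev_f < 0) & (f >= 0) & np.isinf(depth)
            if np.any(cross):
                frac = prev_f[cross] / (prev_f[cross] - f[cross])
                z_star = prev_z + frac * (z - prev_z)
                depth[cross] = H - z_star
        prev_f, prev_z = f, z
    return depth.reshape(params.image_shape)


def render_depth(body: BodySpec, params: SceneParams, covered: bool = False,
                 thickness: float | None = None,
                 noise: np.ndarray | None = None) -> DepthFrame:
    """Z-buffer render of the scene from the top-view pinhole camera.

    ``covered=True`` drapes a blanket of the given thickness over the
    body; covered and uncovered renders of the same body are identical
    outside the blanket's coverage region.  ``noise`` (same shape as the
    image) is added last, so paired frames can share one noise field.
    """
    apex = max(e.center[2] + np.sqrt(e.shape_matrix[2, 2]) for e in body.primitives)
    if apex >= params.camera_height:
        raise GenerationError("body apex reaches the camera plane (outside the frustum)")
    half_x = params.bed_extent[0] / 2.0 + 0.3
    if any(abs(e.center[0]) > half_x for e in body.primitives):
        raise GenerationError("body extends far outside the bed area")

    depth = _scene_depth(body, params)
    if covered:
        t = params.blanket_thickness if thickness is None else thickness
        depth = np.minimum(depth, _blanket_depth(body, params, t))
    if noise is not None:
        depth = depth + noise
    return DepthFrame(depths=np.maximum(depth, 1e-6), intrinsics=params.intrinsics)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """A training-set element: covered and uncovered clouds of one subject
    in one pose, plus the exact ground-truth weight."""

    covered: PointCloud
    uncovered: PointCloud
    weight: float
    meta: dict
    covered_frame: DepthFrame | None = None
    uncovered_frame: DepthFrame | None = None


def generate_dataset(n: int, params: SceneParams, keep_frames: bool = False,
                     progress: bool = False) -> list[PairedSample]:
    """Generate ``n`` paired covered/uncovered samples (one subject each).

    Fully determined by ``params.seed``: sample i uses the stream seeded
    by ``(seed, i)``, so prefixes of datasets with equal parameters
    coincide.  Both frames of a pair share one depth-noise field, so
    they differ exactly and only where the blanket lies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples: list[PairedSample] = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, i]))
        body = sample_body(rng, params, subject_id=i)
        cover = "thin" if rng.uniform() < 0.5 else "thick"
        t = params.thin_thickness if cover == "thin" else params.thick_thickness
        noise = None
        if params.depth_noise_std > 0:
            noise = rng.normal(0.0, params.depth_noise_std, size=params.image_shape)
        f_unc = render_depth(body, params, covered=False, noise=noise)
        f_cov = render_depth(body, params, covered=True, thickness=t, noise=noise)
        position = "supine" if body.pose == "supine" else "lateral"
        meta = {
            "subject_id": i,
            "pose": body.pose,
            "position": position,
            "cover": cover,
            "weight_kg": body.weight,
            "intrinsics": [params.intrinsics.fx, params.intrinsics.fy,
                           params.intrinsics.cx, params.intrinsics.cy],
        }
        samples.append(
            PairedSample(
                covered=depth_to_cloud(f_cov, metadata={**meta, "frame": "covered"}),
                uncovered=depth_to_cloud(f_unc, metadata={**meta, "frame": "uncovered", "cover": "none"}),
                weight=body.weight,
                meta=meta,
                covered_frame=f_cov if keep_frames else None,
                uncovered_frame=f_unc if keep_frames else None,
            )
        )
        if progress and (i + 1) % 25 == 0:  # pragma: no cover - cosmetic
            print(f"  generated {i + 1}/{n} scenes")
    return samples


def write_dataset(samples: list[PairedSample], out_dir, params: SceneParams) -> dict:
    """Write PNG depth maps, PLY clouds, a JSON manifest and YAML params.

    Returns the manifest dict.  Requires samples generated with
    ``keep_frames=True`` for the PNG outputs.
    """
    from pathlib import Path

    import yaml

    from .depth_io import save_depth_png, save_ply

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"params_seed": params.seed, "samples": []}
    for s in samples:
        sid = s.meta["subject_id"]
        stem = f"subject{sid:04d}"
        if s.covered_frame is not None:
            save_depth_png(s.covered_frame, out / f"{stem}_covered.png")
            save_depth_png(s.uncovered_frame, out / f"{stem}_uncovered.png")
        save_ply(s.covered, out / f"{stem}_covered.ply")
        save_ply(s.uncovered, out / f"{stem}_uncovered.ply")
        manifest["samples"].append(dict(s.meta))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "scene_params.yaml", "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
    return manifest
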