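"""Preprocessing chain: pinhole back-projection, bed isolation, plane
segmentation and mean-centering, plus the PNG/PLY readers and writers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedweight.depth_io import (
    CameraIntrinsics,
    DepthFrame,
    EmptySceneError,
    PointCloud,
    SegmentationError,
    depth_to_cloud,
    extract_bed_region,
    fit_plane_ransac,
    load_depth_png,
    load_ply,
    mean_center,
    save_depth_png,
    save_ply,
    segment_patient_from_bed,
)

K = CameraIntrinsics(fx=100.0, fy=100.0, cx=4.0, cy=3.0)


def frame_of(depths):
    return DepthFrame(depths=np.asarray(depths, dtype=float), intrinsics=K)


def test_principal_point_back_projects_on_axis():
    depths = np.zeros((8, 10))
    depths[3, 4] = 2.0  # pixel exactly at (cy, cx)
    cloud = depth_to_cloud(frame_of(depths))
    assert len(cloud) == 1
    assert np.allclose(cloud.points[0], [0.0, 0.0, 2.0])


def test_pinhole_formula_one_focal_length_off_axis():
    depths = np.zeros((8, 200))
    depths[3, 104] = 1.0  # u = cx + fx
    cloud = depth_to_cloud(DepthFrame(depths, CameraIntrinsics(100.0, 100.0, 4.0, 3.0)))
    assert np.allclose(cloud.points[0], [1.0, 0.0, 1.0])


def test_invalid_pixels_emit_no_points():
    depths = np.array([[0.0, 1.0], [np.nan, 2.0]])
    cloud = depth_to_cloud(frame_of(depths))
    assert len(cloud) == 2
    all_invalid = depth_to_cloud(frame_of(np.zeros((4, 4))))
    assert len(all_invalid) == 0  # warning case, not an error


def test_round_trip_reprojection_reproduces_depths():
    rng = np.random.default_rng(0)
    depths = rng.uniform(1.0, 3.0, size=(8, 10))
    cloud = depth_to_cloud(frame_of(depths))
    u = cloud.points[:, 0] * K.fx / cloud.points[:, 2] + K.cx
    v = cloud.points[:, 1] * K.fy / cloud.points[:, 2] + K.cy
    assert np.allclose(u, cloud.pixels[:, 1], atol=1e-6)
    assert np.allclose(v, cloud.pixels[:, 0], atol=1e-6)
    assert np.allclose(cloud.points[:, 2], depths[cloud.pixels[:, 0], cloud.pixels[:, 1]], atol=1e-6)


def test_extract_bed_region_removes_floor_and_keeps_largest_cluster():
    depths = np.full((20, 20), 2.8)  # floor
    depths[2:12, 2:12] = 2.0  # bed region (100 px)
    depths[16:18, 16:18] = 2.05  # small spurious cluster (4 px)
    cloud = depth_to_cloud(frame_of(depths))
    bed = extract_bed_region(cloud, (1.5, 2.2), min_cluster_size=10)
    assert len(bed) == 100
    assert np.all(bed.points[:, 2] <= 2.2)
    assert len(extract_bed_region(bed, (1.5, 2.2), min_cluster_size=10)) == len(bed)  # idempotent


def test_extract_bed_region_error_cases():
    with pytest.raises(EmptySceneError):
        extract_bed_region(PointCloud(np.empty((0, 3))), (1.0, 2.0))
    depths = np.full((5, 5), 2.8)
    cloud = depth_to_cloud(frame_of(depths))
    with pytest.raises(EmptySceneError):
        extract_bed_region(cloud, (1.0, 2.0))  # nothing in band
    with pytest.raises(ValueError):
        extract_bed_region(cloud, (2.0, 1.0))  # empty interval


def test_extract_bed_region_spatial_fallback_without_pixels():
    rng = np.random.default_rng(1)
    blob_a = rng.normal([0, 0, 2.0], 0.01, size=(80, 3))
    blob_b = rng.normal([1.5, 0, 2.0], 0.01, size=(10, 3))
    cloud = PointCloud(np.vstack([blob_a, blob_b]))
    kept = extract_bed_region(cloud, (1.5, 2.5), min_cluster_size=20)
    assert len(kept) == 80


def test_segment_patient_keeps_exactly_off_plane_points():
    rng = np.random.default_rng(2)
    plane = np.column_stack([rng.uniform(-1, 1, 600), rng.uniform(-1, 1, 600), np.full(600, 2.0)])
    box = np.column_stack([rng.uniform(-0.2, 0.2, 120), rng.uniform(-0.2, 0.2, 120), np.full(120, 1.9)])
    cloud = PointCloud(np.vstack([plane, box]))
    patient = segment_patient_from_bed(cloud, tolerance=0.02, seed=0)
    assert len(patient) == 120
    assert np.all(patient.points[:, 2] < 1.95)


def test_segment_patient_removes_points_below_plane():
    rng = np.random.default_rng(3)
    plane = np.column_stack([rng.uniform(-1, 1, 600), rng.uniform(-1, 1, 600), np.full(600, 2.0)])
    below = np.column_stack([rng.uniform(-0.2, 0.2, 50), rng.uniform(-0.2, 0.2, 50), np.full(50, 2.3)])
    cloud = PointCloud(np.vstack([plane, below]))
    patient = segment_patient_from_bed(cloud, tolerance=0.02, seed=0)
    assert len(patient) == 0  # pure plane plus sub-plane outliers -> nothing above


def test_segment_patient_fails_on_nonplanar_blob():
    rng = np.random.default_rng(4)
    blob = rng.normal(0.0, 0.3, size=(300, 3)) + [0, 0, 2.0]
    with pytest.raises(SegmentationError):
        segment_patient_from_bed(PointCloud(blob), tolerance=0.02, seed=0)


def test_fit_plane_is_seeded_and_oriented():
    rng = np.random.default_rng(5)
    pts = np.column_stack([rng.uniform(-1, 1, 500), rng.uniform(-1, 1, 500),
                           2.0 + rng.normal(0, 0.003, 500)])
    n1, d1 = fit_plane_ransac(pts, seed=9)
    n2, d2 = fit_plane_ransac(pts, seed=9)
    assert np.array_equal(n1, n2) and d1 == d2
    assert d1 < 0  # normal oriented toward the camera origin
    assert abs(abs(n1[2]) - 1.0) < 1e-3


def test_mean_center_examples_and_isometry():
    cloud = PointCloud([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    centered = mean_center(cloud)
    assert np.allclose(centered.points, [[-1, 0, 0], [1, 0, 0]])
    assert np.linalg.norm(centered.points.mean(axis=0)) < 1e-9
    again = mean_center(centered)
    assert np.allclose(again.points, centered.points)  # idempotent
    with pytest.raises(ValueError):
        mean_center(PointCloud(np.empty((0, 3))))


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**31 - 1))
def test_mean_center_preserves_pairwise_distances(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(12, 3)) * 3.0
    centered = mean_center(PointCloud(pts))
    d_before = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d_after = np.linalg.norm(centered.points[:, None] - centered.points[None, :], axis=-1)
    assert np.abs(d_before - d_after).max() < 1e-9


def test_subset_operations_create_no_points():
    depths = np.full((10, 10), 2.0)
    cloud = depth_to_cloud(frame_of(depths))
    bed = extract_bed_region(cloud, (1.5, 2.5), min_cluster_size=5)
    as_set = {tuple(p) for p in cloud.points}
    assert all(tuple(p) in as_set for p in bed.points)


def test_depth_png_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    depths = rng.uniform(1.0, 3.0, size=(6, 7))
    frame = frame_of(depths)
    path = tmp_path / "depth.png"
    save_depth_png(frame, path)
    loaded = load_depth_png(path, K)
    assert np.abs(loaded.depths - depths).max() <= 0.0005 + 1e-9  # mm quantization


def test_ply_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(40, 3))
    path = tmp_path / "cloud.ply"
    save_ply(PointCloud(pts), path)
    loaded = load_ply(path)
    assert np.allclose(np.sort(loaded.points, axis=0), np.sort(pts, axis=0), atol=1e-6)
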