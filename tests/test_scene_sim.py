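"""Scene simulator: analytic weights, rendering geometry, blanket drape
and dataset determinism."""

import numpy as np
import pytest

from bedweight.depth_io import CameraIntrinsics
from bedweight.scene_sim import (
    BodySpec,
    ConfigurationError,
    Ellipsoid,
    SceneParams,
    body_height_field,
    drape_blanket,
    generate_dataset,
    lens_overlap_volume,
    render_depth,
    sample_body,
)


@pytest.fixture(scope="module")
def params():
    return SceneParams(seed=123, depth_noise_std=0.0)


def test_single_ellipsoid_weight_is_closed_form():
    e = Ellipsoid([0.0, 0.0, 0.2], [0.2, 0.6, 0.12])
    body = BodySpec([e], [], "supine", {}, density=1000.0, weight=0.0)
    expected = 4.0 / 3.0 * np.pi * 0.2 * 0.6 * 0.12 * 1000.0
    assert body.density * body.analytic_volume() == pytest.approx(expected, rel=1e-12)


def test_doubling_semi_axes_scales_weight_eightfold():
    e1 = Ellipsoid([0, 0, 1], [0.1, 0.2, 0.1])
    e2 = Ellipsoid([0, 0, 1], [0.2, 0.4, 0.2])
    b1 = BodySpec([e1], [], "supine", {}, 1000.0, 0.0)
    b2 = BodySpec([e2], [], "supine", {}, 1000.0, 0.0)
    assert b2.analytic_volume() == pytest.approx(8 * b1.analytic_volume(), rel=1e-12)


def test_lens_overlap_matches_numeric_integration():
    # co-oriented equal ellipsoids overlapping along y: compare the
    # analytic lens volume with a dense-grid indicator integration
    a = Ellipsoid([0.0, 0.0, 0.0], [0.05, 0.15, 0.05])
    b = Ellipsoid([0.0, 0.24, 0.0], [0.05, 0.15, 0.05])
    analytic = lens_overlap_volume(a, b)
    assert analytic > 0
    step = 0.002
    xs = np.arange(-0.06, 0.06, step)
    ys = np.arange(0.05, 0.20, step)
    zs = np.arange(-0.06, 0.06, step)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    in_a = (X / 0.05) ** 2 + (Y / 0.15) ** 2 + (Z / 0.05) ** 2 <= 1
    in_b = (X / 0.05) ** 2 + ((Y - 0.24) / 0.15) ** 2 + (Z / 0.05) ** 2 <= 1
    numeric = (in_a & in_b).sum() * step**3
    assert analytic == pytest.approx(numeric, rel=0.02)
    far = Ellipsoid([0.0, 1.0, 0.0], [0.05, 0.15, 0.05])
    assert lens_overlap_volume(a, far) == 0.0


def test_sampled_weight_equals_density_times_analytic_volume(params):
    rng = np.random.default_rng(0)
    for i in range(20):
        body = sample_body(rng, params, i)
        assert body.weight == pytest.approx(body.density * body.analytic_volume(), rel=1e-9)
        assert all(e.lowest_z() >= -1e-9 for e in body.primitives)


def test_sampled_weight_against_voxel_integration_oracle(params):
    # independent check of the analytic volume: dense-grid indicator sum
    body = sample_body(np.random.default_rng(5), params, 0)
    step = 0.004
    lo = np.min([e.center - e.semi_axes.max() for e in body.primitives], axis=0) - 0.01
    hi = np.max([e.center + e.semi_axes.max() for e in body.primitives], axis=0) + 0.01
    xs, ys, zs = (np.arange(l, h, step) for l, h in zip(lo, hi))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    inside = np.zeros(X.shape, dtype=bool)
    for e in body.primitives:
        A = np.linalg.inv(e.shape_matrix)
        d = pts - e.center
        inside |= np.einsum("...i,ij,...j->...", d, A, d) <= 1.0
    numeric = inside.sum() * step**3 * body.density
    assert body.weight == pytest.approx(numeric, rel=0.02)


def test_thousand_sampled_weights_stay_in_configured_range(params):
    rng = np.random.default_rng(1)
    weights = np.array([sample_body(rng, params, i).weight for i in range(1000)])
    assert weights.min() >= 43.7
    assert weights.max() <= 105.1
    assert weights.std() >= 10.0


def test_invalid_distribution_parameters_rejected():
    with pytest.raises(ConfigurationError):
        SceneParams(weight_std=-1.0)
    with pytest.raises(ConfigurationError):
        SceneParams(depth_noise_std=-0.1)
    with pytest.raises(ConfigurationError):
        SceneParams(blanket_coverage=1.5)


def test_flat_scene_depth_equals_camera_height(params):
    # a body far off to the side leaves the bed pixels at exactly H
    body = BodySpec([Ellipsoid([5.0, 0.0, 0.1], [0.05, 0.05, 0.05])], [], "supine", {}, 1000.0, 0.0)
    with pytest.raises(Exception):
        render_depth(body, params)  # far outside the bed -> generation error
    near = BodySpec([Ellipsoid([0.0, 0.0, 0.1], [0.05, 0.05, 0.05])], [], "supine", {}, 1000.0, 0.0)
    frame = render_depth(near, params)
    K, H = params.intrinsics, params.camera_height
    corner = frame.depths[0, 0]
    assert corner in (pytest.approx(H, abs=1e-9), pytest.approx(H + params.bed_height, abs=1e-9))
    # most bed pixels sit exactly at H
    assert (np.abs(frame.depths - H) < 1e-9).sum() > 5000


def test_apex_depth_matches_ray_intersection(params):
    # sphere apex directly under the principal point: the central ray is
    # vertical, so depth = H - (apex height) exactly
    r, cz = 0.11, 0.13
    body = BodySpec([Ellipsoid([0.0, 0.0, cz], [r, r, r])], [], "supine", {}, 1000.0, 0.0)
    # principal point at integer pixel so one ray passes straight down
    p = SceneParams(seed=0, depth_noise_std=0.0,
                    intrinsics=CameraIntrinsics(140.0, 140.0, 64.0, 80.0))
    frame = render_depth(body, p)
    assert frame.depths[80, 64] == pytest.approx(p.camera_height - (cz + r), abs=1e-9)


def test_covered_equals_uncovered_outside_coverage_region(params):
    body = sample_body(np.random.default_rng(2), params, 0)
    unc = render_depth(body, params, covered=False)
    cov = render_depth(body, params, covered=True, thickness=0.003)
    diff = np.abs(unc.depths - cov.depths)
    K, H = params.intrinsics, params.camera_height
    v = np.arange(params.image_shape[0])
    y_bed = (v - K.cy) / K.fy * H
    y_min = params.bed_extent[1] / 2 - params.blanket_coverage * params.bed_extent[1]
    outside_rows = y_bed < y_min - 0.1  # margin for parallax of raised surfaces
    assert np.all(diff[outside_rows, :] == 0.0)
    assert diff.max() > 0  # and the blanket does change something


def test_covered_surface_never_below_uncovered(params):
    body = sample_body(np.random.default_rng(3), params, 0)
    unc = render_depth(body, params, covered=False)
    cov = render_depth(body, params, covered=True, thickness=0.003)
    assert np.all(cov.depths <= unc.depths + 1e-9)  # smaller depth = higher surface


def test_drape_constant_body_adds_thickness():
    p = SceneParams(seed=0, blanket_coverage=1.0)
    h = np.full((121, 221), 0.2)
    covered = drape_blanket(h, p, thickness=0.003)
    assert np.allclose(covered, 0.203, atol=1e-9)


def test_drape_bridges_narrow_gap():
    # two parallel ridges closer than the closing diameter: the drape
    # spans the hollow instead of falling into it
    p = SceneParams(seed=0, blanket_coverage=1.0)
    h = np.zeros((121, 221))
    h[50:55, :] = 0.3
    h[60:65, :] = 0.3  # 5 cm gap < 2 * closing radius (8 cm)
    covered = drape_blanket(h, p, thickness=0.003)
    assert covered[55:60, 100].min() >= 0.3  # hollow space created
    assert np.all(covered >= h + 0.003 - 1e-9)


def test_drape_zero_coverage_is_identity():
    p = SceneParams(seed=0, blanket_coverage=0.0)
    h = np.random.default_rng(0).uniform(0, 0.3, size=(121, 221))
    assert np.array_equal(drape_blanket(h, p, thickness=0.003), h)


def test_height_field_matches_primitive_tops(params):
    body = BodySpec([Ellipsoid([0.0, 0.0, 0.1], [0.1, 0.2, 0.1])], [], "supine", {}, 1000.0, 0.0)
    h, x_nodes, y_nodes = body_height_field(body, params)
    i = np.argmin(np.abs(x_nodes))
    j = np.argmin(np.abs(y_nodes))
    assert h[i, j] == pytest.approx(0.2, abs=1e-6)
    assert h.max() == pytest.approx(0.2, abs=1e-6)


def test_generate_dataset_is_seed_deterministic():
    p = SceneParams(seed=77)
    a = generate_dataset(2, p)
    b = generate_dataset(2, p)
    for s1, s2 in zip(a, b):
        assert np.array_equal(s1.covered.points, s2.covered.points)
        assert np.array_equal(s1.uncovered.points, s2.uncovered.points)
        assert s1.weight == s2.weight and s1.meta == s2.meta


def test_generate_dataset_pairs_agree_outside_coverage():
    p = SceneParams(seed=31)
    sample = generate_dataset(1, p, keep_frames=True)[0]
    dc = sample.covered_frame.depths
    du = sample.uncovered_frame.depths
    K, H = p.intrinsics, p.camera_height
    v = np.arange(p.image_shape[0])
    y_bed = (v - K.cy) / K.fy * H
    y_min = p.bed_extent[1] / 2 - p.blanket_coverage * p.bed_extent[1]
    outside = y_bed < y_min - 0.1
    assert np.array_equal(dc[outside, :], du[outside, :])  # shared noise field


def test_generate_dataset_cardinality_and_manifest(tmp_path):
    from bedweight.scene_sim import write_dataset

    p = SceneParams(seed=5)
    samples = generate_dataset(3, p, keep_frames=True)
    assert len({s.meta["subject_id"] for s in samples}) == 3
    manifest = write_dataset(samples, tmp_path, p)
    assert len(manifest["samples"]) == 3
    assert (tmp_path / "subject0000_covered.png").exists()
    assert (tmp_path / "subject0000_uncovered.ply").exists()
    for m in manifest["samples"]:
        assert m["cover"] in ("thin", "thick")
        assert m["position"] in ("supine", "lateral")
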