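import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from isletvasc import (
    Branch,
    Centerline,
    SceneConfig,
    SegmentationMask,
    Tube,
    assign_diameters,
    distance_field,
    extract_centerline,
    scene_from_geometry,
)

from conftest import oblique_tube_scene, random_blobby_masks, straight_tube_scene


# ---------------------------------------------------------------------------
# distance field
# ---------------------------------------------------------------------------

def test_empty_mask_gives_zero_field():
    df = distance_field(SegmentationMask(np.zeros((5, 5, 5), bool), (1, 1, 1)))
    assert (df.values == 0).all()


def test_all_foreground_mask_is_an_error():
    with pytest.raises(ValueError, match="boundary"):
        distance_field(SegmentationMask(np.ones((5, 5, 5), bool), (1, 1, 1)))


def test_single_voxel_distance_is_one_voxel():
    m = np.zeros((5, 5, 5), bool)
    m[2, 2, 2] = True
    df = distance_field(SegmentationMask(m, (1, 1, 1)))
    assert df.values[2, 2, 2] == pytest.approx(1.0)
    assert df.values[~m].max() == 0.0


def test_sphere_centre_distance_matches_analytic_radius():
    z, y, x = np.ogrid[:25, :25, :25]
    sph = (z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 100
    df = distance_field(SegmentationMask(sph, (1, 1, 1)))
    assert abs(df.values[12, 12, 12] - 10.0) <= 1.0


def test_field_matches_exact_edt_on_random_masks():
    for i, blob in enumerate(random_blobby_masks(5, seed=1)):
        df = distance_field(SegmentationMask(blob, (1.0, 1.0, 1.0)))
        edt = distance_transform_edt(blob)
        assert np.abs(df.values - edt).max() <= 1.0, f"mask {i}"


def test_field_handles_anisotropic_spacing():
    z, y, x = np.ogrid[:25, :25, :25]
    sph = ((z - 12) * 2.0) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 100
    df = distance_field(SegmentationMask(sph, (2.0, 1.0, 1.0)))
    edt = distance_transform_edt(sph, sampling=(2.0, 1.0, 1.0))
    assert np.abs(df.values - edt).max() <= 1.0  # finest voxel


def test_field_is_discretely_lipschitz():
    """|∇d| ≤ 1 w.r.t. physical distance: neighbouring foreground values can
    differ by at most the physical step (plus scheme tolerance)."""
    blob = random_blobby_masks(1, seed=4)[0]
    spacing = np.array([1.0, 1.0, 1.0])
    df = distance_field(SegmentationMask(blob, tuple(spacing)))
    v = df.values
    for ax, h in enumerate(spacing):
        diff = np.abs(np.diff(v, axis=ax))
        interior = np.minimum(
            np.take(blob, range(1, blob.shape[ax]), axis=ax),
            np.take(blob, range(0, blob.shape[ax] - 1), axis=ax),
        )
        assert diff[interior].max() <= h * 1.05


# ---------------------------------------------------------------------------
# centerline extraction
# ---------------------------------------------------------------------------

def test_empty_mask_gives_empty_centerline():
    m = SegmentationMask(np.zeros((5, 5, 5), bool), (1, 1, 1))
    cline = extract_centerline(m, distance_field(m))
    assert cline.n_branches == 0
    assert cline.total_length_um() == 0.0


def test_straight_tube_single_branch_on_axis():
    _, _, truth = straight_tube_scene(4.0, spacing=1.0, snr=np.inf)
    mask = truth.vessel_mask
    df = distance_field(mask)
    cline = extract_centerline(mask, df)
    assert cline.n_branches == 1
    pts = cline.branches[0].points_um
    c = truth.tube_centerlines[0].points_um[0][:2]  # true (z, y) of the axis
    perp = np.linalg.norm(pts[:, :2] - c, axis=1)
    assert perp.max() <= 0.5  # within half a voxel of the true axis


def test_quarter_torus_arc_length_within_5_percent():
    R, r = 45.0, 3.0
    cfg = SceneConfig(
        shape_voxels=(20, 70, 70), spacing_um=(1, 1, 1), n_tubes=0, n_cells=0,
        islet_center_um=(10.0, 35.0, 35.0), psf_sigma_um=(0, 0, 0), snr=np.inf,
        seed=1, tube_radius_range_um=(r, r), cell_radius_um=2.0, roi_radius_um=5.0,
    )
    th = np.linspace(-0.1, np.pi / 2 + 0.1, 1000)
    pts = np.stack([np.full_like(th, 10.0), R * np.sin(th), R * np.cos(th)], axis=1)
    _, truth = scene_from_geometry(cfg, [Tube(pts, np.full_like(th, r))], np.zeros((0, 3)))
    df = distance_field(truth.vessel_mask)
    cline = extract_centerline(truth.vessel_mask, df)
    analytic = R * np.pi / 2
    assert abs(cline.total_length_um() - analytic) / analytic < 0.05


# ---------------------------------------------------------------------------
# diameters
# ---------------------------------------------------------------------------

def test_empty_centerline_diameters():
    m = SegmentationMask(np.zeros((5, 5, 5), bool), (1, 1, 1))
    df = distance_field(m)
    out = assign_diameters(Centerline(), df)
    assert out.n_branches == 0


def test_constant_radius_tube_diameter_within_one_voxel():
    _, _, truth = straight_tube_scene(4.0, spacing=1.0, snr=np.inf)
    df = distance_field(truth.vessel_mask)
    cline = assign_diameters(extract_centerline(truth.vessel_mask, df), df)
    diam = np.concatenate([2 * b.radii_um for b in cline.branches])
    assert abs(diam.mean() - 8.0) <= 1.0


def test_linearly_varying_radius_recovered_monotonically():
    sp = 0.5
    n, L = 56, 220
    cfg = SceneConfig(
        shape_voxels=(n, n, L), spacing_um=(sp,) * 3, n_tubes=0, n_cells=0,
        islet_center_um=(14.0, 14.0, 55.0), psf_sigma_um=(0.5,) * 3, snr=np.inf,
        seed=5, tube_radius_range_um=(2.0, 6.0), cell_radius_um=1.0, roi_radius_um=5.0,
    )
    xs = np.arange(-5.0, L * sp + 5.0, 0.25)
    c = n * sp / 2
    pts = np.stack([np.full_like(xs, c), np.full_like(xs, c), xs], axis=1)
    rr = 2.0 + 4.0 * (xs - xs[0]) / (xs[-1] - xs[0])
    _, truth = scene_from_geometry(cfg, [Tube(pts, rr)], np.zeros((0, 3)))
    df = distance_field(truth.vessel_mask)
    cline = assign_diameters(extract_centerline(truth.vessel_mask, df), df)
    b = max(cline.branches, key=lambda b: len(b.points_um))
    order = np.argsort(b.points_um[:, 2])
    x = b.points_um[order, 2]
    d = np.convolve(2 * b.radii_um[order], np.ones(3) / 3, mode="valid")
    x = x[1:-1]
    # monotone recovery: averaged in 8 bins along the tube, strictly increasing
    bins = np.array_split(np.arange(len(d)), 8)
    means = [d[i].mean() for i in bins]
    assert all(a < b for a, b in zip(means, means[1:]))
    # interior endpoints track the true linear profile within one voxel
    true_d = 2 * (2.0 + 4.0 * (x - xs[0]) / (xs[-1] - xs[0]))
    interior = (x > 15) & (x < L * sp - 15)
    assert abs(d[interior][0] - true_d[interior][0]) <= 2 * sp
    assert abs(d[interior][-1] - true_d[interior][-1]) <= 2 * sp


def test_anisotropic_grid_gives_same_physical_diameter():
    # same 4 µm tube along x, isotropic 1 µm vs 2×1×1 µm spacing
    _, _, truth_iso = straight_tube_scene(4.0, spacing=1.0, snr=np.inf)
    cfg = SceneConfig(
        shape_voxels=(20, 40, 100), spacing_um=(2.0, 1.0, 1.0), n_tubes=0, n_cells=0,
        islet_center_um=(20.0, 20.0, 50.0), psf_sigma_um=(0, 0, 0), snr=np.inf, seed=1,
        tube_radius_range_um=(4.0, 4.0), cell_radius_um=4.0, roi_radius_um=5.0,
    )
    xs = np.arange(-5.0, 105.0, 0.25)
    pts = np.stack([np.full_like(xs, 20.0), np.full_like(xs, 20.0), xs], axis=1)
    _, truth_ani = scene_from_geometry(cfg, [Tube(pts, np.full_like(xs, 4.0))], np.zeros((0, 3)))

    means = []
    for truth in (truth_iso, truth_ani):
        df = distance_field(truth.vessel_mask)
        cline = assign_diameters(extract_centerline(truth.vessel_mask, df), df)
        means.append(np.concatenate([2 * b.radii_um for b in cline.branches]).mean())
    assert abs(means[0] - means[1]) <= 1.0  # one finest voxel


def test_rotation_robustness_of_mean_diameter():
    means = []
    for direction in ((0, 0, 1), (0, 1, 1), (1, 1, 1)):
        _, _, truth = oblique_tube_scene(direction, radius_um=4.0)
        df = distance_field(truth.vessel_mask)
        cline = assign_diameters(extract_centerline(truth.vessel_mask, df), df)
        pts = np.concatenate([b.points_um for b in cline.branches])
        radii = np.concatenate([b.radii_um for b in cline.branches])
        near = np.linalg.norm(pts - 30.0, axis=1) < 20.0
        means.append(2 * radii[near].mean())
    ref = means[0]
    assert all(abs(m - ref) / ref < 0.10 for m in means[1:])


def test_point_outside_foreground_is_reported():
    m = np.zeros((9, 9, 9), bool)
    m[4, 4, 2:7] = True
    mask = SegmentationMask(m, (1, 1, 1))
    df = distance_field(mask)
    rogue = Centerline(
        branches=[Branch(points_um=np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]))],
        component_ids=[0],
    )
    with pytest.raises(ValueError, match="branch 0"):
        assign_diameters(rogue, df)
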