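import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletvasc import (
    Branch,
    Centerline,
    CtTable,
    ImageStack,
    SegmentationMask,
    SphericalRoi,
    count_cells,
    integrated_density,
    normalized_regrowth,
    polyline_length_in_sphere,
    relative_expression,
    roi_stats,
)

from conftest import flood_fill_count


# ---------------------------------------------------------------------------
# spherical ROI statistics
# ---------------------------------------------------------------------------

def straight_centerline(y=10.0, z=10.0, x0=0.0, x1=40.0, radius=2.0, n=81):
    xs = np.linspace(x0, x1, n)
    pts = np.stack([np.full_like(xs, z), np.full_like(xs, y), xs], axis=1)
    return Centerline(
        branches=[Branch(points_um=pts, radii_um=np.full_like(xs, radius))],
        component_ids=[0],
    )


def box_mask(shape=(20, 20, 40), spacing=(1.0, 1.0, 1.0)):
    m = np.zeros(shape, bool)
    m[8:13, 8:13, :] = True
    return SegmentationMask(m, spacing)


def test_default_roi_radius_is_100_um():
    roi = SphericalRoi(center_um=(0, 0, 0))
    assert roi.radius_um == 100.0


def test_no_centerline_in_roi_flags_undefined_diameters():
    cline = straight_centerline()
    roi = SphericalRoi(center_um=(10.0, 10.0, 200.0), radius_um=5.0)
    mask = box_mask(shape=(20, 20, 210))
    rs = roi_stats(cline, mask, roi)
    assert rs.density_um_per_um3 == 0.0
    assert rs.n_capillaries == 0
    assert not rs.diameters_defined
    assert math.isnan(rs.mean_diameter_um) and math.isnan(rs.sd_diameter_um)


def test_roi_entirely_outside_stack_is_an_error():
    cline = straight_centerline()
    with pytest.raises(ValueError, match="outside"):
        roi_stats(cline, box_mask(), SphericalRoi(center_um=(500.0, 500.0, 500.0), radius_um=10.0))


def test_density_of_straight_line_through_sphere_is_exact():
    # a diameter chord of length 2R inside the ROI
    cline = straight_centerline(y=10, z=10, x0=0, x1=40, radius=2.0)
    roi = SphericalRoi(center_um=(10.0, 10.0, 20.0), radius_um=8.0)
    rs = roi_stats(cline, box_mask(), roi)
    assert rs.total_length_um == pytest.approx(16.0, rel=1e-6)
    assert rs.density_um_per_um3 == pytest.approx(16.0 / roi.volume_um3, rel=1e-6)
    assert rs.n_capillaries == 1
    assert rs.mean_diameter_um == pytest.approx(4.0)
    assert rs.sd_diameter_um == pytest.approx(0.0, abs=1e-12)


def test_enlarging_roi_never_decreases_length_or_capillaries():
    rng = np.random.default_rng(0)
    branches = []
    for i in range(4):
        pts = np.cumsum(rng.normal(0, 2, (30, 3)), axis=0) + [10, 10, 20]
        branches.append(Branch(points_um=pts, radii_um=np.full(30, 1.5)))
    cline = Centerline(branches=branches, component_ids=list(range(4)))
    mask = box_mask()
    prev_len, prev_cap = -1.0, -1
    for radius in (4.0, 8.0, 16.0, 32.0):
        rs = roi_stats(cline, mask, SphericalRoi(center_um=(10, 10, 20), radius_um=radius))
        assert rs.total_length_um >= prev_len
        assert rs.n_capillaries >= prev_cap
        prev_len, prev_cap = rs.total_length_um, rs.n_capillaries


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_clipped_length_matches_dense_sampling(seed):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(0, 3, (12, 3)), axis=0)
    center = rng.normal(0, 5, 3)
    radius = rng.uniform(2, 15)
    exact = polyline_length_in_sphere(pts, center, radius)
    approx = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        ts = np.linspace(0, 1, 2001)[:-1] + 0.00025
        mids = a[None] + ts[:, None] * (b - a)[None]
        inside = np.linalg.norm(mids - center, axis=1) <= radius
        approx += np.linalg.norm(b - a) * inside.mean()
    assert exact == pytest.approx(approx, abs=0.05)


# ---------------------------------------------------------------------------
# integrated density
# ---------------------------------------------------------------------------

def test_integrated_density_closed_forms():
    stack = ImageStack(np.zeros((4, 4, 4)), (1, 1, 1))
    assert integrated_density(stack) == 0.0
    stack = ImageStack(np.full((4, 4, 4), 7.0), (1, 1, 1))
    assert integrated_density(stack) == 7.0 * 64


def test_integrated_density_equals_brute_force_sum():
    rng = np.random.default_rng(1)
    vox = rng.integers(0, 1000, (6, 7, 8))
    stack = ImageStack(vox, (1, 1, 1))
    region = SegmentationMask(rng.random((6, 7, 8)) < 0.4, (1, 1, 1))
    expected = sum(
        float(vox[z, y, x])
        for z, y, x in np.ndindex(vox.shape)
        if region.voxels[z, y, x]
    )
    assert integrated_density(stack, region) == expected


def test_integrated_density_additive_over_disjoint_regions():
    rng = np.random.default_rng(2)
    vox = rng.random((6, 6, 6))
    stack = ImageStack(vox, (1, 1, 1))
    a = np.zeros((6, 6, 6), bool)
    a[:3] = True
    b = ~a
    total = integrated_density(stack, SegmentationMask(a, (1, 1, 1))) + integrated_density(
        stack, SegmentationMask(b, (1, 1, 1))
    )
    assert total == pytest.approx(float(vox.sum()), rel=1e-12)


def test_integrated_density_box_region_and_empty_warning():
    stack = ImageStack(np.full((4, 4, 4), 3.0), (1, 1, 1))
    assert integrated_density(stack, ((0, 2), (0, 4), (0, 4))) == 3.0 * 32
    with pytest.warns(UserWarning):
        assert integrated_density(stack, ((0, 0), (0, 0), (0, 0))) == 0.0


# ---------------------------------------------------------------------------
# cell counts
# ---------------------------------------------------------------------------

def test_count_cells_empty_mask():
    assert count_cells(SegmentationMask(np.zeros((4, 4, 4), bool), (1, 1, 1))) == 0


def test_count_cells_matches_flood_fill_oracle():
    rng = np.random.default_rng(4)
    for _ in range(3):
        m = rng.random((15, 15, 15)) < 0.15
        mask = SegmentationMask(m, (1, 1, 1))
        assert count_cells(mask) == flood_fill_count(m)


def test_separated_spheres_counted_and_overlapping_merge():
    z, y, x = np.ogrid[:30, :30, :30]
    sep = ((z - 7) ** 2 + (y - 7) ** 2 + (x - 7) ** 2 <= 9) | (
        (z - 22) ** 2 + (y - 22) ** 2 + (x - 22) ** 2 <= 9
    )
    assert count_cells(SegmentationMask(sep, (1, 1, 1))) == 2
    overlap = ((z - 14) ** 2 + (y - 14) ** 2 + (x - 14) ** 2 <= 25) | (
        (z - 17) ** 2 + (y - 17) ** 2 + (x - 17) ** 2 <= 25
    )
    assert count_cells(SegmentationMask(overlap, (1, 1, 1))) == 1


def test_count_cells_min_volume_filter():
    m = np.zeros((10, 10, 10), bool)
    m[1, 1, 1] = True  # 1 µm³
    m[5:8, 5:8, 5:8] = True  # 27 µm³
    mask = SegmentationMask(m, (1, 1, 1))
    assert count_cells(mask, min_volume_um3=10.0) == 1
    assert count_cells(mask, min_volume_um3=0.0) == 2


# ---------------------------------------------------------------------------
# fin regrowth and qPCR
# ---------------------------------------------------------------------------

def test_normalized_regrowth_closed_forms():
    assert normalized_regrowth(0.0, 500.0) == 0.0
    assert normalized_regrowth(1000.0, 500.0) == 2.0
    with pytest.raises(ValueError):
        normalized_regrowth(10.0, 0.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(1.0, 1e6), st.floats(1.0, 1e4), st.floats(0.1, 10.0))
def test_normalized_regrowth_scales_linearly(area, length, c):
    # area × c², length × c  →  result × c (dimensional identity)
    base = normalized_regrowth(area, length)
    scaled = normalized_regrowth(area * c * c, length * c)
    assert scaled == pytest.approx(base * c, rel=1e-9)


def ct_table(rows, refs=("ef1a", "arp"), calibrator="wt"):
    return CtTable(
        data=pd.DataFrame(rows, columns=["sample_id", "gene", "ct"]),
        reference_genes=refs,
        calibrator=calibrator,
    )


def test_relative_expression_identity():
    t = ct_table(
        [("wt", "ins", 20.0), ("wt", "ef1a", 18.0), ("wt", "arp", 18.0)],
    )
    assert relative_expression(t, "ins", "wt") == pytest.approx(1.0)


def test_relative_expression_closed_form():
    # ΔCt sample = 20 − 18 = 2; ΔCt calibrator = 22 − 18 = 4; ΔΔCt = −2 → 4.0
    t = ct_table(
        [
            ("mut", "ins", 20.0), ("mut", "ef1a", 18.0), ("mut", "arp", 18.0),
            ("wt", "ins", 22.0), ("wt", "ef1a", 18.0), ("wt", "arp", 18.0),
        ]
    )
    assert relative_expression(t, "ins", "mut") == pytest.approx(4.0)


def test_two_reference_genes_use_mean_ct():
    t = ct_table(
        [
            ("s", "tgt", 21.0), ("s", "ef1a", 18.0), ("s", "arp", 20.0),
            ("cal", "tgt", 23.0), ("cal", "ef1a", 19.0), ("cal", "arp", 19.0),
        ],
        calibrator="cal",
    )
    # brute-force formula evaluation
    d_s = 21.0 - (18.0 + 20.0) / 2
    d_c = 23.0 - (19.0 + 19.0) / 2
    assert relative_expression(t, "tgt", "s") == pytest.approx(2.0 ** (-(d_s - d_c)))


def test_ct_table_validates_missing_reference():
    with pytest.raises(ValueError, match="reference"):
        ct_table([("s", "tgt", 21.0), ("s", "ef1a", 18.0)])


def test_missing_gene_is_a_key_error():
    t = ct_table([("s", "ef1a", 18.0), ("s", "arp", 18.0)])
    with pytest.raises(KeyError):
        relative_expression(t, "nope", "s", calibrator="s")
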