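"""Shared fixtures: small phantoms with known geometry and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from isletvasc import SceneConfig, Tube, scene_from_geometry


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0


def straight_tube_scene(
    radius_um: float,
    spacing: float = 1.0,
    length_um: float = 100.0,
    snr: float = 10.0,
    seed: int = 1,
    psf_um: float = 0.5,
):
    """Axis-aligned (along x) constant-radius tube phantom through the volume."""
    n_lat = int(round((6 * radius_um + 16) / spacing))
    n_lat += n_lat % 2  # even, so the axis sits on a voxel row at n_lat/2
    nx = int(round(length_um / spacing))
    cfg = SceneConfig(
        shape_voxels=(n_lat, n_lat, nx),
        spacing_um=(spacing,) * 3,
        n_tubes=0,
        n_cells=0,
        islet_center_um=(n_lat * spacing / 2,) * 3,
        psf_sigma_um=(psf_um,) * 3,
        snr=snr,
        seed=seed,
        tube_radius_range_um=(max(2 * spacing, radius_um),) * 2,
        cell_radius_um=2 * spacing,
        roi_radius_um=5.0,
    )
    c = (n_lat / 2) * spacing
    xs = np.arange(-5.0, nx * spacing + 5.0, 0.25)
    pts = np.stack([np.full_like(xs, c), np.full_like(xs, c), xs], axis=1)
    tube = Tube(points_um=pts, radii_um=np.full_like(xs, radius_um))
    stacks, truth = scene_from_geometry(cfg, [tube], np.zeros((0, 3)))
    return cfg, stacks, truth


def oblique_tube_scene(direction, radius_um=4.0, seed=1, snr=np.inf):
    """Constant-radius tube through the volume centre along an arbitrary axis."""
    cfg = SceneConfig(
        shape_voxels=(60, 60, 60),
        spacing_um=(1.0, 1.0, 1.0),
        n_tubes=0,
        n_cells=0,
        islet_center_um=(30.0, 30.0, 30.0),
        psf_sigma_um=(0.0, 0.0, 0.0),
        snr=snr,
        seed=seed,
        tube_radius_range_um=(radius_um, radius_um),
        cell_radius_um=2.0,
        roi_radius_um=5.0,
    )
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)
    s = np.arange(-60.0, 121.0, 0.25)
    pts = np.array([30.0, 30.0, 30.0]) + s[:, None] * d
    tube = Tube(points_um=pts, radii_um=np.full(len(s), radius_um))
    stacks, truth = scene_from_geometry(cfg, [tube], np.zeros((0, 3)))
    return cfg, stacks, truth


def separated_blob_scene(snr: float = 10.0, seed: int = 2):
    """Five well-separated β-cell-like blobs (radius 4 voxels)."""
    cfg = SceneConfig(
        shape_voxels=(64, 64, 64),
        spacing_um=(1.5, 1.5, 1.5),
        n_tubes=0,
        n_cells=0,
        cell_radius_um=6.0,
        islet_center_um=(48.0, 48.0, 48.0),
        psf_sigma_um=(1.5, 0.75, 0.75),
        snr=snr,
        seed=seed,
        tube_radius_range_um=(3.0, 3.0),
        roi_radius_um=5.0,
    )
    centers = np.array(
        [[25, 25, 25], [25, 65, 65], [65, 25, 65], [65, 65, 25], [48, 48, 70]], float
    )
    stacks, truth = scene_from_geometry(cfg, [], centers)
    return cfg, stacks, truth


def random_blobby_masks(n: int, seed: int = 0, max_side: int = 40):
    """Random smooth binary masks ≤ max_side³ (for distance-field oracle tests)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    masks = []
    while len(masks) < n:
        shape = tuple(rng.integers(20, max_side + 1, size=3))
        blob = gaussian_filter((rng.random(shape) < 0.5).astype(float), 2.0) > 0.5
        if blob.any() and not blob.all():
            masks.append(blob)
    return masks


def flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 26-connected component count by BFS (oracle for count_cells)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) and mask[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
    return count


@pytest.fixture(scope="session")
def default_scene():
    """One default-configuration scene, shared across tests (expensive)."""
    from isletvasc import make_scene

    cfg = SceneConfig(seed=7)
    stacks, truth = make_scene(cfg)
    return cfg, stacks, truth
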