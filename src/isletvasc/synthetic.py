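"""Synthetic two-channel confocal phantoms with known vessel/islet geometry.

Emulates stacks of a zebrafish pancreatic islet: a cluster of bright spherical
blobs (β cells, "red" channel) surrounded by a network of curved tubes of
capillary calibre (vessels, "green" channel).  Every scene carries full ground
truth — tube centerlines with per-point radii, exact rasterized masks, cell
centres and the islet centroid — so the downstream segmentation, centerline
and morphometry steps can be validated against known geometry.

Conventions (used everywhere in this package):
    * axis order z, y, x; voxel centre of index ``i`` sits at ``i * spacing``;
    * all coordinates and radii in micrometres;
    * a voxel is vessel foreground iff its centre lies within ``r(s)`` of the
      *nearest* centerline sample point ``s`` of some tube.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .io_stack import ImageStack, SegmentationMask

__all__ = [
    "SceneConfig",
    "CohortConfig",
    "Tube",
    "SceneTruth",
    "CohortScene",
    "make_scene",
    "make_cohort",
    "scene_from_geometry",
    "rasterize_tubes",
    "rasterize_balls",
]

# Peak fluorophore amplitude in relative intensity units (full scale = 1.0);
# leaves headroom above background + noise before quantization.
SIGNAL_AMPLITUDE = 0.7


@dataclass
class SceneConfig:
    """Parameters of one synthetic islet scene.

    ``seed`` drives both the random geometry and the default noise stream;
    :func:`make_scene` accepts a separate ``noise_seed`` to redraw only the
    noise for a fixed geometry.
    """

    shape_voxels: tuple[int, int, int] = (68, 136, 136)
    spacing_um: tuple[float, float, float] = (3.0, 1.5, 1.5)
    n_tubes: int = 6
    tube_radius_range_um: tuple[float, float] = (4.5, 6.5)
    tube_waviness: float = 5.0  # SD of lateral waypoint jitter, µm
    n_cells: int = 30
    cell_radius_um: float = 5.0
    islet_center_um: tuple[float, float, float] | str = "auto"
    psf_sigma_um: tuple[float, float, float] = (1.5, 0.75, 0.75)
    background_level: float = 0.15
    background_gradient: float = 0.03
    snr: float = 10.0
    bit_depth: int = 16
    seed: int = 0
    roi_radius_um: float = 100.0  # radius of the downstream spherical analysis ROI

    def __post_init__(self) -> None:
        self.shape_voxels = tuple(int(v) for v in self.shape_voxels)
        self.spacing_um = tuple(float(v) for v in self.spacing_um)
        self.tube_radius_range_um = tuple(float(v) for v in self.tube_radius_range_um)
        if len(self.shape_voxels) != 3 or any(v <= 0 for v in self.shape_voxels):
            raise ValueError("shape_voxels must be 3 positive ints (z, y, x)")
        if len(self.spacing_um) != 3 or any(v <= 0 for v in self.spacing_um):
            raise ValueError("spacing_um must be 3 positive reals (z, y, x)")
        lo, hi = self.tube_radius_range_um
        if not (0 < lo <= hi):
            raise ValueError("tube_radius_range_um must satisfy 0 < lo <= hi")
        if self.n_tubes < 0 or self.n_cells < 0:
            raise ValueError("n_tubes and n_cells must be >= 0")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be > 0")
        if self.tube_waviness < 0:
            raise ValueError("tube_waviness must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0 (use numpy.inf for noise-free)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.background_level < 0 or self.background_gradient < 0:
            raise ValueError("background must be >= 0")
        min_sp = min(self.spacing_um)
        if self.n_tubes and lo < 2 * min_sp:
            raise ValueError(
                f"tube radius {lo} µm below resolvability: need >= 2x the finest "
                f"spacing ({2 * min_sp} µm)"
            )
        if self.n_cells and self.cell_radius_um < 2 * min_sp:
            raise ValueError(
                f"cell radius {self.cell_radius_um} µm below resolvability: need >= "
                f"2x the finest spacing ({2 * min_sp} µm)"
            )
        extent = self.extent_um
        if isinstance(self.islet_center_um, str):
            if self.islet_center_um != "auto":
                raise ValueError("islet_center_um must be 3 reals or 'auto'")
            if any(e < 2 * self.roi_radius_um for e in extent):
                raise ValueError(
                    f"volume extent {tuple(round(e, 1) for e in extent)} µm too small "
                    f"for the {self.roi_radius_um} µm analysis ROI centred at the "
                    "volume centre; enlarge the volume or set islet_center_um explicitly"
                )
        else:
            self.islet_center_um = tuple(float(v) for v in self.islet_center_um)
            if len(self.islet_center_um) != 3:
                raise ValueError("islet_center_um must have 3 entries")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape_voxels, self.spacing_um))

    def resolved_islet_center(self) -> np.ndarray:
        if isinstance(self.islet_center_um, str):
            return np.array(self.extent_um) / 2.0
        return np.asarray(self.islet_center_um, dtype=float)


@dataclass
class CohortConfig:
    """A two-group study design: control vs mutant scenes.

    The mutant group differs from control only through ``diameter_scale_mutant``
    (tube radii multiplied by it) and ``density_scale_mutant`` (tube count
    multiplied, rounded, floored at 1), mirroring a genotype with thinner and
    sparser islet capillaries.  Group sizes are equal (default 5 per group).
    """

    base: SceneConfig = field(default_factory=SceneConfig)
    n_per_group: int = 5
    diameter_scale_mutant: float = 0.7
    density_scale_mutant: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for name in ("diameter_scale_mutant", "density_scale_mutant"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass
class Tube:
    """A single vessel: dense centerline polyline with per-point radii (µm)."""

    points_um: np.ndarray  # (N, 3), z/y/x
    radii_um: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.points_um = np.atleast_2d(np.asarray(self.points_um, dtype=float))
        self.radii_um = np.atleast_1d(np.asarray(self.radii_um, dtype=float))
        if self.points_um.shape[0] != self.radii_um.shape[0]:
            raise ValueError("points and radii must have equal length")
        if (self.radii_um <= 0).any():
            raise ValueError("tube radii must be positive")

    @property
    def length_um(self) -> float:
        if len(self.points_um) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene (pre-noise geometry)."""

    tube_centerlines: list[Tube]
    vessel_mask: SegmentationMask
    cell_centers_um: np.ndarray
    cell_mask: SegmentationMask
    islet_centroid_um: np.ndarray
    roi_radius_um: float
    centerline_length_in_roi_um: float

    def mean_radius_um(self) -> float:
        """Length-weighted mean tube radius over all centerline samples."""
        radii = np.concatenate([t.radii_um for t in self.tube_centerlines]) if self.tube_centerlines else np.array([])
        return float(radii.mean()) if radii.size else float("nan")

    def in_roi_diameters_um(self) -> np.ndarray:
        """Per-sample true diameters of centerline points inside the ROI."""
        out = []
        c = self.islet_centroid_um
        for t in self.tube_centerlines:
            d = np.linalg.norm(t.points_um - c, axis=1)
            out.append(2.0 * t.radii_um[d <= self.roi_radius_um])
        return np.concatenate(out) if out else np.array([])


@dataclass
class CohortScene:
    subject_id: str
    group: str
    stacks: tuple[ImageStack, ImageStack]  # (vessel, cell)
    truth: SceneTruth


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_tubes(
    tubes: Sequence[Tube],
    shape: tuple[int, int, int],
    spacing_um: tuple[float, float, float],
) -> np.ndarray:
    """Exact tube rasterization: voxel centre within ``r`` of its *nearest*
    centerline sample of a given tube, union over tubes.

    A candidate superset of voxels (within the tube's maximum radius of any
    sample point) is stamped first, then the nearest-point rule is evaluated
    with a KD-tree restricted to those candidates, which reproduces the
    brute-force all-voxels result exactly.
    """
    spacing = np.asarray(spacing_um, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    for tube in tubes:
        pts = tube.points_um
        radii = tube.radii_um
        if len(pts) == 0:
            continue
        rmax = float(radii.max())
        cand = _stamp_candidates(pts, rmax, shape, spacing)
        if not cand.any():
            continue
        idx = np.argwhere(cand)
        centers = idx * spacing
        tree = cKDTree(pts)
        dist, nearest = tree.query(centers, k=1)
        inside = dist <= radii[nearest]
        zz, yy, xx = idx[inside].T
        mask[zz, yy, xx] = True
    return mask


def _stamp_candidates(pts, rmax, shape, spacing) -> np.ndarray:
    cand = np.zeros(shape, dtype=bool)
    lo_all = np.floor((pts - rmax) / spacing).astype(int)
    hi_all = np.ceil((pts + rmax) / spacing).astype(int) + 1
    np.clip(lo_all, 0, np.array(shape), out=lo_all)
    np.clip(hi_all, 0, np.array(shape), out=hi_all)
    for lo, hi in zip(lo_all, hi_all):
        if (hi > lo).all():
            cand[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return cand


def rasterize_balls(
    centers_um: np.ndarray,
    radius_um: float,
    shape: tuple[int, int, int],
    spacing_um: tuple[float, float, float],
) -> np.ndarray:
    """Union of spheres of a common radius (exact voxel-centre test)."""
    spacing = np.asarray(spacing_um, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    centers = np.atleast_2d(np.asarray(centers_um, dtype=float))
    if centers.size == 0:
        return mask
    for c in centers:
        lo = np.clip(np.floor((c - radius_um) / spacing).astype(int), 0, shape)
        hi = np.clip(np.ceil((c + radius_um) / spacing).astype(int) + 1, 0, shape)
        if not (hi > lo).all():
            continue
        grids = np.meshgrid(
            *[np.arange(lo[a], hi[a]) * spacing[a] - c[a] for a in range(3)],
            indexing="ij",
        )
        d2 = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= d2 <= radius_um**2
    return mask


# ---------------------------------------------------------------------------
# Random geometry
# ---------------------------------------------------------------------------

def _random_tube(rng: np.random.Generator, config: SceneConfig) -> Tube:
    """Smoothed random walk: spline through jittered waypoints along a random
    chord passing near the islet, radius varying linearly along arc length."""
    lo, hi = config.tube_radius_range_um
    r0 = rng.uniform(lo, hi)
    r1 = rng.uniform(lo, hi)

    center = _draw_anchor(rng, config)
    direction = _random_unit(rng)
    extent = np.array(config.extent_um)
    # margins are radius-independent so that scaling the radius range (the
    # cohort diameter effect) rescales radii on an identical point set
    half_len = 0.5 * float(np.linalg.norm(extent)) + 30.0

    n_way = max(4, int(2 * half_len / 25.0))
    t = np.linspace(-half_len, half_len, n_way)
    base = center[None, :] + t[:, None] * direction[None, :]
    # lateral jitter only (keeps the tube from doubling back on itself)
    e1, e2 = _perp_basis(direction)
    jit = rng.normal(0.0, config.tube_waviness, size=(n_way, 2))
    jit[0] = jit[-1] = 0.0
    way = base + jit[:, :1] * e1[None, :] + jit[:, 1:] * e2[None, :]

    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(way, axis=0), axis=1))]
    spline = CubicSpline(chord, way, axis=0)
    ds = 0.5 * min(config.spacing_um)
    s = np.arange(0.0, chord[-1] + ds, ds)
    pts = spline(s)

    # keep the stretch intersecting the volume (with a fixed margin generous
    # enough for any admissible radius)
    margin = 15.0 + ds
    inside = np.all((pts >= -margin) & (pts <= extent + margin), axis=1)
    if not inside.any():
        inside[:] = True  # degenerate; keep everything rather than emit an empty tube
    first, last = np.argmax(inside), len(inside) - np.argmax(inside[::-1]) - 1
    pts = pts[first:last + 1]
    s = s[first:last + 1]
    frac = (s - s[0]) / max(s[-1] - s[0], 1e-9)
    radii = r0 + (r1 - r0) * frac
    return Tube(points_um=pts, radii_um=radii)


def _draw_anchor(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    """Tube anchor near the islet: capillaries surround, not pierce, the islet."""
    center = config.resolved_islet_center()
    islet_r = _islet_sigma(config) * 2.0 + config.cell_radius_um
    shell = islet_r + rng.uniform(2.0, max(4.0, 0.4 * config.roi_radius_um))
    return center + shell * _random_unit(rng)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:  # pragma: no cover
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _islet_sigma(config: SceneConfig) -> float:
    """Spread (SD, µm) of the β-cell cluster around the islet centre."""
    n = max(config.n_cells, 1)
    return config.cell_radius_um * max(1.2, 0.8 * n ** (1.0 / 3.0))


def _draw_cells(rng: np.random.Generator, config: SceneConfig) -> np.ndarray:
    if config.n_cells == 0:
        return np.zeros((0, 3))
    center = config.resolved_islet_center()
    sigma = _islet_sigma(config)
    return center[None, :] + rng.normal(0.0, sigma, size=(config.n_cells, 3))


# ---------------------------------------------------------------------------
# Rendering: PSF blur + background + Poisson-Gaussian noise + quantization
# ---------------------------------------------------------------------------

def _render_channel(
    mask: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    signal = SIGNAL_AMPLITUDE * mask.astype(np.float64)
    sigma_vox = np.asarray(config.psf_sigma_um) / np.asarray(config.spacing_um)
    if (sigma_vox > 0).any():
        signal = gaussian_filter(signal, sigma=sigma_vox)

    nz, ny, nx = config.shape_voxels
    ramp = (np.arange(ny, dtype=np.float64) / max(ny - 1, 1))[None, :, None]
    clean = signal + config.background_level + config.background_gradient * ramp

    noisy = _add_noise(clean, config, rng)
    scale = 2**config.bit_depth - 1
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return np.clip(np.rint(noisy * scale), 0, scale).astype(dtype)


def _add_noise(clean: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on photon-scaled signal plus Gaussian read noise.

    The photon scale and read-noise SD are chosen so that, at the nominal
    background level, the total noise SD equals peak_signal / snr — i.e.
    ``snr`` is peak signal over background-region noise SD, split evenly
    between the two noise sources.
    """
    if not np.isfinite(config.snr):
        return clean
    peak = SIGNAL_AMPLITUDE
    sigma = peak / config.snr
    b0 = config.background_level
    if b0 > 0:
        gamma = 2.0 * b0 / sigma**2  # photons per intensity unit
        shot = rng.poisson(np.maximum(clean, 0.0) * gamma) / gamma
        read = rng.normal(0.0, sigma / np.sqrt(2.0), size=clean.shape)
        return shot + read
    return clean + rng.normal(0.0, sigma, size=clean.shape)


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def scene_from_geometry(
    config: SceneConfig,
    tubes: Sequence[Tube],
    cell_centers_um: np.ndarray,
    noise_seed: int | None = None,
) -> tuple[tuple[ImageStack, ImageStack], SceneTruth]:
    """Render a scene from explicit geometry (the deterministic second half of
    :func:`make_scene`; useful for phantoms with hand-built tubes)."""
    from .morphometry import polyline_length_in_sphere  # local import: avoid cycle at import time

    shape = config.shape_voxels
    spacing = config.spacing_um
    vessel_mask = rasterize_tubes(tubes, shape, spacing)
    cell_centers = np.atleast_2d(np.asarray(cell_centers_um, dtype=float)).reshape(-1, 3)
    cell_mask = rasterize_balls(cell_centers, config.cell_radius_um, shape, spacing)

    if len(cell_centers):
        centroid = cell_centers.mean(axis=0)
    else:
        centroid = config.resolved_islet_center()

    length_in_roi = sum(
        polyline_length_in_sphere(t.points_um, centroid, config.roi_radius_um) for t in tubes
    )
    truth = SceneTruth(
        tube_centerlines=list(tubes),
        vessel_mask=SegmentationMask(vessel_mask, spacing),
        cell_centers_um=cell_centers,
        cell_mask=SegmentationMask(cell_mask, spacing),
        islet_centroid_um=centroid,
        roi_radius_um=config.roi_radius_um,
        centerline_length_in_roi_um=float(length_in_roi),
    )

    if noise_seed is None:
        noise_ss = np.random.SeedSequence(config.seed).spawn(3)[2]
    else:
        noise_ss = np.random.SeedSequence(noise_seed)
    rng_v, rng_c = (np.random.default_rng(s) for s in noise_ss.spawn(2))
    vessel = ImageStack(_render_channel(vessel_mask, config, rng_v), spacing, "vessel")
    cell = ImageStack(_render_channel(cell_mask, config, rng_c), spacing, "cell")
    return (vessel, cell), truth


def make_scene(
    config: SceneConfig,
    noise_seed: int | None = None,
) -> tuple[tuple[ImageStack, ImageStack], SceneTruth]:
    """Generate one two-channel scene with ground truth.

    Identical ``config`` (including its ``seed``) gives bit-identical output.
    Passing ``noise_seed`` redraws only the noise: the geometry — and hence
    the truth masks — stays fixed by ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    tube_root, cell_root, _ = root.spawn(3)
    tubes = [
        _random_tube(np.random.default_rng(s), config)
        for s in tube_root.spawn(config.n_tubes)
    ]
    cells = _draw_cells(np.random.default_rng(cell_root), config)
    return scene_from_geometry(config, tubes, cells, noise_seed=noise_seed)


def make_cohort(cohort: CohortConfig) -> list[CohortScene]:
    """Generate a paired control/mutant cohort.

    Subject ``i`` of each group shares the same geometry seed, so with
    ``density_scale_mutant = 1`` the mutant's tubes are the control's tubes
    with radii multiplied by ``diameter_scale_mutant`` exactly.
    """
    seeds = np.random.SeedSequence(cohort.seed).generate_state(cohort.n_per_group)
    seeds = (seeds & 0x7FFFFFFF).tolist()
    base = cohort.base
    lo, hi = base.tube_radius_range_um
    mut_tubes = max(1, round(base.n_tubes * cohort.density_scale_mutant)) if base.n_tubes else 0
    scenes: list[CohortScene] = []
    for group, cfg_of in (
        ("control", lambda s: replace(base, seed=s)),
        (
            "mutant",
            lambda s: replace(
                base,
                seed=s,
                n_tubes=mut_tubes,
                tube_radius_range_um=(
                    lo * cohort.diameter_scale_mutant,
                    hi * cohort.diameter_scale_mutant,
                ),
            ),
        ),
    ):
        for i, s in enumerate(seeds, start=1):
            stacks, truth = make_scene(cfg_of(int(s)))
            scenes.append(CohortScene(f"{group}_{i}", group, stacks, truth))
    return scenes
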