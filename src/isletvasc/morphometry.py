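"""Quantitative readouts: spherical-ROI vascular statistics, integrated
fluorescence density, cell counts, fin-regrowth normalization and qPCR
relative expression.

The vascular readout restricts the diameter-annotated centerline to a sphere
of fixed physical radius (default 100 µm = 0.1 mm) centred on the β-cell
centroid and reports:

* vessel density — total in-ROI centerline length per ROI volume (µm⁻²),
  with polyline segments clipped exactly at the sphere boundary;
* mean and SD of the in-ROI per-point diameters;
* capillary count — connected centerline components with ≥ 1 in-ROI point;
* vessel volume fraction — in-ROI foreground voxels over in-ROI voxels
  (secondary readout).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .centerline import Centerline
from .io_stack import ImageStack, SegmentationMask

__all__ = [
    "SphericalRoi",
    "RoiStats",
    "CtTable",
    "roi_stats",
    "integrated_density",
    "count_cells",
    "normalized_regrowth",
    "relative_expression",
    "load_ct_table",
    "polyline_length_in_sphere",
]

DEFAULT_ROI_RADIUS_UM = 100.0  # the fixed 0.1 mm analysis sphere
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SphericalRoi:
    """Spherical analysis region: centre (µm, z/y/x) and radius (µm)."""

    center_um: np.ndarray
    radius_um: float = DEFAULT_ROI_RADIUS_UM

    def __post_init__(self) -> None:
        self.center_um = np.asarray(self.center_um, dtype=float).reshape(3)
        self.radius_um = float(self.radius_um)
        if self.radius_um <= 0:
            raise ValueError("ROI radius must be > 0")

    @property
    def volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_um**3


@dataclass
class RoiStats:
    """Vascular summary inside a spherical ROI.

    When no centerline point falls inside the ROI the diameter moments are
    undefined: ``diameters_defined`` is False and the means are NaN (never
    silently zero).
    """

    density_um_per_um3: float
    mean_diameter_um: float
    sd_diameter_um: float
    n_capillaries: int
    vessel_volume_fraction: float
    total_length_um: float
    n_points: int

    @property
    def diameters_defined(self) -> bool:
        return self.n_points > 0


def polyline_length_in_sphere(points_um: np.ndarray, center_um, radius_um: float) -> float:
    """Exact length of the part of a polyline inside a sphere.

    Each segment is clipped analytically at the sphere boundary (roots of the
    quadratic |p0 + t·(p1−p0) − c|² = r²), so tubes crossing the ROI edge
    contribute without bias.
    """
    pts = np.asarray(points_um, dtype=float)
    if len(pts) < 2:
        return 0.0
    c = np.asarray(center_um, dtype=float)
    r2 = float(radius_um) ** 2
    p0 = pts[:-1] - c
    d = pts[1:] - pts[:-1]
    a = np.einsum("ij,ij->i", d, d)
    b = np.einsum("ij,ij->i", p0, d)
    cc = np.einsum("ij,ij->i", p0, p0) - r2
    total = 0.0
    seg_len = np.sqrt(a)
    for i in range(len(a)):
        if a[i] == 0.0:
            continue
        disc = b[i] * b[i] - a[i] * cc[i]
        if disc <= 0.0:  # segment line misses (or grazes) the sphere
            continue
        sq = math.sqrt(disc)
        t0 = (-b[i] - sq) / a[i]
        t1 = (-b[i] + sq) / a[i]
        lo = max(t0, 0.0)
        hi = min(t1, 1.0)
        if hi > lo:
            total += (hi - lo) * seg_len[i]
    return total


def roi_stats(
    cline: Centerline,
    mask: SegmentationMask,
    roi: SphericalRoi | None = None,
) -> RoiStats:
    """Vascular statistics of a diameter-annotated centerline inside a
    spherical ROI (default radius 100 µm)."""
    if roi is None:
        raise ValueError("roi is required; construct SphericalRoi(center_um) for the 100 µm default")
    spacing = np.asarray(mask.spacing_um, dtype=float)
    extent = np.array(mask.shape) * spacing
    if np.any(roi.center_um + roi.radius_um < 0) or np.any(roi.center_um - roi.radius_um > extent):
        raise ValueError(
            f"ROI (centre {roi.center_um} µm, radius {roi.radius_um} µm) lies entirely "
            f"outside the stack extent {extent} µm"
        )

    total_len = 0.0
    diam = []
    comps_hit = set()
    for bi, branch in enumerate(cline.branches):
        total_len += polyline_length_in_sphere(branch.points_um, roi.center_um, roi.radius_um)
        dist = np.linalg.norm(branch.points_um - roi.center_um, axis=1)
        inside = dist <= roi.radius_um
        if inside.any():
            comps_hit.add(cline.component_ids[bi] if cline.component_ids else bi)
            if branch.radii_um is None:
                raise ValueError("centerline has no radii; run assign_diameters first")
            diam.append(2.0 * branch.radii_um[inside])

    diam = np.concatenate(diam) if diam else np.array([])
    mean_d = float(diam.mean()) if diam.size else float("nan")
    sd_d = float(diam.std(ddof=0)) if diam.size else float("nan")

    vf = _volume_fraction(mask, roi, spacing)
    return RoiStats(
        density_um_per_um3=total_len / roi.volume_um3,
        mean_diameter_um=mean_d,
        sd_diameter_um=sd_d,
        n_capillaries=len(comps_hit),
        vessel_volume_fraction=vf,
        total_length_um=total_len,
        n_points=int(diam.size),
    )


def _volume_fraction(mask: SegmentationMask, roi: SphericalRoi, spacing) -> float:
    lo = np.clip(np.floor((roi.center_um - roi.radius_um) / spacing).astype(int), 0, mask.shape)
    hi = np.clip(np.ceil((roi.center_um + roi.radius_um) / spacing).astype(int) + 1, 0, mask.shape)
    if not (hi > lo).all():
        return 0.0
    grids = np.meshgrid(
        *[np.arange(lo[a], hi[a]) * spacing[a] - roi.center_um[a] for a in range(3)],
        indexing="ij",
        sparse=True,
    )
    in_roi = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= roi.radius_um**2
    n_in = int(in_roi.sum())
    if n_in == 0:
        return 0.0
    sub = mask.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return float((sub & in_roi).sum()) / n_in


# ---------------------------------------------------------------------------
# Scalar readouts
# ---------------------------------------------------------------------------

def integrated_density(stack: ImageStack, region=None) -> float:
    """Sum of voxel intensities over a region (raw integrated density,
    identical to region size × mean intensity).

    ``region`` may be a :class:`SegmentationMask`, a tuple of three
    ``(start, stop)`` index pairs (a box, z/y/x), or None for the whole stack.
    An empty region yields 0 with a warning.
    """
    vox = np.asarray(stack.voxels, dtype=np.float64)
    if region is None:
        sel = vox
    elif isinstance(region, SegmentationMask):
        if region.shape != stack.shape:
            raise ValueError("region mask shape does not match the stack")
        sel = vox[region.voxels]
    else:
        (z0, z1), (y0, y1), (x0, x1) = region
        if not (0 <= z0 <= z1 <= stack.shape[0] and 0 <= y0 <= y1 <= stack.shape[1]
                and 0 <= x0 <= x1 <= stack.shape[2]):
            raise ValueError(f"box {region} does not fit inside stack shape {stack.shape}")
        sel = vox[z0:z1, y0:y1, x0:x1]
    if sel.size == 0:
        warnings.warn("integrated_density over an empty region", UserWarning)
        return 0.0
    return float(sel.sum())


def count_cells(mask: SegmentationMask, min_volume_um3: float = 0.0) -> int:
    """Number of 26-connected components with volume ≥ ``min_volume_um3``."""
    if not mask.voxels.any():
        return 0
    labels, n = ndimage.label(mask.voxels, structure=_STRUCT26)
    if min_volume_um3 <= 0:
        return int(n)
    counts = np.bincount(labels.ravel())[1:]
    return int(np.sum(counts * mask.voxel_volume_um3 >= min_volume_um3))


def normalized_regrowth(area_um2: float, dv_length_um: float) -> float:
    """Fin regrowth normalized for fish size: regenerated area divided by the
    dorso-ventral fin length at the amputation site (returns µm)."""
    if dv_length_um <= 0:
        raise ValueError("dorso-ventral length must be > 0")
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    return area_um2 / dv_length_um


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """qPCR threshold-cycle table with designated reference genes.

    ``data`` rows: (sample_id, gene, ct).  Reference Cts are combined by
    arithmetic mean (the geometric mean of the linear quantities), the
    standard multi-reference normalization; with one reference gene this is
    plain ΔΔCt.
    """

    data: pd.DataFrame
    reference_genes: tuple[str, ...]
    calibrator: str | None = None

    def __post_init__(self) -> None:
        need = {"sample_id", "gene", "ct"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"CtTable needs columns {sorted(need)}")
        self.reference_genes = tuple(self.reference_genes)
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        vals = self.data["ct"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("Ct values must be finite")
        for s in self.data["sample_id"].unique():
            have = set(self.data.loc[self.data["sample_id"] == s, "gene"])
            missing = set(self.reference_genes) - have
            if missing:
                raise ValueError(f"sample {s!r} lacks reference gene(s) {sorted(missing)}")

    def ct(self, sample: str, gene: str) -> float:
        rows = self.data[(self.data["sample_id"] == sample) & (self.data["gene"] == gene)]
        if rows.empty:
            raise KeyError(f"no Ct for sample {sample!r}, gene {gene!r}")
        return float(rows["ct"].mean())  # technical replicates average

    def reference_ct(self, sample: str) -> float:
        return float(np.mean([self.ct(sample, g) for g in self.reference_genes]))


def load_ct_table(path, reference_genes, calibrator=None) -> CtTable:
    df = pd.read_csv(path)
    return CtTable(data=df, reference_genes=tuple(reference_genes), calibrator=calibrator)


def relative_expression(
    ct: CtTable,
    target_gene: str,
    sample: str,
    calibrator: str | None = None,
) -> float:
    """Fold change of ``target_gene`` in ``sample`` relative to the calibrator
    by the comparative-Ct method: 2^(−ΔΔCt), with ΔCt = Ct_target − mean
    reference Ct."""
    calibrator = calibrator or ct.calibrator
    if calibrator is None:
        raise ValueError("no calibrator sample designated")
    d_sample = ct.ct(sample, target_gene) - ct.reference_ct(sample)
    d_cal = ct.ct(calibrator, target_gene) - ct.reference_ct(calibrator)
    return float(2.0 ** (-(d_sample - d_cal)))
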