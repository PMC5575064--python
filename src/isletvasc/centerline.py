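"""Distance-to-boundary fields, vessel centerlines and per-point diameters.

The distance field solves the unit-speed eikonal equation from the
foreground/background interface with a multi-stencil fast-marching (MSFM)
scheme: upwind updates over the axis-aligned stencil frame plus the three
plane-diagonal frames, second-order where two accepted upwind values are
available, first-order fallback near the interface.  Interface voxels are
seeded with their exact distance to the nearest background voxel centre, so
the field follows the Euclidean distance-transform convention (distance
between voxel centres); conversion to an inscribed radius subtracts half a
voxel to refer distances to the sub-voxel interface instead (the default,
switchable).

Centerlines are obtained by 3D thinning of the (edge-padded) mask, pruned of
spurs shorter than a multiple of the local radius, and converted to branch
polylines in physical micrometres.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.ndimage import map_coordinates
from skimage.morphology import skeletonize

from .io_stack import SegmentationMask

__all__ = [
    "DistanceField",
    "Branch",
    "Centerline",
    "distance_field",
    "extract_centerline",
    "assign_diameters",
]


@dataclass
class DistanceField:
    """Distance to the object boundary, in µm; exactly 0 on background."""

    values: np.ndarray
    spacing_um: tuple[float, float, float]

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Branch:
    points_um: np.ndarray  # (N, 3) z/y/x in µm
    radii_um: np.ndarray | None = None

    @property
    def length_um(self) -> float:
        if len(self.points_um) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())


@dataclass
class Centerline:
    """Branch polylines plus branch-graph adjacency.

    ``component_ids[i]`` labels the connected skeleton component branch ``i``
    belongs to; ``adjacency`` holds index pairs of branches sharing a node.
    """

    branches: list[Branch] = field(default_factory=list)
    component_ids: list[int] = field(default_factory=list)
    adjacency: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))

    def all_points_um(self) -> np.ndarray:
        if not self.branches:
            return np.zeros((0, 3))
        return np.concatenate([b.points_um for b in self.branches], axis=0)


# ---------------------------------------------------------------------------
# Multi-stencil fast marching
# ---------------------------------------------------------------------------

_STRUCT26_ND = np.ones((3, 3, 3), dtype=bool)

_OFFSETS26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def _stencil_frames(spacing):
    """Orthogonal stencil frames: axes always; plane diagonals where the two
    participating axes share a spacing (diagonal directions are otherwise not
    orthogonal in physical coordinates)."""
    hz, hy, hx = spacing
    frames_d = [np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1)], dtype=np.int64)]
    frames_s = [np.array([hz, hy, hx])]
    if math.isclose(hy, hx, rel_tol=1e-9):
        frames_d.append(np.array([(0, 1, 1), (0, 1, -1), (1, 0, 0)], dtype=np.int64))
        frames_s.append(np.array([hy * math.sqrt(2), hy * math.sqrt(2), hz]))
    if math.isclose(hz, hy, rel_tol=1e-9):
        frames_d.append(np.array([(1, 1, 0), (1, -1, 0), (0, 0, 1)], dtype=np.int64))
        frames_s.append(np.array([hz * math.sqrt(2), hz * math.sqrt(2), hx]))
    if math.isclose(hz, hx, rel_tol=1e-9):
        frames_d.append(np.array([(1, 0, 1), (1, 0, -1), (0, 1, 0)], dtype=np.int64))
        frames_s.append(np.array([hz * math.sqrt(2), hz * math.sqrt(2), hy]))
    return np.stack(frames_d), np.stack(frames_s)


@njit(cache=True)
def _upwind_value(d, state, fg, z, y, x, dz, dy, dx, nz, ny, nx):
    """(first, second) accepted foreground values along one stencil direction.

    Background voxels never feed the solve: the boundary condition enters
    exclusively through the exact-distance interface seeds, which keeps the
    field on the voxel-centre (EDT) convention.
    """
    z1, y1, x1 = z + dz, y + dy, x + dx
    v1 = np.inf
    v2 = np.inf
    if (
        0 <= z1 < nz and 0 <= y1 < ny and 0 <= x1 < nx
        and fg[z1, y1, x1] and state[z1, y1, x1] == 2
    ):
        v1 = d[z1, y1, x1]
        z2, y2, x2 = z + 2 * dz, y + 2 * dy, x + 2 * dx
        if (
            0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx
            and fg[z2, y2, x2] and state[z2, y2, x2] == 2
        ):
            v2 = d[z2, y2, x2]
    return v1, v2


@njit(cache=True)
def _solve_frame(d, state, fg, z, y, x, dirs, lens, nz, ny, nx):
    """Upwind eikonal solve in one orthogonal stencil frame."""
    # per frame-axis: availability, near value, (p, q) of the linear term p*T - q
    t1 = np.empty(3)
    pp = np.empty(3)
    qq = np.empty(3)
    avail = np.zeros(3, dtype=np.uint8)
    for i in range(3):
        dz, dy, dx = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        a1, a2 = _upwind_value(d, state, fg, z, y, x, dz, dy, dx, nz, ny, nx)
        b1, b2 = _upwind_value(d, state, fg, z, y, x, -dz, -dy, -dx, nz, ny, nx)
        if b1 < a1:
            a1, a2 = b1, b2
        if a1 == np.inf:
            continue
        s = lens[i]
        avail[i] = 1
        t1[i] = a1
        if a2 != np.inf and a2 <= a1:
            pp[i] = 3.0 / (2.0 * s)
            qq[i] = (4.0 * a1 - a2) / (2.0 * s)
        else:
            pp[i] = 1.0 / s
            qq[i] = a1 / s
    # solve, dropping non-causal axes (largest near value first)
    while True:
        a = 0.0
        b = 0.0
        c = -1.0
        n_used = 0
        tmax = 0.0
        imax = -1
        for i in range(3):
            if avail[i]:
                a += pp[i] * pp[i]
                b += pp[i] * qq[i]
                c += qq[i] * qq[i]
                n_used += 1
                if imax < 0 or t1[i] > tmax:
                    tmax = t1[i]
                    imax = i
        if n_used == 0:
            return np.inf
        disc = b * b - a * c
        if disc >= 0.0:
            t = (b + math.sqrt(disc)) / a
            if n_used == 1 or t >= tmax:
                return t
        avail[imax] = 0  # non-causal or inconsistent: drop farthest axis


@njit(cache=True)
def _march(d, state, fg, frames_d, frames_s, seeds_z, seeds_y, seeds_x, seeds_v):
    """Fast-marching expansion.  ``state``: 0 = far/trial, 2 = accepted.

    Seed voxels arrive already accepted (exact interface-band distances) and
    are only expanded, never re-valued."""
    nz, ny, nx = fg.shape
    n_seeds = seeds_v.shape[0]
    cap = 8 * max(int(np.sum(fg)), 1) + 26 * n_seeds + 64
    heap_v = np.empty(cap, dtype=np.float64)
    heap_i = np.empty(cap, dtype=np.int64)
    expanded = np.zeros(fg.shape, dtype=np.uint8)
    size = 0

    for k in range(n_seeds):
        z, y, x = seeds_z[k], seeds_y[k], seeds_x[k]
        d[z, y, x] = seeds_v[k]
        state[z, y, x] = 2
        heap_v[size] = seeds_v[k]
        heap_i[size] = (z * ny + y) * nx + x
        size = _sift_up(heap_v, heap_i, size)

    while size > 0:
        v = heap_v[0]
        idx = heap_i[0]
        size = _pop(heap_v, heap_i, size)
        z = idx // (ny * nx)
        y = (idx // nx) % ny
        x = idx % nx
        if expanded[z, y, x]:
            continue
        expanded[z, y, x] = 1
        if state[z, y, x] != 2:
            state[z, y, x] = 2
            d[z, y, x] = v
        for n in range(26):
            zn = z + _OFF[n, 0]
            yn = y + _OFF[n, 1]
            xn = x + _OFF[n, 2]
            if zn < 0 or zn >= nz or yn < 0 or yn >= ny or xn < 0 or xn >= nx:
                continue
            if not fg[zn, yn, xn] or state[zn, yn, xn] == 2:
                continue
            best = d[zn, yn, xn]
            for f in range(frames_d.shape[0]):
                t = _solve_frame(d, state, fg, zn, yn, xn, frames_d[f], frames_s[f], nz, ny, nx)
                if t < best:
                    best = t
            if best < d[zn, yn, xn]:
                d[zn, yn, xn] = best
                if size >= cap:  # grow
                    new_cap = cap * 2
                    hv = np.empty(new_cap, dtype=np.float64)
                    hi = np.empty(new_cap, dtype=np.int64)
                    hv[:size] = heap_v[:size]
                    hi[:size] = heap_i[:size]
                    heap_v = hv
                    heap_i = hi
                    cap = new_cap
                heap_v[size] = best
                heap_i[size] = (zn * ny + yn) * nx + xn
                size = _sift_up(heap_v, heap_i, size)
    return d


@njit(cache=True)
def _sift_up(hv, hi, size):
    i = size
    v, ix = hv[i], hi[i]
    while i > 0:
        p = (i - 1) // 2
        if hv[p] <= v:
            break
        hv[i] = hv[p]
        hi[i] = hi[p]
        i = p
    hv[i] = v
    hi[i] = ix
    return size + 1


@njit(cache=True)
def _pop(hv, hi, size):
    size -= 1
    if size > 0:
        v, ix = hv[size], hi[size]
        i = 0
        while True:
            l = 2 * i + 1
            if l >= size:
                break
            r = l + 1
            c = l
            if r < size and hv[r] < hv[l]:
                c = r
            if hv[c] >= v:
                break
            hv[i] = hv[c]
            hi[i] = hi[c]
            i = c
        hv[i] = v
        hi[i] = ix
    return size


# module-level constant for numba
_OFF = _OFFSETS26


def distance_field(mask: SegmentationMask) -> DistanceField:
    """Distance of every foreground voxel from the object boundary (µm).

    Empty mask → all-zero field.  All-foreground mask → error (no boundary
    exists to measure from).
    """
    fg = np.ascontiguousarray(mask.voxels)
    spacing = np.asarray(mask.spacing_um, dtype=float)
    if not fg.any():
        return DistanceField(np.zeros(fg.shape, dtype=np.float64), mask.spacing_um)
    if fg.all():
        raise ValueError("mask is entirely foreground: no boundary to measure distance from")

    # Exact-distance initialization in a narrow interface band: every
    # foreground voxel within 3 voxel steps of background gets its exact
    # distance to the nearest background voxel centre (the nearest background
    # voxel always lies on the foreground-facing background surface, so a
    # KD-tree over that surface suffices).  Marching continues inward.
    bg = ~fg
    from scipy.spatial import cKDTree

    bg_surface = bg & ndimage.binary_dilation(fg, _STRUCT26_ND)
    band = fg & ndimage.binary_dilation(bg, _STRUCT26_ND, iterations=3)
    surf_idx = np.argwhere(bg_surface)
    band_idx = np.argwhere(band)
    tree = cKDTree(surf_idx * spacing)
    seed_vals, _ = tree.query(band_idx * spacing, k=1)

    d = np.full(fg.shape, np.inf)
    d[bg] = 0.0
    state = np.zeros(fg.shape, dtype=np.uint8)
    state[bg] = 2
    frames_d, frames_s = _stencil_frames(spacing)
    d = _march(
        d,
        state,
        fg,
        frames_d,
        frames_s,
        np.ascontiguousarray(band_idx[:, 0]),
        np.ascontiguousarray(band_idx[:, 1]),
        np.ascontiguousarray(band_idx[:, 2]),
        np.ascontiguousarray(seed_vals),
    )
    d[bg] = 0.0
    d[~np.isfinite(d)] = 0.0  # unreached foreground (isolated from any boundary) — none in practice
    return DistanceField(d, mask.spacing_um)


# ---------------------------------------------------------------------------
# Skeleton → branch polylines
# ---------------------------------------------------------------------------

def extract_centerline(
    mask: SegmentationMask,
    dfield: DistanceField,
    prune_factor: float = 1.5,
) -> Centerline:
    """One-voxel-wide centerline of a tubular mask as branch polylines (µm).

    The mask is edge-padded before thinning so tubes cut by the volume faces
    keep their skeleton up to the face instead of being rounded off; spur
    branches shorter than ``prune_factor`` × the local radius are removed.
    """
    fg = mask.voxels
    if not fg.any():
        return Centerline()
    spacing = np.asarray(mask.spacing_um, dtype=float)
    pad = int(np.ceil(float(dfield.values.max()) / float(spacing.min()))) + 1
    padded = np.pad(fg, pad, mode="edge")
    skel = skeletonize(padded)
    skel = skel[pad:-pad, pad:-pad, pad:-pad] & fg

    voxels = [tuple(v) for v in np.argwhere(skel)]
    if not voxels:  # thinning of a tiny blob can vanish inside the volume
        # fall back to the distance-field maximum as a single-point centerline
        zmax = np.unravel_index(np.argmax(dfield.values), dfield.values.shape)
        voxels = [tuple(int(i) for i in zmax)]
    adj = _voxel_adjacency(voxels)

    # spur pruning against the local radius
    for _ in range(3):
        removed = _prune_spurs(adj, dfield, spacing, prune_factor)
        if not removed:
            break

    return _to_polylines(adj, spacing)


def _voxel_adjacency(voxels):
    vset = set(voxels)
    adj = {v: [] for v in voxels}
    for v in voxels:
        z, y, x = v
        for dz, dy, dx in _OFFSETS26:
            n = (z + dz, y + dy, x + dx)
            if n in vset:
                adj[v].append(n)
    _reduce_triangles(adj)
    return adj


def _reduce_triangles(adj) -> None:
    """Drop redundant diagonal edges of 26-connectivity cliques.

    A thinning skeleton is one voxel wide, but in 26-connectivity mutually
    adjacent voxel triples form triangles whose diagonals masquerade as extra
    micro-branches at junctions.  Removing, longest first, every edge whose
    endpoints stay connected through a common neighbour keeps the graph's
    connectivity and paths while eliminating the clutter."""
    edges = []
    for v, ns in adj.items():
        for n in ns:
            if v < n:
                d2 = sum((a - b) ** 2 for a, b in zip(v, n))
                edges.append((d2, v, n))
    edges.sort(reverse=True)
    for d2, v, n in edges:
        if d2 == 1:
            break  # face edges are never redundant shortcuts
        if n in adj[v] and set(adj[v]) & set(adj[n]):
            adj[v].remove(n)
            adj[n].remove(v)


def _branch_paths(adj):
    """Decompose the skeleton graph into maximal degree-2 paths."""
    deg = {v: len(ns) for v, ns in adj.items()}
    nodes = [v for v, d in deg.items() if d != 2]
    visited_edges = set()
    paths = []

    def walk(start, nxt):
        path = [start, nxt]
        visited_edges.add((start, nxt))
        visited_edges.add((nxt, start))
        cur, prev = nxt, start
        while deg[cur] == 2:
            a, b = adj[cur]
            nxt2 = a if a != prev else b
            if (cur, nxt2) in visited_edges:
                break
            visited_edges.add((cur, nxt2))
            visited_edges.add((nxt2, cur))
            path.append(nxt2)
            prev, cur = cur, nxt2
        return path

    for v in nodes:
        for n in adj[v]:
            if (v, n) not in visited_edges:
                paths.append(walk(v, n))
    # pure cycles (no node of degree != 2)
    seen = {p for path in paths for p in path}
    for v in adj:
        if v in seen or deg[v] != 2:
            continue
        for n in adj[v]:
            if (v, n) not in visited_edges:
                path = walk(v, n)
                paths.append(path)
                seen.update(path)
    # isolated voxels
    for v, d in deg.items():
        if d == 0:
            paths.append([v])
    return paths


def _prune_spurs(adj, dfield, spacing, prune_factor) -> int:
    deg = {v: len(ns) for v, ns in adj.items()}
    paths = _branch_paths(adj)
    removed = 0
    for path in paths:
        if len(path) < 2:
            continue
        end_a, end_b = path[0], path[-1]
        a_term = deg[end_a] == 1
        b_term = deg[end_b] == 1
        if not (a_term ^ b_term):  # prune only junction-to-endpoint spurs
            continue
        pts = np.array(path, dtype=float) * spacing
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        junction = end_b if a_term else end_a
        r = float(dfield.values[junction])
        if length < prune_factor * max(r, float(spacing.min())):
            keep = {junction}
            for v in path:
                if v not in keep and v in adj:
                    for n in adj.pop(v):
                        if n in adj and v in adj[n]:
                            adj[n].remove(v)
                    removed += 1
    return removed


def _to_polylines(adj, spacing) -> Centerline:
    paths = _branch_paths(adj)
    if not paths and adj:  # single voxel or tiny ring remnants
        paths = [[v] for v in adj]
    # connected components over skeleton voxels
    comp = {}
    cid = 0
    for v in adj:
        if v in comp:
            continue
        stack = [v]
        comp[v] = cid
        while stack:
            u = stack.pop()
            for n in adj[u]:
                if n not in comp:
                    comp[n] = cid
                    stack.append(n)
        cid += 1

    branches = []
    comp_ids = []
    endpoint_owner: dict[tuple, list[int]] = {}
    for path in paths:
        pts = np.array(path, dtype=float) * spacing
        pts = _smooth_polyline(pts)
        branches.append(Branch(points_um=pts))
        comp_ids.append(comp.get(path[0], 0))
        for end in (path[0], path[-1]):
            endpoint_owner.setdefault(end, []).append(len(branches) - 1)
    adjacency = set()
    for owners in endpoint_owner.values():
        for i in owners:
            for j in owners:
                if i < j:
                    adjacency.add((i, j))
    return Centerline(branches=branches, component_ids=comp_ids, adjacency=adjacency)


def _smooth_polyline(pts: np.ndarray, passes: int = 2) -> np.ndarray:
    """3-point moving average of interior points (endpoints fixed).

    Undoes the voxel staircase: a digital 26-connected chain overestimates the
    smooth curve's length by up to ~8%, and its points wobble around the true
    axis; averaging recovers sub-voxel positions."""
    if len(pts) < 3:
        return pts
    out = pts.astype(float).copy()
    for _ in range(passes):
        out[1:-1] = (out[:-2] + out[1:-1] + out[2:]) / 3.0
    return out


# ---------------------------------------------------------------------------
# Diameters
# ---------------------------------------------------------------------------

def assign_diameters(
    cline: Centerline,
    dfield: DistanceField,
    interface_correction: bool = False,
) -> Centerline:
    """Attach a radius (µm) to every centerline point from the distance field.

    The radius is the trilinearly interpolated distance value (voxel
    centre-to-centre convention).  With ``interface_correction`` half the
    finest voxel spacing is subtracted to refer distances to the sub-voxel
    interface instead; at the medial axis of discretized tubes the nearest
    background centre already sits almost exactly on the true boundary, so
    the uncorrected convention is the less biased default.  Points on
    background are an error (they indicate a mask/centerline mismatch),
    reported with branch and point index.
    """
    spacing = np.asarray(dfield.spacing_um, dtype=float)
    corr = 0.5 * float(spacing.min()) if interface_correction else 0.0
    floor = 0.25 * float(spacing.min())
    out = Centerline(branches=[], component_ids=list(cline.component_ids),
                     adjacency=set(cline.adjacency))
    for bi, branch in enumerate(cline.branches):
        pts = branch.points_um
        d = _sample(dfield, pts / spacing)
        if (d <= 0).any():
            pi = int(np.argmax(d <= 0))
            raise ValueError(
                f"centerline branch {bi}, point {pi} at {pts[pi]} µm lies outside "
                "the foreground of the distance field"
            )
        d = np.maximum(d, _tent_fit_radius(pts, d, dfield, spacing))
        radii = np.maximum(d - corr, floor)
        out.branches.append(Branch(points_um=pts.copy(), radii_um=radii))
    return out


def _sample(dfield: DistanceField, coords_vox: np.ndarray) -> np.ndarray:
    return map_coordinates(dfield.values, coords_vox.T, order=1, mode="nearest")


def _tent_fit_radius(pts: np.ndarray, d_center: np.ndarray, dfield: DistanceField,
                     spacing: np.ndarray) -> np.ndarray:
    """Apex of the cross-vessel distance profile at each centerline point.

    Inside a tube the distance field is a tent, d(q) ≈ r − |q_perp − axis|,
    so trilinear sampling at a point offset from the (sub-voxel) medial axis
    understates the radius by the full offset — up to half a voxel along each
    axis, which matters on coarse/anisotropic grids.  For perpendicular
    directions n and half-width t, (d(p+tn) + d(p−tn))/2 + t equals r
    whenever the axis offset is parallel to n with magnitude ≤ t, and never
    exceeds r while both samples stay under the same tent.  The maximum of
    this estimate over a small set of directions and widths is therefore a
    tight, one-sided reconstruction of the local radius."""
    if len(pts) == 0:
        return d_center
    tang = np.gradient(pts, axis=0) if len(pts) > 1 else np.zeros((len(pts), 3))
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = np.where(norms > 1e-9, tang / np.maximum(norms, 1e-9), [[0.0, 0.0, 1.0]])
    # perpendicular frame per point
    ref = np.where(np.abs(tang[:, :1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e1 = np.cross(tang, ref)
    e1 /= np.maximum(np.linalg.norm(e1, axis=1, keepdims=True), 1e-9)
    e2 = np.cross(tang, e1)

    # one half-width of the finest voxel covers the skeleton's sub-voxel
    # wobble; wider probes start bridging neighbouring tents at junctions
    # and inflate the estimate
    t = float(spacing.min())
    best = d_center.copy()
    lim = t <= 1.2 * d_center  # keep samples under the local tent
    for theta in np.linspace(0.0, np.pi, 6, endpoint=False):
        n = np.cos(theta) * e1 + np.sin(theta) * e2
        dp = _sample(dfield, (pts + t * n) / spacing)
        dm = _sample(dfield, (pts - t * n) / spacing)
        est = 0.5 * (dp + dm) + t
        est = np.where(lim & (dp > 0) & (dm > 0), est, 0.0)
        best = np.maximum(best, est)
    return best
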