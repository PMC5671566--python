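"""Distance-map Rayburst sampling.

From each centroid candidate a near-uniform core of rays is cast through the
Euclidean distance map (not the image intensity).  Along a ray leaving a
soma centre the distance value decreases; it reaches zero at the background
(isolated surface) or passes through a regional minimum in the neck between
touching somata.  Each ray therefore stops at the first of:

* background — the interpolated distance falls to the half-voxel surface
  level (d = 0.5, the material boundary between the last foreground and the
  first background voxel centre), located by linear sub-step refinement;
* distance increase — the distance starts rising again after having
  strictly decreased, i.e. the ray crossed the neck minimum of a touching
  pair; the stop is placed at the local minimum sample;
* max range.

A ray additionally records an *inner* boundary: the first position where a
monotone decrease ends in a flat run (the transition from a soma's private
distance basin into the shared/uncertain region).  Where no such transition
exists the inner and outer boundaries coincide.  After casting, rays whose
outer radius exceeds alpha times the median inner radius are clipped back to
that bound — runaway rays that escaped through a thin bridge are fixed by
the ensemble's inner boundary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .localize import DistanceMap

__all__ = [
    "RayCore",
    "RaySample",
    "SurfaceSample",
    "build_ray_core",
    "cast_ray",
    "sample_surface",
]

# distance-map units are voxels of the isotropic grid
EPS_BG = 0.5  # "at surface" distance level: half a voxel from background
EPS_RISE = 1e-3  # minimum increase that counts as crossing a neck minimum
EPS_FLAT = 1e-3  # |change| below this is a flat (plateau) step


@dataclass
class RayCore:
    """A set of near-uniform unit direction vectors (antipodally symmetric)."""

    directions: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=np.float64)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("ray directions must be unit vectors")

    @property
    def count(self) -> int:
        return len(self.directions)


@dataclass
class RaySample:
    """One cast ray: direction, stop position and boundary radii."""

    direction: np.ndarray
    outer_point: np.ndarray  # (z, y, x)
    outer_radius: float
    inner_radius: Optional[float]
    stop_reason: str  # background | distance_increase | clipped_by_inner | max_range


@dataclass
class SurfaceSample:
    """All rays of one soma plus the outer-boundary point cloud."""

    centroid: np.ndarray
    rays: list[RaySample]

    @property
    def points(self) -> np.ndarray:
        return np.array([r.outer_point for r in self.rays])


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return verts, faces


def _geodesic_vertices(freq: int) -> np.ndarray:
    """Vertices of the frequency-`freq` geodesic icosahedron (10 f^2 + 2)."""
    verts, faces = _icosahedron()
    pts = []
    for a, b, c in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                k = freq - i - j
                p = (i * va + j * vb + k * vc) / freq
                pts.append(p / np.linalg.norm(p))
    pts = np.asarray(pts)
    # dedupe shared edge/corner vertices
    _, idx = np.unique(np.round(pts, 9), axis=0, return_index=True)
    return pts[np.sort(idx)]


def _antipodal_pairs(verts: np.ndarray) -> np.ndarray:
    """Pair each vertex with its antipode; returns one representative per pair."""
    used = np.zeros(len(verts), dtype=bool)
    reps = []
    for i, v in enumerate(verts):
        if used[i]:
            continue
        d = np.linalg.norm(verts + v, axis=1)
        j = int(np.argmin(d))
        if d[j] > 1e-6:
            raise RuntimeError("tessellation is not antipodally symmetric")
        used[i] = used[j] = True
        reps.append(v)
    return np.asarray(reps)


def build_ray_core(n_requested: int) -> RayCore:
    """Near-uniform direction core with exactly `n_requested` rays.

    The smallest geodesic icosahedron tessellation with at least
    `n_requested` vertices (12, 42, 92, 162, 252, 362, ...) is decimated to
    the requested count by farthest-point selection over antipodal vertex
    *pairs*, so the core stays exactly antipodally symmetric (for even n)
    and its direction vectors sum to ~0.
    """
    if n_requested < 6:
        raise ValueError("a ray core needs at least 6 directions")
    freq = 1
    while 10 * freq * freq + 2 < n_requested:
        freq += 1
    verts = _geodesic_vertices(freq)
    if len(verts) == n_requested:
        return RayCore(verts)
    reps = _antipodal_pairs(verts)
    n_pairs = n_requested // 2
    # farthest-point selection on the projective metric (pairs are lines)
    absdot = np.clip(np.abs(reps @ reps.T), 0.0, 1.0)
    angle = np.arccos(absdot)
    start = int(np.argmax(reps[:, 0]))  # deterministic: pair closest to +z
    chosen = [start]
    mind = angle[start].copy()
    while len(chosen) < n_pairs:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, angle[nxt])
    sel = reps[chosen]
    dirs = np.concatenate([sel, -sel], axis=0)
    if n_requested % 2:
        # odd count: add the unpaired leftover direction farthest from the set
        rest = np.concatenate([np.delete(reps, chosen, axis=0)])
        gaps = np.arccos(np.clip(np.abs(rest @ sel.T), 0, 1)).min(axis=1)
        dirs = np.concatenate([dirs, rest[int(np.argmax(gaps))][None]], axis=0)
    return RayCore(dirs)


def _sample_values(
    d: np.ndarray, origin: np.ndarray, directions: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Trilinear samples of d along origin + t*direction; outside -> 0."""
    coords = origin[None, None, :] + t[None, :, None] * directions[:, None, :]
    flat = coords.reshape(-1, 3).T
    vals = ndi.map_coordinates(d, flat, order=1, mode="constant", cval=0.0)
    return vals.reshape(len(directions), len(t))


def _scan_ray(
    v: np.ndarray, t: np.ndarray, step: float
) -> tuple[float, Optional[float], str]:
    """Apply the stopping rules to one ray's sampled distance profile."""
    diffs = np.diff(v)
    dec = diffs < -EPS_FLAT
    armed = np.concatenate([[False], np.cumsum(dec) > 0])  # armed[j]: any decrease before step j
    # background stop: first sample at/below the surface level, refined
    bg_hits = np.nonzero(v <= EPS_BG)[0]
    i_bg = int(bg_hits[0]) if len(bg_hits) else None
    # neck stop: first rise after an armed decrease
    rise = (diffs > EPS_RISE) & armed[:-1]
    rise_hits = np.nonzero(rise)[0]
    i_rise = int(rise_hits[0]) + 1 if len(rise_hits) else None  # sample index of the risen value
    # inner boundary: first flat step immediately ending a decrease run
    flat = np.abs(diffs) <= EPS_FLAT
    inner_hits = np.nonzero(flat[1:] & dec[:-1])[0]
    inner_t: Optional[float] = float(t[inner_hits[0] + 1]) if len(inner_hits) else None

    if i_bg is not None and (i_rise is None or i_bg <= i_rise):
        if i_bg == 0:
            outer = max(float(t[0]), step * 1e-3)
        else:
            v0, v1 = v[i_bg - 1], v[i_bg]
            frac = (v0 - EPS_BG) / (v0 - v1) if v0 > v1 else 1.0
            outer = float(t[i_bg - 1] + frac * step)
        reason = "background"
    elif i_rise is not None:
        outer = float(t[i_rise - 1])  # the local-minimum sample
        reason = "distance_increase"
    else:
        outer = float(t[-1])
        reason = "max_range"
    if inner_t is not None and inner_t > outer:
        inner_t = None
    if inner_t is None:
        inner_t = outer  # the two boundaries coincide (isolated surface)
    return outer, inner_t, reason


def cast_ray(
    dmap: DistanceMap | np.ndarray,
    origin,
    direction,
    step: float = 0.5,
    max_range: float = 60.0,
) -> RaySample:
    """Cast a single ray from `origin` along `direction` through the EDT."""
    d = dmap.dist if isinstance(dmap, DistanceMap) else np.asarray(dmap, dtype=np.float64)
    if not 0 < step <= 1:
        raise ValueError("ray step must be in (0, 1] voxels")
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    t = np.arange(0.0, max_range + step / 2, step)
    v = _sample_values(d, origin, direction[None, :], t)[0]
    if v[0] <= 0:
        raise ValueError("seed outside foreground: distance map is zero at the ray origin")
    outer, inner, reason = _scan_ray(v, t, step)
    return RaySample(
        direction=direction,
        outer_point=origin + outer * direction,
        outer_radius=outer,
        inner_radius=inner,
        stop_reason=reason,
    )


def sample_surface(
    dmap: DistanceMap | np.ndarray,
    centroid,
    core: RayCore,
    step: float = 0.5,
    max_range: float = 60.0,
    alpha_clip: float = 2.0,
) -> SurfaceSample:
    """Cast the whole ray core from one centroid and fix runaway rays.

    After casting, the median m of the per-ray inner radii is computed and
    every ray with outer_radius > alpha_clip * m is clipped to that bound
    (stop_reason 'clipped_by_inner').  On isolated somata inner ~ outer so
    the clip is a no-op.
    """
    d = dmap.dist if isinstance(dmap, DistanceMap) else np.asarray(dmap, dtype=np.float64)
    origin = np.asarray(centroid, dtype=np.float64)
    t = np.arange(0.0, max_range + step / 2, step)
    vals = _sample_values(d, origin, core.directions, t)
    if vals[0, 0] <= 0:
        raise ValueError("seed outside foreground: distance map is zero at the ray origin")
    rays: list[RaySample] = []
    for direction, v in zip(core.directions, vals):
        outer, inner, reason = _scan_ray(v, t, step)
        rays.append(
            RaySample(
                direction=direction,
                outer_point=origin + outer * direction,
                outer_radius=outer,
                inner_radius=inner,
                stop_reason=reason,
            )
        )
    inner_radii = [r.inner_radius for r in rays if r.inner_radius is not None]
    if inner_radii and alpha_clip > 0:
        bound = alpha_clip * float(np.median(inner_radii))
        for r in rays:
            if r.outer_radius > bound:
                r.outer_radius = bound
                r.outer_point = origin + bound * r.direction
                r.stop_reason = "clipped_by_inner"
    return SurfaceSample(centroid=origin, rays=rays)
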