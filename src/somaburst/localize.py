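"""Soma localization on the Euclidean distance transform.

Soma centroids sit far from the background, so they appear as regional
maxima of the EDT of the foreground mask.  Touching somata and rough mask
surfaces create shallow spurious maxima ("jitter"); the H-dome transform
(greyscale reconstruction by dilation) suppresses maxima whose prominence is
below the jitter height h, and each surviving maximum plateau becomes one
centroid candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima, reconstruction

from .preprocess import STRUCT_26, ForegroundMask

__all__ = [
    "DistanceMap",
    "CentroidCandidate",
    "distance_transform",
    "hdome_transform",
    "hdome_candidates",
]


@dataclass
class DistanceMap:
    """Per-voxel Euclidean distance to the nearest background voxel.

    Distances are in voxels of the isotropic grid and are exactly zero on
    background.  The volume is treated as padded with background, so
    foreground touching the stack border still gets finite distances.
    """

    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=np.float64)
        if self.dist.ndim != 3:
            raise ValueError("distance map must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dist.shape


@dataclass
class CentroidCandidate:
    """One candidate soma centroid.

    position is the (z, y, x) centroid of the regional-maximum plateau,
    snapped to the nearest plateau voxel if the plateau is non-convex;
    peak_distance is the EDT value on the plateau; plateau_size its voxel
    count.
    """

    position: tuple[float, float, float]
    peak_distance: float
    plateau_size: int


def distance_transform(mask: ForegroundMask | np.ndarray) -> DistanceMap:
    """Exact Euclidean distance transform of the foreground.

    The mask is padded with one background layer before the transform so
    that border-touching foreground is measured against virtual background
    outside the stack (border policy: process clipped somata, exclude them
    only at evaluation time if requested).
    """
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    dist = ndi.distance_transform_edt(padded)
    return DistanceMap(dist[1:-1, 1:-1, 1:-1])


def _dmap_array(dmap: DistanceMap | np.ndarray) -> np.ndarray:
    return dmap.dist if isinstance(dmap, DistanceMap) else np.asarray(dmap, dtype=np.float64)


def hdome_transform(dmap: DistanceMap | np.ndarray, h: float) -> np.ndarray:
    """H-dome image: dmap - R(dmap - h; dmap).

    R is greyscale reconstruction by dilation (26-connected) of the marker
    dmap - h under the mask dmap; the result is the classical dome image
    with values in [0, h], equal to min(prominence, h) at each maximum.
    """
    if h < 0:
        raise ValueError("jitter height h must be >= 0")
    d = _dmap_array(dmap)
    if h == 0:
        return np.zeros_like(d)
    rec = reconstruction(d - h, d, method="dilation", footprint=STRUCT_26)
    return d - rec


def hdome_candidates(dmap: DistanceMap | np.ndarray, h: float = 1.0) -> list[CentroidCandidate]:
    """Centroid candidates: regional maxima with dome height >= h.

    Regional-maximum plateaus (26-connected sets of equal maximal values)
    of the distance map whose dome height reaches the jitter height h
    survive; each yields one candidate at the plateau centroid with
    peak_distance equal to the plateau value.  h = 0 keeps every maximum.
    """
    d = _dmap_array(dmap)
    if not np.any(d > 0):
        return []
    maxima = local_maxima(d, connectivity=3, allow_borders=True)
    maxima &= d > 0
    if not maxima.any():
        # a single plateau spanning the whole foreground has no strict
        # neighbours below it only when the map is constant on its support
        maxima = d == d.max()
        maxima &= d > 0
    dome = hdome_transform(d, h) if h > 0 else None
    labels, n = ndi.label(maxima, structure=STRUCT_26)
    out: list[CentroidCandidate] = []
    for idx, com in zip(
        range(1, n + 1), ndi.center_of_mass(maxima, labels, range(1, n + 1))
    ):
        voxels = np.argwhere(labels == idx)
        value = float(d[tuple(voxels[0])])
        if dome is not None:
            height = float(dome[tuple(voxels[0])])
            if height < h - 1e-9:
                continue
        pos = np.asarray(com, dtype=float)
        # snap the centroid into the plateau if the plateau is non-convex
        nearest = voxels[np.argmin(((voxels - pos) ** 2).sum(axis=1))]
        if d[tuple(np.round(pos).astype(int).clip(0, np.array(d.shape) - 1))] <= 0:
            pos = nearest.astype(float)
        out.append(
            CentroidCandidate(
                position=tuple(pos), peak_distance=value, plateau_size=len(voxels)
            )
        )
    return out
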