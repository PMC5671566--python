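"""End-to-end segmentation pipeline and its configuration.

resample -> LoG enhancement -> Otsu -> mask cleanup -> EDT -> H-dome
candidates -> per-candidate Rayburst sampling + ellipsoid fit -> volume
filter -> label assembly.  Candidates are processed in descending
peak-distance order; a candidate whose position already lies inside a
generated segment is skipped, and voxels claimed by several ellipsoids go
to the one in whose interior they lie deepest (most negative quadric value,
normalized by the value at the ellipsoid center).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import ellipsoid as ell
from .localize import distance_transform, hdome_candidates
from .preprocess import clean_mask, enhance_foreground, otsu_binarize
from .rayburst import RayCore, SurfaceSample, build_ray_core, sample_surface
from .stack_io import ImageStack, LabelVolume, resample_isotropic

__all__ = ["PipelineConfig", "SomaSegment", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters.

    Defaults suit whole-brain optical imaging at ~0.5 um resolution, where
    somata are ~10-15 voxels in radius; set sigmas, volume_threshold and rc
    from the actual soma size of the dataset at hand.

    Units are voxels of the isotropic working grid throughout.
    """

    sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)  # LoG scales
    min_region_size: int = 200  # smallest surviving mask component
    jitter_height: float = 1.0  # H-dome prominence threshold (typical range 0-2)
    n_rays: int = 258  # sampling core size
    ray_step: float = 0.5  # ray sampling step, voxels
    max_range: float = 60.0  # longest ray, voxels
    alpha_clip: float = 2.0  # runaway-ray clip: outer <= alpha * median inner
    volume_threshold: float = 4200.0  # smallest accepted soma, voxels
    max_axis_factor: float = 1.5  # reject fits extrapolating past the sampled surface
    rc: float = 14.0  # mean soma radius, the centroid-matching tolerance
    target_voxel_size: Optional[float] = None  # isotropic target; None = min input size
    seed: int = 0  # recorded for provenance; the pipeline itself is deterministic

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["sigmas"] = tuple(data.get("sigmas", (1, 2, 3, 4)))
        return cls(**data)


@dataclass
class SomaSegment:
    """One segmented soma: seed, sampled surface, fitted ellipsoid, voxels."""

    id: int
    centroid: np.ndarray  # seed position (z, y, x) on the working grid
    surface: SurfaceSample
    coeffs: ell.QuadricCoefficients
    geometry: ell.EllipsoidGeometry
    voxels: np.ndarray  # (n, 3) indices after overlap resolution


def run_pipeline(
    stack: ImageStack, cfg: PipelineConfig | None = None
) -> tuple[LabelVolume, list[SomaSegment]]:
    """Run the full segmentation pipeline on one stack.

    Returns the label volume (on the isotropic working grid) and the list
    of accepted segments, labeled 1..K in processing order.  An empty
    foreground yields an empty result with a warning, not an exception.
    """
    cfg = cfg or PipelineConfig()
    iso = resample_isotropic(stack, cfg.target_voxel_size)
    enhanced = enhance_foreground(iso.voxels, cfg.sigmas)
    try:
        raw_mask = otsu_binarize(enhanced)
    except ValueError:
        warnings.warn("empty segmentation: enhanced volume is constant", stacklevel=2)
        return LabelVolume(np.zeros(iso.shape, dtype=np.int32), iso.voxel_size), []
    mask = clean_mask(raw_mask, cfg.min_region_size)
    if not mask.mask.any():
        warnings.warn("empty segmentation: no foreground after cleanup", stacklevel=2)
        return LabelVolume(np.zeros(iso.shape, dtype=np.int32), iso.voxel_size), []
    dmap = distance_transform(mask)
    candidates = hdome_candidates(dmap, cfg.jitter_height)
    candidates.sort(key=lambda c: -c.peak_distance)
    core = build_ray_core(cfg.n_rays)

    shape = iso.shape
    labels = np.zeros(shape, dtype=np.int32)
    depth = np.zeros(shape, dtype=np.float64)  # normalized quadric value of the owner
    segments: list[SomaSegment] = []

    for cand in candidates:
        seed_idx = tuple(np.clip(np.round(cand.position).astype(int), 0, np.array(shape) - 1))
        if labels[seed_idx] != 0:
            continue  # candidate sits inside an already-generated segment
        try:
            surface = sample_surface(
                dmap,
                cand.position,
                core,
                step=cfg.ray_step,
                max_range=cfg.max_range,
                alpha_clip=cfg.alpha_clip,
            )
            coeffs, geometry = ell.fit_ellipsoid(surface.points)
        except ValueError:
            continue  # degenerate sample or non-ellipsoid fit: drop the candidate
        # an ellipsoid is only trusted where its surface was sampled: fits on
        # cylinder-like clouds (neurites) extrapolate far beyond their data
        max_outer = max(r.outer_radius for r in surface.rays)
        if cfg.max_axis_factor > 0 and geometry.semi_axes[0] > cfg.max_axis_factor * max_outer:
            continue
        voxels = ell.voxelize(coeffs, shape)
        if len(voxels) < cfg.volume_threshold:
            continue
        # depth: quadric value normalized by the center value, in [-1, 0)
        center_val = coeffs.evaluate(geometry.center[None, :])[0]
        values = coeffs.evaluate(voxels) / abs(center_val)
        seg_id = len(segments) + 1
        vz, vy, vx = voxels[:, 0], voxels[:, 1], voxels[:, 2]
        claim = (labels[vz, vy, vx] == 0) | (values < depth[vz, vy, vx])
        labels[vz[claim], vy[claim], vx[claim]] = seg_id
        depth[vz[claim], vy[claim], vx[claim]] = values[claim]
        segments.append(
            SomaSegment(
                id=seg_id,
                centroid=np.asarray(cand.position, dtype=float),
                surface=surface,
                coeffs=coeffs,
                geometry=geometry,
                voxels=voxels,
            )
        )

    # final voxel ownership after contested-voxel resolution
    for seg in segments:
        seg.voxels = np.argwhere(labels == seg.id)
    # drop segments that lost (nearly) everything and relabel contiguously
    kept = [s for s in segments if len(s.voxels) >= cfg.volume_threshold]
    relabeled = np.zeros_like(labels)
    for new_id, seg in enumerate(kept, start=1):
        relabeled[seg.voxels[:, 0], seg.voxels[:, 1], seg.voxels[:, 2]] = new_id
        seg.id = new_id
    return LabelVolume(relabeled, iso.voxel_size), kept
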