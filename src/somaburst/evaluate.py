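"""Evaluation of localization and segmentation against ground truth.

Localization: predicted and truth centroids are matched greedily one-to-one
in ascending distance order; a pair matches iff their Euclidean distance is
strictly less than Rc, the mean soma radius.  Both the standard convention
(recall = N_correct / N_truth, precision = N_correct / N_predicted) and the
swapped labeling are reported, since both appear in the literature.

Segmentation: per-soma overlap ratio |Seg n GT| / ((|Seg| + |GT|) / 2)
(algebraically the Dice coefficient), plus volume and area ratios of the
fitted ellipsoid against the voxel-counted truth volume and its
marching-cubes surface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import measure

from .pipeline import SomaSegment
from .stack_io import LabelVolume

__all__ = [
    "EvaluationReport",
    "match_somata",
    "localization_scores",
    "overlap_ratio",
    "size_ratios",
    "evaluate_segmentation",
    "mask_surface_area",
]


@dataclass
class EvaluationReport:
    """Everything the evaluation computes, JSON-serializable via to_dict."""

    n_predicted: int
    n_truth: int
    n_correct: int
    recall: Optional[float]  # standard: N_correct / N_truth
    precision: Optional[float]  # standard: N_correct / N_predicted
    recall_as_printed: Optional[float]  # swapped-denominator labeling
    precision_as_printed: Optional[float]
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    overlap_ratios: list[float] = field(default_factory=list)
    volume_ratios: list[float] = field(default_factory=list)
    area_ratios: list[float] = field(default_factory=list)

    @property
    def mean_overlap_ratio(self) -> Optional[float]:
        return float(np.mean(self.overlap_ratios)) if self.overlap_ratios else None

    def to_dict(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_truth": self.n_truth,
            "n_correct": self.n_correct,
            "recall": self.recall,
            "precision": self.precision,
            "recall_as_printed": self.recall_as_printed,
            "precision_as_printed": self.precision_as_printed,
            "matches": [list(m) for m in self.matches],
            "overlap_ratios": self.overlap_ratios,
            "volume_ratios": self.volume_ratios,
            "area_ratios": self.area_ratios,
            "mean_overlap_ratio": self.mean_overlap_ratio,
        }


def match_somata(
    pred_centroids: np.ndarray, truth_centroids: np.ndarray, rc: float
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one centroid matching under the Rc rule.

    Candidate pairs are taken in ascending distance order; a pair matches
    iff distance < rc (strict).  Returns (pred index, truth index, distance).
    """
    if rc <= 0:
        raise ValueError("Rc must be positive")
    P = np.atleast_2d(np.asarray(pred_centroids, dtype=float))
    T = np.atleast_2d(np.asarray(truth_centroids, dtype=float))
    if P.size == 0 or T.size == 0:
        return []
    dist = np.linalg.norm(P[:, None, :] - T[None, :, :], axis=2)
    order = np.argsort(dist, axis=None)
    used_p = np.zeros(len(P), dtype=bool)
    used_t = np.zeros(len(T), dtype=bool)
    matches: list[tuple[int, int, float]] = []
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        d = float(dist[i, j])
        if d >= rc:
            break
        if used_p[i] or used_t[j]:
            continue
        used_p[i] = used_t[j] = True
        matches.append((int(i), int(j), d))
    return matches


def localization_scores(
    n_correct: int, n_pred: int, n_truth: int
) -> tuple[Optional[float], Optional[float]]:
    """Standard (recall, precision); None where the denominator is zero."""
    recall = n_correct / n_truth if n_truth > 0 else None
    precision = n_correct / n_pred if n_pred > 0 else None
    return recall, precision


def overlap_ratio(seg_voxels: np.ndarray, truth_voxels: np.ndarray) -> float:
    """|Seg n GT| / ((|Seg| + |GT|) / 2), i.e. the Dice coefficient."""
    seg = {tuple(v) for v in np.atleast_2d(np.asarray(seg_voxels, dtype=int)).reshape(-1, 3)}
    gt = {tuple(v) for v in np.atleast_2d(np.asarray(truth_voxels, dtype=int)).reshape(-1, 3)}
    if not seg and not gt:
        import warnings

        warnings.warn("overlap ratio of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * len(seg & gt) / (len(seg) + len(gt))


def mask_surface_area(voxels: np.ndarray, shape: tuple[int, int, int]) -> Optional[float]:
    """Surface area of a voxel set via a marching-cubes isosurface at 0.5."""
    mask = np.zeros(shape, dtype=np.float64)
    v = np.atleast_2d(np.asarray(voxels, dtype=int))
    if v.size == 0:
        return None
    mask[v[:, 0], v[:, 1], v[:, 2]] = 1.0
    padded = np.pad(mask, 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    except (ValueError, RuntimeError):
        return None
    return float(measure.mesh_surface_area(verts, faces))


def size_ratios(
    seg: SomaSegment, truth_voxels: np.ndarray, shape: tuple[int, int, int]
) -> tuple[float, Optional[float]]:
    """(volume ratio, area ratio) of the fitted ellipsoid vs the truth set.

    Truth volume is the voxel count; truth area comes from a marching-cubes
    mesh of the truth set.  A degenerate truth surface yields area ratio
    None; an empty (filtered) segment yields ratios 0.
    """
    truth_voxels = np.atleast_2d(np.asarray(truth_voxels, dtype=int))
    if truth_voxels.size == 0:
        raise ValueError("truth voxel set must be nonempty")
    if seg is None or len(seg.voxels) == 0:
        return 0.0, 0.0
    vol_ratio = seg.geometry.volume / len(truth_voxels)
    gt_area = mask_surface_area(truth_voxels, shape)
    area_ratio = seg.geometry.area / gt_area if gt_area else None
    return float(vol_ratio), (float(area_ratio) if area_ratio is not None else None)


def evaluate_segmentation(
    segments: list[SomaSegment],
    truth_labels: LabelVolume,
    truth_centroids: np.ndarray,
    rc: float,
    exclude_border_truth: bool = False,
) -> EvaluationReport:
    """Match segments to truth and compute all localization/shape metrics.

    With ``exclude_border_truth`` set, truth somata whose bounding box
    touches the stack border are excluded from scoring (broken somata).
    """
    truth_centroids = np.atleast_2d(np.asarray(truth_centroids, dtype=float)).reshape(-1, 3)
    shape = truth_labels.labels.shape
    truth_ids = list(range(1, truth_labels.n_labels + 1))
    truth_sets = {i: np.argwhere(truth_labels.labels == i) for i in truth_ids}

    keep = []
    for i in truth_ids:
        vox = truth_sets[i]
        if len(vox) == 0:
            continue
        if exclude_border_truth:
            lo, hi = vox.min(axis=0), vox.max(axis=0)
            if np.any(lo == 0) or np.any(hi == np.array(shape) - 1):
                continue
        keep.append(i)

    pred_centroids = np.array([s.geometry.center for s in segments]).reshape(-1, 3)
    kept_centroids = (
        truth_centroids[[i - 1 for i in keep]] if len(keep) else np.empty((0, 3))
    )
    matches = match_somata(pred_centroids, kept_centroids, rc)
    n_correct = len(matches)
    recall, precision = localization_scores(n_correct, len(segments), len(keep))
    recall_printed = n_correct / len(segments) if len(segments) else None
    precision_printed = n_correct / len(keep) if len(keep) else None

    overlaps, vol_ratios, area_ratios = [], [], []
    for pi, tj, _d in matches:
        truth_vox = truth_sets[keep[tj]]
        seg = segments[pi]
        overlaps.append(overlap_ratio(seg.voxels, truth_vox))
        vr, ar = size_ratios(seg, truth_vox, shape)
        vol_ratios.append(vr)
        if ar is not None:
            area_ratios.append(ar)

    return EvaluationReport(
        n_predicted=len(segments),
        n_truth=len(keep),
        n_correct=n_correct,
        recall=recall,
        precision=precision,
        recall_as_printed=recall_printed,
        precision_as_printed=precision_printed,
        matches=matches,
        overlap_ratios=overlaps,
        volume_ratios=vol_ratios,
        area_ratios=area_ratios,
    )
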