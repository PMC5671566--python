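"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from somaburst.phantom import render_phantom, suite_spec


def digital_ball(shape, center, radius) -> np.ndarray:
    """Binary mask of lattice points within `radius` of `center`."""
    idx = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(idx, center))
    return d2 <= radius * radius


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """O(N^2) nearest-background distance, treating outside as background.

    Independent oracle for the Euclidean distance transform: for every
    foreground voxel the minimum Euclidean distance to any background voxel
    of the one-layer-padded mask is found by exhaustive search.
    """
    padded = np.pad(mask.astype(bool), 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape, dtype=float)
    if len(fg) == 0:
        return out[1:-1, 1:-1, 1:-1]
    for start in range(0, len(fg), 256):
        chunk = fg[start : start + 256]
        d2 = ((chunk[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2)
        out[tuple(chunk.T)] = np.sqrt(d2.min(axis=1))
    return out[1:-1, 1:-1, 1:-1]


def reconstruction_fixpoint(marker: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Greyscale reconstruction by dilation, run as a literal fixpoint
    iteration (dilate under the mask until nothing changes)."""
    from scipy.ndimage import grey_dilation

    rec = marker.copy()
    footprint = np.ones((3, 3, 3))
    while True:
        nxt = np.minimum(grey_dilation(rec, footprint=footprint), mask)
        if np.array_equal(nxt, rec):
            return rec
        rec = nxt


def otsu_bruteforce(volume: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance maximization over histogram cuts."""
    hist, edges = np.histogram(volume.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    hist = hist.astype(float)
    best_var, best_thr = -1.0, centers[0]
    for cut in range(1, nbins):
        w0, w1 = hist[:cut].sum(), hist[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut] * centers[:cut]).sum() / w0
        mu1 = (hist[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[cut - 1]
    return best_thr


def random_ellipsoid_points(rng, n=258, max_ratio=5.0, center_range=100.0):
    """Exact surface samples of a random rotated ellipsoid (truth returned)."""
    from somaburst.phantom import _rotation_matrix

    while True:
        axes = np.sort(rng.uniform(2.0, 10.0, 3))[::-1]
        if axes[0] / axes[2] <= max_ratio:
            break
    rot = _rotation_matrix(rng.uniform(0, np.pi, 3))
    center = rng.uniform(0, center_range, 3)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    points = center + (rot @ (axes * u).T).T
    return points, center, axes, rot


@pytest.fixture(scope="session")
def s5_run():
    """One S5 field phantom rendered and segmented (shared across tests)."""
    from somaburst.evaluate import evaluate_segmentation
    from somaburst.phantom import field_pipeline_config
    from somaburst.pipeline import run_pipeline

    spec = suite_spec("S5")
    stack, truth = render_phantom(spec)
    cfg = field_pipeline_config()
    labels, segments = run_pipeline(stack, cfg)
    report = evaluate_segmentation(segments, truth.labels, truth.centroids, rc=cfg.rc)
    return {
        "spec": spec,
        "stack": stack,
        "truth": truth,
        "cfg": cfg,
        "labels": labels,
        "segments": segments,
        "report": report,
    }
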