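"""Image-stack and table I/O, plus isotropic resampling.

Axis order is (z, y, x) everywhere in this package: axis 0 is the slice
(axial) axis, axes 1 and 2 are the in-plane rows and columns.  Voxel sizes
are given in the same order, in micrometres (or any consistent length unit).
All coordinates written to CSV tables are 0-based voxel indices of the grid
the volume lives on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "LabelVolume",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "write_table",
    "resample_isotropic",
]


@dataclass
class ImageStack:
    """A 3-D scalar volume with per-axis voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity volume in (z, y, x) order.
    voxel_size : tuple of float
        Physical size of one voxel along (z, y, x), all > 0.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3-D, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("every stack axis must have length >= 1")
        vs = tuple(float(s) for s in self.voxel_size)
        if len(vs) != 3 or any(s <= 0 for s in vs):
            raise ValueError(f"voxel_size must be three positive numbers, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        sz, sy, sx = self.voxel_size
        return np.isclose(sz, sy) and np.isclose(sy, sx)


@dataclass
class LabelVolume:
    """Integer segmentation volume: 0 = background, k >= 1 = soma id.

    Label ids form the contiguous range 1..K (relabeling is the caller's
    responsibility if segments are dropped).
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    allow_2d: bool = False,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an ImageStack.

    Voxel size is taken from the caller (CLI/config), not from TIFF tags,
    whose dialects vary; the default is (1, 1, 1).
    """
    try:
        voxels = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize to one error type
        raise IOError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    voxels = np.asarray(voxels)
    if voxels.ndim == 2:
        if not allow_2d:
            raise ValueError("stack must have >= 2 planes (pass allow_2d to accept a single page)")
        voxels = voxels[np.newaxis]
    if voxels.ndim != 3:
        raise ValueError(f"TIFF content is {voxels.ndim}-D, expected a 3-D grayscale stack")
    return ImageStack(voxels, voxel_size)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageStack as a multi-page TIFF (dtype preserved)."""
    tifffile.imwrite(str(path), np.asarray(stack.voxels), photometric="minisblack")


def read_labels(
    path: str | Path, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> LabelVolume:
    """Read a label TIFF written by :func:`write_labels`."""
    labels = np.asarray(tifffile.imread(str(path)))
    if labels.ndim == 2:
        labels = labels[np.newaxis]
    return LabelVolume(labels.astype(np.int64), voxel_size)


def write_labels(vol: LabelVolume, path: str | Path, force_32bit: bool = False) -> None:
    """Write a LabelVolume as a 16-bit (or 32-bit) multi-page TIFF."""
    n = vol.n_labels
    if n > 65535 and not force_32bit:
        raise ValueError(
            f"{n} labels exceed the 16-bit range; pass force_32bit=True for 32-bit output"
        )
    dtype = np.uint32 if (force_32bit or n > 65535) else np.uint16
    tifffile.imwrite(str(path), vol.labels.astype(dtype), photometric="minisblack")


def write_table(rows: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write a result table as CSV.

    Column order for soma tables is (id, z, y, x, ...); coordinates are
    0-based voxel indices on the isotropic grid, which the header states.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based voxel indices (z, y, x) on the isotropic grid\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _resample_axis(vol: np.ndarray, axis: int, src: float, target: float) -> np.ndarray:
    """1-D linear resampling of `vol` along `axis` from spacing src to target.

    Sample positions are j*target in physical units, clamped to the edge
    slices; output length n' = round((n-1)*src/target) + 1, which preserves
    the physical extent within one voxel.
    """
    n = vol.shape[axis]
    n_new = int(round((n - 1) * src / target)) + 1
    pos = np.arange(n_new) * (target / src)  # in old-index units
    pos = np.clip(pos, 0.0, n - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    w = (pos - i0).reshape([-1 if a == axis else 1 for a in range(vol.ndim)])
    lo = np.take(vol, i0, axis=axis).astype(np.float64)
    hi = np.take(vol, i1, axis=axis).astype(np.float64)
    return lo * (1.0 - w) + hi * w


def resample_isotropic(stack: ImageStack, target: float | None = None) -> ImageStack:
    """Resample an anisotropic stack to an isotropic grid.

    Each axis whose voxel size differs from `target` is linearly interpolated
    slice-by-slice along that axis (for the typical axially-anisotropic data
    only the z axis is touched); axes already at `target` are returned
    untouched, so an already-isotropic stack passes through bit-identically.

    Parameters
    ----------
    target : float, optional
        Target isotropic voxel size.  Defaults to the smallest of the three
        input voxel sizes (the in-plane resolution for axial anisotropy).
    """
    if target is None:
        target = min(stack.voxel_size)
    target = float(target)
    if target <= 0:
        raise ValueError("target voxel size must be > 0")
    extents = [n * s for n, s in zip(stack.shape, stack.voxel_size)]
    if any(target > e for e in extents):
        raise ValueError(
            f"target voxel size {target} exceeds a stack extent {tuple(extents)}"
        )
    vol = stack.voxels
    touched = False
    for axis, src in enumerate(stack.voxel_size):
        if not np.isclose(src, target):
            vol = _resample_axis(vol, axis, src, target)
            touched = True
    if not touched:
        return ImageStack(stack.voxels, (target, target, target))
    return ImageStack(vol, (target, target, target))
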