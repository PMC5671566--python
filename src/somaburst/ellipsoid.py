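"""Direct least-squares ellipsoid fitting under the 4J - I^2 = 1 constraint.

A quadric surface

    a x^2 + b y^2 + c z^2 + d xy + e xz + f yz + p x + q y + r z + k = 0

is fitted to the Rayburst point cloud by the Li-Griffiths constrained
least-squares method: with the design matrix D (rows x^2 y^2 z^2 xy xz yz
x y z 1) and scatter matrix S = D^T D partitioned into S1 (6x6), S2 (6x4),
S3 (4x4), the quadratic part a1 = (a b c d e f) solves

    M a1 = lambda a1,    M = C1^{-1} (S1 - S2 S3^{-1} S2^T),

where C1 encodes the invariant constraint 4J - I^2 = 1 (I = tr Q, J = sum of
principal 2x2 minors of the quadratic-form matrix Q), a sufficient condition
for the quadric to be an ellipsoid.  a1 is the eigenvector of the unique
positive eigenvalue; the linear part follows as a2 = -S3^{-1} S2^T a1.
Points are shifted/scaled per axis to [0, 1] before fitting for numerical
stability and the coefficients are mapped back afterwards.

Coordinates are generic 3-vectors; throughout this package column order is
(z, y, x), and the symbols x, y, z above simply name the three columns.
The returned coefficient vector is normalized so the constraint value is +1
and the quadric is negative in the interior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "QuadricCoefficients",
    "ScaleFrame",
    "EllipsoidGeometry",
    "scale_points",
    "fit_quadric",
    "unscale_quadric",
    "quadric_to_geometry",
    "fit_ellipsoid",
    "voxelize",
    "volume_filter",
]

THOMSEN_P = 1.6075  # surface-area approximation exponent (max error ~1.06%)


@dataclass
class QuadricCoefficients:
    """10-vector (a, b, c, d, e, f, p, q, r, k) of the quadric equation."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.shape != (10,):
            raise ValueError("quadric coefficient vector must have 10 entries")
        if np.allclose(self.a[:6], 0):
            raise ValueError("degenerate quadric: no quadratic terms")

    @property
    def quadratic_form(self) -> np.ndarray:
        a, b, c, d, e, f = self.a[:6]
        return np.array(
            [[a, d / 2, e / 2], [d / 2, b, f / 2], [e / 2, f / 2, c]]
        )

    @property
    def linear(self) -> np.ndarray:
        return self.a[6:9]

    @property
    def constant(self) -> float:
        return float(self.a[9])

    def constraint_value(self) -> float:
        """4J - I^2 of the quadratic form (== 1 for a normalized ellipsoid)."""
        Q = self.quadratic_form
        I = np.trace(Q)
        J = (
            Q[0, 0] * Q[1, 1] - Q[0, 1] ** 2
            + Q[0, 0] * Q[2, 2] - Q[0, 2] ** 2
            + Q[1, 1] * Q[2, 2] - Q[1, 2] ** 2
        )
        return float(4 * J - I * I)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Quadric value at points (n, 3); negative inside the ellipsoid."""
        P = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return np.einsum("ni,ij,nj->n", P, self.quadratic_form, P) + P @ self.linear + self.constant


@dataclass
class ScaleFrame:
    """Per-axis shift/scale applied to points before fitting."""

    mins: np.ndarray
    scales: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.scales = np.asarray(self.scales, dtype=np.float64)
        if np.any(self.scales <= 0):
            raise ValueError("scale factors must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.mins) / self.scales

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) * self.scales + self.mins


@dataclass
class EllipsoidGeometry:
    """Geometric ellipsoid: center, sorted semi-axes, rotation, size."""

    center: np.ndarray  # (z, y, x)
    semi_axes: np.ndarray  # (A, B, C), A >= B >= C > 0
    rotation: np.ndarray  # columns are the axis directions, det +1

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.semi_axes = np.asarray(self.semi_axes, dtype=np.float64)
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")
        if np.any(np.diff(self.semi_axes) > 1e-12):
            raise ValueError("semi-axes must be sorted descending")

    @property
    def volume(self) -> float:
        A, B, C = self.semi_axes
        return float(4.0 / 3.0 * np.pi * A * B * C)

    @property
    def area(self) -> float:
        """Thomsen's approximation of the ellipsoid surface area."""
        A, B, C = self.semi_axes
        p = THOMSEN_P
        return float(4 * np.pi * (((A * B) ** p + (A * C) ** p + (B * C) ** p) / 3) ** (1 / p))


def scale_points(points: np.ndarray) -> tuple[np.ndarray, ScaleFrame]:
    """Shift/scale each coordinate axis of the cloud into [0, 1].

    Scale factors are the per-axis ranges; an axis of zero range keeps
    scale 1 so degenerate (planar) clouds do not divide by zero.
    """
    P = np.asarray(points, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point cloud must have shape (n, 3)")
    if len(P) < 10:
        raise ValueError("insufficient points for quadric fit (need >= 10)")
    mins = P.min(axis=0)
    scales = P.max(axis=0) - mins
    scales[scales == 0] = 1.0
    frame = ScaleFrame(mins, scales)
    return frame.apply(P), frame


def _design_matrix(P: np.ndarray) -> np.ndarray:
    x, y, z = P[:, 0], P[:, 1], P[:, 2]
    return np.column_stack(
        [x * x, y * y, z * z, x * y, x * z, y * z, x, y, z, np.ones_like(x)]
    )


# constraint matrix for 4J - I^2: a1^T C1 a1 = 2ab+2ac+2bc - a^2-b^2-c^2 - d^2-e^2-f^2
_C1 = np.zeros((6, 6))
_C1[:3, :3] = np.array([[-1, 1, 1], [1, -1, 1], [1, 1, -1]], dtype=float)
_C1[3:, 3:] = -np.eye(3)


def _is_real_ellipsoid(a: np.ndarray) -> bool:
    """True if the 10-vector describes a real (non-degenerate) ellipsoid."""
    try:
        coeffs = QuadricCoefficients(a.copy())
        center, val = _center_value(coeffs)
    except (ValueError, np.linalg.LinAlgError):
        return False
    if not np.all(np.isfinite(center)):
        return False
    eigs = np.linalg.eigvalsh(coeffs.quadratic_form)
    # definite quadratic form with opposite-sign centered constant
    return bool((np.all(eigs > 0) and val < 0) or (np.all(eigs < 0) and val > 0))


def _center_value(coeffs: QuadricCoefficients) -> tuple[np.ndarray, float]:
    Q, b = coeffs.quadratic_form, coeffs.linear
    center = np.linalg.solve(2 * Q, -b)
    return center, float(coeffs.evaluate(center[None, :])[0])


def _normalize_constraint(a: np.ndarray) -> np.ndarray:
    """Scale to constraint value +1 and make the interior negative."""
    coeffs = QuadricCoefficients(a.copy())
    cval = coeffs.constraint_value()
    if cval <= 0:
        raise ValueError("no ellipsoid solution: constraint 4J - I^2 is non-positive")
    a = a / np.sqrt(cval)
    _center, val = _center_value(QuadricCoefficients(a))
    if val > 0:
        a = -a
    return a


def _normalize_interior(a: np.ndarray) -> np.ndarray:
    """Scale so the quadric value at the center is exactly -1.

    Used in the original (possibly anisotropically unscaled) frame, where
    the 4J - I^2 invariant is not preserved; any positive multiple keeps
    the zero set, and value -1 at the center makes the interior-negative
    convention and the voxel-depth comparison deterministic.
    """
    coeffs = QuadricCoefficients(a.copy())
    _center, val = _center_value(coeffs)
    if val == 0:
        raise ValueError("degenerate quadric: zero value at the center")
    return a / (-val)


def fit_quadric(points: np.ndarray) -> QuadricCoefficients:
    """Constrained least-squares quadric fit of an (already scaled) cloud.

    Returns the coefficient vector in the frame of the given points,
    normalized to constraint value +1, interior negative.
    """
    P = np.asarray(points, dtype=np.float64)
    if len(P) < 10:
        raise ValueError("insufficient points for quadric fit (need >= 10)")
    D = _design_matrix(P)
    D1, D2 = D[:, :6], D[:, 6:]
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        S3_inv_S2T = linalg.solve(S3, S2.T, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise ValueError("degenerate point cloud: reduced scatter matrix is singular") from exc
    M = linalg.solve(_C1, S1 - S2 @ S3_inv_S2T)
    eigvals, eigvecs = linalg.eig(M)
    # The classical solution is the eigenvector of the unique positive
    # eigenvalue.  Two degeneracies require care: on (near-)exact data that
    # eigenvalue collapses to ~0 (lambda * a1^T C1 a1 = ||D a||^2, and the
    # residual vanishes), and elongated ellipsoids (axis ratio > 2) have
    # 4J - I^2 < 0, i.e. live outside the constraint's representable set
    # although they are perfectly real ellipsoids.  The stable selection is
    # therefore: among eigenvectors whose completed quadric is a real
    # ellipsoid, take the smallest algebraic residual ||D a||.
    candidates: list[tuple[float, float, np.ndarray]] = []
    for i in range(6):
        if abs(eigvals[i].imag) > 1e-8 * (abs(eigvals[i]) + 1):
            continue
        a1 = eigvecs[:, i].real
        cand = np.concatenate([a1, -S3_inv_S2T @ a1])
        if not _is_real_ellipsoid(cand):
            continue
        res = float(np.linalg.norm(D @ (cand / np.linalg.norm(cand))))
        candidates.append((res, eigvals[i].real, cand))
    if not candidates:
        raise ValueError("no ellipsoid solution: eigensystem has no positive eigenvalue")
    tol = 1e-10 * float(np.max(np.abs(eigvals)))
    if sum(ev > tol for _res, ev, _a in candidates) > 1:
        warnings.warn(
            "multiple positive eigenvalues; picking the candidate with the "
            "smallest algebraic residual",
            stacklevel=2,
        )
    candidates.sort(key=lambda c: c[0])
    a = candidates[0][2]
    coeffs = QuadricCoefficients(a.copy())
    if coeffs.constraint_value() > 0:
        return QuadricCoefficients(_normalize_constraint(a))
    # elongated solution outside the constraint's representable set:
    # normalize to value -1 at the center instead
    return QuadricCoefficients(_normalize_interior(a))


def unscale_quadric(coeffs: QuadricCoefficients, frame: ScaleFrame) -> QuadricCoefficients:
    """Map scaled-frame quadric coefficients back to the original frame.

    Substituting x_hat = (x - m_x)/s_x (etc.) into the scaled-frame quadric
    gives the original-frame coefficients in closed form; the result is
    re-normalized (constraint +1, interior negative), which leaves the zero
    set unchanged.
    """
    A, B, C, D_, E, F, P_, Q_, R_, K = coeffs.a
    mx, my, mz = frame.mins
    sx, sy, sz = frame.scales
    a = A / sx**2
    b = B / sy**2
    c = C / sz**2
    d = D_ / (sx * sy)
    e = E / (sx * sz)
    f = F / (sy * sz)
    p = -2 * A * mx / sx**2 - D_ * my / (sx * sy) - E * mz / (sx * sz) + P_ / sx
    q = -2 * B * my / sy**2 - D_ * mx / (sx * sy) - F * mz / (sy * sz) + Q_ / sy
    r = -2 * C * mz / sz**2 - E * mx / (sx * sz) - F * my / (sy * sz) + R_ / sz
    k = (
        A * mx**2 / sx**2 + B * my**2 / sy**2 + C * mz**2 / sz**2
        + D_ * mx * my / (sx * sy) + E * mx * mz / (sx * sz) + F * my * mz / (sy * sz)
        - P_ * mx / sx - Q_ * my / sy - R_ * mz / sz + K
    )
    return QuadricCoefficients(_normalize_interior(np.array([a, b, c, d, e, f, p, q, r, k])))


def quadric_to_geometry(coeffs: QuadricCoefficients) -> EllipsoidGeometry:
    """Center, semi-axes and orientation of an ellipsoid quadric."""
    Q = coeffs.quadratic_form
    b = coeffs.linear
    center = np.linalg.solve(2 * Q, -b)
    level = coeffs.evaluate(center[None, :])[0]  # quadric value at the center
    eigvals, eigvecs = np.linalg.eigh(Q)
    if level >= 0 or np.any(eigvals <= 0):
        raise ValueError("quadric is not a real ellipsoid")
    semi = np.sqrt(-level / eigvals)  # descending when eigvals ascending
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    rot = eigvecs[:, order]
    if np.linalg.det(rot) < 0:
        rot = rot.copy()
        rot[:, -1] *= -1
    return EllipsoidGeometry(center=center, semi_axes=semi, rotation=rot)


def fit_ellipsoid(points: np.ndarray) -> tuple[QuadricCoefficients, EllipsoidGeometry]:
    """Scale -> constrained fit -> unscale -> geometric parameters."""
    scaled, frame = scale_points(points)
    coeffs = unscale_quadric(fit_quadric(scaled), frame)
    return coeffs, quadric_to_geometry(coeffs)


def voxelize(
    coeffs: QuadricCoefficients, shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxel centers strictly inside the ellipsoid, clipped to `shape`.

    Returns an (n, 3) integer array of (z, y, x) indices; empty when the
    ellipsoid lies outside the volume.
    """
    geom = quadric_to_geometry(coeffs)
    lo = np.maximum(np.floor(geom.center - geom.semi_axes[0] - 1).astype(int), 0)
    hi = np.minimum(np.ceil(geom.center + geom.semi_axes[0] + 1).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    inside = coeffs.evaluate(pts) < 0
    return pts[inside]


def volume_filter(segments: list, v_min: float, key=len) -> list:
    """Drop segments whose voxelized volume is below `v_min` voxels.

    `key` extracts the voxel count from a segment (defaults to ``len`` for
    plain voxel arrays/sets).
    """
    if v_min < 0:
        raise ValueError("volume threshold must be >= 0")
    return [s for s in segments if key(s) >= v_min]
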