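"""Rigid registration: Kabsch solution and size-preserving generalized
Procrustes analysis.

Configurations are aligned by removing translation and rotation only.
Scale is deliberately left untouched -- the shape of a large jaw is not a
magnification of a small one, so centroid size is an informative variable
the model must keep.  Reflections are forbidden throughout (a left/right
mirrored dentition is a different anatomy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "kabsch_rotation",
    "rigid_fit",
    "gpa_align",
    "centroid_size",
    "GPAResult",
]


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t with R proper orthogonal (no reflection, no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1), not a reflection")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) point array (or a single 3-vector)."""
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first ``other``, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def centroid_size(points: np.ndarray) -> float:
    """Root-sum-of-squares distance of landmarks to their centroid (mm)."""
    points = np.asarray(points, dtype=float)
    return float(np.linalg.norm(points - points.mean(axis=0)))


def kabsch_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation minimizing ||R @ source_i - target_i||^2 over rows.

    Both inputs must already be centered.  The reflection case (negative
    determinant of the correlation matrix) is resolved by flipping the sign
    of the smallest singular direction, the standard constrained solution.
    """
    H = np.asarray(source, dtype=float).T @ np.asarray(target, dtype=float)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def rigid_fit(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Best rigid transform mapping ``source`` points onto ``target``.

    Requires >= 3 points that are not all collinear; with fewer constraints
    the in-plane/axial rotation is undetermined.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    if source.shape[0] < 3:
        raise ValueError("rigid fit needs at least 3 landmarks")
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    centered = source - sc
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("landmarks are collinear; rotation is undetermined")
    R = kabsch_rotation(centered, target - tc)
    return RigidTransform(R, tc - R @ sc)


@dataclass(frozen=True)
class GPAResult:
    """Aligned configurations plus per-individual pose and diagnostics."""

    aligned: np.ndarray            # (n, K, 3) in the common frame
    transforms: tuple[RigidTransform, ...]  # original frame -> common frame
    mean_shape: np.ndarray         # (K, 3)
    n_iterations: int
    converged: bool


def gpa_align(configurations: np.ndarray, tol: float = 1e-7,
              max_iter: int = 100) -> GPAResult:
    """Size-preserving generalized Procrustes alignment.

    Parameters
    ----------
    configurations : (n, K, 3) array
        n individuals' matching landmark configurations, mm.
    tol : float
        Convergence threshold on the RMS change of the mean shape (mm).
    max_iter : int
        Iteration cap.

    Each configuration is centered, then iteratively rotated (Kabsch, no
    reflection) to the running mean, which is re-estimated until stable.
    Initialization is deterministic: the first individual's centered
    configuration is the starting mean.  Centroid sizes are untouched.
    """
    X = np.asarray(configurations, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError(f"expected (n, K, 3) configurations, got {X.shape}")
    n, K, _ = X.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 individuals")
    for i in range(n):
        sv = np.linalg.svd(X[i] - X[i].mean(axis=0), compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise ValueError(f"configuration {i} is degenerate (collinear/coincident)")

    centroids = X.mean(axis=1)                      # (n, 3)
    centered = X - centroids[:, None, :]
    rotations = [np.eye(3) for _ in range(n)]
    aligned = centered.copy()
    mean = aligned[0].copy()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            R = kabsch_rotation(centered[i], mean)
            rotations[i] = R
            aligned[i] = centered[i] @ R.T
        new_mean = aligned.mean(axis=0)
        rms = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        mean = new_mean
        if rms < tol:
            converged = True
            break

    transforms = tuple(
        RigidTransform(rotations[i], -rotations[i] @ centroids[i]) for i in range(n)
    )
    return GPAResult(aligned=aligned, transforms=transforms, mean_shape=mean,
                     n_iterations=it, converged=converged)
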