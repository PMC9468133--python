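"""Tooth-axis fitting and the three axis-error measures.

The idealized root axis of a tooth is the 3D least-squares line through the
root-canal landmarks LM-1..LM-4 (LM-5, the apex, is carried in the data
model but excluded from the fit).  "Least squares" is taken in the
orthogonal (total) sense: the line minimizing the sum of squared
perpendicular distances, i.e. the dominant principal direction of the
centered points.  Unlike coordinate-wise regression this does not depend on
an arbitrary choice of the independent axis, which matters because no
global anatomical frame is assumed.

Accuracy of a predicted axis against the actual one is quantified by

* angle alpha - the undirected angle between the two axis directions;
* Distance A - shortest distance from the predicted LM-1 (CEJL level) to
  the actual axis line;
* Distance B - shortest distance from the predicted LM-4 (apical third) to
  the actual axis line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import ToothId

__all__ = [
    "ToothAxisLine",
    "AxisErrorMetrics",
    "DegenerateAxisError",
    "fit_tooth_axis",
    "angle_between_axes",
    "point_to_axis_distance",
    "axis_errors",
]

#: Points whose centered coordinates have dominant singular value below this
#: are considered coincident and cannot define an axis.
DEGENERACY_TOL_MM = 1e-9


class DegenerateAxisError(ValueError):
    """Raised when the landmarks do not determine a line (all coincident)."""


@dataclass(frozen=True)
class ToothAxisLine:
    """A 3D line: centroid anchor + unit direction, oriented coronal->apical."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        anchor = np.asarray(self.anchor, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if anchor.shape != (3,) or direction.shape != (3,):
            raise ValueError("anchor and direction must be 3-vectors")
        norm = np.linalg.norm(direction)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"direction must be a unit vector, |d| = {norm}")
        anchor.setflags(write=False)
        direction.setflags(write=False)
        object.__setattr__(self, "anchor", anchor)
        object.__setattr__(self, "direction", direction)

    def point_at(self, t: float) -> np.ndarray:
        return self.anchor + t * self.direction

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ToothAxisLine":
        return ToothAxisLine(rotation @ self.anchor + translation,
                             rotation @ self.direction)


@dataclass(frozen=True)
class AxisErrorMetrics:
    """Per-tooth accuracy of a predicted axis versus the actual one."""

    tooth: ToothId
    angle_alpha_deg: float
    distance_A_mm: float
    distance_B_mm: float


def fit_tooth_axis(root_points: np.ndarray) -> ToothAxisLine:
    """Fit the orthogonal least-squares line through LM-1..LM-4.

    Parameters
    ----------
    root_points : (4, 3) array
        The root-canal landmarks LM-1..LM-4 of one tooth, in order, mm.

    Returns
    -------
    ToothAxisLine
        Anchored at the centroid; direction is the dominant right singular
        vector of the centered points, sign-fixed so that it points from
        the LM-1 side toward the LM-4 side (coronal -> apical).  No other
        line has a smaller sum of squared orthogonal distances.
    """
    pts = np.asarray(root_points, dtype=float)
    if pts.shape != (4, 3):
        raise ValueError(f"expected 4 points in 3D, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("root landmarks contain non-finite coordinates")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < DEGENERACY_TOL_MM:
        raise DegenerateAxisError("all root landmarks coincide; axis undefined")
    direction = vt[0]
    apical = pts[3] - pts[0]  # LM-4 - LM-1
    if direction @ apical < 0:
        direction = -direction
    return ToothAxisLine(centroid, direction)


def angle_between_axes(a: ToothAxisLine, b: ToothAxisLine) -> float:
    """Undirected angle between two axes in degrees, in [0, 90]."""
    c = abs(float(a.direction @ b.direction))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def point_to_axis_distance(p: np.ndarray, axis: ToothAxisLine) -> float:
    """Euclidean distance (mm) from a point to the infinite axis line."""
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError("point must be a finite 3-vector")
    r = p - axis.anchor
    return float(np.linalg.norm(r - (r @ axis.direction) * axis.direction))


def axis_errors(tooth: ToothId, predicted_root: np.ndarray,
                actual_root: np.ndarray) -> AxisErrorMetrics:
    """All three error measures for one tooth.

    Both arguments are (4, 3) arrays of LM-1..LM-4.  The axis is fitted to
    each set; angle alpha compares the two fitted axes, Distances A and B
    measure the predicted LM-1 and LM-4 against the *actual* fitted axis.
    """
    predicted_root = np.asarray(predicted_root, dtype=float)
    actual_root = np.asarray(actual_root, dtype=float)
    pred_axis = fit_tooth_axis(predicted_root)
    act_axis = fit_tooth_axis(actual_root)
    return AxisErrorMetrics(
        tooth=tooth,
        angle_alpha_deg=angle_between_axes(pred_axis, act_axis),
        distance_A_mm=point_to_axis_distance(predicted_root[0], act_axis),
        distance_B_mm=point_to_axis_distance(predicted_root[3], act_axis),
    )
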