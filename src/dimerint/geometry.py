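"""Kinked-helix geometry: bend angle, wobble angle and face shift.

A proline (or Gly/Ser/Thr) kink divides a transmembrane helix into a
pre-kink and a post-kink segment.  The three descriptors computed here are

* **bend** — the angle between the two segment axes, in [0, 180);
* **wobble** — the azimuthal direction of the post-segment axis around the
  pre-segment axis.  Zero reference is the radial direction from the
  pre-segment axis to the flex residue's Cα; positive is counterclockwise
  looking from the N- toward the C-terminus;
* **face shift** — how far the helical face of the first post-segment Cα has
  rotated about the axis relative to the unkinked extrapolation of the
  pre-segment's azimuthal phase progression.

All angles are degrees; wobble and face shift wrap to (−180, 180].

Axis fitting uses the second-difference property of helical points: for an
ideal helix p(k) the discrete second difference p(k−1) − 2p(k) + p(k+1) is a
purely radial vector, so the axis direction is the null direction of the
stacked second differences.  This is exact for ideal helices and far more
robust on short (~2-turn) segments than principal-component fitting, whose
leading axis tilts strongly for non-integer turn counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cm import HelixConformation

__all__ = ["HelixGeometry", "fit_axis", "kink_geometry"]


@dataclass(frozen=True)
class HelixGeometry:
    bend_deg: float
    wobble_deg: float
    face_shift_deg: float
    flex_residue: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.bend_deg) and self.bend_deg >= 0):
            raise ValueError("bend must be finite and >= 0")
        for v in (self.wobble_deg, self.face_shift_deg):
            if not math.isfinite(v):
                raise ValueError("angles must be finite")


def _wrap(x: float) -> float:
    x = (x + 180.0) % 360.0 - 180.0
    return 180.0 if x == -180.0 else x


def fit_axis(ca_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares helix axis of an ordered run of Cα positions.

    Returns ``(axis, centroid)``: the unit axis oriented N→C, and a point on
    the axis (the circle-fit centre of the points projected into the normal
    plane, lifted to the points' mean axial height).  Requires ≥ 4 points.
    """
    p = np.asarray(ca_coords, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise ValueError("need at least 4 Cα positions")
    second = p[:-2] - 2 * p[1:-1] + p[2:]
    # axis = null direction of the (radial) second differences
    _, _, vt = np.linalg.svd(second - 0.0)
    axis = vt[-1]
    if np.dot(axis, p[-1] - p[0]) < 0:
        axis = -axis
    # project points into the plane normal to the axis and fit a circle
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = p @ e1
    v = p @ e2
    # Kåsa linear circle fit: u² + v² = 2a·u + 2b·v + c
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    sol, *_ = np.linalg.lstsq(A, u**2 + v**2, rcond=None)
    center_plane = sol[0] * e1 + sol[1] * e2
    axial = float(np.mean(p @ axis))
    centroid = center_plane + axial * axis
    return axis, centroid


def _radial(point: np.ndarray, axis: np.ndarray, origin: np.ndarray) -> np.ndarray:
    d = point - origin
    return d - np.dot(d, axis) * axis


def _signed_azimuth(ref: np.ndarray, vec: np.ndarray, axis: np.ndarray) -> float:
    """Angle from ref to vec about axis, counterclockwise looking N→C."""
    return math.degrees(math.atan2(float(np.dot(axis, np.cross(ref, vec))),
                                   float(np.dot(ref, vec))))


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def kink_geometry(
    helix: HelixConformation | np.ndarray,
    flex_residue: int,
    window: int = 7,
    flex_span: int = 4,
) -> HelixGeometry:
    """Bend/wobble/face-shift descriptors of a kinked helix.

    ``flex_residue`` is the 0-based index *i* of the hinge residue (e.g. the
    proline).  The flexible span i−flex_span..i is excluded from both axis
    fits; the pre-segment is the ``window`` residues immediately before it
    and the post-segment the ``window`` residues immediately after *i*.
    """
    ca = helix.ca_coords if isinstance(helix, HelixConformation) else np.asarray(helix, float)
    n = len(ca)
    pre_end = flex_residue - flex_span  # exclusive
    pre_start = pre_end - window
    post_start = flex_residue + 1
    post_end = post_start + window
    if pre_start < 0 or post_end > n:
        raise ValueError(
            f"need {window} residues on each side of the flexible span "
            f"(have pre {pre_end} and post {n - post_start})"
        )
    a1, c1 = fit_axis(ca[pre_start:pre_end])
    a2, c2 = fit_axis(ca[post_start:post_end])

    bend = math.degrees(math.acos(float(np.clip(np.dot(a1, a2), -1.0, 1.0))))

    flex_ca = ca[flex_residue]
    r0 = _radial(flex_ca, a1, c1)
    r0n = np.linalg.norm(r0)
    if r0n < 1e-9:
        raise ValueError("flex residue Cα lies on the pre-segment axis")
    r0 = r0 / r0n
    a2_perp = a2 - np.dot(a2, a1) * a1
    if np.linalg.norm(a2_perp) < 1e-12:
        wobble = 0.0  # no tilt: wobble direction undefined, reported as 0
    else:
        wobble = _wrap(_signed_azimuth(r0, a2_perp / np.linalg.norm(a2_perp), a1))

    face_shift = _face_shift(ca, a1, c1, a2, flex_ca, pre_start, pre_end, post_start, bend)
    return HelixGeometry(
        bend_deg=bend, wobble_deg=_wrap(wobble),
        face_shift_deg=_wrap(face_shift), flex_residue=flex_residue,
    )


def _face_shift(
    ca: np.ndarray,
    a1: np.ndarray,
    c1: np.ndarray,
    a2: np.ndarray,
    hinge: np.ndarray,
    pre_start: int,
    pre_end: int,
    post_start: int,
    bend_deg: float,
) -> float:
    """Observed minus extrapolated azimuth of the first post-segment Cα.

    The pre-segment Cα azimuths about the pre-axis advance ~100°/residue;
    a linear fit of the unwrapped phases extrapolates where the first
    post-segment Cα's face *would* point had the helix continued unkinked.
    The observed position is the first post-segment Cα un-bent back into the
    pre-segment frame (rotated by −bend about the hinge axis).
    """
    ref = _radial(ca[pre_start], a1, c1)
    ref /= np.linalg.norm(ref)
    phases = []
    for k in range(pre_start, pre_end):
        r = _radial(ca[k], a1, c1)
        phases.append(_signed_azimuth(ref, r / np.linalg.norm(r), a1))
    phases = np.unwrap(np.radians(phases))
    idx = np.arange(pre_start, pre_end)
    slope, intercept = np.polyfit(idx, phases, 1)
    predicted = math.degrees(slope * post_start + intercept)

    p = ca[post_start]
    if bend_deg > 0.5:
        rot_axis = np.cross(a1, a2)
        rot = _rotation_matrix(rot_axis, -math.radians(bend_deg))
        p = hinge + rot @ (p - hinge)
    r = _radial(p, a1, c1)
    observed = _signed_azimuth(ref, r / np.linalg.norm(r), a1)
    return _wrap(observed - predicted)
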