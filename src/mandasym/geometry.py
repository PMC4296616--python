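"""Planar geometric primitives underlying every measurement.

All functions work in the image coordinate convention of
:mod:`mandasym.landmarks` (origin top-left, y down).  Horizontal distances
to the median sagittal plane (MSP) are measured parallel to the image
x-axis — the on-screen "horizontal link" of the original analysis — with a
signed convention: positive toward the patient's *left* (larger x).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .landmarks import PixelCalibration, Point2D

#: MSP construction rules (see :func:`construct_msp`).
MSP_RULES = ("perpendicular_through_ans", "ans_to_midpoint")


class DegenerateGeometryError(ValueError):
    """Raised when a geometric primitive is undefined for its inputs."""


@dataclass(frozen=True, slots=True)
class MSPLine:
    """The median sagittal plane as a 2-D line: an anchor point plus a unit
    direction vector.  The direction is canonicalised to point downward
    (``dy > 0``; ``dx > 0`` for exactly horizontal lines) so equal lines
    compare equal."""

    anchor: Point2D
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        dx, dy = self.direction
        norm = math.hypot(dx, dy)
        if norm == 0.0 or not math.isfinite(norm):
            raise DegenerateGeometryError("MSP direction must be a nonzero finite vector")
        dx, dy = dx / norm, dy / norm
        if dy < 0.0 or (dy == 0.0 and dx < 0.0):
            dx, dy = -dx, -dy
        object.__setattr__(self, "direction", (dx, dy))


def distance(a: Point2D, b: Point2D, cal: PixelCalibration) -> float:
    """Euclidean distance between two image points, in millimetres."""
    return math.hypot(b.x - a.x, b.y - a.y) * cal.mm_per_pixel


def angle_at_vertex(vertex: Point2D, p1: Point2D, p2: Point2D) -> float:
    """Interior angle (degrees, in [0, 180]) between rays vertex->p1 and
    vertex->p2.  Independent of calibration and of rigid motion or uniform
    scaling of all three points."""
    u = (p1.x - vertex.x, p1.y - vertex.y)
    v = (p2.x - vertex.x, p2.y - vertex.y)
    nu, nv = math.hypot(*u), math.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle undefined: ray endpoint coincides with vertex")
    # atan2 of cross/dot is far better conditioned near 0 and 180 than acos.
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return math.degrees(math.atan2(abs(cross), dot))


def construct_msp(
    ans: Point2D,
    rpf: Point2D,
    lpf: Point2D,
    rule: str = "perpendicular_through_ans",
) -> MSPLine:
    """Construct the median sagittal plane from the three maxillary landmarks.

    ``perpendicular_through_ans`` (default): the line through ANS
    perpendicular to the RPF-LPF segment.  For a level head with symmetric
    fossae this is the vertical facial midline, and it degrades gracefully
    under symmetric head tilt.

    ``ans_to_midpoint``: the line through ANS and the RPF-LPF midpoint.
    """
    if rule not in MSP_RULES:
        raise ValueError(f"unknown msp_rule {rule!r}; expected one of {MSP_RULES}")
    dx, dy = lpf.x - rpf.x, lpf.y - rpf.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("RPF and LPF coincide; MSP undefined")
    if rule == "perpendicular_through_ans":
        direction = (-dy, dx)
    else:
        mid = Point2D((rpf.x + lpf.x) / 2.0, (rpf.y + lpf.y) / 2.0)
        direction = (mid.x - ans.x, mid.y - ans.y)
        if direction == (0.0, 0.0):
            raise DegenerateGeometryError("ANS coincides with the RPF-LPF midpoint; MSP undefined")
    return MSPLine(anchor=ans, direction=direction)


def horizontal_intercept(line: MSPLine, y: float) -> float:
    """x-coordinate where the line crosses the horizontal at height ``y``."""
    dx, dy = line.direction
    if abs(dy) < 1e-12:
        raise DegenerateGeometryError("line is horizontal: no x-parallel intersection")
    return line.anchor.x + (y - line.anchor.y) * (dx / dy)


def horizontal_distance_to_line(p: Point2D, line: MSPLine, cal: PixelCalibration) -> float:
    """Signed x-parallel distance from ``p`` to ``line``, in millimetres.

    Positive when ``p`` lies toward the patient's left of the line (larger
    x), negative toward the patient's right.
    """
    return (p.x - horizontal_intercept(line, p.y)) * cal.mm_per_pixel


def reflect_across_line(p: Point2D, line: MSPLine) -> Point2D:
    """Mirror image of ``p`` across ``line`` (an involution)."""
    dx, dy = line.direction
    rx, ry = p.x - line.anchor.x, p.y - line.anchor.y
    t = rx * dx + ry * dy  # projection onto the line direction
    fx, fy = line.anchor.x + t * dx, line.anchor.y + t * dy  # foot of perpendicular
    return Point2D(2.0 * fx - p.x, 2.0 * fy - p.y)
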