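"""Per-hemimandible Distortion Factor (DF) correction.

Panoramic radiographs magnify the two halves of the mandible by different
horizontal factors.  A DF is a dimensionless multiplier (true length /
measured length) obtained by imaging a calibration object of known size on
each hemimandible; multiplying a measured horizontal length by the DF of
its side recovers the true length.  Horizontal quantities (corpus length,
Pg-MSP, IP-MSP) are corrected; vertical quantities (ramus height, condylar
height difference) and the gonial angle are not.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .geometry import MSPLine, horizontal_intercept
from .landmarks import Point2D


class DistortionSource(str, enum.Enum):
    UNIT = "unit"
    CALIBRATION_OBJECT = "calibration_object"
    MACHINE_NOMINAL = "machine_nominal"


@dataclass(frozen=True, slots=True)
class DistortionConfig:
    """Per-side distortion factors and where they came from."""

    df_right: float = 1.0
    df_left: float = 1.0
    source: DistortionSource = DistortionSource.UNIT

    def __post_init__(self) -> None:
        for side, df in (("right", self.df_right), ("left", self.df_left)):
            if not (math.isfinite(df) and df > 0):
                raise ValueError(f"df_{side} must be positive and finite, got {df}")
        if self.source == DistortionSource.UNIT and (self.df_right != 1.0 or self.df_left != 1.0):
            raise ValueError("source 'unit' requires both distortion factors to equal 1")

    @classmethod
    def unit(cls) -> "DistortionConfig":
        return cls()

    def factor(self, side: str) -> float:
        if side == "right":
            return self.df_right
        if side == "left":
            return self.df_left
        raise ValueError(f"unknown side {side!r}")

    def swapped(self) -> "DistortionConfig":
        """The configuration of the mirror-imaged patient."""
        return DistortionConfig(self.df_left, self.df_right, self.source)


def df_from_calibration(
    true_length_mm: float,
    measured_length_right_mm: float,
    measured_length_left_mm: float,
) -> DistortionConfig:
    """DF per side from a calibration object of known size.

    ``df_side = true / measured_side``; a side magnified 1.25x yields
    DF = 0.8.
    """
    for label, v in (
        ("true_length_mm", true_length_mm),
        ("measured_length_right_mm", measured_length_right_mm),
        ("measured_length_left_mm", measured_length_left_mm),
    ):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{label} must be positive and finite, got {v}")
    return DistortionConfig(
        df_right=true_length_mm / measured_length_right_mm,
        df_left=true_length_mm / measured_length_left_mm,
        source=DistortionSource.CALIBRATION_OBJECT,
    )


def correct_horizontal(raw_mm: float, side: str, dc: DistortionConfig) -> float:
    """Scale a raw horizontal measurement by the DF of its side.

    ``side`` is ``right``, ``left`` or ``midline``.  Midline deviations
    (Pg-MSP, IP-MSP) use the factor of the hemimandible the point deviates
    toward — positive values deviate toward the patient's left — and keep
    their sign; a zero deviation is returned unchanged.
    """
    if side == "midline":
        if raw_mm == 0.0:
            return 0.0
        side = "left" if raw_mm > 0 else "right"
    return raw_mm * dc.factor(side)


def undistort_point(p: Point2D, msp: MSPLine, dc: DistortionConfig) -> Point2D:
    """Invert per-hemimandible horizontal magnification for one landmark.

    The landmark's signed horizontal offset from the MSP is multiplied by
    the DF of the side it lies on (positive offset = patient's left);
    vertical position is untouched.  With unit factors this is the exact
    identity.  Measurements recomputed from undistorted landmarks agree
    with :func:`correct_horizontal` for x-parallel quantities and extend
    the correction consistently to oblique ones such as corpus length.
    """
    if dc.df_right == 1.0 and dc.df_left == 1.0:
        return p
    x_line = horizontal_intercept(msp, p.y)
    offset = p.x - x_line
    df = dc.df_left if offset > 0 else dc.df_right
    return Point2D(x_line + offset * df, p.y)
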