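"""The six asymmetry measurements taken from one panoramic radiograph.

Per side: ramus height RH (condylar summit to gonion), corpus length CL
(gonion to pogonion, distortion-corrected) and gonial angle GA (at the
gonion, between the ramus and corpus segments).  Midline: the x-parallel
deviations of pogonion (Pg-MSP) and the inter-incisive point (IP-MSP)
from the median sagittal plane, and the condylar height difference CHD
(vertical offset between the two condylar summits).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from . import geometry
from .distortion import DistortionConfig, correct_horizontal, undistort_point
from .geometry import MSPLine, construct_msp
from .landmarks import (
    LandmarkName,
    LandmarkSet,
    ValidationError,
    validate_landmark_set,
)

_SIDE_LANDMARKS = {
    "right": (LandmarkName.RHC, LandmarkName.RGO),
    "left": (LandmarkName.LHC, LandmarkName.LGO),
}


def _side_points(ls: LandmarkSet, side: str):
    try:
        hc_name, go_name = _SIDE_LANDMARKS[side]
    except KeyError:
        raise ValueError(f"unknown side {side!r}; expected 'right' or 'left'") from None
    return ls.point(hc_name), ls.point(go_name)


def msp_of(ls: LandmarkSet, msp_rule: str = "perpendicular_through_ans") -> MSPLine:
    """Median sagittal plane of a landmark set (from ANS, RPF, LPF)."""
    return construct_msp(
        ls.point(LandmarkName.ANS),
        ls.point(LandmarkName.RPF),
        ls.point(LandmarkName.LPF),
        rule=msp_rule,
    )


def ramus_height(ls: LandmarkSet, side: str) -> float:
    """RH: condylar summit to gonion distance of one side, mm (uncorrected;
    the measure is predominantly vertical)."""
    hc, go = _side_points(ls, side)
    return geometry.distance(hc, go, ls.calibration)


def corpus_length(
    ls: LandmarkSet,
    side: str,
    dc: DistortionConfig | None = None,
    msp_rule: str = "perpendicular_through_ans",
) -> tuple[float, float]:
    """CL: gonion-to-pogonion distance of one side; returns (raw, corrected) mm.

    The corrected value recomputes the distance after per-landmark
    horizontal demagnification about the MSP (see
    :func:`mandasym.distortion.undistort_point`), which exactly inverts
    per-hemimandible horizontal magnification and reduces to raw x DF for
    a horizontal same-side segment.  With a unit configuration the two
    values are identical.
    """
    dc = dc or DistortionConfig.unit()
    _, go = _side_points(ls, side)
    pg = ls.point(LandmarkName.PG)
    raw = geometry.distance(go, pg, ls.calibration)
    msp = msp_of(ls, msp_rule)
    corrected = geometry.distance(
        undistort_point(go, msp, dc), undistort_point(pg, msp, dc), ls.calibration
    )
    return raw, corrected


def gonial_angle(ls: LandmarkSet, side: str) -> float:
    """GA: interior angle at the gonion between the ramus (toward the
    condylar summit) and the corpus (toward pogonion), degrees.  Computed
    from raw coordinates; no distortion correction is applied."""
    hc, go = _side_points(ls, side)
    return geometry.angle_at_vertex(go, hc, ls.point(LandmarkName.PG))


class MidlineDeviations(NamedTuple):
    pg_msp_raw: float
    pg_msp_corr: float
    ip_msp_raw: float
    ip_msp_corr: float


def midline_deviations(
    ls: LandmarkSet,
    dc: DistortionConfig | None = None,
    msp_rule: str = "perpendicular_through_ans",
) -> MidlineDeviations:
    """Signed x-parallel deviations of Pg and IP from the MSP, mm.

    Positive values deviate toward the patient's left.  Corrected values
    apply the DF of the side the point deviates toward.
    """
    dc = dc or DistortionConfig.unit()
    msp = msp_of(ls, msp_rule)
    out = []
    for name in (LandmarkName.PG, LandmarkName.IP):
        raw = geometry.horizontal_distance_to_line(ls.point(name), msp, ls.calibration)
        out += [raw, correct_horizontal(raw, "midline", dc)]
    return MidlineDeviations(*out)


def condylar_height_difference(ls: LandmarkSet) -> tuple[float, str]:
    """CHD: absolute vertical (image y) offset between the condylar
    summits, mm, plus which side is taller (more cranial = smaller y).

    Returns ``(chd_mm, taller_side)`` with ``taller_side`` in
    ``{'right', 'left', 'equal'}``; ``equal`` requires exact coordinate
    equality (callers may round if they need a tolerance).
    """
    y_r = ls.point(LandmarkName.RHC).y
    y_l = ls.point(LandmarkName.LHC).y
    chd = abs(y_r - y_l) * ls.calibration.mm_per_pixel
    if y_r == y_l:
        return 0.0, "equal"
    return chd, ("right" if y_r < y_l else "left")


@dataclass(frozen=True)
class MeasurementReport:
    """All per-side and midline measurements of one radiograph."""

    patient_id: str
    rh_right: float
    rh_left: float
    cl_right_raw: float
    cl_right_corr: float
    cl_left_raw: float
    cl_left_corr: float
    ga_right: float
    ga_left: float
    pg_msp_raw: float
    pg_msp_corr: float
    ip_msp_raw: float
    ip_msp_corr: float
    chd: float
    taller_side: str
    msp: MSPLine

    def __post_init__(self) -> None:
        for label in ("rh_right", "rh_left", "cl_right_raw", "cl_right_corr",
                      "cl_left_raw", "cl_left_corr", "chd"):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be non-negative")
        for label in ("ga_right", "ga_left"):
            if not 0.0 < getattr(self, label) < 180.0:
                raise ValueError(f"{label} must lie strictly between 0 and 180 degrees")
        if (self.taller_side == "equal") != (self.chd == 0.0):
            raise ValueError("taller_side must be 'equal' exactly when chd is 0")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "patient_id", "rh_right", "rh_left", "cl_right_raw", "cl_right_corr",
            "cl_left_raw", "cl_left_corr", "ga_right", "ga_left",
            "pg_msp_raw", "pg_msp_corr", "ip_msp_raw", "ip_msp_corr",
            "chd", "taller_side")}
        d["msp"] = {"anchor": [self.msp.anchor.x, self.msp.anchor.y],
                    "direction": list(self.msp.direction)}
        return d


def analyze(
    ls: LandmarkSet,
    dc: DistortionConfig | None = None,
    msp_rule: str = "perpendicular_through_ans",
) -> MeasurementReport:
    """Run the full analysis on a validated landmark set."""
    findings = validate_landmark_set(ls)
    if findings:
        raise ValidationError("; ".join(findings))
    dc = dc or DistortionConfig.unit()
    cl_r = corpus_length(ls, "right", dc, msp_rule)
    cl_l = corpus_length(ls, "left", dc, msp_rule)
    mid = midline_deviations(ls, dc, msp_rule)
    chd, taller = condylar_height_difference(ls)
    return MeasurementReport(
        patient_id=ls.patient_id,
        rh_right=ramus_height(ls, "right"),
        rh_left=ramus_height(ls, "left"),
        cl_right_raw=cl_r[0],
        cl_right_corr=cl_r[1],
        cl_left_raw=cl_l[0],
        cl_left_corr=cl_l[1],
        ga_right=gonial_angle(ls, "right"),
        ga_left=gonial_angle(ls, "left"),
        pg_msp_raw=mid.pg_msp_raw,
        pg_msp_corr=mid.pg_msp_corr,
        ip_msp_raw=mid.ip_msp_raw,
        ip_msp_corr=mid.ip_msp_corr,
        chd=chd,
        taller_side=taller,
        msp=msp_of(ls, msp_rule),
    )
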