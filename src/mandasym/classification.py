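"""Severity grading of millimetre differences and the functional-vs-
morphological differential diagnosis.

Differences between sides (or midline deviations) are graded on the
standard four-band scale: non-significant [0, 2) mm, light [2, 3) mm,
moderate [3, 5] mm, severe > 5 mm.  The printed band edges overlap at 2,
3 and 5 mm; this implementation uses lower-inclusive half-open intervals
except for the severe band, whose bound is the scale's one explicitly
strict inequality (> 5 mm), making moderate the closed interval [3, 5].

Variables split as in the analysis they grade: RH and CL side differences
are *morphological* (true size asymmetry of the mandible); Pg-MSP, IP-MSP
and CHD are *functional* (positional, since the radiograph is taken in
functional movement).  The gonial-angle difference is reported in degrees
but not graded — the millimetre bands do not apply to angles.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .measurements import MeasurementReport


class AsymmetryCategory(enum.IntEnum):
    """Severity grades, totally ordered."""

    NON_SIGNIFICANT = 0
    LIGHT = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:  # 'non_significant', 'light', ...
        return self.name.lower()


def classify_difference(diff_mm: float) -> AsymmetryCategory:
    """Grade a non-negative millimetre difference on the four-band scale."""
    if not (math.isfinite(diff_mm) and diff_mm >= 0):
        raise ValueError(f"difference must be a non-negative finite length, got {diff_mm}")
    if diff_mm < 2.0:
        return AsymmetryCategory.NON_SIGNIFICANT
    if diff_mm < 3.0:
        return AsymmetryCategory.LIGHT
    if diff_mm <= 5.0:
        return AsymmetryCategory.MODERATE
    return AsymmetryCategory.SEVERE


@dataclass(frozen=True)
class DiagnosisReport:
    """Per-variable severity grades plus the overall verdict.

    ``verdict`` is ``none`` / ``functional`` / ``morphological`` /
    ``combined`` according to which variable groups reach the flag
    threshold.
    """

    patient_id: str
    cat_rh: AsymmetryCategory
    cat_cl: AsymmetryCategory
    cat_pg: AsymmetryCategory
    cat_ip: AsymmetryCategory
    cat_chd: AsymmetryCategory
    ga_diff_deg: float
    overall_morphological: bool
    overall_functional: bool
    verdict: str

    def __post_init__(self) -> None:
        expected = {
            (False, False): "none",
            (True, False): "morphological",
            (False, True): "functional",
            (True, True): "combined",
        }[(self.overall_morphological, self.overall_functional)]
        if self.verdict != expected:
            raise ValueError(
                f"verdict {self.verdict!r} inconsistent with overall flags "
                f"(expected {expected!r})"
            )

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "cat_rh": str(self.cat_rh),
            "cat_cl": str(self.cat_cl),
            "cat_pg": str(self.cat_pg),
            "cat_ip": str(self.cat_ip),
            "cat_chd": str(self.cat_chd),
            "ga_diff_deg": self.ga_diff_deg,
            "overall_morphological": self.overall_morphological,
            "overall_functional": self.overall_functional,
            "verdict": self.verdict,
        }


def diagnose(
    report: MeasurementReport,
    threshold: AsymmetryCategory = AsymmetryCategory.LIGHT,
) -> DiagnosisReport:
    """Differential diagnosis from one measurement report.

    Morphological variables: |RH right - left| and |corrected CL right -
    left|.  Functional variables: |corrected Pg-MSP|, |corrected IP-MSP|
    and CHD.  A variable group flags when any of its variables reaches
    ``threshold`` (default: light) or worse.
    """
    cat_rh = classify_difference(abs(report.rh_right - report.rh_left))
    cat_cl = classify_difference(abs(report.cl_right_corr - report.cl_left_corr))
    cat_pg = classify_difference(abs(report.pg_msp_corr))
    cat_ip = classify_difference(abs(report.ip_msp_corr))
    cat_chd = classify_difference(report.chd)

    morph = any(c >= threshold for c in (cat_rh, cat_cl))
    func = any(c >= threshold for c in (cat_pg, cat_ip, cat_chd))
    verdict = {
        (False, False): "none",
        (True, False): "morphological",
        (False, True): "functional",
        (True, True): "combined",
    }[(morph, func)]
    return DiagnosisReport(
        patient_id=report.patient_id,
        cat_rh=cat_rh,
        cat_cl=cat_cl,
        cat_pg=cat_pg,
        cat_ip=cat_ip,
        cat_chd=cat_chd,
        ga_diff_deg=abs(report.ga_right - report.ga_left),
        overall_morphological=morph,
        overall_functional=func,
        verdict=verdict,
    )
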