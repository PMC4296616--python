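"""Batch output: per-patient CSV/JSON records, group summary tables in the
mean ± SD layout of the reference analysis, and the optional landmark
overlay renderer."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import DiagnosisReport
from .landmarks import CANONICAL_ORDER, LandmarkName, LandmarkSet
from .measurements import MeasurementReport

#: Fixed column order of the per-patient measurement CSV.
CSV_COLUMNS = (
    "patient_id",
    "rh_right", "rh_left",
    "cl_right_raw", "cl_right_corr", "cl_left_raw", "cl_left_corr",
    "ga_right", "ga_left",
    "pg_msp_raw", "pg_msp_corr", "ip_msp_raw", "ip_msp_corr",
    "chd", "taller_side",
    "cat_rh", "cat_cl", "cat_pg", "cat_ip", "cat_chd", "verdict",
)

# Table-1/2 style rows use the "ramus height + condyle" label of the source
# tables: the condylar summit-to-gonion distance includes the condyle by
# construction, so the CSV/summary name spells that out.
_SIDE_VARIABLES = (
    ("ramus_condyle_height_mm", "rh_right", "rh_left"),
    ("corpus_length_mm", "cl_right_corr", "cl_left_corr"),
    ("gonial_angle_deg", "ga_right", "ga_left"),
)
_MIDLINE_VARIABLES = (
    ("pg_msp_mm", "pg_msp_corr"),
    ("ip_msp_mm", "ip_msp_corr"),
    ("chd_mm", "chd"),
)


def fmt_value(x: float) -> str:
    """Canonical numeric formatting shared by CSV output and overlay labels
    (single source of truth for displayed values)."""
    return f"{x:.3f}"


def csv_record(mr: MeasurementReport, dr: DiagnosisReport) -> dict[str, str]:
    """One measurement+diagnosis row, all values pre-formatted."""
    rec = {"patient_id": mr.patient_id}
    for col in CSV_COLUMNS[1:14]:
        rec[col] = fmt_value(getattr(mr, col))
    rec["taller_side"] = mr.taller_side
    for col in ("cat_rh", "cat_cl", "cat_pg", "cat_ip", "cat_chd"):
        rec[col] = str(getattr(dr, col))
    rec["verdict"] = dr.verdict
    return rec


def records_to_csv(records: Sequence[Mapping[str, str]]) -> str:
    lines = [",".join(CSV_COLUMNS)]
    lines += [",".join(str(rec[c]) for c in CSV_COLUMNS) for rec in records]
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD of every variable for one group of reports."""

    label: str
    n: int
    table: pd.DataFrame  # columns: variable, side, mean, sd


def summarize(groups: Mapping[str, Sequence[MeasurementReport]]) -> pd.DataFrame:
    """Per-group, per-variable mean and sample SD (n-1 denominator).

    Returns a tidy frame with columns ``group, n, variable, side, mean,
    sd``; side-paired variables get right/left rows (the Table-1/2
    layout), midline variables a single row with magnitudes for the
    signed deviations (the Table-3 layout).  SD is reported as 0 for
    single-report groups.
    """
    rows = []
    for label, reports in groups.items():
        if not reports:
            raise ValueError(f"group {label!r} is empty")
        n = len(reports)

        def stat(values: list[float]) -> tuple[float, float]:
            arr = np.asarray(values, dtype=float)
            sd = float(arr.std(ddof=1)) if n > 1 else 0.0
            return float(arr.mean()), sd

        for var, right_attr, left_attr in _SIDE_VARIABLES:
            for side, attr in (("right", right_attr), ("left", left_attr)):
                mean, sd = stat([getattr(r, attr) for r in reports])
                rows.append((label, n, var, side, mean, sd))
        for var, attr in _MIDLINE_VARIABLES:
            mean, sd = stat([abs(getattr(r, attr)) for r in reports])
            rows.append((label, n, var, "midline", mean, sd))
    return pd.DataFrame(rows, columns=["group", "n", "variable", "side", "mean", "sd"])


def format_summary(table: pd.DataFrame) -> str:
    """Human-readable mean ± SD block per group."""
    lines = []
    for group, sub in table.groupby("group", sort=False):
        n = int(sub["n"].iloc[0])
        lines.append(f"Group {group} (n={n})")
        for _, row in sub.iterrows():
            side = "" if row["side"] == "midline" else f" [{row['side']}]"
            lines.append(
                f"  {row['variable']}{side}: {row['mean']:.1f} ± {row['sd']:.1f}"
            )
    return "\n".join(lines) + "\n"


def render_overlay(
    ls: LandmarkSet,
    report: MeasurementReport,
    out_path: str | Path,
    image_path: str | Path | None = None,
) -> None:
    """Draw the analysis over a radiograph (or a blank canvas).

    Renders the nine points, the RH and CL segments, the MSP, the CHD
    horizontal from the taller condyle and the Pg/IP midline links, with
    value labels taken verbatim from the CSV formatting.  Purely
    cosmetic: never feeds back into any reported value.
    """
    from PIL import Image, ImageDraw

    pts = {name: ls.point(name) for name in CANONICAL_ORDER}
    if image_path is not None:
        img = Image.open(image_path).convert("RGB")
    else:
        xs = [p.x for p in pts.values()]
        ys = [p.y for p in pts.values()]
        pad = 60
        img = Image.new(
            "RGB",
            (int(max(xs) - min(xs)) + 2 * pad, int(max(ys) - min(ys)) + 2 * pad),
            "white",
        )
        shift_x, shift_y = pad - min(xs), pad - min(ys)
        pts = {k: type(p)(p.x + shift_x, p.y + shift_y) for k, p in pts.items()}

    w, h = img.size
    if any(not (0 <= p.x < w and 0 <= p.y < h) for p in pts.values()):
        warnings.warn("some landmarks fall outside the image bounds", stacklevel=2)

    draw = ImageDraw.Draw(img)

    def seg(a: LandmarkName, b: LandmarkName, color: str) -> None:
        draw.line([(pts[a].x, pts[a].y), (pts[b].x, pts[b].y)], fill=color, width=2)

    # ramus and corpus segments
    seg(LandmarkName.RHC, LandmarkName.RGO, "red")
    seg(LandmarkName.LHC, LandmarkName.LGO, "red")
    seg(LandmarkName.RGO, LandmarkName.PG, "blue")
    seg(LandmarkName.LGO, LandmarkName.PG, "blue")

    # MSP across the full canvas (re-anchored if the canvas was shifted)
    msp = report.msp
    anchor = pts[LandmarkName.ANS]
    dx, dy = msp.direction
    if abs(dy) > 1e-12:
        top = (anchor.x + (0 - anchor.y) * dx / dy, 0)
        bottom = (anchor.x + (h - anchor.y) * dx / dy, h)
        draw.line([top, bottom], fill="green", width=2)
        # horizontal midline links
        for name in (LandmarkName.PG, LandmarkName.IP):
            p = pts[name]
            x_line = anchor.x + (p.y - anchor.y) * dx / dy
            draw.line([(x_line, p.y), (p.x, p.y)], fill="purple", width=2)

    # CHD horizontal from the taller condyle toward the other side
    if report.taller_side != "equal":
        taller = pts[LandmarkName.RHC if report.taller_side == "right" else LandmarkName.LHC]
        other = pts[LandmarkName.LHC if report.taller_side == "right" else LandmarkName.RHC]
        draw.line([(taller.x, taller.y), (other.x, taller.y)], fill="orange", width=2)
        draw.line([(other.x, taller.y), (other.x, other.y)], fill="orange", width=1)

    for name, p in pts.items():
        draw.ellipse([p.x - 4, p.y - 4, p.x + 4, p.y + 4], outline="red", width=2)
        draw.text((p.x + 6, p.y - 12), name.value, fill="black")

    labels = [
        f"RH R/L: {fmt_value(report.rh_right)}/{fmt_value(report.rh_left)} mm",
        f"CL R/L: {fmt_value(report.cl_right_corr)}/{fmt_value(report.cl_left_corr)} mm",
        f"GA R/L: {fmt_value(report.ga_right)}/{fmt_value(report.ga_left)} deg",
        f"Pg-MSP: {fmt_value(report.pg_msp_corr)} mm",
        f"IP-MSP: {fmt_value(report.ip_msp_corr)} mm",
        f"CHD: {fmt_value(report.chd)} mm ({report.taller_side})",
    ]
    for i, text in enumerate(labels):
        draw.text((10, 10 + 14 * i), text, fill="black")

    img.save(out_path)
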