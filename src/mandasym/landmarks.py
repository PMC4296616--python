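"""Nine-landmark data model for panoramic-radiograph asymmetry analysis.

Coordinate convention (used throughout the package): image pixels with the
origin at the top-left corner, ``x`` increasing to the viewer's right and
``y`` increasing downward.  Panoramic radiographs are displayed in the
conventional radiographic orientation, i.e. the *patient's right* side
appears on the *viewer's left*; "most cranial" therefore means smallest
``y``.  A single isotropic ``mm_per_pixel`` scale converts pixel distances
to millimetres.
"""
from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class LandmarkError(ValueError):
    """Base class for landmark I/O and validation errors."""


class ParseError(LandmarkError):
    """A landmark file could not be parsed."""


class ValidationError(LandmarkError):
    """A parsed landmark set violates a structural invariant."""


class CalibrationError(LandmarkError):
    """Missing or non-positive pixel calibration."""


class LandmarkName(str, enum.Enum):
    """The nine anatomic landmarks, in canonical acquisition order 1-9.

    RPF/LPF: right/left pterygomaxillary fossa; ANS: anterior nasal spine;
    RHC/LHC: most cranial point of the right/left condyle; RGO/LGO:
    right/left gonion; PG: pogonion; IP: inter-incisive point.
    """

    RPF = "RPF"
    ANS = "ANS"
    LPF = "LPF"
    LHC = "LHC"
    LGO = "LGO"
    RHC = "RHC"
    RGO = "RGO"
    PG = "PG"
    IP = "IP"

    @classmethod
    def parse(cls, name: str) -> "LandmarkName":
        """Case-insensitive lookup ('Pg', 'pg' and 'PG' are the same point)."""
        try:
            return cls(name.strip().upper())
        except ValueError:
            raise ParseError(f"unknown landmark name {name!r}") from None


#: Canonical acquisition order (point 1 through point 9).
CANONICAL_ORDER: tuple[LandmarkName, ...] = tuple(LandmarkName)


@dataclass(frozen=True, slots=True)
class Point2D:
    """A point in image coordinates (pixels unless stated otherwise)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True, slots=True)
class PixelCalibration:
    """Isotropic pixel-to-millimetre scale."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mm_per_pixel) and self.mm_per_pixel > 0):
            raise CalibrationError(
                f"mm_per_pixel must be a positive finite number, got {self.mm_per_pixel}"
            )


@dataclass(frozen=True)
class LandmarkSet:
    """The nine named landmarks of one radiograph plus its calibration."""

    patient_id: str
    points: Mapping[LandmarkName, Point2D]
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", dict(self.points))

    def point(self, name: LandmarkName) -> Point2D:
        return self.points[name]

    def replace_points(self, points: Mapping[LandmarkName, Point2D]) -> "LandmarkSet":
        return LandmarkSet(self.patient_id, dict(points), self.calibration)


# Laterality orderings enforced in viewer coordinates (patient's right on the
# viewer's left): each tuple must be strictly increasing in x.
_LATERALITY_CHAINS: tuple[tuple[LandmarkName, ...], ...] = (
    (LandmarkName.RPF, LandmarkName.ANS, LandmarkName.LPF),
    (LandmarkName.RHC, LandmarkName.LHC),
    (LandmarkName.RGO, LandmarkName.LGO),
)


def validate_landmark_set(ls: LandmarkSet) -> list[str]:
    """Check structural invariants; return one finding string per violation.

    An empty list means the set is valid.  Findings name the offending
    landmark(s) so they can be surfaced directly to the user.
    """
    findings: list[str] = []
    for name in CANONICAL_ORDER:
        if name not in ls.points:
            findings.append(f"missing landmark {name.value}")
    for chain in _LATERALITY_CHAINS:
        if any(name not in ls.points for name in chain):
            continue
        for a, b in zip(chain, chain[1:]):
            if not ls.points[a].x < ls.points[b].x:
                findings.append(
                    f"laterality violation: expected x({a.value}) < x({b.value}) "
                    f"(patient's right must appear on the viewer's left), got "
                    f"x({a.value})={ls.points[a].x} and x({b.value})={ls.points[b].x}"
                )
    return findings


def _require_valid(ls: LandmarkSet) -> LandmarkSet:
    findings = validate_landmark_set(ls)
    if findings:
        raise ValidationError("; ".join(findings))
    return ls


def _parse_points_mapping(raw: Mapping[str, object]) -> dict[LandmarkName, Point2D]:
    points: dict[LandmarkName, Point2D] = {}
    for key, value in raw.items():
        name = LandmarkName.parse(str(key))
        if name in points:
            raise ParseError(f"duplicate landmark {name.value}")
        try:
            x, y = value  # type: ignore[misc]
            points[name] = Point2D(float(x), float(y))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad coordinates for landmark {name.value}: {value!r}") from exc
    return points


def read_landmarks(
    path: str | Path,
    format: str | None = None,
    *,
    mm_per_pixel: float | None = None,
    patient_id: str | None = None,
) -> LandmarkSet:
    """Read one landmark set from ``path``.

    ``format`` is one of ``json``, ``csv`` or ``imagej_points``; when omitted
    it is inferred from the file suffix (.json / .csv / anything else ->
    imagej_points).  The imagej_points dialect is a plain whitespace- or
    tab-separated ``x y`` list in canonical acquisition order 1-9 with an
    optional non-numeric header line; it carries no calibration, so
    ``mm_per_pixel`` must be supplied.  Explicit ``mm_per_pixel`` /
    ``patient_id`` arguments override values found in the file.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "imagej_points", ".json": "json", ".csv": "csv"}.get(suffix, "imagej_points")
    if format not in {"json", "csv", "imagej_points"}:
        raise ValueError(f"unknown landmark format {format!r}")

    reader = {"json": _read_json, "csv": _read_csv, "imagej_points": _read_imagej}[format]
    pid, points, cal = reader(path)
    if patient_id is not None:
        pid = patient_id
    if mm_per_pixel is not None:
        cal = float(mm_per_pixel)
    if pid is None:
        pid = path.stem
    if cal is None:
        raise CalibrationError(f"{path}: no mm_per_pixel calibration supplied")
    ls = LandmarkSet(pid, points, PixelCalibration(cal))
    return _require_valid(ls)


def _read_json(path: Path):
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(data, dict) or "points" not in data:
        raise ParseError(f"{path}: expected an object with a 'points' mapping")
    points = _parse_points_mapping(data["points"])
    cal = data.get("mm_per_pixel")
    return data.get("patient_id"), points, (float(cal) if cal is not None else None)


def _read_csv(path: Path):
    pid = None
    cal = None
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            key, _, value = stripped.lstrip("#").partition("=")
            key = key.strip().lower()
            if key == "mm_per_pixel":
                try:
                    cal = float(value)
                except ValueError as exc:
                    raise ParseError(f"{path}: bad #mm_per_pixel comment {value!r}") from exc
            elif key == "patient_id":
                pid = value.strip()
            continue
        rows.append(next(csv.reader([stripped])))
    if not rows or [c.strip().lower() for c in rows[0][:3]] != ["name", "x", "y"]:
        raise ParseError(f"{path}: expected CSV header 'name,x,y'")
    mapping: dict[str, tuple[str, str]] = {}
    for row in rows[1:]:
        if len(row) < 3:
            raise ParseError(f"{path}: short CSV row {row!r}")
        if row[0] in mapping:
            raise ParseError(f"{path}: duplicate landmark {row[0]!r}")
        mapping[row[0]] = (row[1], row[2])
    points = _parse_points_mapping(mapping)
    return pid, points, cal


def _read_imagej(path: Path):
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    rows: list[tuple[float, float]] = []
    for i, line in enumerate(lines):
        fields = line.replace(",", " ").split()
        try:
            values = [float(f) for f in fields]
        except ValueError:
            if i == 0:  # tolerate a single header line
                continue
            raise ParseError(f"{path}: non-numeric point row {line!r}") from None
        if len(values) == 3:  # ImageJ measurement exports prepend a row index
            values = values[1:]
        if len(values) != 2:
            raise ParseError(f"{path}: expected 'x y' row, got {line!r}")
        rows.append((values[0], values[1]))
    if len(rows) != 9:
        raise ParseError(f"{path}: expected 9 points, got {len(rows)}")
    points = {name: Point2D(x, y) for name, (x, y) in zip(CANONICAL_ORDER, rows)}
    return None, points, None


def write_landmarks(ls: LandmarkSet, path: str | Path, format: str | None = None) -> None:
    """Write a valid landmark set to ``path`` as ``json`` or ``csv``.

    Coordinates are stored at full precision so write -> read is an exact
    round trip.  Refuses to serialize an invalid set.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format not in {"json", "csv"}:
        raise ValueError(f"unknown landmark output format {format!r}")
    _require_valid(ls)
    if format == "json":
        payload = {
            "patient_id": ls.patient_id,
            "mm_per_pixel": ls.calibration.mm_per_pixel,
            "points": {name.value: [p.x, p.y] for name, p in _ordered(ls)},
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        lines = [
            f"#patient_id={ls.patient_id}",
            f"#mm_per_pixel={ls.calibration.mm_per_pixel!r}",
            "name,x,y",
        ]
        lines += [f"{name.value},{p.x!r},{p.y!r}" for name, p in _ordered(ls)]
        path.write_text("\n".join(lines) + "\n")


def _ordered(ls: LandmarkSet) -> Iterable[tuple[LandmarkName, Point2D]]:
    return ((name, ls.points[name]) for name in CANONICAL_ORDER)
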