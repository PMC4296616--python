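import json

import pytest

from mandasym.landmarks import (
    CANONICAL_ORDER,
    CalibrationError,
    LandmarkName,
    LandmarkSet,
    ParseError,
    PixelCalibration,
    Point2D,
    ValidationError,
    read_landmarks,
    validate_landmark_set,
    write_landmarks,
)


def test_canonical_order_is_the_nine_point_acquisition_sequence():
    assert [n.value for n in CANONICAL_ORDER] == [
        "RPF", "ANS", "LPF", "LHC", "LGO", "RHC", "RGO", "PG", "IP",
    ]


@pytest.mark.parametrize("raw", ["Pg", "pg", "PG", " pg "])
def test_landmark_names_parse_case_insensitively(raw):
    assert LandmarkName.parse(raw) is LandmarkName.PG


def test_unknown_landmark_name_is_a_parse_error():
    with pytest.raises(ParseError):
        LandmarkName.parse("XYZ")


def test_point_rejects_non_finite_coordinates():
    with pytest.raises(ValueError):
        Point2D(float("nan"), 0.0)


def test_calibration_must_be_positive():
    with pytest.raises(CalibrationError):
        PixelCalibration(0.0)


def test_validate_accepts_a_complete_well_ordered_set(symmetric_patient):
    assert validate_landmark_set(symmetric_patient) == []


@pytest.mark.parametrize("dropped", list(CANONICAL_ORDER))
def test_deleting_any_single_landmark_yields_exactly_one_missing_finding(
    symmetric_patient, dropped
):
    points = dict(symmetric_patient.points)
    del points[dropped]
    findings = validate_landmark_set(symmetric_patient.replace_points(points))
    assert len(findings) == 1
    assert findings[0] == f"missing landmark {dropped.value}"


def test_swapped_condyles_produce_a_laterality_finding(symmetric_patient):
    points = dict(symmetric_patient.points)
    points[LandmarkName.RHC], points[LandmarkName.LHC] = (
        points[LandmarkName.LHC], points[LandmarkName.RHC])
    findings = validate_landmark_set(symmetric_patient.replace_points(points))
    assert len(findings) == 1
    assert "RHC" in findings[0] and "LHC" in findings[0]


@pytest.mark.parametrize("fmt", ["json", "csv"])
def test_write_read_round_trip_is_exact(tmp_path, asymmetric_patient, fmt):
    path = tmp_path / f"patient.{fmt}"
    write_landmarks(asymmetric_patient, path, format=fmt)
    back = read_landmarks(path, format=fmt)
    assert back.patient_id == asymmetric_patient.patient_id
    assert back.calibration == asymmetric_patient.calibration
    assert back.points == dict(asymmetric_patient.points)


def test_write_refuses_an_invalid_set(tmp_path, symmetric_patient):
    points = dict(symmetric_patient.points)
    del points[LandmarkName.IP]
    with pytest.raises(ValidationError, match="missing landmark IP"):
        write_landmarks(symmetric_patient.replace_points(points), tmp_path / "bad.json")


def test_all_three_readers_agree_on_the_same_patient(tmp_path, asymmetric_patient):
    ls = asymmetric_patient
    write_landmarks(ls, tmp_path / "p.json", format="json")
    write_landmarks(ls, tmp_path / "p.csv", format="csv")
    ij = "\n".join(f"{ls.points[n].x!r}\t{ls.points[n].y!r}" for n in CANONICAL_ORDER)
    (tmp_path / "p.txt").write_text(ij + "\n")

    from_json = read_landmarks(tmp_path / "p.json")
    from_csv = read_landmarks(tmp_path / "p.csv")
    from_ij = read_landmarks(tmp_path / "p.txt", format="imagej_points",
                             mm_per_pixel=ls.calibration.mm_per_pixel,
                             patient_id=ls.patient_id)
    assert from_json.points == from_csv.points == from_ij.points
    assert from_json.calibration == from_csv.calibration == from_ij.calibration


def test_imagej_first_row_maps_to_rpf(tmp_path, symmetric_patient):
    ls = symmetric_patient
    rows = [f"{ls.points[n].x} {ls.points[n].y}" for n in CANONICAL_ORDER]
    (tmp_path / "pts.txt").write_text("\n".join(rows))
    back = read_landmarks(tmp_path / "pts.txt", mm_per_pixel=0.1)
    assert back.points[LandmarkName.RPF] == ls.points[LandmarkName.RPF]


def test_imagej_with_wrong_point_count_is_a_parse_error(tmp_path):
    (tmp_path / "pts.txt").write_text("\n".join(f"{i} {i}" for i in range(1, 9)))
    with pytest.raises(ParseError, match="expected 9 points, got 8"):
        read_landmarks(tmp_path / "pts.txt", mm_per_pixel=0.1)


def test_imagej_without_calibration_is_a_calibration_error(tmp_path, symmetric_patient):
    rows = [f"{p.x} {p.y}" for p in
            (symmetric_patient.points[n] for n in CANONICAL_ORDER)]
    (tmp_path / "pts.txt").write_text("\n".join(rows))
    with pytest.raises(CalibrationError):
        read_landmarks(tmp_path / "pts.txt")


def test_json_with_extra_unknown_point_is_rejected(tmp_path, symmetric_patient):
    write_landmarks(symmetric_patient, tmp_path / "p.json", format="json")
    data = json.loads((tmp_path / "p.json").read_text())
    data["points"]["BOGUS"] = [1.0, 2.0]
    (tmp_path / "p.json").write_text(json.dumps(data))
    with pytest.raises(ParseError, match="BOGUS"):
        read_landmarks(tmp_path / "p.json")


def test_json_missing_a_landmark_fails_validation(tmp_path, symmetric_patient):
    write_landmarks(symmetric_patient, tmp_path / "p.json", format="json")
    data = json.loads((tmp_path / "p.json").read_text())
    del data["points"]["IP"]
    (tmp_path / "p.json").write_text(json.dumps(data))
    with pytest.raises(ValidationError, match="missing landmark IP"):
        read_landmarks(tmp_path / "p.json")
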