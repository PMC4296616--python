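import math

import numpy as np
import pytest

from conftest import mirror_landmark_set, random_patient_params, transform_landmark_set
from mandasym.distortion import DistortionConfig, DistortionSource
from mandasym.landmarks import (
    LandmarkName as L,
    LandmarkSet,
    PixelCalibration,
    Point2D,
    ValidationError,
)
from mandasym.measurements import (
    analyze,
    condylar_height_difference,
    corpus_length,
    gonial_angle,
    midline_deviations,
    ramus_height,
)
from mandasym.synthetic import PatientParams, generate_patient

_DEFAULT_POINTS = {
    L.RPF: (60, 90), L.ANS: (100, 100), L.LPF: (140, 90),
    L.LHC: (170, 150), L.LGO: (150, 190),
    L.RHC: (30, 150), L.RGO: (50, 190),
    L.PG: (100, 230), L.IP: (100, 215),
}


def make_set(cal=1.0, **overrides):
    pts = dict(_DEFAULT_POINTS, **{getattr(L, k): v for k, v in overrides.items()})
    return LandmarkSet("hand", {k: Point2D(*v) for k, v in pts.items()},
                       PixelCalibration(cal))


def test_ramus_height_345_triangle():
    ls = make_set(RHC=(100, 100), RGO=(130, 140))
    assert ramus_height(ls, "right") == pytest.approx(50.0)


def test_ramus_height_zero_for_coincident_landmarks():
    ls = make_set(RHC=(50, 190), RGO=(50, 190))
    assert ramus_height(ls, "right") == 0.0


def test_corpus_length_5_12_13_and_df_scaling():
    ls = make_set(RGO=(40, 205), PG=(100, 230))  # dx 60, dy 25 -> 65
    raw, corr = corpus_length(ls, "right")
    assert raw == pytest.approx(65.0)
    assert corr == pytest.approx(65.0)  # unit DF: identical

    dc = DistortionConfig(0.9, 1.0, DistortionSource.MACHINE_NOMINAL)
    _, corr = corpus_length(ls, "right", dc)
    # horizontal-component correction: both endpoints' offsets from the
    # vertical MSP at x=100 shrink by 0.9
    assert corr == pytest.approx(math.hypot(60 * 0.9, 25))


def test_gonial_angle_right_angle_configuration():
    ls = make_set(RHC=(50, 120), RGO=(50, 190), PG=(100, 190), IP=(100, 180))
    assert gonial_angle(ls, "right") == pytest.approx(90.0)


def test_gonial_angle_collinear_is_180():
    ls = make_set(RHC=(20, 150), RGO=(60, 190), PG=(100, 230))
    assert gonial_angle(ls, "right") == pytest.approx(180.0)


def test_gonial_angle_matches_dot_product_oracle_on_generated_anatomy():
    ls = generate_patient(PatientParams(gonial_right=107.0, gonial_left=118.0))
    for side, hc, go in (("right", L.RHC, L.RGO), ("left", L.LHC, L.LGO)):
        u = np.array([ls.point(hc).x - ls.point(go).x, ls.point(hc).y - ls.point(go).y])
        v = np.array([ls.point(L.PG).x - ls.point(go).x, ls.point(L.PG).y - ls.point(go).y])
        expected = math.degrees(
            math.acos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        )
        assert gonial_angle(ls, side) == pytest.approx(expected, abs=1e-9)


def test_midline_deviations_zero_for_symmetric_patient(symmetric_patient):
    dev = midline_deviations(symmetric_patient)
    assert dev.pg_msp_raw == pytest.approx(0.0, abs=1e-9)
    assert dev.ip_msp_raw == pytest.approx(0.0, abs=1e-9)


def test_pg_deviation_is_pixel_offset_times_calibration():
    ls = make_set(cal=0.1, PG=(128, 230))  # +28 px from the x=100 midline
    dev = midline_deviations(ls)
    assert dev.pg_msp_raw == pytest.approx(2.8)
    assert dev.pg_msp_corr == pytest.approx(2.8)


def test_chd_definition_and_taller_side():
    ls = make_set(cal=0.1, RHC=(30, 400), LHC=(170, 432))
    chd, taller = condylar_height_difference(ls)
    assert chd == pytest.approx(3.2)
    assert taller == "right"  # smaller y = more cranial

    swapped = make_set(cal=0.1, RHC=(30, 432), LHC=(170, 400))
    chd2, taller2 = condylar_height_difference(swapped)
    assert chd2 == pytest.approx(chd)
    assert taller2 == "left"


def test_chd_equal_heights():
    chd, taller = condylar_height_difference(make_set())
    assert chd == 0.0 and taller == "equal"


def test_analyze_symmetric_patient_has_no_asymmetry(symmetric_patient):
    r = analyze(symmetric_patient)
    assert r.rh_right == pytest.approx(r.rh_left, abs=1e-9)
    assert r.cl_right_raw == pytest.approx(r.cl_left_raw, abs=1e-9)
    assert r.ga_right == pytest.approx(r.ga_left, abs=1e-9)
    assert r.pg_msp_raw == pytest.approx(0.0, abs=1e-9)
    assert r.ip_msp_raw == pytest.approx(0.0, abs=1e-9)
    assert r.chd == pytest.approx(0.0, abs=1e-9)


def test_shortening_one_corpus_shifts_only_that_measurement():
    base = PatientParams(patient_id="a")
    shorter = PatientParams(patient_id="b", corpus_left=71.0)
    ra = analyze(generate_patient(base))
    rb = analyze(generate_patient(shorter))
    assert rb.cl_right_raw - rb.cl_left_raw == pytest.approx(4.0, abs=1e-9)
    assert rb.cl_right_raw == pytest.approx(ra.cl_right_raw, abs=1e-9)
    assert rb.rh_right == pytest.approx(ra.rh_right, abs=1e-9)
    assert rb.ga_right == pytest.approx(ra.ga_right, abs=1e-9)


def test_analyze_rejects_invalid_landmark_sets(symmetric_patient):
    points = dict(symmetric_patient.points)
    del points[L.PG]
    with pytest.raises(ValidationError):
        analyze(symmetric_patient.replace_points(points))


def test_mirror_equivariance_swaps_sides_and_negates_midline(asymmetric_patient):
    dc = DistortionConfig(0.85, 1.05, DistortionSource.MACHINE_NOMINAL)
    r = analyze(asymmetric_patient, dc)
    m = analyze(mirror_landmark_set(asymmetric_patient), dc.swapped())
    assert m.rh_right == pytest.approx(r.rh_left, abs=1e-9)
    assert m.rh_left == pytest.approx(r.rh_right, abs=1e-9)
    assert m.cl_right_corr == pytest.approx(r.cl_left_corr, abs=1e-9)
    assert m.ga_right == pytest.approx(r.ga_left, abs=1e-9)
    assert m.pg_msp_corr == pytest.approx(-r.pg_msp_corr, abs=1e-9)
    assert m.ip_msp_corr == pytest.approx(-r.ip_msp_corr, abs=1e-9)
    assert m.chd == pytest.approx(r.chd, abs=1e-9)
    assert {r.taller_side, m.taller_side} == {"right", "left"}


def test_translation_leaves_every_report_value_unchanged(asymmetric_patient):
    r = analyze(asymmetric_patient)
    t = analyze(transform_landmark_set(asymmetric_patient, tx=123.4, ty=-56.7))
    for attr in ("rh_right", "rh_left", "cl_right_raw", "cl_left_raw",
                 "ga_right", "ga_left", "pg_msp_raw", "ip_msp_raw", "chd"):
        assert getattr(t, attr) == pytest.approx(getattr(r, attr), abs=1e-9)
    assert t.taller_side == r.taller_side


def test_rotation_preserves_the_rotation_invariant_measurements(asymmetric_patient):
    # Pg-MSP / IP-MSP (x-parallel links) and CHD (image-vertical) are
    # defined in the standardized image frame and are deliberately not
    # rotation-invariant; distances and angles are.
    r = analyze(asymmetric_patient)
    t = analyze(transform_landmark_set(asymmetric_patient, angle_deg=3.0))
    for attr in ("rh_right", "rh_left", "cl_right_raw", "cl_left_raw",
                 "ga_right", "ga_left"):
        assert getattr(t, attr) == pytest.approx(getattr(r, attr), abs=1e-9)


def test_doubling_calibration_doubles_lengths_and_fixes_angles(asymmetric_patient):
    ls = asymmetric_patient
    doubled = LandmarkSet(ls.patient_id, dict(ls.points),
                          PixelCalibration(ls.calibration.mm_per_pixel * 2))
    r, d = analyze(ls), analyze(doubled)
    for attr in ("rh_right", "rh_left", "cl_right_raw", "cl_left_corr",
                 "pg_msp_raw", "ip_msp_corr", "chd"):
        assert getattr(d, attr) == pytest.approx(2 * getattr(r, attr), abs=1e-9)
    assert d.ga_right == r.ga_right
    assert d.ga_left == r.ga_left


def test_report_invariants_hold_over_a_random_parameter_sweep():
    rng = np.random.default_rng(7)
    for _ in range(200):
        pp = random_patient_params(rng, noise_sd=rng.uniform(0, 1), seed=int(rng.integers(2**31)))
        r = analyze(generate_patient(pp))  # __post_init__ enforces the invariants
        assert r.ga_right > 0 and r.ga_left < 180
        assert (r.taller_side == "equal") == (r.chd == 0.0)
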