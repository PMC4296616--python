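import math

import numpy as np
import pytest
from hypothesis import settings

from mandasym.landmarks import LandmarkName, LandmarkSet, PixelCalibration, Point2D
from mandasym.geometry import reflect_across_line
from mandasym.measurements import msp_of
from mandasym.synthetic import PatientParams, generate_patient

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: lateral landmark pairs swapped when a patient is mirror-imaged
MIRROR_PAIRS = (
    (LandmarkName.RPF, LandmarkName.LPF),
    (LandmarkName.RHC, LandmarkName.LHC),
    (LandmarkName.RGO, LandmarkName.LGO),
)


def mirror_landmark_set(ls: LandmarkSet) -> LandmarkSet:
    """Reflect every landmark across the constructed MSP and swap the
    left/right names (the anatomy of the mirror-imaged patient)."""
    msp = msp_of(ls)
    swap = {}
    for a, b in MIRROR_PAIRS:
        swap[a], swap[b] = b, a
    points = {
        swap.get(name, name): reflect_across_line(p, msp)
        for name, p in ls.points.items()
    }
    return LandmarkSet(ls.patient_id, points, ls.calibration)


def transform_landmark_set(ls: LandmarkSet, angle_deg: float = 0.0,
                           tx: float = 0.0, ty: float = 0.0) -> LandmarkSet:
    """Rigidly rotate (about the landmark centroid) and translate all points."""
    pts = list(ls.points.values())
    cx = sum(p.x for p in pts) / len(pts)
    cy = sum(p.y for p in pts) / len(pts)
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    out = {}
    for name, p in ls.points.items():
        x, y = p.x - cx, p.y - cy
        out[name] = Point2D(cx + c * x - s * y + tx, cy + s * x + c * y + ty)
    return LandmarkSet(ls.patient_id, out, ls.calibration)


def random_patient_params(rng: np.random.Generator, *, noise_sd: float = 0.0,
                          magnify: bool = False, seed: int = 0) -> PatientParams:
    """Randomized but geometrically feasible ground-truth parameters."""
    mag_r = mag_l = 1.0
    if magnify:
        mag_r, mag_l = rng.uniform(0.85, 1.3, size=2)
    return PatientParams(
        patient_id="rand",
        corpus_right=rng.uniform(62, 85),
        corpus_left=rng.uniform(62, 85),
        ramus_right=rng.uniform(44, 60),
        ramus_left=rng.uniform(44, 60),
        gonial_right=rng.uniform(100, 126),
        gonial_left=rng.uniform(100, 126),
        condyle_offset=rng.uniform(-4.5, 4.5),
        pg_shift=rng.uniform(-4.5, 4.5),
        ip_shift=rng.uniform(-4.5, 4.5),
        mag_right=mag_r,
        mag_left=mag_l,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture
def symmetric_patient() -> LandmarkSet:
    return generate_patient(PatientParams(patient_id="sym"))


@pytest.fixture
def asymmetric_patient() -> LandmarkSet:
    return generate_patient(PatientParams(
        patient_id="asym", corpus_left=71.0, ramus_right=53.5,
        gonial_left=114.0, condyle_offset=3.2, pg_shift=-2.8, ip_shift=-2.0,
    ))
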