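"""Synthetic landmark sets and cohorts with known ground truth.

The generator builds the nine landmarks from a parametric hemimandible
template in a millimetre "anatomy frame" whose median sagittal plane is
the vertical axis x = 0 (y down, patient's right at negative x):

* maxillary frame: ANS at the origin, pterygomaxillary fossae placed
  symmetrically at the same height, so the constructed MSP is exactly
  vertical;
* pogonion and the inter-incisive point sit below ANS, offset laterally
  by their ground-truth deviations;
* each gonion is placed from pogonion along a corpus of the requested
  length, and each condylar summit from its gonion along a ramus of the
  requested length at the requested gonial angle.  The right corpus runs
  at a fixed inclination; the left corpus inclination is solved in closed
  form so that the condylar summits differ in height by exactly the
  requested condyle offset.

Per-hemimandible horizontal magnification (about the MSP) and isotropic
Gaussian placement noise are then applied, and coordinates are converted
to image pixels.  With zero noise and unit magnification, running
:func:`mandasym.measurements.analyze` on the output recovers every
ground-truth parameter (the round-trip contract the test-suite leans on).

Cohort sampling draws per-patient parameters from group-level
distributions whose functional-magnitude targets (CHD, |Pg-MSP|,
|IP-MSP|) are truncated-at-zero normals calibrated so their means equal
the group targets exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .landmarks import (
    LandmarkName,
    LandmarkSet,
    PixelCalibration,
    Point2D,
    validate_landmark_set,
)

#: Inclination of the (right) corpus above the image horizontal, degrees.
CORPUS_INCLINATION_DEG = 8.0

# Template frame constants (millimetres, multiplied by the anatomy scale).
_PF_HALFWIDTH = 42.0   # lateral offset of each pterygomaxillary fossa
_PF_DROP = -6.0        # fossa height relative to ANS (negative = more cranial)
_PG_DROP = 68.0        # pogonion below ANS
_IP_DROP = 58.0        # inter-incisive point below ANS

# Pixel-frame placement of the anatomy origin (cosmetic; translation-invariant
# measurements do not depend on it).
_X_OFFSET_PX = 1300.0
_Y_OFFSET_PX = 350.0


class ConstructionError(ValueError):
    """Parameters do not yield a geometrically valid landmark set."""


class SamplingExhaustionError(RuntimeError):
    """Eligibility filtering rejected too many consecutive draws."""


@dataclass(frozen=True)
class PatientParams:
    """Ground-truth parameters of one synthetic patient.

    Lengths in mm, angles in degrees.  ``condyle_offset`` is the signed
    vertical condylar height difference (positive = right condyle taller,
    i.e. more cranial); ``pg_shift`` / ``ip_shift`` are signed lateral
    deviations from the midline (positive = toward the patient's left).
    ``mag_right`` / ``mag_left`` are horizontal magnification factors
    applied about the MSP; ``noise_sd`` is the per-coordinate standard
    deviation of landmark placement noise in mm.
    """

    patient_id: str = "synthetic"
    scale: float = 1.0
    corpus_right: float = 75.0
    corpus_left: float = 75.0
    ramus_right: float = 51.0
    ramus_left: float = 51.0
    gonial_right: float = 110.0
    gonial_left: float = 110.0
    condyle_offset: float = 0.0
    pg_shift: float = 0.0
    ip_shift: float = 0.0
    mag_right: float = 1.0
    mag_left: float = 1.0
    noise_sd: float = 0.0
    mm_per_pixel: float = 0.1
    teeth_in_crossbite: int = 0
    midline_dev_clinical: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "scale": self.scale,
            "corpus_right": self.corpus_right, "corpus_left": self.corpus_left,
            "ramus_right": self.ramus_right, "ramus_left": self.ramus_left,
            "mag_right": self.mag_right, "mag_left": self.mag_left,
            "mm_per_pixel": self.mm_per_pixel,
        }
        for label, v in positives.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{label} must be positive, got {v}")
        for label, v in (("gonial_right", self.gonial_right), ("gonial_left", self.gonial_left)):
            if not 0.0 < v < 180.0:
                raise ValueError(f"{label} must lie in (0, 180) degrees, got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.teeth_in_crossbite < 0:
            raise ValueError("teeth_in_crossbite must be non-negative")


def _hemimandible(pg: tuple[float, float], side_sign: float, corpus: float,
                  ramus: float, gonial_deg: float, theta: float):
    """Gonion and condylar-summit positions for one side.

    ``side_sign`` is -1 for the patient's right (negative x), +1 for the
    left; ``theta`` is the corpus inclination above horizontal (radians,
    positive = gonion more cranial than pogonion).
    """
    ga = math.radians(gonial_deg) * side_sign
    go = (pg[0] + corpus * side_sign * math.cos(theta), pg[1] - corpus * math.sin(theta))
    # unit vector gonion -> pogonion, rotated by the (signed) gonial angle
    dx, dy = -side_sign * math.cos(theta), math.sin(theta)
    wx = math.cos(ga) * dx - math.sin(ga) * dy
    wy = math.sin(ga) * dx + math.cos(ga) * dy
    hc = (go[0] + ramus * wx, go[1] + ramus * wy)
    return go, hc


def _solve_corpus_inclination(corpus: float, ramus: float, gonial_deg: float,
                              target_y: float, prefer: float) -> float:
    """Corpus inclination whose condylar summit sits at ``target_y``
    (relative to pogonion); of the two solutions, the one nearest
    ``prefer`` is returned."""
    ga = math.radians(gonial_deg)
    a = ramus * math.cos(ga) - corpus
    b = -ramus * math.sin(ga)
    amp = math.hypot(a, b)
    if amp == 0.0 or abs(target_y) > amp:
        raise ConstructionError(
            f"condyle height {target_y:.2f} mm unreachable with corpus {corpus:.1f}, "
            f"ramus {ramus:.1f}, gonial angle {gonial_deg:.1f}"
        )
    phi = math.atan2(b, a)
    base = math.asin(target_y / amp)
    candidates = [base - phi, math.pi - base - phi]
    candidates = [((t + math.pi) % (2.0 * math.pi)) - math.pi for t in candidates]
    return min(candidates, key=lambda t: abs(t - prefer))


def generate_patient(pp: PatientParams) -> LandmarkSet:
    """Deterministically build the nine landmarks for one patient."""
    s = pp.scale
    theta_r = math.radians(CORPUS_INCLINATION_DEG)
    pg = (pp.pg_shift, _PG_DROP * s)

    go_r, hc_r = _hemimandible(pg, -1.0, pp.corpus_right, pp.ramus_right,
                               pp.gonial_right, theta_r)
    target_y = (hc_r[1] - pg[1]) + pp.condyle_offset
    theta_l = _solve_corpus_inclination(pp.corpus_left, pp.ramus_left,
                                        pp.gonial_left, target_y, theta_r)
    go_l, hc_l = _hemimandible(pg, +1.0, pp.corpus_left, pp.ramus_left,
                               pp.gonial_left, theta_l)

    anatomy_mm = {
        LandmarkName.RPF: (-_PF_HALFWIDTH * s, _PF_DROP * s),
        LandmarkName.ANS: (0.0, 0.0),
        LandmarkName.LPF: (_PF_HALFWIDTH * s, _PF_DROP * s),
        LandmarkName.LHC: hc_l,
        LandmarkName.LGO: go_l,
        LandmarkName.RHC: hc_r,
        LandmarkName.RGO: go_r,
        LandmarkName.PG: pg,
        LandmarkName.IP: (pp.ip_shift, _IP_DROP * s),
    }

    rng = np.random.default_rng(pp.seed)
    noise = rng.normal(0.0, pp.noise_sd, size=(9, 2)) if pp.noise_sd > 0 else np.zeros((9, 2))

    points: dict[LandmarkName, Point2D] = {}
    for i, name in enumerate(LandmarkName):
        x, y = anatomy_mm[name]
        x *= pp.mag_left if x > 0 else pp.mag_right  # horizontal magnification about the MSP
        x += noise[i, 0]
        y += noise[i, 1]
        points[name] = Point2D(x / pp.mm_per_pixel + _X_OFFSET_PX,
                               y / pp.mm_per_pixel + _Y_OFFSET_PX)

    ls = LandmarkSet(pp.patient_id, points, PixelCalibration(pp.mm_per_pixel))
    findings = validate_landmark_set(ls)
    if findings:
        raise ConstructionError(
            "parameters produced an invalid landmark set: " + "; ".join(findings)
        )
    return ls


def eligibility(pp: PatientParams) -> str:
    """Study-group assignment from the clinical metadata.

    The crossbite group requires at least two posterior teeth in crossbite
    and a clinical mandibular dental midline deviation of at least 1 mm;
    the normal-occlusion group requires no teeth in crossbite and a
    deviation under 1 mm.  Everything else is ineligible.
    """
    if pp.teeth_in_crossbite >= 2 and pp.midline_dev_clinical >= 1.0:
        return "crossbite_group"
    if pp.teeth_in_crossbite == 0 and pp.midline_dev_clinical < 1.0:
        return "normal_group"
    return "ineligible"


@lru_cache(maxsize=64)
def _calibrated_truncnorm(target_mean: float, sd: float):
    """Frozen truncated-at-zero normal whose mean equals ``target_mean``.

    The location parameter is solved so that truncation does not shift the
    mean off the target (scale is kept at ``sd``).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")

    def mean_at(loc: float) -> float:
        return truncnorm.mean((0.0 - loc) / sd, np.inf, loc=loc, scale=sd)

    loc = brentq(lambda m: mean_at(m) - target_mean, target_mean - 8.0 * sd,
                 target_mean, xtol=1e-12)
    return truncnorm((0.0 - loc) / sd, np.inf, loc=loc, scale=sd)


@dataclass(frozen=True)
class GroupParams:
    """Sampling distribution over :class:`PatientParams` for one study group.

    Side-paired variables use a patient-level base value (normal with the
    group mean/SD) plus a within-patient left-minus-right asymmetry term;
    functional magnitudes use mean-calibrated truncated normals.
    ``crossbite_side`` fixes the deviation direction (condyle taller and
    midline points shifted toward the crossbite side); ``None`` draws an
    independent random sign per variable.
    """

    label: str
    crossbite_side: Optional[str] = None  # 'right', 'left' or None
    ramus_mean: float = 51.1
    ramus_sd: float = 1.9
    ramus_asym_mean: float = 0.4
    ramus_asym_sd: float = 1.0
    corpus_mean: float = 75.4
    corpus_sd: float = 4.4
    corpus_asym_mean: float = -0.2
    corpus_asym_sd: float = 1.2
    ga_mean: float = 109.7
    ga_sd: float = 2.9
    ga_asym_mean: float = 0.6
    ga_asym_sd: float = 1.5
    chd_mean: float = 1.2
    chd_sd: float = 0.7
    pg_msp_mean: float = 0.8
    pg_msp_sd: float = 1.3
    ip_msp_mean: float = 0.9
    ip_msp_sd: float = 0.9
    mag_right: float = 1.0
    mag_left: float = 1.0
    noise_sd: float = 0.3
    mm_per_pixel: float = 0.1

    def functional_targets(self) -> dict[str, float]:
        """Expected cohort means of the functional magnitudes (exact by
        construction of the calibrated truncated normals)."""
        return {"chd": self.chd_mean, "pg_msp": self.pg_msp_mean,
                "ip_msp": self.ip_msp_mean}

    def side_targets(self) -> dict[str, float]:
        """Expected per-side means of the morphological variables."""
        out = {}
        for var, mean, asym in (
            ("ramus", self.ramus_mean, self.ramus_asym_mean),
            ("corpus", self.corpus_mean, self.corpus_asym_mean),
            ("gonial", self.ga_mean, self.ga_asym_mean),
        ):
            out[f"{var}_right"] = mean - asym / 2.0
            out[f"{var}_left"] = mean + asym / 2.0
        return out

    def _magnitude(self, rng: np.random.Generator, mean: float, sd: float) -> float:
        return float(_calibrated_truncnorm(mean, sd).rvs(random_state=rng))

    def _signed(self, rng: np.random.Generator, magnitude: float, toward_crossbite: bool) -> float:
        """Sign a deviation magnitude.  ``toward_crossbite`` follows the
        clinical direction (shift toward the crossbite side; crossbite-side
        condyle more cranial)."""
        if self.crossbite_side is None:
            return magnitude * float(rng.choice([-1.0, 1.0]))
        sign = -1.0 if self.crossbite_side == "right" else 1.0
        return magnitude * sign if toward_crossbite else magnitude * -sign

    def sample(self, rng: np.random.Generator, patient_id: str, seed: int) -> PatientParams:
        def paired(mean, sd, asym_mean, asym_sd):
            base = rng.normal(mean, sd)
            asym = rng.normal(asym_mean, asym_sd)
            return base - asym / 2.0, base + asym / 2.0

        ramus_r, ramus_l = paired(self.ramus_mean, self.ramus_sd,
                                  self.ramus_asym_mean, self.ramus_asym_sd)
        corpus_r, corpus_l = paired(self.corpus_mean, self.corpus_sd,
                                    self.corpus_asym_mean, self.corpus_asym_sd)
        ga_r, ga_l = paired(self.ga_mean, self.ga_sd, self.ga_asym_mean, self.ga_asym_sd)

        chd = self._magnitude(rng, self.chd_mean, self.chd_sd)
        pg = self._magnitude(rng, self.pg_msp_mean, self.pg_msp_sd)
        ip = self._magnitude(rng, self.ip_msp_mean, self.ip_msp_sd)
        # crossbite-side condyle sits more cranially; + offset = right taller
        condyle_offset = (chd if self.crossbite_side == "right" else
                          -chd if self.crossbite_side == "left" else
                          chd * float(rng.choice([-1.0, 1.0])))
        pg_shift = self._signed(rng, pg, toward_crossbite=True)
        ip_shift = self._signed(rng, ip, toward_crossbite=True)

        if self.crossbite_side is not None:
            teeth = int(rng.integers(1, 5))
            midline = abs(float(rng.normal(1.8, 0.8)))
        else:
            teeth = 0
            midline = abs(float(rng.normal(0.3, 0.3)))

        return PatientParams(
            patient_id=patient_id,
            corpus_right=corpus_r, corpus_left=corpus_l,
            ramus_right=ramus_r, ramus_left=ramus_l,
            gonial_right=ga_r, gonial_left=ga_l,
            condyle_offset=condyle_offset,
            pg_shift=pg_shift, ip_shift=ip_shift,
            mag_right=self.mag_right, mag_left=self.mag_left,
            noise_sd=self.noise_sd, mm_per_pixel=self.mm_per_pixel,
            teeth_in_crossbite=teeth, midline_dev_clinical=midline,
            seed=seed,
        )


def crossbite_group_defaults() -> GroupParams:
    """Unilateral posterior crossbite group (crossbite on the patient's
    right by convention); side-paired defaults follow the crossed /
    non-crossed pattern of the reference sample."""
    return GroupParams(
        label="crossbite",
        crossbite_side="right",
        ramus_mean=51.8, ramus_sd=5.9, ramus_asym_mean=-0.2, ramus_asym_sd=2.0,
        corpus_mean=69.15, corpus_sd=6.7, corpus_asym_mean=1.5, corpus_asym_sd=2.5,
        ga_mean=112.7, ga_sd=6.3, ga_asym_mean=0.2, ga_asym_sd=2.0,
        chd_mean=3.2, chd_sd=1.7,
        pg_msp_mean=2.8, pg_msp_sd=2.2,
        ip_msp_mean=2.0, ip_msp_sd=1.9,
    )


def normal_group_defaults() -> GroupParams:
    """Normal-occlusion control group."""
    return GroupParams(label="normal", crossbite_side=None)


@dataclass(frozen=True)
class CohortParams:
    """A two-group synthetic cohort specification."""

    n_crossbite: int = 5
    n_normal: int = 5
    crossbite: GroupParams = field(default_factory=crossbite_group_defaults)
    normal: GroupParams = field(default_factory=normal_group_defaults)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crossbite < 0 or self.n_normal < 0:
            raise ValueError("group counts must be non-negative")


def generate_cohort(cp: CohortParams) -> list[tuple[LandmarkSet, PatientParams]]:
    """Sample, filter and build a full cohort; reproducible given the seed.

    Draws per-group parameters, keeps only draws passing the matching
    eligibility rule (and geometric construction), and returns exactly the
    requested counts with ground truth attached, crossbite group first.
    """
    rng = np.random.default_rng(cp.seed)
    out: list[tuple[LandmarkSet, PatientParams]] = []
    for group, want, n, prefix in (
        (cp.crossbite, "crossbite_group", cp.n_crossbite, "xb"),
        (cp.normal, "normal_group", cp.n_normal, "ctl"),
    ):
        kept = 0
        attempts = 0
        limit = 100 * max(n, 1) + 100
        while kept < n:
            attempts += 1
            if attempts > limit:
                raise SamplingExhaustionError(
                    f"group {group.label!r}: only {kept}/{n} eligible patients "
                    f"after {attempts - 1} draws"
                )
            seed = int(rng.integers(0, 2**31))
            try:
                pp = group.sample(rng, f"{prefix}{kept + 1:03d}", seed)
            except ValueError:
                continue
            if eligibility(pp) != want:
                continue
            try:
                ls = generate_patient(pp)
            except ConstructionError:
                continue
            out.append((ls, pp))
            kept += 1
    return out
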