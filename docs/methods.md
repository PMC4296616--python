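# Methods

## Coordinate and laterality conventions

All geometry lives in image pixel coordinates: origin top-left, x
increasing to the viewer's right, y increasing downward, so "most
cranial" means smallest y. Radiographs are assumed displayed in the
conventional orientation (patient's right on the viewer's left); the
validator enforces the implied x-orderings — x(RPF) < x(ANS) < x(LPF),
x(RHC) < x(LHC), x(RGo) < x(LGo) — rather than silently relabeling
sides. A single isotropic `mm_per_pixel` scale converts pixels to
millimetres; anisotropic pixel spacing is out of scope (side-dependent
horizontal magnification is handled by the Distortion Factor instead).
Signed midline deviations are positive toward the patient's left — an
arbitrary but fixed, documented choice.

## Median sagittal plane

The MSP is built from the three maxillary landmarks, the maxilla being
a stable reference that is unaffected by mandibular shift. Two rules
are implemented:

* `perpendicular_through_ans` (default): the line through ANS
  perpendicular to the RPF–LPF segment. It uses all three points,
  reduces to the vertical midline for a level, symmetric head, and
  rotates with a symmetrically tilted head.
* `ans_to_midpoint`: the line through ANS and the RPF–LPF midpoint.

The geometric rule behind the original tracing is not documented, so
the choice is exposed as `msp_rule` everywhere the MSP is used.

Pg-MSP and IP-MSP are *x-parallel* ("horizontal link") distances to the
MSP, not perpendicular distances; for a near-vertical MSP the two
nearly coincide, but the horizontal-link definition is followed
literally. One consequence worth stating: because these links (and the
image-vertical CHD) are anchored to the image axes, they are invariant
under translation but *not* under rotation of the whole image — they
presuppose standardized Frankfurt-plane positioning. RH, raw CL and GA
are invariant under any rigid motion, and GA also under uniform
scaling.

## Distortion Factor

Panoramic projection magnifies each hemimandible horizontally by its
own factor. A calibration object of known length imaged over each
hemimandible yields `DF_side = true / measured` (`df_from_calibration`);
with no calibration the configuration defaults to unit factors (no
correction). DF is applied to the horizontal measurements — CL, Pg-MSP
and IP-MSP — and deliberately *not* to RH or CHD (predominantly
vertical) nor to GA (a horizontal-only rescale would distort the angle
in an undocumented way).

Two consistent forms of the correction are used:

* x-parallel quantities (Pg-MSP, IP-MSP) are multiplied by the DF of
  the side the point deviates toward, sign preserved
  (`correct_horizontal`).
* CL, an oblique segment, is recomputed after *per-landmark horizontal
  demagnification*: each landmark's horizontal offset from the MSP is
  multiplied by the DF of its hemimandible, vertical positions
  untouched (`undistort_point`). For a horizontal same-side segment
  this reduces exactly to raw × DF; in general it exactly inverts the
  per-hemimandible horizontal magnification model, including corpora
  that cross the midline, which a scalar rescale of the oblique length
  cannot do. This is the package's own correction model: the source
  analysis recommends a per-hemimandible DF but prints no formula, and
  leaves open whether oblique measures received full or partial
  horizontal correction.

The distortion model is affine per side; position-dependent
(non-affine) distortion is out of scope.

## Severity grading and verdict

Millimetre differences are graded non-significant [0, 2), light
[2, 3), moderate [3, 5], severe (5, ∞). The printed band edges overlap
at 2, 3 and 5 mm; bands are taken lower-inclusive except severe, whose
"> 5 mm" is the scale's only explicitly strict inequality, making
moderate the closed interval [3, 5]. `classify_difference` is monotone
and the four bands partition [0, ∞).

The verdict combines per-variable grades: morphological variables are
|ΔRH| and |ΔCL| (corrected); functional variables are |Pg-MSP|,
|IP-MSP| (corrected) and CHD. A group flags when any of its variables
reaches a threshold category (default: light); the verdict is `none`,
`functional`, `morphological` or `combined` accordingly. The threshold
is configurable because no combined decision rule is documented for
the underlying scale; applying the millimetre bands to the midline
variables as well as the side-difference variables follows the way
"significant asymmetry" is discussed for both CL and CHD. GA
differences are reported in degrees but never graded — the millimetre
bands do not apply to angles.

The "equal condyle heights" state requires exact coordinate equality
(no epsilon), keeping the primitive deterministic; callers can round
first if they want a tolerance.

## Synthetic patients

`generate_patient` builds the nine landmarks in a millimetre anatomy
frame whose MSP is the vertical axis x = 0: ANS at the origin,
pterygomaxillary fossae symmetric at the same height (half-width 42 mm,
6 mm above ANS), pogonion 68 mm and the inter-incisive point 58 mm
below ANS, each offset laterally by its ground-truth deviation. Each
gonion is placed from Pg along a corpus of the requested length, and
each condylar summit from its gonion along a ramus of the requested
length at the requested gonial angle. The right corpus runs at a fixed
8° inclination above the horizontal; the left corpus inclination is
solved in closed form (`A sinθ + B cosθ = c`) so the condylar summits
differ in height by exactly the requested signed condyle offset —
parameters whose offset is unreachable raise a construction error.
Per-hemimandible horizontal magnification about the MSP, isotropic
Gaussian placement noise (per-coordinate SD `noise_sd`, default 0.3 mm
for cohorts — the scale of careful manual landmarking), and the
pixel conversion (0.1 mm/px default) are then applied in that order.

With zero noise and unit magnification, `analyze ∘ generate_patient`
returns every ground-truth parameter exactly (to numerical precision);
with magnification m per side and DF = 1/m, corrected CL, Pg-MSP and
IP-MSP are recovered to ~1e-12 mm. These round trips are the backbone
of the test suite.

Cohort sampling (`generate_cohort`) draws per-patient parameters from
group distributions. Side-paired variables use a patient-level base
value (group mean/SD) plus a within-patient left-minus-right asymmetry
term with its own small SD — per-side SDs describe between-patient
spread, so sampling sides independently would produce wildly
unrealistic within-patient differences. Functional magnitudes (CHD,
|Pg-MSP|, |IP-MSP|) are drawn from truncated-at-zero normals whose
location is solved numerically so the *truncated* mean equals the
group target; the crossbite group deviates toward the crossbite side
(simulated on the patient's right), controls get independent random
signs. Group defaults are seeded from a published ten-patient
reference sample (normal group: ramus ≈ 51 mm, corpus ≈ 75 mm, gonial
angle ≈ 110°, CHD 1.2 mm; crossbite group: corpus 68.4/69.9 mm
crossed/non-crossed, Pg-MSP 2.8 mm, IP-MSP 2.0 mm, CHD 3.2 mm) so that
simulated summary tables resemble clinical ones while being plainly
labelled synthetic. Magnification defaults to 1.0 per side, i.e. the
generated coordinates are treated as already at true scale;
`teeth_in_crossbite` and `midline_dev_clinical` are scalar clinical
metadata with no landmark-level geometry — they exist to exercise the
eligibility filter (crossbite group: ≥ 2 posterior teeth in crossbite
and ≥ 1 mm clinical midline deviation; controls: no crossbite teeth
and < 1 mm). Cohort generation rejects ineligible draws and raises a
sampling-exhaustion error after 100 attempts per requested patient.

What the generator does **not** emulate: real panoramic projection
(curved focal trough, position-dependent and vertical magnification),
correlated landmark placement errors, within-patient correlation
between skeletal and functional asymmetry (parameters are independent
per draw), or any image content. Passing tests therefore certify the
measurement/correction/grading pipeline and its internal consistency,
not the clinical accuracy of panoramic asymmetry assessment.

## Numerical and testing notes

* Angles use `atan2(|cross|, dot)`, well conditioned near 0° and 180°.
* The MSP direction is canonicalised (unit norm, pointing downward) so
  equal lines compare equal; horizontal distances require the
  direction's vertical component to exceed 1e-12.
* Landmark files store coordinates at full `repr` precision; write →
  read is an exact round trip for JSON and CSV. CSV/overlay output
  values are formatted once (3 decimals, ~µm) by a shared formatter so
  displayed numbers cannot diverge between outputs, and batch runs are
  byte-identical across invocations.
* Simulation sizes in the test-suite and acceptance script (500
  round-trip patients, 100 distortion round trips, 200
  mirror/rigid-transform patients, n = 200 per simulated cohort) give
  sub-millimetre standard errors on every group mean while keeping the
  whole suite in a few seconds.
* The cohort-plausibility test compares simulated group means with
  generator targets at 2 SE for the headline functional means; the
  dozen-plus additional side-mean and sign-symmetry comparisons share
  a Bonferroni-style 3.5-SE band, since simultaneous per-variable 2-SE
  checks would reject an unbiased generator about half the time.
* Group summaries report the sample SD (n−1 denominator), with SD = 0
  for single-patient groups.
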