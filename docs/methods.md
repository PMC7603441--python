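# Methods

## The arcial construction

The analysis operates on named 2-D landmarks digitised from a lateral
cephalometric radiograph. After isotropic pixel→mm calibration against a
10-mm ruler and averaging of non-superimposed bilateral landmarks, all
coordinates are expressed in a standardised frame: sella (S) at the origin,
the x-axis along the "true horizontal" obtained by rotating the S→N direction
7.0° clockwise, +x anterior, +y superior. The 7.0° constant is the
conventional inclination of the sella–nasion line above true horizontal; it
is configurable. Input files declare their raw axis facing in a header
(`x_anterior`, `y_up`), since digitisers differ and guessing a convention
silently flips anatomy.

Four reference planes are built from frame coordinates: mandibular (Go–Me),
occlusal (U1/L1 incisal midpoint to U6/L6 molar midpoint — a functional
bisected occlusal plane; the source material names the four tooth landmarks
but not a fitting rule, so the bisected form was chosen as the standard
operationalisation), palatal (ANS–PNS), and basal (the S→N direction anchored
at Si, taking S–N as the anterior-cranial-base axis and Si as the single
digitisable stand-in for the tangent contact at the sella floor).

**Point O.** The planes of a real face are not concurrent, so a theoretical
convergence point is required. The default strategy minimises the sum of
squared perpendicular distances to the four lines (closed-form 2×2 normal
equations over the line normals); it coincides with the exact intersection
whenever the planes are concurrent, is invariant under rigid motion of the
inputs, and reports the root-mean-square residual as a face-proportionality
diagnostic. A `pairwise_mean` strategy (centroid of the six pairwise
intersections) is provided for sensitivity analysis. The commercial tracing
software whose output motivated this package derives O from "an averaged
angle of the four planes" by an undisclosed rule; both strategies here are
explicit, documented surrogates, and every result records which was used.

**Arcs and estimates.** The anterior arc is the circle centred at O with
radius |O–ANS|; the posterior arc has radius |O–Sp|. Estimated gonion is the
intersection of the posterior arc with the mandibular plane; estimated
pogonion the intersection of the anterior arc with the same plane. Both
circles are centred at O and the mandibular plane always runs near O (it is
one of the planes defining it), so the two roots of each circle–line
intersection generically straddle O; the root posterior of O is a mirror
artefact with no anatomical meaning. Root selection therefore keeps only
candidates anterior of O, then takes the more posterior for gonion and the
more anterior for pogonion (ties broken away from Me and Go respectively).
Selecting by frame-x alone, without the anterior-of-O restriction, would pick
the mirror root for gonion and break the exactness of the construction on
concurrent templates. A missing intersection (arc short of the plane) is
reported as an explicit failure, never silently dropped.

Differences are reported as estimated − traced per axis, with the Euclidean
norm as the gap. When the traced pogonion sits above the mandibular plane —
as it does anatomically, since pogonion is not used to define that plane —
the estimate, which lies on the plane, is systematically inferior: the
construction's known vertical bias, which the property tests assert.

**Shape classification.** The palate/mandible shape triads (concave / convex /
horizontal palate; curved / horizontal / oblique mandible) were assigned
visually in the source workflow. External labels are therefore the primary
path. The shipped heuristic exists mainly to label synthetic data: palate by
the signed perpendicular deviation of an optional vault point from the
ANS–PNS chord normalised by chord length (threshold 0.05, deviation toward
inferior counted convex; the sign is configurable since the original
diagrams are qualitative), mandible by the MdP-to-basal divergence angle with
thresholds 22° (below: horizontal/hypodivergent) and 32° (above:
oblique/hyperdivergent). Boundary values fall to the non-extreme class.

## Statistics

* **Bland–Altman**: differences first − second; limits at mean ± 2·sd with
  the sample (n−1) standard deviation. The 2·sd multiplier (not 1.96)
  matches the reporting convention of the study being replicated and is
  configurable.
* **ICC(3,k)**: two-way mixed model, average measures, consistency —
  (MS_subject − MS_error)/MS_subject — with the 95% interval from the F
  ratio on (n−1) and (n−1)(k−1) df. The consistency form was chosen because
  the phrase "two-way fixed mixed-effects" names that formulation; absolute
  agreement is not computed. Between-subject mean squares below 1e−15 of the
  data's mean square are treated as degenerate and raise, so rounding dust in
  replicated columns cannot masquerade as signal.
* **Ryan–Joiner**: correlation of the sorted sample with Blom normal scores
  Φ⁻¹((i−3/8)/(n+1/4)); rejection when the statistic falls below the
  published critical-value approximation polynomials in 1/√n, 1/n and 1/n²
  at α ∈ {0.10, 0.05, 0.01}. No installed library provides this test, so it
  is implemented here; a Monte-Carlo critical value can be substituted.
* **Quartiles** use the (n+1)p order-statistic interpolation (the convention
  of the statistics package named in the source workflow); gap distributions
  are reported with mean and IQR side by side, and the normality gate selects
  which is emphasised — both are always emitted.
* **Spearman** rho is the Pearson correlation of average ranks; the interval
  uses the Fisher-z transform with the rank-correlation standard error
  1.03/√(n−3), and the p-value the t approximation on n−2 df. The exact
  interval method behind the study's printed CI is not documented, so the
  method here is stated and configurable rather than tuned to match.
* **Association**: uncorrected Pearson chi-squared for r×c tables with full
  expected and per-cell contribution blocks (no Yates correction — the
  reference table's printed contributions are uncorrected); collapse onto a
  2×2 indicator table preserving the grand total; Fisher's exact test with
  the two-sided point-probability rule (tables at most as probable as the
  observed, 1e−7 relative tie tolerance); Bonferroni adjustment min(1, m·p)
  with m = 9 for the nine shape combinations.

The canonical in-memory orientation of the reference contingency table is
palate shapes on rows and mandible shapes on columns; chi-squared and Fisher
are transpose-invariant, so this is purely a layout choice.

## Synthetic cohorts

The generator builds an ideal template face in frame coordinates in which the
four planes are exactly concurrent at O = (−90, −14) mm and the arc
memberships of the well-proportioned face hold exactly: ANS, N, U1 and Pog on
the anterior arc (radius 162 mm), Go and Sp on the posterior arc (83 mm).
Plane slopes default to +7° (basal, necessarily equal to the S→N
inclination), −3° (palatal), −10° (occlusal) and −25° (mandibular), giving
|SN| ≈ 71 mm — the operating range of the published Go-Me regression — and a
MdP-to-basal divergence of 32°. These are conventional craniofacial
magnitudes, not estimates of any real population.

Two template flavours exist. In *ideal* mode pogonion lies exactly on the
mandibular plane, so the construction closes with zero gap — the limiting
case used by the geometric-closure tests. The *study-like* flavour slides
pogonion 1.5° counter-clockwise along the anterior arc, lifting it ~4 mm
above the plane as on a real chin; this is the default for cohort generation
because the method's vertical pogonion bias only exists when the traced point
is above the plane.

Cohorts default to the reference study's conditions: n = 100 with a 28/26/46
skeletal class I/II/III mix; class II/III subjects have Go, Me, Pog and Gn
shifted ∓6 mm sagittally (a moderate discrepancy; the shift keeps the three
points collinear, so class alone does not lift pogonion off the plane);
every landmark then receives independent isotropic Gaussian jitter of
0.5 mm per axis, a conventional digitisation-error magnitude. Repeat
digitisation adds fresh jitter (default 0.3 mm in the repeatability
sub-study). Shape labels are drawn from the reference cohort's 3×3 joint
frequencies. Cohorts can be written as pixel-space files — rotated, scaled,
y-down, with a 10-mm ruler pair and gonion split into left/right halves — so
the reading, calibration, bilateral-averaging and frame-building stages are
exercised end to end. All randomness flows from one explicit seed and
cohorts are bit-reproducible.

Separately, `sample_sn_gome` draws (|SN|, Go-Me) pairs from the published
linear relation (intercept 22.65 mm, slope 0.5426) with residual sd 4.5 mm
and SN ~ N(71, 3.5²); the SN spread was fixed so the implied correlation
(~0.38) matches the reported correlation strength.

What the generator does *not* emulate: population covariance of craniofacial
shape, growth, sex differences, correlated digitisation errors, or landmark
identification ambiguity. Passing tests therefore demonstrate the internal
consistency and statistical calibration of the pipeline under a known model,
not the anatomical accuracy reported on real radiographs; the real cohort's
gap magnitudes (driven by genuine non-convergence of the planes) are not
reproducible without the original images.

## Missing-mandible mode

With no mandibular landmarks, point O is located from the three cranial
planes and both arcs are built; the mandibular plane itself cannot be derived
from the cranium, so its inclination must be supplied externally, anchored
either at an explicit point or at the intersection of the anterior arc with a
configured chin-height line. The mode refuses to guess an inclination, logs
the caveat into its output, and reports the regression prediction of Go-Me
from |SN| as an independent length check. Vertical positioning of a missing
mandible remains an open problem; this mode makes the dependency explicit
rather than hiding it.

## Numerical choices

Lines are stored as anchor + direction angle normalised to [0, 180)°, so
vertical planes are representable; angles are degrees throughout. Lines are
parallel below 1e−7° of direction difference (far under the 0.1° precision
of digitised tracings). Line–circle tangency is declared within 1e−9·radius,
returning the single foot-of-perpendicular point. Circle–line intersections
come from the stable half-chord form; the least-squares point from 2×2
normal equations with an explicit all-parallel guard. Reported values are
rounded to 0.1 mm / 0.1° only at the reporting layer; full precision is kept
internally. The pipeline skips unreadable subjects with a logged reason and
aborts if more than 20% of a cohort fails.

## Problem sizes

The shipped tests use cohorts of 10–100 subjects, 500 replicates for
regression recovery, 1000 replicates for the type-I-error calibration, 10⁴
random configurations for the intersection oracle, and exhaustive Fisher
enumeration for all 2×2 tables with total ≤ 60 — sizes chosen to make the
Monte-Carlo tolerances tight while keeping a full run in the order of a
minute on one core.
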