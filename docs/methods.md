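# Methods

## Scores and their conventions

All geometry lives in cm at the isocenter plane; DICOM millimetre values are
converted once, at the I/O boundary. Bank naming follows the score
definitions: the "left bank" is the higher-coordinate bank (`leaf_pos_b`),
the "right bank" the lower (`leaf_pos_a`), so the per-pair gap
`leaf_pos_b − leaf_pos_a` is non-negative. Because DICOM does not fix which
physical bank is serialized first, the reader picks the assignment that makes
the gap non-negative for the majority of *moving* pairs (closed pairs carry
no sign information) and records the choice in the parse metadata.

**In-field rule.** A leaf pair enters the score computations when its gap is
*strictly* greater than a closed-gap threshold (default **0.05 cm**,
configurable) and its leaf strip overlaps the open y-jaw interval with
positive measure. The threshold is a practical reading of "closed leaves are
excluded": abutted or parked leaves in real plans sit within a fraction of a
millimetre of contact. The y-jaws alone decide membership; the x-jaws do not
clip gaps in SW/SA, since the scores are defined on leaf positions.

**Degenerate cases.**
- LSV: a bank with ≤ 1 in-field pair, or zero position range, contributes a
  factor of 1 (no shape variability). This convention is forced by the
  unmodulated limit: a static rectangular aperture must score MCS = 1.
- SW/SA of a fully closed control point are 0, and its AAV is 0; a closed CP
  mid-arc is legal. An arc closed at *every* CP has a zero AAV denominator
  and raises an explicit error.
- The AAV denominator ("maximal aperture defined by all the segments") uses,
  per pair, the maximal left-bank and minimal right-bank positions over only
  the CPs where that pair is in-field; pairs never in-field contribute 0.
  Restricting to in-field CPs keeps parked-leaf positions (often at the
  axis) from contaminating the extent.
- LSV differences run over the in-field pairs in physical order; if the
  in-field set has interior holes, consecutive members are differenced across
  the hole. Such apertures are rare in conformal arcs and the alternative
  (splitting into islands) is not part of the score's definition.

**Segment ↔ control point.** LSV and AAV are evaluated *at* control points;
the MCS weights `w_i = cum_weight_{i+1} − cum_weight_i` belong to the spans
between them, and each span uses the mean of its endpoint scores. The MCS
accumulation uses compensated summation (`math.fsum`) over the exact
adjacent-weight differences so the unmodulated limit evaluates to 1.0
exactly rather than to within float noise.

**Plan-level aggregation.** The plan MCS is the MU-weighted mean of arc MCS.
For SW/SA/LSV/AAV the report carries both the unweighted pooled per-CP means
and MU-weighted variants, because cohort tables in the literature rarely say
which was used; the comparison layer defaults to the unweighted pooled mean.

## Machine models

Geometry is factual: 60 pairs in a 10×1.0 / 40×0.5 / 10×1.0 cm width pattern
with 15.0 cm overtravel for the Millennium-style MLC; 40 × 1.0 cm pairs with
12.5 cm overtravel for the MLCi-style MLC; boundaries symmetric about the
axis. Delivery limits are **assumptions**, shipped in
`src/vmatcx/data/machines.yaml` and editable without code changes:
4.8 deg/s, 600 MU/min continuous, 2.5 cm/s leaf speed for the
continuous-type machine; 6.0 deg/s, a halving bin ladder
600…18.75 MU/min, 2.0 cm/s for the binned-type machine. Tongue-and-groove
geometry, rounded leaf ends and interdigitation limits are out of scope.

## Kinematic estimator

Per span, the duration is the largest of the three minimal times (gantry
travel at maximum speed, MU at maximum dose rate, worst-leaf travel at
maximum leaf speed); speeds are piecewise constant (no acceleration model,
since plans carry no acceleration data). Gantry travel is measured on the
circle along the arc's rotation direction. For binned machines the commanded
dose rate is the largest bin not exceeding the continuous solution, and the
span time is recomputed — this can only lengthen delivery. When the
continuous solution falls below the smallest bin, the machine is modeled as
gating the beam at the smallest bin: the reported rate is that commanded bin
and the span time is unchanged. This is a forward model of what the plan
*demands*; measured traces (inclinometer or vendor logs) are deliberately
out of scope, so measured-delivery tables are qualitative context only.

## Paired statistics

Cohort tables report mean ± sample SD (n − 1) and two-sided Wilcoxon
matched-pair signed-rank p-values at α = 0.05, one metric per row
(MU, SW, SA, LSV, AAV, MCS), pairing by plan identity. Zero differences are
dropped before ranking and tied absolute differences get midranks. The
p-value is exact — the full null distribution of the positive rank sum via a
generating-function recursion over doubled midranks — for up to 25 non-zero
differences, and a normal approximation with continuity and tie corrections
beyond. All-zero-difference cohorts return p = 1 with a degenerate flag. No
multiple-testing correction is applied by default, matching per-metric
reporting practice. Per-plan comparison is the default unit; per-segment
pairing is available when the two cohorts share CP layouts.

## Synthetic generator

The generator emulates the two clinical arc geometries: `full_dual` — two
358° arcs (181°→179° CW, then CCW) at 2° CP spacing, as in head-and-neck
treatments, default 800 MU per plan — and `partial_dual` — two 40° arcs
(296°→336°, 104°→144°, CW), as in tangential breast treatments. Apertures
conform each CP to a projected ellipse: per pair, the gap is the full chord
at the pair's y-midpoint; pairs whose midpoint misses the ellipse stay
closed. The y-midpoint chord is the simplest geometry that exposes
leaf-width discretization differences between the two MLCs. Modulation is a
single dial: independent zero-mean Gaussian perturbations (SD =
`modulation_amplitude`, cm) on every open leaf, clipped to overtravel and
travel limits, with crossed pairs collapsed to a closed midpoint. MU
profiles are uniform or symmetric-Dirichlet over spans. One seeded
`numpy.random.Generator` is threaded through all draws — no global state —
so identical configurations produce byte-identical plans.

What the generator does **not** emulate: optimizer-correlated leaf
sequences (real VMAT apertures evolve smoothly with gantry angle and track
anatomy), inter-leaf collision and interdigitation constraints, jaw
tracking, couch/collimator geometry effects, or realistic dose
distributions. Passing tests therefore establish the correctness and the
analytic contracts of the scores (ranges, limits, invariances, orderings),
not clinical score distributions: cohort means from this generator are not
comparable to clinical cohort tables.

## Problem sizes and numerics

Property and ordering checks run on partial arcs (21 CPs per arc) in the
hundreds of arcs, and range scans use 200 randomized arcs per machine model;
these sizes give stable means while keeping the full suite fast. Round-trip
tolerances are 1e-4 cm on positions (mm values serialized at 6 decimals) and
1e-6 on cumulative weights; cumulative weights within 1e-6 outside [0, 1]
are clamped, larger excursions are errors. The equivalence check against a
naive per-leaf double-loop reference is at 1e-12 relative.

## Known limitations

- Complexity indices beyond SW/SA/LSV/AAV/MCS (leaf travel, small-aperture
  score, edge metrics) are not implemented.
- The kinematic model ignores acceleration and treats the dose-rate servo as
  ideal; binned-machine beam-gating is modeled only through the commanded
  bin.
- RT Dose / RT Struct objects, DVH-based plan quality, and measurement-based
  QA (gamma analysis) are out of scope.
- Beam MU is read from the fraction-group meterset; files lacking it need a
  per-beam MU sidecar mapping.
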