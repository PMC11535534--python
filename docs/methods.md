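# Methods

## The estimand and the sampling design

The quantity of interest is N, the number of follicles of a given stage in
one ovary.  The simulated workflow mirrors the standard fractionator
design for ovarian material:

1. **Slabs.** The ovary is cut into slabs of thickness 1000 µm
   perpendicular to its long axis.  Slabs tile the long-axis extent with
   half-open intervals; a terminal partial slab is kept.
2. **Slab selection (f2).** Systematic uniform random sampling: interval 3,
   start drawn uniformly from {1, 2, 3}.  The *realized* fraction
   selected/total — not the nominal 1/3 — enters the estimator (with 10
   slabs at start 1 the realized f2 is 0.4).
3. **Sections and serial runs (f3).** Each selected slab is cut into
   5-µm sections (floor(width/5) sections; a sliver thinner than one
   section is not cut, as on a real microtome).  Within every group of 50
   consecutive sections, a run of 5 consecutive sections is sampled; one
   uniformly random run offset is drawn per ovary and reused across groups
   and slabs (a per-slab re-randomized variant is available behind a
   flag).  A run overhanging a partial terminal group is truncated, and
   realized f3 = sampled/total sections over the selected slabs.
4. **Tissue availability (f1).** Partial tissue removal is modeled as
   independent Bernoulli deletion of each follicle with probability
   1 − f1 before sectioning.  The estimator divides by the *realized*
   kept/total fraction, the simulation analog of determining f1 by
   weighing the removed wedge (nominal f1 is the fallback for an empty
   ovary).
5. **Counting.** A follicle is counted when its oocyte nucleolus is seen
   (below), once per serial run; profile diameters of oocyte and nucleus
   are recorded in the counting section.
6. **Scale-up.** N̂ = ΣQ / (f1·f2·f3), exact arithmetic, no rounding in
   internal tables.

Under this design each counting unit is examined with probability
f1·f2·f3, so N̂ is design-unbiased whenever the counting gate fires in
exactly one section per follicle.

## The nucleolus gate and the visibility parameter

Real sections have thickness, and a ~3-µm nucleolus crosses a 5-µm
section boundary with probability 3/5; a rule that counts a follicle in
*any* section its nucleolus touches therefore sees 1.6 sections per
nucleolus on average.  With 5-of-50 serial runs the chance that a k-section
nucleolus footprint intersects a sampled run is (5 + k − 1)/50, giving an
expected +12% overcount relative to f3 = 5/50 — the classical
particle-height bias, which the printed estimator equation does not
correct.

`nucleolus_visibility ∈ [0, 1]` makes the observer model explicit: the
nucleolus is "clearly defined" in a section iff its in-section chord
reaches that fraction of its true diameter.

* **Default 1.0 (in-focus rule).** The chord equals the full diameter only
  in the section containing the nucleolus center, so the gate fires in
  exactly one section and the fractionator is unbiased.  This is the
  conventional reading of "clearly defined" and the package default.
* **0.0 (any intersection).** The literal permissive reading; biased by
  the mechanism above.  `mc_study.run_replicates(...,
  nucleolus_visibility=0.0)` reproduces the +12% figure, and intermediate
  thresholds trace the sensitivity curve between the two readings.

The adjacent-section exclusion is implemented as: once counted, a follicle
is suppressed in all later sections of the same serial run (runs are
maximal sets of z-contiguous sampled sections, which under exhaustive
sampling extends across abutting slab faces).  For 5-µm sections and
~3-µm nucleoli this coincides with excluding only the immediately
adjacent section, and it is the safe interpretation for structures
spanning more than two sections.

## Why large follicles get a separate scheme

A spherical object of diameter d intersects on average (d + t)/t sections
of thickness t under uniform random phase.  Naive profile-presence
counting therefore inflates linearly with object size: 7 section hits per
30-µm oocyte but 31 per 150-µm secondary-follicle oocyte at t = 5 µm.
`mc_study.overcount_experiment` demonstrates both the analytic rate and
the contrast with the nucleolus gate, which stays exact across the size
sweep.  Secondary follicles are accordingly offered only as a *relative*
count (nucleolus-gated, 1-of-50 single sections, no scale-up, for
between-ovary comparison), and growing-follicle raw counts per section
(primary + secondary + antral, any oocyte profile, no gate — the
whole-section raw scheme) are provided without a fractionator total.
Antral totals are not offered via the fractionator at all: whether a human
analyst would re-identify the same large follicle across the 225-µm gap
between serial runs is an observer property the geometry alone cannot
settle.

## The synthetic ovary

* **Geometry.** Prolate ellipsoid, default semi-axes (7.5, 10, 15) mm with
  the z (sectioning) axis longest.  The default 30-mm long axis cuts into
  exactly 30 slabs of 200 sections each — no partial slabs or groups, so
  the realized fractions equal the nominal ones and the unbiasedness
  argument is clean.  Geometries that do produce partial slabs/groups are
  fully supported and their realized fractions bookkeept.
* **Follicles.** Nested concentric spheres; the nucleolus center is offset
  uniformly within the ball that keeps it strictly inside the nucleus
  (this randomizes the nucleolus phase relative to the section grid, which
  the unbiasedness of the gate relies on).  Stage-specific diameters are
  truncated normals (bounds mean ± 3 sd, floored above zero, resampled
  until nesting holds).  Defaults — primordial follicle 35 µm / oocyte 30
  / nucleus 18 / nucleolus 3; primary 60; secondary 150; antral 1000 µm —
  are literature-informed simulator parameters, not study measurements,
  and every one is overridable.
* **Placement.** Uniform rejection sampling in the cortical shell, defined
  between the ovary ellipsoid and a concentric ellipsoid with semi-axes
  reduced by `cortex_thickness` (default 1.5 mm) — an approximation to
  true distance-from-surface that is exact on the axes and slightly
  conservative elsewhere.  Whole-ovary placement is a flag.  Sphere-inside-
  ovary containment is checked *exactly* by maximizing the ellipsoid
  quadratic over the follicle sphere (a trust-region subproblem solved by
  vectorized bisection on the Lagrange multiplier, hard case included);
  the simple "shrink the semi-axes by r" test is provably insufficient
  for elongated ellipsoids and is used only as a fast sufficient
  certificate via the Lipschitz bound on the ellipsoid norm.
* **Overlap.** Allowed by default (packing density is irrelevant to
  estimator correctness); a non-overlap mode does greedy sequential
  rejection with a budget of 1000 attempts per follicle.
* **Determinism.** One seeded `numpy.random.Generator` per ovary; draws in
  a fixed order (per stage: sizes, nucleolus offsets, centers).  Identical
  seeds give bitwise-identical serialized tables.

## What the simulator does and does not emulate

It emulates the geometry and sampling probabilities that determine the
estimator's statistical properties: stage-specific object sizes, cortical
localization, section thickness, systematic sampling, partial tissue
availability.  It does not render granulosa layers, theca, stroma,
fibrosis or staining; there is no tissue shrinkage, lost-cap or
misclassification model, and stage labels are carried as ground truth
rather than inferred from morphology.  Passing tests therefore validate
the *sampling and estimation* machinery, not histological recognition:
with real material, classification error and processing artifacts add
error components the simulator deliberately excludes.

## Monte-Carlo harness and numerical choices

* Replicate seeds derive from `SeedSequence(master_seed).spawn(reps)`, one
  sub-seed each for generation and sampling; summaries record the master
  seed and a SHA-256 fingerprint of the generating configuration.
* Relative bias is E[N̂]/N_true − 1 with its standard error from the
  replicate SD; 3-SE acceptance bands keep the false-failure rate below
  1% at the replicate counts used.
* Default study scale: 500 replicates of a 1000-primordial-follicle ovary
  at the default design run in well under a minute on one CPU; the test
  suite uses a 10-mm ovary (10 slabs × 200 sections) and populations of
  10²–10⁴ follicles, sizes chosen so the full suite completes in about
  half a minute.  All grids and replicate counts are arguments.
* All z intervals are half-open [lo, hi): a point exactly on a boundary
  belongs to the interval that starts there, so frames tile slabs and a
  nucleolus center is attributed to exactly one section, never two.
  Oocyte/nucleus profiles are mid-plane chords; degenerate
  zero-chord profiles are emitted as 0 (the follicle is present but its
  mid-plane is outside the sphere).
* The frames × follicles observation broadcast is chunked to at most
  5 × 10⁶ pairs to bound memory.

## Known limitations

* The nucleolus-height bias under permissive visibility is reported, not
  corrected; no correction factor (e.g. a height-adjusted f3) is applied
  in the estimator, matching the printed equation.
* The cortical shell is an ellipsoid-difference approximation to a
  constant-depth shell; for strongly flattened ovaries the shell thickness
  varies slightly with position.
* Bernoulli thinning models tissue removal as spatially unstructured; a
  planar wedge-cut mode (spatially correlated removal) is not implemented.
* Group summaries assume each subject contributes at most two ovaries and
  ages fall inside the configured bins; statistical tests between age
  groups are out of scope.
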