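# Methods

`mandiblemetrics` quantifies how accurately a mandibular resection and
reconstruction follows its three-dimensional virtual surgical plan. The
inputs are triangulated surface meshes segmented from planning and
postoperative CT/CBCT (the planned mandible, the planned resection-plane
patches, the postoperative mandible, and the achieved resection-plane
patches), together with a small set of manually supplied anatomical
inputs: five skull landmarks, region-of-interest (ROI) vertex sets for
the condylar heads and the posterior/inferior border bands, the tumor
centroid, and plate metadata. This note documents the procedure, its
assumptions, the tunable parameters, and the synthetic phantom used to
validate the whole chain.

## Anatomical reference frame

All measurements are expressed in a patient frame built from the skull
landmarks (`reference_frame`):

* **Frankfort horizontal plane** through left/right porion and the right
  orbitale, normal oriented superiorly (positive signed distance to the
  nasion).
* **Midsagittal plane**: the unique plane containing nasion and basion
  that is perpendicular to the Frankfort plane, normal oriented towards
  the right porion. ("Rotating the Frankfort plane by 90°" leaves the
  rotation axis free; perpendicularity plus the two contained landmarks
  pins the plane down uniquely and testably.)
* **Coronal plane**: mutually perpendicular to both, normal oriented
  anteriorly. Its through-point is irrelevant — every downstream
  quantity uses plane *orientations* and tangent directions only — so it
  defaults to the basion; the irrelevance is asserted by test.

The axis triad is `right = midsagittal normal`, `superior = Frankfort
normal`, `anterior = coronal normal`; for anatomically sensible
landmarks it is right-handed and orthonormal, and the construction is
rigid-equivariant (property-tested).

## Registration

The postoperative scene is mapped into planned coordinates with trimmed
point-to-point ICP (`registration`): nearest-target-vertex
correspondences for the source vertices, optional discarding of the
worst `trim_fraction` by distance, a Kabsch least-squares rigid fit
(reflections excluded by construction), iterated until the
correspondence RMS changes by less than `rms_change_tol`.

Parameters (defaults): `max_iterations` 100, `rms_change_tol` 1e-4 mm,
`trim_fraction` 0.10, `sample_size` 5000 source vertices
(`None` = all), deterministic farthest-point subsampling with a fixed
seed, identity initialization (same-patient scans are near-aligned after
export). Trimming is what makes whole-mesh registration usable when part
of the anatomy was resected; on clean, fully corresponding surfaces it
is unnecessary and the exact-recovery validations therefore run with
`trim_fraction=0` and all vertices, where ICP recovers synthetic rigid
transforms up to 25° / 20 mm to ~1e-6° / 1e-13 mm on the phantom.

When a **registration mask** is supplied (a vertex ROI marking anatomy
expected to be unaffected by surgery), `run_case` registers in two
passes: a coarse whole-mesh pass for initialization, then an untrimmed
refinement driven by the masked vertices on both sides of the
correspondence. The mask already excludes non-corresponding structures,
so trimming (which can let a smooth surface slide tangentially) is
disabled in the refinement.

## Resection-plane deviations

Each resection plane is a bounded, approximately planar patch; its
infinite plane is the least-squares fit, and every patch vertex must lie
within `planarity_tol` (default 1.0 mm — postoperative patches come from
voxel data at 0.2–2 mm slice spacing) of it. Five key points are
extracted per patch in the shared frame: the area-weighted centroid and
four outline points — superior/inferior extremes along the projection of
the superior axis onto the patch plane, and the two transverse extremes,
of which the **buccal** point is the one with the larger absolute
distance to the midsagittal plane (the rule degrades only for cuts near
the midline where "buccal/lingual" genuinely loses meaning; a cut plane
nearly perpendicular to the superior axis — in-plane projection norm
below 0.1 — is rejected with instructions to supply manual key points).
Outline extremal ties break to the lowest vertex index.

Deviations for a planned/achieved pair: role-wise Euclidean distances
between corresponding key points, the folded angle between fitted planes
(degrees, [0, 90], flip-invariant), and signed offsets of the achieved
points along the planned plane's normal oriented towards the tumor
centroid; the centroid offset's sign classifies the plane shift as
toward / away from the tumor (|offset| < 1e-9 → on-plane). Cohort
aggregation reports mean, sample SD (n−1) and range per key point,
anterior/posterior splits with a paired Wilcoxon p-value, and
toward-tumor counts per measurement. Planes are only ever excluded via
an explicit caller-supplied exclusion list, which the output echoes.

## Cephalometric reconstruction measures

Landmarks are defined by tangent-plane and bisecting-plane
constructions so they are reproducible on any surface:

* **lateral condyle point** — ROI vertex extremal along ±(midsagittal
  normal); the condylar ROI is required because the lateral-most point
  of a whole postoperative mandible can lie on a flared graft;
* **pogonion** — vertex extremal along the anterior axis;
* **gonion** — least-squares planes through the posterior and inferior
  border bands (outward-oriented away from the mesh centroid; band RMS
  must stay below `border_fit_tol`, default 2.0 mm), then the plane
  through their intersection line spanning the outward bisector
  direction `d ∝ n_post + n_inf` is intersected with the mesh, and the
  gonion is the intersection point extremal along `d` (the most
  postero-inferior point of the cut curve). Note that a plane through
  the intersection line with *normal* along `d` would be degenerate —
  `d·x` is constant on it — so the bisecting plane is the one containing
  `d`, with normal ∝ `n_post − n_inf`. Candidates are restricted to the
  landmark's side of the midsagittal plane (the bisecting plane also
  slices the contralateral ramus), and near-ties along `d` (a perfectly
  sharp prismatic corner yields a whole tied edge) break to the
  lexicographically smallest point within a 1e-9 relative band, which is
  deterministic and stable against registration round-off.

Measures: ICD = |condyle_L − condyle_R|; IGD = |gonion_L − gonion_R|;
APD = distance from the pogonion to the intercondylar line; per side the
**gonial angle** (interior dihedral between the outward border-plane
normals, 180° − arccos(n_post·n_inf), the anatomical ~120° convention),
the **coronal angle** (condyle–gonion line vs midsagittal plane) and the
**axial angle** (gonion–pogonion line vs midsagittal). Line–plane angles
are folded into [0, 90]°, matching the small positive magnitudes such
tables report. An optional switch projects the axial lines into the
Frankfort plane first (the strict "axial view" reading); the default is
the unprojected 3D line–plane angle, and the switch is covered by test.
Differences are reported as per-measure absolute planned-vs-postop
values, aggregated as mean absolute difference (MAD) with sample SD,
overall and within conventional/PSI plate groups, with a Mann–Whitney
group p-value.

## Agreement statistics

* **Wilcoxon signed-rank** — zero differences dropped, average ranks for
  ties, statistic `W = min(W⁺, W⁻)`. Exact two-sided p for n ≤ 25 via
  the generating function of the positive-rank sum over doubled ranks —
  identical to enumerating all 2ⁿ sign patterns, verified against
  literal enumeration for n ≤ 10; beyond that, normal approximation with
  continuity and tie corrections.
* **Mann–Whitney U** — exact for n+m ≤ 16 by enumerating all C(n+m, n)
  labelings of the (tied-average) pooled ranks, with the distribution
  cached per rank multiset; normal approximation with tie correction
  otherwise. The thresholds cover the plate-subgroup sizes such cohorts
  produce while bounding enumeration cost.
* Two-sided p-values double the smaller tail, capped at 1.
* **Cohen's kappa** with none/linear/quadratic weights; quadratic is the
  suggested default for ordinal staging tables.
* **ICC** from two-way ANOVA mean squares; default form is two-way,
  absolute agreement, single measures (repeatability of single
  measurements), with the consistency form available. Values ≥ 0.75
  carry the conventional "excellent" label.
* Correlation/regression (Pearson, Spearman on average ranks, OLS with
  slope t-test) and the 2×2 chi-square/Fisher decision (chi-square
  without continuity correction when all expected counts ≥ 5, Fisher's
  exact otherwise) delegate to scipy.

## The synthetic phantom

No patient imaging ships with the package; the study conditions are
emulated by a parametric mandible phantom (`phantom`) whose every
measured feature is known by construction:

* a horseshoe **body**: a prismatic tube swept along a half-elliptic
  arch (half-width 45 mm, chin at y = 50 mm, constant z), cross-section
  a nine-sided profile 12 mm wide × 30 mm tall with exactly flat top,
  bottom and side bands and a slightly protruding outward apex (so the
  most-anterior chin vertex — the pogonion — is unique rather than tied
  across a flat face);
* two straight **rami** (length 55 mm) tilted backwards by
  (gonial angle − 90°), so the exactly planar posterior band of each
  ramus meets the exactly planar inferior band of the body at precisely
  the target gonial angle (default 120°). The body-to-ramus junction is
  a miter joint: both prisms are cut by the bend's bisecting plane, so
  the faces stay exactly planar up to a sharp corner edge — the gonial
  corner the bisecting-plane construction must find;
* spherical **condylar heads** (radius 8 mm) centred at
  x = ±50 mm with a vertex exactly at each lateral pole;
* two **resection patches** cut as exact elliptical tube cross-sections
  at configurable arc positions on the operated side, with vertices at
  the four pole positions (unique key-point answers) and the tumor
  centroid placed between them;
* canonical skull landmarks, so the phantom's anatomical frame is the
  coordinate frame.

Two deliberate irregularities exist purely for numerical
well-posedness: the tube's lateral half-width is smoothly modulated
along the sweep, and both the sweep stations and the profile
subdivision are deterministically non-uniform. A perfectly regular
prism grid is self-similar under one-step shifts along its flat faces,
which hands nearest-vertex ICP spurious fixed points ~1 mm from the
true optimum; the irregular sampling removes them (and is closer to
real segmented surfaces, which are never regular grids).

### Error model and ground truth

`apply_error` derives a postoperative copy by sampling, in fixed order:
per-patch rigid errors (translation per axis ~ N(0, `plane_translation_sd`²),
rotation ~ N(0, `plane_rotation_sd`²) about a uniformly random in-plane
axis through the centroid); per-ramus errors (lateral translation
~ N(0, `segment_shift_sd`²) and rotation ~ N(0, `segment_rotation_sd`²)
about the lateral axis through the gonial corner); an independent
condylar-head displacement ~ N(0, `condyle_shift_sd`² I₃) per side
(condylar settling); a horizontal body translation
~ N(0, `body_shift_sd`² I₂); optional i.i.d. vertex noise; and one
global rigid misalignment of the whole scene (rotation angle
~ U(0, `global_rotation_max`), translation magnitude
~ U(0, `global_translation_max`)). An `operated_factor` can scale the
operated side's segment errors.

The restricted perturbation *directions* are what keep the ground truth
closed-form: a ramus rotation about the corner's own axis maps the
corner edge onto itself, so the fitted border planes, the bisecting
construction and the gonion transform exactly; a horizontal body shift
leaves the inferior border plane invariant. Ground-truth metrics are
derived in `phantom_truth` from the sampled parameters and the phantom's
analytic anchors (patch rings, sphere vertex sets, corner-edge
candidates, exact border-plane normals) using small self-contained
replicas of the measurement formulas — never by running the measurement
pipeline on the meshes. Because segment and body errors destroy
whole-mesh rigidity, metrics are defined in *body-anchored* planned
coordinates (the body registers exactly; everything else carries an
extra −body-shift), which is also what the pipeline's masked
registration produces; with zero segment/body errors this coincides
with plain planned coordinates. On noise-free meshes the pipeline
reproduces every stored ground-truth value to ~1e-12 (mm / degrees);
with vertex noise σ > 0 agreement degrades gracefully and tolerance
must be scaled with σ (near-tied extremal vertices can swap).

Cohort simulation draws independent cases from one phantom with
per-case seeds spawned from a master seed (fully deterministic), assigns
plate labels by a PSI fraction, and optionally gives the PSI group its
own error model so the group-comparison machinery can be exercised at a
known effect size. "Analytic generating means" for cohort-recovery
checks are computed by evaluating the same closed-form ground-truth
formulas on a large fresh sample of parameter draws (mesh-free,
separate RNG) — joint landmark perturbations do not admit textbook
closed-form means for every cephalometric measure; the centroid
deviation, whose Maxwell mean σ√(8/π) is closed-form, is additionally
checked against it exactly. Under the default directions the coronal
angle is invariant to ramus rotation/lateral shift, so
`condyle_shift_sd` is the component that exercises it.

What the phantom does **not** emulate: CT noise, partial-volume and
segmentation artifacts, dental structures, fibula-graft geometry,
osteotomy kerf, or deformable anatomy. Passing the phantom suite
demonstrates the correctness of the geometry and statistics chain under
known rigid perturbations, not robustness to real segmentation quality.

## Problem sizes and tolerances used in validation

The shipped validation uses a 2.0 mm phantom (≈7 400 vertices; the
default spec is 1.0 mm, ≈28 000), 20 random transforms for registration
recovery, 50 randomized phantoms for landmark oracles, a 200-case
cohort against 20 000 analytic draws (3-standard-error criterion), and
2 000 null simulations for the exact Mann–Whitney test size (attained
size must lie in [0.03, 0.07] at nominal 0.05). Identity and
closed-form checks assert at 1e-9 mm / 1e-6–1e-5 degrees (the folded
plane angle has an arccos precision floor of ≈1e-6 degrees);
registration recovery at 0.05 mm / 0.05°; the gonial-angle recovery at
0.01°. Vertex merge tolerance is 1e-6 mm, far below imaging resolution.

## Known limitations

* Point-to-point, nearest-vertex ICP converges locally; from large
  misalignments on smooth, feature-poor surfaces it can stall. The
  two-pass masked scheme and full-vertex untrimmed refinement handle the
  intended near-aligned clinical setting; arbitrary global registration
  is out of scope (a principal-axes initializer is available behind a
  flag for stress tests).
* The gonion tie-break is a convention; on a real (rounded) gonial
  corner the extremal point is unique and the convention is inert, but
  on perfectly prismatic geometry the choice of corner-edge endpoint is
  arbitrary (and consistently mirrored left/right, which slightly
  asymmetrizes the phantom's axial/coronal angles).
* Exact ground-truth equality holds for the restricted perturbation
  directions; fully general segment rotations would move the corner off
  the inferior border plane and make the gonion's ground truth only
  approximately analytic.
* Manifest ROIs are author-supplied, matching interactive clinical
  practice; no automatic band/condyle detection is attempted.
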