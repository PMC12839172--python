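# mandiblemetrics

Geometric accuracy analysis for 3D-planned mandibular resection and
reconstruction.

When a segmental mandibulectomy is planned virtually — resection planes
placed on the segmented mandible, cutting guides and plates designed to
match — the postoperative scan can be compared against that plan to ask
*how closely the surgery followed it*. This package implements that
comparison as a tested, reusable pipeline for surgeons, clinical
physicists and 3D-lab engineers working with segmented surface meshes
(STL/PLY):

* an anatomical reference frame from skull landmarks (Frankfort
  horizontal, midsagittal and coronal planes, with a right/anterior/
  superior axis triad);
* rigid registration of the postoperative scene onto the plan by
  trimmed iterative-closest-point (ICP), optionally driven by a mask of
  surgically unaffected anatomy;
* **resection-plane accuracy**: for each osteotomy plane, Euclidean
  deviations of five key points (superior, inferior, buccal, lingual,
  centre of gravity), the angle between planned and achieved planes

  d_k = ‖p_k^achieved − p_k^planned‖,  θ = arccos |n_planned · n_achieved|,

  and the shift direction relative to the tumor centroid;
* **reconstruction accuracy**: plane-contact landmarks (lateral condyle
  points, gonia via the border-plane bisecting construction, pogonion)
  and the cephalometric measures ICD, IGD, APD and the side-specific
  gonial, axial and coronal angles, compared plan-vs-result as mean
  absolute differences (MAD);
* **agreement statistics**: exact Wilcoxon signed-rank and
  Mann–Whitney U tests (enumeration for small samples), weighted
  Cohen's kappa, two-way ICC, correlation/regression and the 2×2
  chi-square/Fisher decision;
* a **synthetic mandible phantom** with fully analytic ground truth
  (exactly planar border bands meeting at a prescribed gonial angle,
  spherical condylar heads, elliptical resection patches) and an error
  model that simulates per-plane, per-segment and global errors — the
  validation bed for the entire chain.

## Worked example

`examples/02_resection_deviation.py` measures an achieved resection
patch that is the planned patch moved by a known rigid error:

```
pure translation by (1, 2, 2) mm  [expect 3.00 mm everywhere, 0 deg]:
  d_centroid    3.00 mm
  d_superior    3.00 mm
  d_inferior    3.00 mm
  d_buccal      3.00 mm
  d_lingual     3.00 mm
  angle        0.00 deg   shift: away_from_tumor

10 deg rotation about in-plane centroid axis  [expect centroid 0, angle 10]:
  d_centroid    0.00 mm
  ...
  angle       10.00 deg   shift: on_plane
```

A translation by (1, 2, 2) mm moves every key point by |(1,2,2)| = 3 mm
and leaves the plane angle at zero; a rotation about an in-plane axis
through the centroid leaves the centroid in place and tilts the plane by
exactly the rotation angle. `examples/03_full_case_analysis.py` runs the
complete pipeline (frame → registration → deviations → cephalometrics)
on a simulated case and prints every metric next to the generator's
analytic ground truth — on noise-free meshes they agree to ~1e-12.

The other examples cover phantom generation (`01`), cohort simulation
with group statistics (`04`) and the statistical toolbox (`05`). A thin
CLI wraps the same functions:

```bash
mandiblemetrics simulate --n 10 --seed 1 --out cohort/
mandiblemetrics aggregate cohort/ --exact --seed 1 --out tables/
mandiblemetrics analyze-case cohort/case_0000.yaml --exact
mandiblemetrics validate
```

Real cases enter through the same YAML manifest the simulator writes
(mesh paths, skull landmarks, ROIs, tumor centroid, plate metadata); the
schema is documented in `docs/manifest_schema.md`, and the science and
all numerical conventions in `docs/methods.md`.

## Layout

```
src/mandiblemetrics/
  geometry.py         planes, rigid transforms, fits, extremal points
  mesh_io.py          STL/PLY + manifest I/O, cleaning, result tables
  reference_frame.py  Frankfort / midsagittal / coronal construction
  registration.py     trimmed point-to-point ICP
  resection.py        key points and plane-deviation metrics
  reconstruction.py   landmarks, ICD/IGD/APD, gonial/axial/coronal angles
  stats.py            exact rank tests, kappa, ICC, correlation
  phantom.py          synthetic mandible generator
  phantom_truth.py    error model, analytic ground truth, cohorts
  pipeline.py         per-case and cohort orchestration
  cli.py              command-line interface
```
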