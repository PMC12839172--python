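# Case manifest schema (version 1)

A case manifest is a YAML file collecting everything one case needs
besides the meshes themselves. Relative mesh paths resolve against the
manifest's own directory. All coordinates are millimetres in the
planned-scan coordinate system.

```yaml
schema_version: 1
case_id: case_0001
operated_side: right          # left | right | front
plate_type: PSI               # conventional | miniplate | PSI | bookshelf-PSI
n_segments: 1
scale: 1.0                    # optional; STL is unitless, applied on load

tumor_centroid: [38.4, 4.6, -20.0]

landmarks:                    # manually placed on the planning scan
  porion_L:   [-60.0, -60.0, 40.0]
  porion_R:   [ 60.0, -60.0, 40.0]
  orbitale_R: [ 45.0,  30.0, 40.0]
  nasion:     [  0.0,  60.0, 45.0]
  basion:     [  0.0, -60.0, -10.0]

meshes:                       # STL (binary/ascii) or PLY
  planned_mandible:        case_0001_planned_mandible.ply
  planned_patch_anterior:  case_0001_planned_patch_anterior.ply
  planned_patch_posterior: case_0001_planned_patch_posterior.ply
  postop_mandible:         case_0001_postop_mandible.ply
  achieved_patch_anterior: case_0001_achieved_patch_anterior.ply
  achieved_patch_posterior: case_0001_achieved_patch_posterior.ply

rois:                         # vertex sets on the planned mandible; either
  condyle_L: {indices: [101, 102, 103]}          # explicit index lists
  condyle_R: {seed: [50.0, -72.5, 27.6], radius: 9.0}   # or seed/radius balls
  posterior_border_L: {indices: [...]}
  posterior_border_R: {indices: [...]}
  inferior_border_L:  {indices: [...]}
  inferior_border_R:  {indices: [...]}

# optional: vertices of the postoperative mandible expected to be
# unaffected by surgery; drives the two-pass masked registration
registration_roi: {indices: [...]}
```

Notes

* Index-list ROIs refer to the mesh **after** loading (duplicate
  vertices merged within 1e-6 mm, degenerate faces dropped). PLY
  preserves vertex order through this cleaning, STL does not — use PLY
  for index-based ROIs, or seed/radius balls with STL.
* A ball ROI resolves to every vertex within `radius` of `seed`; each
  ROI must resolve to at least 3 vertices.
* ROIs are resolved on the planned mandible and reused by index on the
  postoperative mandible, so the two meshes must share vertex indexing
  (as the simulator guarantees). For independently segmented
  postoperative meshes, re-export them with matching indexing or adapt
  the ROIs before analysis.
* `simulate`d synthetic cases write exactly this layout, so a generated
  cohort doubles as a worked example of the format.
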