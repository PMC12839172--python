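"""Generate a synthetic mandible phantom and build its anatomical frame.

The phantom is a labeled, watertight-per-component surface model with
exactly planar border bands, spherical condylar heads and two planar
resection patches; the skull landmarks it carries define the Frankfort,
midsagittal and coronal reference planes.
"""

import numpy as np

from mandiblemetrics import PhantomSpec, SkullLandmarks, build_frame, generate_phantom

planned = generate_phantom(PhantomSpec(mesh_edge_length=2.0))
frame = build_frame(SkullLandmarks.from_dict(planned.landmarks))

print(f"mandible: {planned.mandible.n_vertices} vertices, "
      f"{len(planned.mandible.faces)} faces")
print(f"condyle centres: L {planned.condyle_centers['L'].round(2)}, "
      f"R {planned.condyle_centers['R'].round(2)}")
print(f"tumor centroid: {planned.tumor_centroid.round(2)}")
print("axes (right / anterior / superior):")
for name in ("axis_right", "axis_anterior", "axis_superior"):
    print(f"  {name}: {getattr(frame, name).round(6)}")

# the phantom's skull landmarks are canonical, so the axes are the
# coordinate axes; with landmarks from a real scan the frame follows the
# patient's head orientation instead
pole = planned.mandible.vertices[planned.sphere_indices["R"][0]]
print(f"right condylar lateral pole (ground truth): {pole.round(2)}")
print("expected x = arch_half_width + condyle_radius =",
      planned.spec.arch_half_width + planned.spec.condyle_radius)
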