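"""Measure resection-plane deviations for a known perturbation.

The achieved (postoperative) resection patch is the planned patch moved
by a known rigid error, so the printed metrics have exact expected
values: a (1, 2, 2) mm translation moves all five key points by
|(1,2,2)| = 3 mm and leaves the plane angle at 0; a 10-degree rotation
about an in-plane axis through the centroid leaves the centroid in place
and tilts the plane by exactly 10 degrees.
"""

import numpy as np

from mandiblemetrics import PhantomSpec, PlanarPatch, SkullLandmarks, build_frame, generate_phantom
from mandiblemetrics.resection import KEY_POINT_ROLES, ResectionPatchPair, plane_deviation
from scipy.spatial.transform import Rotation

planned = generate_phantom(PhantomSpec(mesh_edge_length=2.0))
frame = build_frame(SkullLandmarks.from_dict(planned.landmarks))
info = planned.patches["anterior"]


def measure(achieved_mesh, title):
    pair = ResectionPatchPair(
        planned=PlanarPatch.from_mesh(info.mesh),
        achieved=PlanarPatch.from_mesh(achieved_mesh),
        label="anterior", case_id="example")
    dev = plane_deviation(pair, frame, planned.tumor_centroid)
    print(title)
    for role in KEY_POINT_ROLES:
        print(f"  d_{role:<9} {dev.distance(role):6.2f} mm")
    print(f"  angle      {dev.angle:6.2f} deg   shift: {dev.shift_direction}")


moved = info.mesh.copy()
moved.vertices = moved.vertices + np.array([1.0, 2.0, 2.0])
measure(moved, "pure translation by (1, 2, 2) mm  [expect 3.00 mm everywhere, 0 deg]:")

R = Rotation.from_rotvec(np.radians(10.0) * np.array([0, 0, 1.0])).as_matrix()
rotated = info.mesh.copy()
rotated.vertices = (rotated.vertices - info.center) @ R.T + info.center
measure(rotated, "10 deg rotation about in-plane centroid axis  [expect centroid 0, angle 10]:")
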