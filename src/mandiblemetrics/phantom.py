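"""Synthetic mandible phantom with exact, labeled ground truth.

The phantom stands in for patient imaging: a horseshoe-shaped mandible
built as a swept prismatic tube (elliptical-arch body rising into two
straight rami), capped by spherical condylar heads, with two planar
resection patches cut as tube cross-sections. Its construction
guarantees the features every downstream stage measures:

* the posterior face of each ramus and the inferior face of the body are
  *exactly* planar bands (labeled ROIs), meeting at the target gonial
  angle along a sharp miter-joint corner edge — the gonial corner;
* each condylar head is a sphere with a vertex exactly at its lateral
  pole, so the lateral condyle landmark is known by construction;
* the chin apex is a single most-anterior vertex (the pogonion);
* resection patches are exact ellipses with vertices at the four pole
  positions, so key-point extraction has unambiguous answers.

A "postoperative" copy is derived by sampling per-plane rigid errors,
per-segment errors, vertex noise and a global scene misalignment
(:class:`ErrorModel`); every sampled parameter is stored and the implied
deviation metrics are derived analytically in
:mod:`mandiblemetrics.phantom_truth`, never re-measured from the meshes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh_io import TriangleMesh

__all__ = [
    "PhantomSpec",
    "ErrorModel",
    "PatchInfo",
    "PlannedBundle",
    "generate_phantom",
]

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric parameters of the synthetic mandible (mm / degrees)."""

    arch_half_width: float = 50.0    # |x| of each condyle centre
    body_height: float = 30.0        # full craniocaudal tube height
    ramus_height: float = 55.0       # ramus centreline length
    condyle_radius: float = 8.0
    target_gonial_angle: float = 120.0
    tube_radii: tuple = (6.0, None)  # (buccolingual, craniocaudal) half-widths
    mesh_edge_length: float = 1.0
    operated_side: str = "right"
    cut_fractions: tuple = (0.45, 0.85)  # (anterior, posterior) arc positions
    lateral_setback: float = 5.0     # condyle centre lateral offset from ramus plane
    chin_y: float = 50.0             # body centreline y at the chin
    back_y_factor: float = 0.9       # body centreline ends at y = -factor * arch_half_width
    centerline_z: float = -20.0
    seed: int = 0

    def __post_init__(self):
        for name in ("arch_half_width", "body_height", "ramus_height",
                     "condyle_radius", "mesh_edge_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (90.0 < self.target_gonial_angle < 170.0):
            raise ValueError("target_gonial_angle must lie in (90, 170) degrees")
        r_bl, r_cc = self.tube_radii
        if r_cc is None:
            r_cc = self.body_height / 2.0
        if r_bl <= 0 or r_cc <= 0:
            raise ValueError("tube radii must be positive")
        object.__setattr__(self, "tube_radii", (float(r_bl), float(r_cc)))

    # derived quantities -----------------------------------------------------
    @property
    def beta_rad(self) -> float:
        """Backward tilt of the ramus axis from vertical; sets the gonial angle."""
        return math.radians(self.target_gonial_angle - 90.0)

    @property
    def ramus_x(self) -> float:
        return self.arch_half_width - self.lateral_setback

    @property
    def back_y(self) -> float:
        return -self.back_y_factor * self.arch_half_width

    @property
    def ramus_dir(self) -> np.ndarray:
        b = self.beta_rad
        return np.array([0.0, -math.sin(b), math.cos(b)])

    def condyle_center(self, side: int) -> np.ndarray:
        base = np.array([side * self.ramus_x, self.back_y, self.centerline_z])
        return base + self.ramus_height * self.ramus_dir + np.array(
            [side * self.lateral_setback, 0.0, 0.0]
        )

    def body_centerline(self, s) -> np.ndarray:
        """Horseshoe centreline, s in [-1, 1] (left to right), z constant."""
        s = np.asarray(s, dtype=float)
        a = s * (math.pi / 2.0)
        x = self.ramus_x * np.sin(a)
        y = (self.chin_y - self.back_y) * np.cos(a) + self.back_y
        z = np.full_like(x, self.centerline_z)
        return np.stack([x, y, z], axis=-1)

    def body_tangent(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        a = s * (math.pi / 2.0)
        dx = self.ramus_x * np.cos(a)
        dy = -(self.chin_y - self.back_y) * np.sin(a)
        t = np.stack([dx, dy, np.zeros_like(dx)], axis=-1)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)


@dataclass(frozen=True)
class ErrorModel:
    """Error magnitudes for the simulated postoperative scene.

    Per-plane rigid errors act on the achieved resection patches
    (translation per axis, rotation about a random in-plane axis through
    the patch centroid). Per-segment errors displace each ramus (with
    condyle) laterally and rotate it about the lateral axis through its
    gonial corner, and shift the body horizontally — directions chosen so
    that every ground-truth landmark stays closed-form. A global rigid
    misalignment moves the whole postoperative scene, and optional
    Gaussian vertex noise emulates segmentation roughness.
    """

    plane_translation_sd: float = 1.0   # mm per axis
    plane_rotation_sd: float = 5.0      # degrees
    global_rotation_max: float = 5.0    # degrees
    global_translation_max: float = 5.0  # mm
    vertex_noise_sd: float = 0.0        # mm
    segment_shift_sd: float = 0.0       # mm, lateral per ramus
    segment_rotation_sd: float = 0.0    # degrees, per ramus about its corner axis
    condyle_shift_sd: float = 0.0       # mm per axis, condylar head displacement
    body_shift_sd: float = 0.0          # mm, horizontal body translation per axis
    operated_factor: float = 1.0        # scale on operated-side segment errors

    def __post_init__(self):
        for name in ("plane_translation_sd", "plane_rotation_sd", "global_rotation_max",
                     "global_translation_max", "vertex_noise_sd", "segment_shift_sd",
                     "segment_rotation_sd", "condyle_shift_sd", "body_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PatchInfo:
    """One planar resection patch plus its analytic description."""

    label: str                 # anterior | posterior
    mesh: TriangleMesh         # vertex 0 = centre, vertices 1..N = boundary ring
    center: np.ndarray
    normal: np.ndarray         # unit, horizontal
    ring: np.ndarray           # (N, 3) boundary ring coordinates (== mesh.vertices[1:])
    s_position: float


@dataclass
class PlannedBundle:
    """Planned-side synthetic case: meshes, landmarks, ROIs and the exact
    analytic quantities the error model's ground truth is derived from."""

    spec: PhantomSpec
    mandible: TriangleMesh
    patches: dict               # label -> PatchInfo
    landmarks: dict             # skull landmark name -> (3,)
    tumor_centroid: np.ndarray
    rois: dict                  # roi name -> vertex index array
    segments: dict              # 'body' | 'ramus_L' | 'ramus_R' -> vertex index array
    # analytic ground-truth anchors
    condyle_centers: dict       # 'L'/'R' -> (3,)
    sphere_indices: dict        # 'L'/'R' -> vertex index array (condyle sphere)
    corner_indices: dict        # 'L'/'R' -> index array of gonial corner-edge vertices
    border_planes: dict         # ('L'|'R', 'posterior'|'inferior') -> (point, outward normal)
    chin_apex_index: int

    @property
    def mesh_resolution(self) -> float:
        return self.spec.mesh_edge_length


# ---------------------------------------------------------------------------
# cross-section profile
# ---------------------------------------------------------------------------


def _subdivided_polygon(corners: np.ndarray, edge: float):
    """Closed polygon subdivided so no segment is much longer than
    ``edge``, with deterministically *non-uniform* interior spacing.

    A perfectly regular grid on the large flat faces is self-similar
    under a one-step in-plane shift, which gives nearest-vertex
    registration spurious fixed points; warping the subdivision breaks
    that symmetry. Corner vertices are kept exact."""
    pts = []
    n = len(corners)
    for i in range(n):
        a, b = corners[i], corners[(i + 1) % n]
        length = float(np.linalg.norm(b - a))
        k = max(1, int(math.ceil(length / edge)))
        for j in range(k):
            f = j / k
            f = f + 0.3 / k * math.sin(2.0 * math.pi * f + 1.7 * i) * (1 if 0 < j < k else 0)
            pts.append(a + (b - a) * f)
    return np.asarray(pts)


def _tube_profile(r_a: float, r_b: float, edge: float):
    """Octagon-like tube cross-section in local (a, b) coordinates.

    ``a`` is the outward/lateral axis (apex vertex at (+r_a, 0)), ``b``
    the section-up axis. Flat top and bottom bands at b = ±r_b and flat
    side bands at a = ±r_a give the exactly planar border bands.
    Returns (points (N,2), bottom_mask).
    """
    h1, w1 = 0.55 * r_b, 0.55 * r_a
    # the outward apex protrudes slightly so the most-anterior chin vertex
    # (and any outward extremal) is unique rather than tied across a flat face
    corners = np.array([
        (1.12 * r_a, 0.0), (r_a, h1), (w1, r_b), (-w1, r_b), (-r_a, h1),
        (-r_a, -h1), (-w1, -r_b), (w1, -r_b), (r_a, -h1),
    ])
    pts = _subdivided_polygon(corners, edge)
    bottom = np.abs(pts[:, 1] + r_b) < 1e-12
    return pts, bottom


def _ring_points(center, a_axis, b_axis, profile, a_scale: float = 1.0):
    return center + a_scale * profile[:, :1] * a_axis + profile[:, 1:2] * b_axis


def _uv_sphere(center, radius, axis_sign, edge):
    """UV sphere with poles on the ±x axis; vertex 0 is the *lateral* pole
    (center + axis_sign * radius * x)."""
    n_lat = max(6, int(math.ceil(math.pi * radius / edge)))
    n_lon = max(8, int(math.ceil(2 * math.pi * radius / edge)))
    verts = [center + axis_sign * radius * _X]
    for j in range(1, n_lat):
        phi = math.pi * j / n_lat
        x = axis_sign * radius * math.cos(phi)
        r = radius * math.sin(phi)
        for k in range(n_lon):
            th = 2 * math.pi * k / n_lon
            verts.append(center + np.array([x, r * math.cos(th), r * math.sin(th)]))
    verts.append(center - axis_sign * radius * _X)
    verts = np.asarray(verts)
    faces = []
    # top fan
    for k in range(n_lon):
        faces.append((0, 1 + k, 1 + (k + 1) % n_lon))
    # strips
    for j in range(n_lat - 2):
        a0 = 1 + j * n_lon
        b0 = 1 + (j + 1) * n_lon
        for k in range(n_lon):
            k1 = (k + 1) % n_lon
            faces.append((a0 + k, b0 + k, b0 + k1))
            faces.append((a0 + k, b0 + k1, a0 + k1))
    # bottom fan
    last = len(verts) - 1
    c0 = 1 + (n_lat - 2) * n_lon
    for k in range(n_lon):
        faces.append((last, c0 + (k + 1) % n_lon, c0 + k))
    return verts, np.asarray(faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def _miter_corner_ring(profile_pts_3d, travel_dir, miter_point, miter_normal):
    """Project a prism ring along its travel direction onto the miter plane."""
    denom = float(np.dot(miter_normal, travel_dir))
    t = (miter_point - profile_pts_3d) @ miter_normal / denom
    return profile_pts_3d + t[:, None] * travel_dir


def generate_phantom(spec: PhantomSpec | None = None) -> PlannedBundle:
    """Build the planned-side bundle. Deterministic for a fixed spec."""
    spec = spec or PhantomSpec()
    r_a, r_b = spec.tube_radii
    edge = spec.mesh_edge_length
    beta = spec.beta_rad
    sb, cb = math.sin(beta), math.cos(beta)
    r_hat = spec.ramus_dir                      # ramus axis, up and backward
    t_hat = np.array([0.0, cb, sb])             # ramus section-up axis (antero-superior)
    zb = spec.centerline_z

    profile, bottom_mask = _tube_profile(r_a, r_b, edge)
    n_prof = len(profile)

    g0 = {s: np.array([s * spec.ramus_x, spec.back_y, zb]) for s in (-1, 1)}
    # miter planes at the two gonial corners (normal along travel direction)
    m_hat = {}
    for s in (-1, 1):
        d_in = -r_hat if s == -1 else -_Y       # travel into the corner
        d_out = _Y if s == -1 else r_hat        # travel out of the corner
        m = d_in + d_out
        m_hat[s] = m / np.linalg.norm(m)

    rings = []       # list of (points (N,3), tag)
    clear = 0.25 * edge

    # Width modulation along the sweep: anatomical surfaces are not
    # constant-section tubes, and a perfectly uniform section makes
    # nearest-vertex registration slide tangentially. Only the lateral
    # (a) profile coordinate is scaled, so the planar border bands stay
    # exactly planar; the modulation vanishes at the gonial corners.
    def body_width(s):
        return 1.0 + 0.25 * (1.0 - s * s) * (0.6 + 0.4 * math.sin(2.2 * s))

    def ramus_width(tau):
        return 1.0 + 0.15 * tau / spec.ramus_height

    def _warped(u):
        # non-uniform station spacing (+-30%): regular spacing makes the
        # swept surface self-similar under a one-ring shift, which leaves
        # nearest-vertex registration a spurious fixed point
        return u + 0.3 * (1.0 - np.cos(2 * np.pi * u)) * np.sin(3.7 * np.pi * u) / (3.7 * np.pi)

    def ramus_rings(s):
        a_axis = s * _X
        n_r = max(2, int(math.ceil(spec.ramus_height / edge)))
        u = np.linspace(1.0, 0.0, n_r + 1)
        taus = spec.ramus_height * _warped(u)
        out = []
        for tau in taus:
            pts = _ring_points(g0[s] + tau * r_hat, a_axis, t_hat, profile,
                               a_scale=ramus_width(tau))
            margin = (pts - g0[s]) @ m_hat[s]
            ok = np.all(margin >= clear) if s == 1 else np.all(margin <= -clear)
            if ok:
                out.append(pts)
        return out

    def body_rings():
        # arc-length-based count for roughly uniform ring spacing
        ss = np.linspace(-1.0, 1.0, 4001)
        seg = np.linalg.norm(np.diff(spec.body_centerline(ss), axis=0), axis=1)
        arc = float(seg.sum())
        n_b = int(math.ceil(arc / edge))
        if n_b % 2 == 1:
            n_b += 1
        u = np.linspace(-1.0, 1.0, n_b + 1)       # odd count, includes u = 0
        svals = np.sign(u) * _warped(np.abs(u))   # warped but fixed at -1, 0, 1
        out, s_kept = [], []
        for s in svals:
            c = spec.body_centerline(s)
            d = spec.body_tangent(s)
            a_axis = np.cross(_Z, d)
            a_axis /= np.linalg.norm(a_axis)
            pts = _ring_points(c, a_axis, _Z, profile, a_scale=body_width(s))
            if np.all((pts - g0[-1]) @ m_hat[-1] >= clear) and np.all(
                (pts - g0[1]) @ m_hat[1] <= -clear
            ):
                out.append(pts)
                s_kept.append(float(s))
        return out, s_kept

    # --- assemble sweep: left ramus top -> left corner -> body -> right corner -> right ramus
    left_ramus = ramus_rings(-1)
    body, body_s = body_rings()
    right_ramus = ramus_rings(1)[::-1]          # base -> top

    base_left = _ring_points(g0[-1], -_X, t_hat, profile)
    corner_left = _miter_corner_ring(base_left, -r_hat, g0[-1], m_hat[-1])
    base_right_body = _ring_points(
        g0[1], _X, _Z, profile
    )  # body frame at s=+1 (a_axis = +x)
    corner_right = _miter_corner_ring(base_right_body, -_Y, g0[1], m_hat[1])

    for pts in left_ramus:
        rings.append((pts, "ramus_L"))
    rings.append((corner_left, "corner_L"))
    for pts in body:
        rings.append((pts, "body"))
    rings.append((corner_right, "corner_R"))
    for pts in right_ramus:
        rings.append((pts, "ramus_R"))

    vertices = []
    faces = []
    ring_start = []
    for pts, _tag in rings:
        ring_start.append(len(vertices))
        vertices.extend(pts)
    for k in range(len(rings) - 1):
        a0, b0 = ring_start[k], ring_start[k + 1]
        for i in range(n_prof):
            i1 = (i + 1) % n_prof
            faces.append((a0 + i, b0 + i, b0 + i1))
            faces.append((a0 + i, b0 + i1, a0 + i1))

    # caps at the two ramus tops
    def cap(ring_index, flip):
        center = np.mean(rings[ring_index][0], axis=0)
        ci = len(vertices)
        vertices.append(center)
        a0 = ring_start[ring_index]
        for i in range(n_prof):
            i1 = (i + 1) % n_prof
            tri = (ci, a0 + i, a0 + i1)
            faces.append(tri[::-1] if flip else tri)
        return ci

    cap_left = cap(0, flip=False)
    cap_right = cap(len(rings) - 1, flip=True)

    # condylar head spheres
    sphere_indices = {}
    condyle_centers = {}
    for side_name, s in (("L", -1), ("R", 1)):
        center = spec.condyle_center(s)
        sv, sf = _uv_sphere(center, spec.condyle_radius, s, edge)
        off = len(vertices)
        vertices.extend(sv)
        faces.extend(sf + off)
        sphere_indices[side_name] = np.arange(off, off + len(sv))
        condyle_centers[side_name] = center

    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    mandible = TriangleMesh(vertices, faces, name="phantom_mandible")

    # --- ROI and segment bookkeeping
    tags = {}
    for (pts, tag), start in zip(rings, ring_start):
        tags.setdefault(tag, []).append((start, len(pts)))

    def tag_indices(tag, mask=None):
        idx = []
        for start, count in tags.get(tag, []):
            local = np.arange(start, start + count)
            idx.append(local[mask] if mask is not None else local)
        return np.concatenate(idx) if idx else np.empty(0, dtype=int)

    corner_indices = {
        "L": tag_indices("corner_L", bottom_mask),
        "R": tag_indices("corner_R", bottom_mask),
    }
    body_idx_all = tag_indices("body")
    body_bottom = tag_indices("body", bottom_mask)
    # inferior border bands: posterior third of the body's bottom flat, per side
    body_bottom_pts = vertices[body_bottom]
    y_cut = spec.back_y + 0.35 * (spec.chin_y - spec.back_y)
    post_third = body_bottom_pts[:, 1] <= y_cut
    inferior_L = body_bottom[post_third & (body_bottom_pts[:, 0] < 0)]
    inferior_R = body_bottom[post_third & (body_bottom_pts[:, 0] > 0)]

    rois = {
        "condyle_L": sphere_indices["L"],
        "condyle_R": sphere_indices["R"],
        "posterior_border_L": np.concatenate(
            [tag_indices("ramus_L", bottom_mask), corner_indices["L"]]
        ),
        "posterior_border_R": np.concatenate(
            [tag_indices("ramus_R", bottom_mask), corner_indices["R"]]
        ),
        "inferior_border_L": inferior_L,
        "inferior_border_R": inferior_R,
    }

    segments = {
        "body": body_idx_all,
        "ramus_L": np.concatenate(
            [tag_indices("ramus_L"), tag_indices("corner_L"), [cap_left],
             sphere_indices["L"]]
        ),
        "ramus_R": np.concatenate(
            [tag_indices("ramus_R"), tag_indices("corner_R"), [cap_right],
             sphere_indices["R"]]
        ),
    }

    # exact border planes (outward normals)
    n_post = -t_hat
    border_planes = {}
    for side_name, s in (("L", -1), ("R", 1)):
        border_planes[(side_name, "posterior")] = (g0[s] - r_b * t_hat, n_post.copy())
        border_planes[(side_name, "inferior")] = (
            np.array([s * spec.ramus_x, spec.back_y, zb - r_b]),
            -_Z.copy(),
        )

    # chin apex: profile apex vertex of the s = 0 ring
    s0_ring = min(
        (k for k, (pts, tag) in enumerate(rings) if tag == "body"),
        key=lambda k: abs(body_s[k - (1 + len(left_ramus))]),
    )
    chin_apex_index = ring_start[s0_ring] + 0  # profile index 0 is the apex (+a)

    # --- resection patches (exact elliptical tube cross-sections)
    side_sign = {"right": 1.0, "left": -1.0, "front": 1.0}[spec.operated_side]
    if spec.operated_side == "front":
        s_cuts = (-0.3, 0.3)
    else:
        s_cuts = (side_sign * spec.cut_fractions[0], side_sign * spec.cut_fractions[1])
    patches = {}
    for label, s_cut in zip(("anterior", "posterior"), s_cuts):
        center = spec.body_centerline(s_cut)
        normal = spec.body_tangent(s_cut)
        o_axis = np.cross(_Z, normal)
        o_axis /= np.linalg.norm(o_axis)
        per = math.pi * (3 * (r_a + r_b) - math.sqrt((3 * r_a + r_b) * (r_a + 3 * r_b)))
        n_ring = max(16, 4 * int(math.ceil(per / (4 * edge))))
        th = 2 * math.pi * np.arange(n_ring) / n_ring
        ring = center + r_a * np.cos(th)[:, None] * o_axis + r_b * np.sin(th)[:, None] * _Z
        pverts = np.vstack([center, ring])
        pfaces = np.array(
            [(0, 1 + k, 1 + (k + 1) % n_ring) for k in range(n_ring)], dtype=np.int64
        )
        patches[label] = PatchInfo(
            label=label,
            mesh=TriangleMesh(pverts, pfaces, name=f"patch_{label}"),
            center=center,
            normal=normal,
            ring=ring,
            s_position=float(s_cut),
        )

    tumor_centroid = spec.body_centerline((s_cuts[0] + s_cuts[1]) / 2.0)

    landmarks = {
        "porion_L": np.array([-60.0, spec.back_y - 15.0, 40.0]),
        "porion_R": np.array([60.0, spec.back_y - 15.0, 40.0]),
        "orbitale_R": np.array([45.0, 30.0, 40.0]),
        "nasion": np.array([0.0, spec.chin_y + 10.0, 45.0]),
        "basion": np.array([0.0, spec.back_y - 15.0, -10.0]),
    }

    return PlannedBundle(
        spec=spec,
        mandible=mandible,
        patches=patches,
        landmarks=landmarks,
        tumor_centroid=tumor_centroid,
        rois=rois,
        segments=segments,
        condyle_centers=condyle_centers,
        sphere_indices=sphere_indices,
        corner_indices=corner_indices,
        border_planes=border_planes,
        chin_apex_index=chin_apex_index,
    )


def randomized_spec(rng: np.random.Generator, edge: float = 2.0) -> PhantomSpec:
    """A randomly perturbed phantom spec (for property/oracle testing)."""
    return PhantomSpec(
        arch_half_width=float(rng.uniform(42.0, 58.0)),
        body_height=float(rng.uniform(24.0, 34.0)),
        ramus_height=float(rng.uniform(45.0, 65.0)),
        condyle_radius=float(rng.uniform(6.0, 10.0)),
        target_gonial_angle=float(rng.uniform(105.0, 140.0)),
        tube_radii=(float(rng.uniform(5.0, 8.0)), None),
        mesh_edge_length=edge,
        cut_fractions=(float(rng.uniform(0.35, 0.55)), float(rng.uniform(0.7, 0.9))),
    )
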