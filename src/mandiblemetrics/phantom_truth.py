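"""Error application and analytic ground truth for synthetic cases.

The ground truth for every simulated case is derived from the *sampled
perturbation parameters* and the phantom's analytic anchors (patch
rings, sphere vertices, corner-edge candidates, exact border planes) —
never by re-measuring the perturbed meshes with the measurement
pipeline. The small geometric formulas needed for that (folded plane
angles, line–plane angles, extremal points with tolerance-banded ties)
are deliberately re-stated here so the oracle does not share code with
the modules it validates.

Perturbation directions are chosen so the ground truth stays exact:

* resection patches: arbitrary translation + rotation about an in-plane
  axis through the centroid (centroid deviation = |t|, plane angle =
  |rotation angle| folded to [0, 90]);
* each ramus (with condyle and gonial corner): lateral translation and
  rotation about the lateral axis through its gonial corner — the corner
  edge maps onto itself, so the fitted border planes, the bisecting
  construction and the gonion transform exactly;
* body: horizontal translation (the inferior border plane is invariant);
* whole postoperative scene: one global rigid transform, absorbed by
  registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .mesh_io import TriangleMesh
from .phantom import ErrorModel, PhantomSpec, PlannedBundle, generate_phantom

__all__ = [
    "CaseDraw",
    "GroundTruth",
    "SyntheticCase",
    "apply_error",
    "simulate_cohort",
    "expected_cohort_means",
    "case_ground_truth",
]

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

KEY_POINT_ROLES = ("centroid", "superior", "inferior", "buccal", "lingual")
MEASURE_NAMES = (
    "ICD", "IGD", "APD",
    "gonial_angle_op", "gonial_angle_nonop",
    "axial_angle_op", "axial_angle_nonop",
    "coronal_angle_op", "coronal_angle_nonop",
)


# ---------------------------------------------------------------------------
# oracle-side geometric formulas (intentionally self-contained)
# ---------------------------------------------------------------------------


def _rot(axis, angle_deg) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def _folded_plane_angle(n1, n2) -> float:
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def _line_plane_angle(v, plane_normal) -> float:
    v = np.asarray(v, dtype=float)
    s = abs(float(np.dot(v, plane_normal))) / np.linalg.norm(v)
    return float(np.degrees(np.arcsin(min(s, 1.0))))


def _point_line_dist(p, a, b) -> float:
    ab = np.asarray(b) - np.asarray(a)
    return float(np.linalg.norm(np.cross(np.asarray(p) - a, ab)) / np.linalg.norm(ab))


def extremal_with_ties(points: np.ndarray, direction, tol: float = 1e-9) -> np.ndarray:
    """Point maximizing ``p . direction``; near-ties (within a relative
    tolerance band) broken by lexicographically smallest coordinates."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s = points @ d
    m = float(s.max())
    cand = points[s >= m - tol * (1.0 + abs(m))]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
    return cand[order[0]].copy()


def oracle_key_points(ring, normal, centroid, superior_axis, msp_point, msp_normal):
    """Replicate the resection key-point rule on an analytic boundary ring."""
    n = np.asarray(normal, dtype=float)
    s_axis = np.asarray(superior_axis, dtype=float)
    u = s_axis - np.dot(s_axis, n) * n
    u = u / np.linalg.norm(u)
    w = np.cross(n, u)
    sup = ring[int(np.argmax(ring @ u))]
    inf = ring[int(np.argmax(ring @ -u))]
    e1 = ring[int(np.argmax(ring @ w))]
    e2 = ring[int(np.argmax(ring @ -w))]
    d1 = abs(float(np.dot(e1 - msp_point, msp_normal)))
    d2 = abs(float(np.dot(e2 - msp_point, msp_normal)))
    buccal, lingual = (e1, e2) if d1 >= d2 else (e2, e1)
    return {
        "centroid": np.asarray(centroid, dtype=float),
        "superior": sup, "inferior": inf, "buccal": buccal, "lingual": lingual,
    }


def oracle_measures(cond_L, cond_R, gon_L, gon_R, pogonion,
                    post_normals, inf_normals, msp_normal, operated_side):
    """Replicate the cephalometric measurement formulas from landmark
    coordinates and outward border-plane normals."""
    out = {
        "ICD": float(np.linalg.norm(np.asarray(cond_L) - cond_R)),
        "IGD": float(np.linalg.norm(np.asarray(gon_L) - gon_R)),
        "APD": _point_line_dist(pogonion, cond_L, cond_R),
    }
    per_side = {}
    for side, cond, gon in (("L", cond_L, gon_L), ("R", cond_R, gon_R)):
        gonial = 180.0 - np.degrees(
            np.arccos(np.clip(np.dot(post_normals[side], inf_normals[side]), -1, 1))
        )
        per_side[side] = {
            "gonial": float(gonial),
            "axial": _line_plane_angle(np.asarray(pogonion) - gon, msp_normal),
            "coronal": _line_plane_angle(np.asarray(gon) - cond, msp_normal),
        }
    op = "R" if operated_side == "right" else "L"   # 'front' treated as right
    nonop = "L" if op == "R" else "R"
    for kind in ("gonial", "axial", "coronal"):
        out[f"{kind}_angle_op"] = per_side[op][kind]
        out[f"{kind}_angle_nonop"] = per_side[nonop][kind]
    return out


# ---------------------------------------------------------------------------
# sampled perturbations
# ---------------------------------------------------------------------------


@dataclass
class PatchDraw:
    translation: np.ndarray   # (3,)
    angle_deg: float          # rotation about an in-plane axis through the centroid
    axis: np.ndarray          # unit, in-plane


@dataclass
class RamusDraw:
    lateral_shift: float      # mm along the lateral (x) axis
    rotation_deg: float       # about the lateral axis through the gonial corner
    condyle_shift: np.ndarray = None  # (3,) extra condylar head displacement

    def __post_init__(self):
        if self.condyle_shift is None:
            self.condyle_shift = np.zeros(3)


@dataclass
class CaseDraw:
    patches: dict             # label -> PatchDraw
    rami: dict                # 'L'/'R' -> RamusDraw
    body_shift: np.ndarray    # (3,), horizontal (z = 0)
    global_transform: RigidTransform
    vertex_noise_sd: float


def sample_draw(planned: PlannedBundle, model: ErrorModel,
                rng: np.random.Generator) -> CaseDraw:
    """Draw one case's perturbation parameters (fixed draw order)."""
    patches = {}
    for label in ("anterior", "posterior"):
        info = planned.patches[label]
        t = rng.normal(0.0, model.plane_translation_sd, size=3) \
            if model.plane_translation_sd > 0 else np.zeros(3)
        ang = float(rng.normal(0.0, model.plane_rotation_sd)) \
            if model.plane_rotation_sd > 0 else 0.0
        psi = float(rng.uniform(0.0, 2 * np.pi))
        u0 = _Z  # patch normals are horizontal, so z is in-plane
        w0 = np.cross(info.normal, u0)
        axis = np.cos(psi) * u0 + np.sin(psi) * w0
        patches[label] = PatchDraw(translation=t, angle_deg=ang, axis=axis)

    op = "R" if planned.spec.operated_side in ("right", "front") else "L"
    rami = {}
    for side in ("L", "R"):
        f = model.operated_factor if side == op else 1.0
        d = float(rng.normal(0.0, model.segment_shift_sd * f)) \
            if model.segment_shift_sd > 0 else 0.0
        th = float(rng.normal(0.0, model.segment_rotation_sd * f)) \
            if model.segment_rotation_sd > 0 else 0.0
        dc = rng.normal(0.0, model.condyle_shift_sd * f, size=3) \
            if model.condyle_shift_sd > 0 else np.zeros(3)
        rami[side] = RamusDraw(lateral_shift=d, rotation_deg=th, condyle_shift=dc)

    if model.body_shift_sd > 0:
        bx, by = rng.normal(0.0, model.body_shift_sd, size=2)
    else:
        bx = by = 0.0
    body_shift = np.array([bx, by, 0.0])

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = float(rng.uniform(0.0, model.global_rotation_max))
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    tmag = float(rng.uniform(0.0, model.global_translation_max))
    global_T = RigidTransform(_rot(axis, ang), tmag * tdir)

    return CaseDraw(patches=patches, rami=rami, body_shift=body_shift,
                    global_transform=global_T, vertex_noise_sd=model.vertex_noise_sd)


def _patch_map(info, draw: PatchDraw):
    R = _rot(draw.axis, draw.angle_deg)
    c = info.center

    def apply(pts):
        return (np.asarray(pts) - c) @ R.T + c + draw.translation
    return R, apply


def _ramus_map(pivot, draw: RamusDraw):
    R = _rot(_X, draw.rotation_deg)
    shift = np.array([draw.lateral_shift, 0.0, 0.0])

    def apply(pts):
        return (np.asarray(pts) - pivot) @ R.T + pivot + shift
    return R, apply


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    plane_deviations: dict      # label -> metric dict
    measures_planned: dict
    measures_postop: dict
    measure_difference: dict    # name -> |planned - postop|


def _planned_gonion(planned: PlannedBundle, side: str) -> np.ndarray:
    n_post = planned.border_planes[(side, "posterior")][1]
    n_inf = planned.border_planes[(side, "inferior")][1]
    d = n_post + n_inf
    pts = planned.mandible.vertices[planned.corner_indices[side]]
    return extremal_with_ties(pts, d)


def case_ground_truth(planned: PlannedBundle, draw: CaseDraw) -> GroundTruth:
    """Analytic deviation metrics implied by one case's perturbations.

    Metrics are evaluated in *body-anchored* planned coordinates: the
    global scene transform and any body shift are absorbed by
    registering on the unresected body (the pipeline's registration ROI
    for synthetic cases), so each patch effectively moves by its own
    rigid error minus the body shift, each ramus by its segment error
    minus the body shift, and the body not at all. With a zero body
    shift this coincides with plain planned coordinates.
    """
    spec = planned.spec
    msp_point = np.zeros(3)
    msp_normal = _X
    tumor = planned.tumor_centroid
    anchor = -draw.body_shift  # extra translation seen by non-body structures

    # --- resection-plane deviations
    plane_dev = {}
    for label, info in planned.patches.items():
        pd = draw.patches[label]
        R, amap = _patch_map(info, pd)
        ring2 = amap(info.ring) + anchor
        n2 = R @ info.normal
        kp1 = oracle_key_points(info.ring, info.normal, info.center,
                                _Z, msp_point, msp_normal)
        kp2 = oracle_key_points(ring2, n2, amap(info.center) + anchor,
                                _Z, msp_point, msp_normal)
        n_t = info.normal if np.dot(tumor - info.center, info.normal) > 0 \
            else -info.normal
        offsets = {r: float(np.dot(kp2[r] - info.center, n_t)) for r in KEY_POINT_ROLES}
        centroid_offset = offsets["centroid"]
        if abs(centroid_offset) < 1e-9:
            direction = "on_plane"
        else:
            direction = "toward_tumor" if centroid_offset > 0 else "away_from_tumor"
        plane_dev[label] = {
            **{f"d_{r}": float(np.linalg.norm(kp2[r] - kp1[r])) for r in KEY_POINT_ROLES},
            "angle": _folded_plane_angle(info.normal, n2),
            "signed_centroid_offset": centroid_offset,
            "shift_direction": direction,
            "point_offsets": offsets,
        }

    # --- cephalometric measures
    verts = planned.mandible.vertices
    cond1, cond2, gon1, gon2 = {}, {}, {}, {}
    post_n1, post_n2, inf_n = {}, {}, {}
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        sphere = verts[planned.sphere_indices[side]]
        cond1[side] = sphere[int(np.argmax(sphere @ (sgn * _X)))]
        gon1[side] = _planned_gonion(planned, side)
        n_post = planned.border_planes[(side, "posterior")][1]
        inf_n[side] = planned.border_planes[(side, "inferior")][1]
        post_n1[side] = n_post

        rd = draw.rami[side]
        R, rmap = _ramus_map(gon1[side], rd)
        sphere2 = rmap(sphere) + anchor + rd.condyle_shift
        cond2[side] = sphere2[int(np.argmax(sphere2 @ (sgn * _X)))]
        post_n2[side] = R @ n_post
        corners2 = rmap(verts[planned.corner_indices[side]]) + anchor
        gon2[side] = extremal_with_ties(corners2, post_n2[side] + inf_n[side])

    pog1 = verts[planned.chin_apex_index]
    pog2 = pog1.copy()   # body-anchored: the body (and chin) never moves

    m1 = oracle_measures(cond1["L"], cond1["R"], gon1["L"], gon1["R"], pog1,
                         post_n1, inf_n, msp_normal, spec.operated_side)
    m2 = oracle_measures(cond2["L"], cond2["R"], gon2["L"], gon2["R"], pog2,
                         post_n2, inf_n, msp_normal, spec.operated_side)
    diff = {k: abs(m1[k] - m2[k]) for k in MEASURE_NAMES}
    return GroundTruth(plane_deviations=plane_dev, measures_planned=m1,
                       measures_postop=m2, measure_difference=diff)


# ---------------------------------------------------------------------------
# synthetic cases and cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCase:
    case_id: str
    planned: PlannedBundle
    postop_meshes: dict         # role -> TriangleMesh (in scanner/postop coordinates)
    draw: CaseDraw
    global_transform: RigidTransform
    ground_truth: GroundTruth
    plate_type: str = "conventional"
    n_segments: int = 1
    registration_roi: np.ndarray | None = None  # indices into postop mandible


def apply_error(planned: PlannedBundle, model: ErrorModel,
                seed: int | np.random.Generator = 0,
                case_id: str = "case") -> SyntheticCase:
    """Create the postoperative copy of a planned bundle with known errors."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = sample_draw(planned, model, rng)
    G = draw.global_transform

    verts = planned.mandible.vertices.copy()
    for side in ("L", "R"):
        pivot = _planned_gonion(planned, side)
        _, rmap = _ramus_map(pivot, draw.rami[side])
        idx = planned.segments[f"ramus_{side}"]
        verts[idx] = rmap(verts[idx])
        verts[planned.sphere_indices[side]] += draw.rami[side].condyle_shift
    bidx = planned.segments["body"]
    verts[bidx] = verts[bidx] + draw.body_shift
    if model.vertex_noise_sd > 0:
        verts = verts + rng.normal(0.0, model.vertex_noise_sd, size=verts.shape)
    postop_mandible = TriangleMesh(G.apply(verts), planned.mandible.faces.copy(),
                                   name="postop_mandible")

    postop = {"postop_mandible": postop_mandible}
    for label, info in planned.patches.items():
        _, amap = _patch_map(info, draw.patches[label])
        pv = amap(info.mesh.vertices)
        if model.vertex_noise_sd > 0:
            pv = pv + rng.normal(0.0, model.vertex_noise_sd, size=pv.shape)
        postop[f"achieved_patch_{label}"] = TriangleMesh(
            G.apply(pv), info.mesh.faces.copy(), name=f"achieved_patch_{label}"
        )

    # segment or body errors break whole-mesh rigidity: anchor registration
    # on the unresected body, matching the body-anchored ground truth
    has_segment_error = (
        model.segment_shift_sd > 0 or model.segment_rotation_sd > 0
        or model.condyle_shift_sd > 0 or model.body_shift_sd > 0
    )
    return SyntheticCase(
        case_id=case_id,
        planned=planned,
        postop_meshes=postop,
        draw=draw,
        global_transform=G,
        ground_truth=case_ground_truth(planned, draw),
        registration_roi=planned.segments["body"] if has_segment_error else None,
    )


@dataclass
class Cohort:
    planned: PlannedBundle
    cases: list = field(default_factory=list)

    def ground_truth_table(self):
        import pandas as pd

        rows = []
        for case in self.cases:
            gt = case.ground_truth
            row = {"case_id": case.case_id, "plate_type": case.plate_type}
            for label, dev in gt.plane_deviations.items():
                for r in KEY_POINT_ROLES:
                    row[f"{label}_d_{r}"] = dev[f"d_{r}"]
                row[f"{label}_angle"] = dev["angle"]
                row[f"{label}_shift_direction"] = dev["shift_direction"]
            for k, v in gt.measure_difference.items():
                row[f"mad_{k}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_cohort(n: int, spec: PhantomSpec | None = None,
                    model: ErrorModel | None = None,
                    plate_mix: float = 0.35, seed: int = 0,
                    psi_model: ErrorModel | None = None,
                    planned: PlannedBundle | None = None) -> Cohort:
    """Simulate ``n`` independent cases from one phantom.

    ``plate_mix`` is the fraction labeled PSI (the rest conventional);
    ``psi_model`` optionally gives the PSI group a different error model
    so group-comparison statistics can be exercised at a known effect
    size. Deterministic in ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if planned is None:
        planned = generate_phantom(spec or PhantomSpec())
    model = model or ErrorModel()
    psi_model = psi_model or model
    n_psi = int(round(n * plate_mix))
    children = np.random.SeedSequence(seed).spawn(n)
    cohort = Cohort(planned=planned)
    for i in range(n):
        plate = "PSI" if i < n_psi else "conventional"
        case = apply_error(planned, psi_model if plate == "PSI" else model,
                           seed=np.random.default_rng(children[i]),
                           case_id=f"case_{i:04d}")
        case.plate_type = plate
        cohort.cases.append(case)
    return cohort


def write_synthetic_case(case: SyntheticCase, directory, fmt: str = "ply"):
    """Write one synthetic case as mesh files plus a YAML manifest.

    PLY (default) preserves vertex order, so the manifest can carry the
    phantom's vertex-index ROIs; with STL the condylar ROIs are emitted
    as seed/radius balls instead and the border-band ROIs still require
    index lists, so PLY is the format of choice for full bundles.
    Returns the manifest path.
    """
    import yaml

    from .mesh_io import write_mesh

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    planned = case.planned
    meshes = {
        "planned_mandible": planned.mandible,
        "planned_patch_anterior": planned.patches["anterior"].mesh,
        "planned_patch_posterior": planned.patches["posterior"].mesh,
        **case.postop_meshes,
    }
    mesh_entries = {}
    for role, mesh in meshes.items():
        fname = f"{case.case_id}_{role}.{fmt}"
        write_mesh(mesh, directory / fname)
        mesh_entries[role] = fname
    manifest = {
        "schema_version": 1,
        "case_id": case.case_id,
        "operated_side": planned.spec.operated_side,
        "plate_type": case.plate_type,
        "n_segments": case.n_segments,
        "tumor_centroid": [float(v) for v in planned.tumor_centroid],
        "landmarks": {k: [float(x) for x in v] for k, v in planned.landmarks.items()},
        "meshes": mesh_entries,
        "rois": {k: {"indices": [int(i) for i in v]} for k, v in planned.rois.items()},
    }
    if case.registration_roi is not None:
        manifest["registration_roi"] = {
            "indices": [int(i) for i in case.registration_roi]}
    path = directory / f"{case.case_id}.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def expected_cohort_means(planned: PlannedBundle, model: ErrorModel,
                          n_draws: int = 20000, seed: int = 12345):
    """Generating-distribution means/SDs of every deviation metric,
    estimated by evaluating the analytic ground-truth formulas on
    ``n_draws`` fresh parameter draws (no meshes involved).

    Returns ``{metric: (mean, sd)}`` with the five key-point distances
    and the plane angle pooled over both resection planes, plus the nine
    cephalometric absolute differences.
    """
    rng = np.random.default_rng(seed)
    acc = {f"d_{r}": [] for r in KEY_POINT_ROLES}
    acc["angle"] = []
    for name in MEASURE_NAMES:
        acc[f"mad_{name}"] = []
    for _ in range(n_draws):
        gt = case_ground_truth(planned, sample_draw(planned, model, rng))
        for dev in gt.plane_deviations.values():
            for r in KEY_POINT_ROLES:
                acc[f"d_{r}"].append(dev[f"d_{r}"])
            acc["angle"].append(dev["angle"])
        for k, v in gt.measure_difference.items():
            acc[f"mad_{k}"].append(v)
    return {k: (float(np.mean(v)), float(np.std(v, ddof=1))) for k, v in acc.items()}
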