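"""Resection-plane deviation metrics.

For each resection plane (anterior and posterior of the resected
segment), five key points are identified on the planned and achieved
patches — the superior, inferior, buccal and lingual boundary points and
the area centroid — in the shared anatomical frame. The deviation
metrics are the role-wise Euclidean distances between planned and
achieved key points, the folded angle between the fitted planes, and the
signed centroid offset along the planned-plane normal oriented towards
the tumor centroid (shift towards / away from the tumor).

Scenes must already be co-registered (see
:mod:`mandiblemetrics.registration`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DegenerateGeometryError, PlanarPatch, angle_between_planes, signed_distance
from .reference_frame import ReferenceFrame

__all__ = [
    "KeyPointSet",
    "PlaneDeviation",
    "ResectionPatchPair",
    "boundary_vertex_indices",
    "extract_key_points",
    "plane_deviation",
    "aggregate_resection",
]

KEY_POINT_ROLES = ("centroid", "superior", "inferior", "buccal", "lingual")
PLANE_LABELS = ("anterior", "posterior")
ON_PLANE_TOL = 1e-9


@dataclass
class KeyPointSet:
    centroid: np.ndarray
    superior: np.ndarray
    inferior: np.ndarray
    buccal: np.ndarray
    lingual: np.ndarray

    def as_dict(self) -> dict:
        return {r: getattr(self, r) for r in KEY_POINT_ROLES}


@dataclass
class ResectionPatchPair:
    planned: PlanarPatch
    achieved: PlanarPatch
    label: str
    case_id: str = ""

    def __post_init__(self):
        if self.label not in PLANE_LABELS:
            raise ValueError(f"label must be one of {PLANE_LABELS}")


@dataclass
class PlaneDeviation:
    label: str
    case_id: str
    d_centroid: float
    d_superior: float
    d_inferior: float
    d_buccal: float
    d_lingual: float
    angle: float
    signed_centroid_offset: float
    shift_direction: str
    point_offsets: dict  # role -> signed offset of achieved point vs planned plane

    def distance(self, role: str) -> float:
        return getattr(self, f"d_{role}")

    def as_record(self) -> dict:
        rec = {"case_id": self.case_id, "label": self.label}
        for r in KEY_POINT_ROLES:
            rec[f"d_{r}"] = self.distance(r)
        rec["angle"] = self.angle
        rec["signed_centroid_offset"] = self.signed_centroid_offset
        rec["shift_direction"] = self.shift_direction
        return rec


def boundary_vertex_indices(mesh) -> np.ndarray:
    """Vertex indices on the patch outline: endpoints of edges used by
    exactly one triangle, in ascending index order."""
    faces = np.asarray(mesh.faces)
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border = uniq[counts == 1]
    if border.size == 0:
        raise DegenerateGeometryError("patch mesh has no boundary (closed surface?)")
    return np.unique(border)


def _area_centroid(mesh) -> np.ndarray:
    v = np.asarray(mesh.vertices)
    f = np.asarray(mesh.faces)
    tri = v[f]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    total = areas.sum()
    if total <= 0:
        raise DegenerateGeometryError("patch has zero total area")
    return (tri.mean(axis=1) * areas[:, None]).sum(axis=0) / total


def extract_key_points(patch: PlanarPatch, frame: ReferenceFrame) -> KeyPointSet:
    """Key points of one planar patch in the anatomical frame.

    The in-plane "up" axis is the projection of the superior axis onto
    the fitted plane (its norm must be >= 0.1: a cut plane nearly
    perpendicular to the superior axis has no meaningful superior /
    inferior points and requires manual key points). The transverse axis
    is normal x up; of its two extremes the *buccal* point is the one
    farther (in absolute signed distance) from the midsagittal plane.
    Extremal points are patch-outline vertices, ties broken by lowest
    vertex index.
    """
    n = patch.fitted_plane.normal
    s_axis = frame.axis_superior
    u = s_axis - np.dot(s_axis, n) * n
    nu = np.linalg.norm(u)
    if nu < 0.1:
        raise DegenerateGeometryError(
            "cut plane is nearly perpendicular to the superior axis; "
            "supply manual key points via the manifest override"
        )
    u = u / nu
    w = np.cross(n, u)

    ring = boundary_vertex_indices(patch.mesh)
    verts = np.asarray(patch.mesh.vertices)
    sub = verts[ring]

    def ext(direction):
        return sub[int(np.argmax(sub @ direction))]

    superior, inferior = ext(u), ext(-u)
    e_plus, e_minus = ext(w), ext(-w)
    d_plus = abs(signed_distance(frame.midsagittal, e_plus))
    d_minus = abs(signed_distance(frame.midsagittal, e_minus))
    buccal, lingual = (e_plus, e_minus) if d_plus >= d_minus else (e_minus, e_plus)
    return KeyPointSet(
        centroid=_area_centroid(patch.mesh),
        superior=superior, inferior=inferior, buccal=buccal, lingual=lingual,
    )


def plane_deviation(pair: ResectionPatchPair, frame: ReferenceFrame,
                    tumor_centroid) -> PlaneDeviation:
    """All deviation metrics for one planned/achieved plane pair."""
    kp_plan = extract_key_points(pair.planned, frame).as_dict()
    kp_done = extract_key_points(pair.achieved, frame).as_dict()
    distances = {
        r: float(np.linalg.norm(kp_done[r] - kp_plan[r])) for r in KEY_POINT_ROLES
    }
    angle = angle_between_planes(pair.planned.fitted_plane, pair.achieved.fitted_plane)

    plane_t = pair.planned.fitted_plane.oriented_towards(tumor_centroid)
    # signed offsets measured from the *planned centroid* along the
    # tumor-oriented normal, so patch position (not plane point) anchors the sign
    n_t = plane_t.normal
    offsets = {
        r: float(np.dot(kp_done[r] - kp_plan["centroid"], n_t)) for r in KEY_POINT_ROLES
    }
    c_off = offsets["centroid"]
    if abs(c_off) < ON_PLANE_TOL:
        direction = "on_plane"
    else:
        direction = "toward_tumor" if c_off > 0 else "away_from_tumor"
    return PlaneDeviation(
        label=pair.label, case_id=pair.case_id,
        **{f"d_{r}": distances[r] for r in KEY_POINT_ROLES},
        angle=angle, signed_centroid_offset=c_off, shift_direction=direction,
        point_offsets=offsets,
    )


def aggregate_resection(deviations, exclude=()) -> pd.DataFrame:
    """Cohort summary of resection-plane deviations.

    One row per measurement (five key points + plane angle): mean, SD and
    range over all included planes, the anterior/posterior split, the
    count shifted towards the tumor, and the paired anterior-vs-posterior
    p-value (Wilcoxon signed rank over cases contributing both planes).
    ``exclude`` is an explicit list of (case_id, label) pairs echoed in
    the result attrs; no plane is ever excluded automatically.
    """
    from .stats import wilcoxon_signed_rank

    deviations = list(deviations)
    if not deviations:
        raise ValueError("no deviations to aggregate")
    excl = {tuple(e) for e in exclude}
    included = [d for d in deviations if (d.case_id, d.label) not in excl]
    if not included:
        raise ValueError("all deviations excluded")

    by_label = {lab: [d for d in included if d.label == lab] for lab in PLANE_LABELS}
    paired_cases = sorted(
        {d.case_id for d in by_label["anterior"]} & {d.case_id for d in by_label["posterior"]}
    )

    def value(d, meas):
        return d.angle if meas == "angle" else d.distance(meas)

    rows = []
    for meas in (*KEY_POINT_ROLES, "angle"):
        vals = np.array([value(d, meas) for d in included])
        row = {
            "measurement": meas,
            "all_n": len(vals),
            "all_mean": vals.mean(),
            "all_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "all_min": vals.min(),
            "all_max": vals.max(),
        }
        for lab in PLANE_LABELS:
            sub = np.array([value(d, meas) for d in by_label[lab]])
            row[f"{lab}_n"] = len(sub)
            row[f"{lab}_mean"] = sub.mean() if len(sub) else np.nan
            row[f"{lab}_sd"] = sub.std(ddof=1) if len(sub) > 1 else np.nan
        if meas != "angle":
            toward = sum(1 for d in included if d.point_offsets[meas] > ON_PLANE_TOL)
            row["toward_tumor_n"] = toward
            row["toward_tumor_pct"] = 100.0 * toward / len(included)
        else:
            row["toward_tumor_n"] = np.nan
            row["toward_tumor_pct"] = np.nan
        if len(paired_cases) >= 1:
            ant = {d.case_id: value(d, meas) for d in by_label["anterior"]}
            post = {d.case_id: value(d, meas) for d in by_label["posterior"]}
            x = [ant[c] for c in paired_cases]
            y = [post[c] for c in paired_cases]
            try:
                row["p_anterior_vs_posterior"] = wilcoxon_signed_rank(x, y).p_value
            except ValueError:
                row["p_anterior_vs_posterior"] = np.nan
        else:
            row["p_anterior_vs_posterior"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["excluded"] = sorted(excl)
    table.attrs["n_excluded"] = len(excl)
    return table
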