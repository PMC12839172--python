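"""Cephalometric landmark extraction and measurements on mandible meshes.

Landmarks follow tangent-plane / bisecting-plane constructions so that
they are reproducible on any triangulated surface:

* lateral condyle point — vertex of the condylar ROI extremal along the
  lateral (midsagittal-normal) direction, i.e. where a duplicate of the
  midsagittal plane first touches the condylar head;
* pogonion — vertex extremal along the anterior axis (coronal-plane
  contact with the chin);
* gonion — the posterior and inferior border bands are fitted with
  least-squares planes (outward normals); the plane bisecting their
  dihedral angle, taken through their intersection line, is intersected
  with the mandibular surface and the gonion is the intersection point
  extremal along the outward bisector direction (the most
  postero-inferior point of the cut curve).

Measurements: intercondylar distance (ICD), intergonial distance (IGD),
anteroposterior distance (APD, pogonion to the intercondylar line), and
per side the gonial angle (dihedral between border planes), the coronal
angle (condyle–gonion line vs midsagittal) and the axial angle
(gonion–pogonion line vs midsagittal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .geometry import (
    DegenerateGeometryError,
    Plane,
    angle_line_plane,
    dihedral_angle,
    extremal_point,
    fit_plane,
    point_to_line_distance,
    signed_distance,
)
from .reference_frame import ReferenceFrame

__all__ = [
    "MandibleLandmarks",
    "BorderPlanes",
    "CephalometricMeasures",
    "find_condyle_lateral",
    "find_pogonion",
    "fit_border_planes",
    "find_gonion",
    "measure_mandible",
    "compare_measures",
    "aggregate_reconstruction",
]

MEASURE_NAMES = (
    "ICD", "IGD", "APD",
    "gonial_angle_op", "gonial_angle_nonop",
    "axial_angle_op", "axial_angle_nonop",
    "coronal_angle_op", "coronal_angle_nonop",
)


@dataclass
class MandibleLandmarks:
    condyle_lateral_L: np.ndarray
    condyle_lateral_R: np.ndarray
    gonion_L: np.ndarray
    gonion_R: np.ndarray
    pogonion: np.ndarray

    def validate_sides(self, frame: ReferenceFrame) -> None:
        r = frame.axis_right
        o = frame.midsagittal.point
        for name, sign in (("condyle_lateral_L", -1), ("condyle_lateral_R", 1),
                           ("gonion_L", -1), ("gonion_R", 1)):
            if sign * np.dot(getattr(self, name) - o, r) <= 0:
                raise DegenerateGeometryError(
                    f"{name} lies on the wrong side of the midsagittal plane"
                )


@dataclass
class BorderPlanes:
    posterior: Plane     # outward normal
    inferior: Plane      # outward normal
    rms_posterior: float
    rms_inferior: float


@dataclass
class CephalometricMeasures:
    ICD: float
    IGD: float
    APD: float
    gonial_angle_op: float
    gonial_angle_nonop: float
    axial_angle_op: float
    axial_angle_nonop: float
    coronal_angle_op: float
    coronal_angle_nonop: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in MEASURE_NAMES}


def find_condyle_lateral(mesh, side: str, frame: ReferenceFrame, roi) -> np.ndarray:
    """Most lateral vertex of the condylar ROI (tangent midsagittal plane)."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    direction = frame.axis_right if side == "right" else -frame.axis_right
    point, _ = extremal_point(mesh, direction, roi=roi)
    return point


def find_pogonion(mesh, frame: ReferenceFrame, roi=None) -> np.ndarray:
    """Most anterior vertex of the mandible (tangent coronal plane)."""
    point, _ = extremal_point(mesh, frame.axis_anterior, roi=roi)
    return point


def fit_border_planes(mesh, posterior_roi, inferior_roi,
                      border_fit_tol: float = 2.0) -> BorderPlanes:
    """Least-squares planes through the posterior and inferior border
    bands, outward-oriented (away from the mesh centroid)."""
    centroid = np.asarray(mesh.vertices).mean(axis=0)
    planes = {}
    rms = {}
    for name, roi in (("posterior", posterior_roi), ("inferior", inferior_roi)):
        roi = np.asarray(roi, dtype=int)
        if roi.size < 3:
            raise DegenerateGeometryError(f"{name} border ROI has fewer than 3 vertices")
        plane, r = fit_plane(np.asarray(mesh.vertices)[roi])
        if r > border_fit_tol:
            raise DegenerateGeometryError(
                f"{name} border band fits poorly (rms {r:.2f} mm > {border_fit_tol} mm)"
            )
        if signed_distance(plane, centroid) > 0:
            plane = plane.flipped()   # outward: bone centroid on the negative side
        planes[name] = plane
        rms[name] = r
    return BorderPlanes(posterior=planes["posterior"], inferior=planes["inferior"],
                        rms_posterior=rms["posterior"], rms_inferior=rms["inferior"])


def _bisecting_plane(borders: BorderPlanes):
    """Plane through the border planes' intersection line spanning the
    outward bisector direction; returns (plane, bisector d)."""
    n1, n2 = borders.posterior.normal, borders.inferior.normal
    line_dir = np.cross(n1, n2)
    norm = np.linalg.norm(line_dir)
    if norm < 1e-9:
        raise DegenerateGeometryError("border planes are parallel; no bisecting plane")
    line_dir = line_dir / norm
    d = n1 + n2
    d = d / np.linalg.norm(d)
    # point on both planes: least-norm solution of the two plane equations
    A = np.vstack([n1, n2])
    b = np.array([np.dot(n1, borders.posterior.point), np.dot(n2, borders.inferior.point)])
    p0 = np.linalg.lstsq(A, b, rcond=None)[0]
    n_b = np.cross(line_dir, d)
    return Plane(p0, n_b / np.linalg.norm(n_b)), d


def find_gonion(mesh, borders: BorderPlanes, frame: ReferenceFrame | None = None,
                side: str | None = None, tie_tol: float = 1e-9) -> np.ndarray:
    """Gonion: bisecting-plane/mesh intersection point extremal along the
    outward bisector.

    ``side`` ('left'/'right') with a frame restricts candidates to one
    side of the midsagittal plane (the bisecting plane of one angle also
    slices the contralateral ramus). Near-ties along the bisector (a
    perfectly sharp prismatic corner yields a whole tied edge) are broken
    by lexicographically smallest coordinates, which is deterministic and
    stable under the tolerance band.
    """
    bis, d = _bisecting_plane(borders)
    tm = mesh.to_trimesh() if hasattr(mesh, "to_trimesh") else trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False)
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=bis.normal, plane_origin=bis.point)
    candidates = [np.asarray(segments).reshape(-1, 3)] if len(segments) else []
    # vertices lying exactly in the bisecting plane (knife-edge case)
    verts = np.asarray(mesh.vertices)
    on_plane = np.abs((verts - bis.point) @ bis.normal) < 1e-9
    if on_plane.any():
        candidates.append(verts[on_plane])
    if not candidates:
        raise DegenerateGeometryError("bisecting plane does not intersect the mesh")
    pts = np.vstack(candidates)
    if side is not None:
        if frame is None:
            raise ValueError("side restriction requires a reference frame")
        sgn = 1.0 if side == "right" else -1.0
        keep = sgn * ((pts - frame.midsagittal.point) @ frame.midsagittal.normal) > 0
        pts = pts[keep]
        if pts.shape[0] == 0:
            raise DegenerateGeometryError(f"no bisecting-plane intersection on {side} side")
    score = pts @ d
    m = float(score.max())
    near = pts[score >= m - tie_tol * (1.0 + abs(m))]
    order = np.lexsort((near[:, 2], near[:, 1], near[:, 0]))
    return near[order[0]].copy()


def measure_mandible(landmarks: MandibleLandmarks, borders_L: BorderPlanes,
                     borders_R: BorderPlanes, frame: ReferenceFrame,
                     operated_side: str) -> CephalometricMeasures:
    """All nine cephalometric measures for one mandible model."""
    cl, cr = landmarks.condyle_lateral_L, landmarks.condyle_lateral_R
    if np.linalg.norm(cl - cr) < 1e-9:
        raise DegenerateGeometryError("condyle points coincide")
    per_side = {}
    for side, gon, cond, borders in (
        ("L", landmarks.gonion_L, cl, borders_L),
        ("R", landmarks.gonion_R, cr, borders_R),
    ):
        per_side[side] = {
            "gonial": dihedral_angle(borders.posterior, borders.inferior),
            "coronal": angle_line_plane(gon - cond, frame.midsagittal),
            "axial": angle_line_plane(landmarks.pogonion - gon, frame.midsagittal),
        }
    op = "R" if operated_side in ("right", "front") else "L"
    nonop = "L" if op == "R" else "R"
    return CephalometricMeasures(
        ICD=float(np.linalg.norm(cl - cr)),
        IGD=float(np.linalg.norm(landmarks.gonion_L - landmarks.gonion_R)),
        APD=point_to_line_distance(landmarks.pogonion, cl, cr),
        gonial_angle_op=per_side[op]["gonial"],
        gonial_angle_nonop=per_side[nonop]["gonial"],
        axial_angle_op=per_side[op]["axial"],
        axial_angle_nonop=per_side[nonop]["axial"],
        coronal_angle_op=per_side[op]["coronal"],
        coronal_angle_nonop=per_side[nonop]["coronal"],
    )


def compare_measures(planned: CephalometricMeasures,
                     postop: CephalometricMeasures) -> dict:
    """Per-measure absolute planned-vs-postoperative difference."""
    a, b = planned.as_dict(), postop.as_dict()
    return {k: abs(a[k] - b[k]) for k in MEASURE_NAMES}


def aggregate_reconstruction(differences, plate_types) -> pd.DataFrame:
    """Cohort summary of reconstruction accuracy.

    One row per measure: mean absolute difference (MAD) and SD over all
    cases and within the conventional / PSI subgroups, plus the
    conventional-vs-PSI Mann–Whitney p-value. Subgroup columns are NaN
    when a subgroup is empty.
    """
    from .stats import mann_whitney_u

    differences = list(differences)
    plate_types = list(plate_types)
    if not differences:
        raise ValueError("no differences to aggregate")
    if len(differences) != len(plate_types):
        raise ValueError("differences and plate_types must align")
    rows = []
    for meas in MEASURE_NAMES:
        vals = np.array([d[meas] for d in differences])
        row = {
            "measurement": meas,
            "all_n": len(vals),
            "all_mad": vals.mean(),
            "all_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
        }
        groups = {}
        for grp in ("conventional", "PSI"):
            sub = vals[[p == grp for p in plate_types]]
            groups[grp] = sub
            row[f"{grp}_n"] = len(sub)
            row[f"{grp}_mad"] = sub.mean() if len(sub) else np.nan
            row[f"{grp}_sd"] = sub.std(ddof=1) if len(sub) > 1 else np.nan
        if len(groups["conventional"]) and len(groups["PSI"]):
            row["p_conventional_vs_psi"] = mann_whitney_u(
                groups["conventional"], groups["PSI"]).p_value
        else:
            row["p_conventional_vs_psi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
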