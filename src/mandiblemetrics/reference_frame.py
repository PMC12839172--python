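"""Anatomical reference frame from manually placed skull landmarks.

The frame consists of three mutually perpendicular planes and a
right-handed orthonormal axis triad:

* Frankfort horizontal plane — through left/right porion and the right
  orbitale, normal oriented superiorly (towards the nasion).
* Midsagittal plane — the unique plane through nasion and basion that is
  perpendicular to the Frankfort plane, normal oriented to the patient's
  right (towards porion_R).
* Coronal plane — mutually perpendicular to both, normal oriented
  anteriorly (towards the nasion); its position (through-point) is
  irrelevant to every downstream measurement and defaults to the basion.

Axes: ``axis_right`` = midsagittal normal, ``axis_superior`` = Frankfort
normal, ``axis_anterior`` = coronal normal = superior x right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, Plane, plane_from_points, signed_distance

__all__ = [
    "SkullLandmarks",
    "ReferenceFrame",
    "build_frankfort",
    "build_midsagittal",
    "build_coronal",
    "build_frame",
]


@dataclass(frozen=True)
class SkullLandmarks:
    porion_L: np.ndarray
    porion_R: np.ndarray
    orbitale_R: np.ndarray
    nasion: np.ndarray
    basion: np.ndarray

    def __post_init__(self):
        for name in ("porion_L", "porion_R", "orbitale_R", "nasion", "basion"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} is not a finite 3D point")
            object.__setattr__(self, name, p)
        if np.allclose(self.porion_L, self.porion_R):
            raise ValueError("porion_L and porion_R coincide")
        if np.allclose(self.nasion, self.basion):
            raise ValueError("nasion and basion coincide")

    @classmethod
    def from_dict(cls, d) -> "SkullLandmarks":
        return cls(d["porion_L"], d["porion_R"], d["orbitale_R"], d["nasion"], d["basion"])


@dataclass(frozen=True)
class ReferenceFrame:
    frankfort: Plane
    midsagittal: Plane
    coronal: Plane
    axis_right: np.ndarray
    axis_anterior: np.ndarray
    axis_superior: np.ndarray


def build_frankfort(landmarks: SkullLandmarks) -> Plane:
    """Frankfort horizontal plane through both porions and the right
    orbitale, normal on the nasion (superior) side."""
    plane = plane_from_points(landmarks.porion_L, landmarks.porion_R, landmarks.orbitale_R)
    d = signed_distance(plane, landmarks.nasion)
    if abs(d) < 1e-9:
        raise DegenerateGeometryError(
            "nasion lies on the Frankfort plane; superior orientation is ambiguous"
        )
    return plane if d > 0 else plane.flipped()


def build_midsagittal(frankfort: Plane, nasion, basion, porion_R=None) -> Plane:
    """The unique plane containing nasion and basion and perpendicular to
    the Frankfort plane.

    The normal is ``frankfort.normal x (nasion - basion)`` normalized,
    flipped towards ``porion_R`` when that landmark is supplied.
    """
    nasion = np.asarray(nasion, dtype=float)
    basion = np.asarray(basion, dtype=float)
    axis = nasion - basion
    n = np.cross(frankfort.normal, axis)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * max(np.linalg.norm(axis), 1.0):
        raise DegenerateGeometryError(
            "nasion-basion direction is parallel to the Frankfort normal; "
            "no unique midsagittal plane"
        )
    plane = Plane(nasion, n / norm)
    if porion_R is not None and signed_distance(plane, porion_R) < 0:
        plane = plane.flipped()
    return plane


def build_coronal(frankfort: Plane, midsagittal: Plane, through, nasion=None) -> Plane:
    """Plane mutually perpendicular to Frankfort and midsagittal, through
    ``through``, normal oriented anteriorly (positive towards nasion)."""
    if abs(np.dot(frankfort.normal, midsagittal.normal)) > 1e-6:
        raise DegenerateGeometryError("frankfort and midsagittal planes are not perpendicular")
    n = np.cross(frankfort.normal, midsagittal.normal)
    plane = Plane(np.asarray(through, dtype=float), n / np.linalg.norm(n))
    if nasion is not None:
        d = signed_distance(plane, nasion)
        if abs(d) < 1e-9:
            raise DegenerateGeometryError("nasion lies on the coronal plane; orientation ambiguous")
        if d < 0:
            plane = plane.flipped()
    return plane


def build_frame(landmarks: SkullLandmarks, coronal_through=None) -> ReferenceFrame:
    """Full reference frame; deterministic in the landmark set and
    rigid-equivariant (transforming the landmarks transforms the frame)."""
    frankfort = build_frankfort(landmarks)
    midsagittal = build_midsagittal(
        frankfort, landmarks.nasion, landmarks.basion, porion_R=landmarks.porion_R
    )
    through = landmarks.basion if coronal_through is None else coronal_through
    coronal = build_coronal(frankfort, midsagittal, through, nasion=landmarks.nasion)
    return ReferenceFrame(
        frankfort=frankfort,
        midsagittal=midsagittal,
        coronal=coronal,
        axis_right=midsagittal.normal,
        axis_anterior=coronal.normal,
        axis_superior=frankfort.normal,
    )
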