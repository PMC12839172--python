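"""Surface-mesh and case-manifest I/O.

Meshes are exchanged as STL (binary or ASCII) or PLY files via trimesh;
in memory they live in a minimal :class:`TriangleMesh` container
(float64 vertices in mm, int faces). Loading always applies the same
cleaning pass: duplicate vertices merged within 1e-6 mm and degenerate
(zero-area) faces dropped, preserving the order of surviving vertices so
that vertex-index ROIs remain meaningful for formats that keep vertex
order (PLY).

A case manifest is a human-editable YAML file (``schema_version: 1``)
carrying everything the analysis needs besides the meshes themselves:
the five manually placed skull landmarks, the tumor centroid, the
operated side, plate metadata, and the region-of-interest definitions
(condylar heads, posterior/inferior border bands) that the source study
drew interactively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

logger = logging.getLogger(__name__)

MERGE_TOL = 1e-6  # mm; far below any imaging slice thickness

MANIFEST_SCHEMA_VERSION = 1
SKULL_LANDMARK_NAMES = ("porion_L", "porion_R", "orbitale_R", "nasion", "basion")
ROI_NAMES = (
    "condyle_L",
    "condyle_R",
    "posterior_border_L",
    "posterior_border_R",
    "inferior_border_L",
    "inferior_border_R",
)
PLATE_TYPES = ("conventional", "miniplate", "PSI", "bookshelf-PSI")
OPERATED_SIDES = ("left", "right", "front")


class MeshFormatError(ValueError):
    """Unparseable, empty or otherwise invalid mesh file."""


class ManifestError(ValueError):
    """Manifest fails schema validation; message names the offending field."""


@dataclass
class TriangleMesh:
    """Triangulated anatomical surface (vertices in mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.shape[0] < 3:
            raise MeshFormatError(f"mesh '{self.name}': fewer than 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError(f"mesh '{self.name}': non-finite coordinates")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshFormatError(f"mesh '{self.name}': face index out of range")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def transformed(self, transform) -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def clean_mesh(vertices, faces, name: str = "", tol: float = MERGE_TOL):
    """Merge near-duplicate vertices and drop degenerate faces.

    Vertices within ``tol`` (snapped to a grid of spacing ``tol``) are
    merged onto their first occurrence, so the relative order of
    surviving vertices is preserved and cleaning is idempotent. Returns
    ``(mesh, n_vertices_removed, n_faces_removed)``.
    """
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep first-occurrence order
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    new_vertices = vertices[first[order]]
    remap = rank[inverse]
    new_faces = remap[faces]
    # degenerate: repeated index or (numerically) zero area
    repeated = (
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 0] == new_faces[:, 2])
    )
    keep = ~repeated
    if keep.any():
        areas = _face_areas(new_vertices, new_faces[keep])
        sub = np.ones(int(keep.sum()), dtype=bool)
        sub[areas <= 1e-14] = False
        kept_idx = np.flatnonzero(keep)[sub]
    else:
        kept_idx = np.empty(0, dtype=int)
    n_vr = vertices.shape[0] - new_vertices.shape[0]
    n_fr = faces.shape[0] - kept_idx.size
    mesh = TriangleMesh(new_vertices, new_faces[kept_idx], name)
    return mesh, int(n_vr), int(n_fr)


def read_mesh(path, name: str | None = None) -> TriangleMesh:
    """Read an STL (binary/ASCII) or PLY mesh and clean it.

    Raises FileNotFoundError for a missing file and
    :class:`MeshFormatError` for unparseable or empty content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise MeshFormatError(f"cannot parse mesh file {path}: {exc}") from exc
    if not hasattr(tm, "vertices") or len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise MeshFormatError(f"mesh file {path} contains no triangles")
    mesh, n_vr, n_fr = clean_mesh(tm.vertices, tm.faces, name or path.stem)
    if n_vr or n_fr:
        logger.info(
            "cleaned %s: removed %d duplicate vertices, %d degenerate faces",
            path.name, n_vr, n_fr,
        )
    return mesh


def write_mesh(mesh: TriangleMesh, path, encoding: str = "auto") -> None:
    """Write a mesh as PLY (ascii) or STL (``encoding``: auto|binary|ascii)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
    elif suffix == ".stl":
        if encoding == "ascii":
            path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
        else:
            path.write_bytes(trimesh.exchange.stl.export_stl(tm))
    else:
        raise MeshFormatError(f"unsupported mesh format: {path.suffix}")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MESH_ROLES_REQUIRED = (
    "planned_mandible",
    "planned_patch_anterior",
    "planned_patch_posterior",
    "postop_mandible",
    "achieved_patch_anterior",
    "achieved_patch_posterior",
)


@dataclass
class CaseManifest:
    """Validated per-case inputs: mesh paths, landmarks, ROIs, metadata."""

    case_id: str
    mesh_paths: dict
    landmarks: dict  # name -> (3,) array, planned-scan coordinates
    tumor_centroid: np.ndarray
    operated_side: str
    rois: dict  # name -> vertex index array into planned/postop mandible
    plate_type: str
    n_segments: int = 0
    scale: float = 1.0
    registration_roi: np.ndarray | None = None
    source_path: Path | None = None
    meshes: dict = field(default_factory=dict)  # role -> TriangleMesh (lazy)

    def mesh(self, role: str) -> TriangleMesh:
        if role not in self.meshes:
            self.meshes[role] = read_mesh(self.mesh_paths[role], name=role)
            if self.scale != 1.0:
                self.meshes[role].vertices *= self.scale
        return self.meshes[role]


def _resolve_roi(spec, mesh: TriangleMesh, roi_name: str) -> np.ndarray:
    """An ROI is either an explicit index list or a (seed, radius) ball.

    Ball ROIs resolve to ``{v : |v - seed| <= radius}`` over the mesh
    vertices. Either way the result must contain at least 3 vertices.
    """
    if isinstance(spec, dict) and "indices" in spec:
        idx = np.asarray(spec["indices"], dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_vertices):
            raise ManifestError(f"roi '{roi_name}': index out of range")
    elif isinstance(spec, dict) and "seed" in spec:
        seed = np.asarray(spec["seed"], dtype=float)
        radius = float(spec["radius"])
        d = np.linalg.norm(mesh.vertices - seed, axis=1)
        idx = np.flatnonzero(d <= radius)
    elif isinstance(spec, (list, tuple, np.ndarray)):
        idx = np.asarray(spec, dtype=int)
    else:
        raise ManifestError(f"roi '{roi_name}': expected indices list or seed/radius mapping")
    if idx.size < 3:
        raise ManifestError(f"roi '{roi_name}': resolves to fewer than 3 vertices")
    return idx


def load_manifest(path) -> CaseManifest:
    """Load and validate a YAML case manifest; relative paths resolve
    against the manifest's own directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ManifestError("manifest is not a mapping")
    version = data.get("schema_version")
    if version != MANIFEST_SCHEMA_VERSION:
        raise ManifestError(f"unsupported schema_version: {version!r}")

    for fieldname in ("case_id", "meshes", "landmarks", "tumor_centroid", "operated_side", "rois", "plate_type"):
        if fieldname not in data:
            raise ManifestError(f"missing field '{fieldname}'")

    landmarks = {}
    for lm in SKULL_LANDMARK_NAMES:
        if lm not in data["landmarks"]:
            raise ManifestError(f"missing landmark '{lm}'")
        landmarks[lm] = np.asarray(data["landmarks"][lm], dtype=float)
        if landmarks[lm].shape != (3,) or not np.all(np.isfinite(landmarks[lm])):
            raise ManifestError(f"landmark '{lm}' is not a finite 3D point")

    if data["operated_side"] not in OPERATED_SIDES:
        raise ManifestError(f"operated_side must be one of {OPERATED_SIDES}")
    if data["plate_type"] not in PLATE_TYPES:
        raise ManifestError(f"plate_type must be one of {PLATE_TYPES}")

    mesh_paths = {}
    for role in MESH_ROLES_REQUIRED:
        if role not in data["meshes"]:
            raise ManifestError(f"missing mesh role '{role}'")
    for role, rel in data["meshes"].items():
        p = (path.parent / rel).resolve() if not Path(rel).is_absolute() else Path(rel)
        if not p.exists():
            raise ManifestError(f"mesh role '{role}': file not found: {p}")
        mesh_paths[role] = p

    manifest = CaseManifest(
        case_id=str(data["case_id"]),
        mesh_paths=mesh_paths,
        landmarks=landmarks,
        tumor_centroid=np.asarray(data["tumor_centroid"], dtype=float),
        operated_side=data["operated_side"],
        rois={},
        plate_type=data["plate_type"],
        n_segments=int(data.get("n_segments", 0)),
        scale=float(data.get("scale", 1.0)),
        source_path=path,
    )
    planned = manifest.mesh("planned_mandible")
    for roi_name in ROI_NAMES:
        if roi_name not in data["rois"]:
            raise ManifestError(f"missing roi '{roi_name}'")
        manifest.rois[roi_name] = _resolve_roi(data["rois"][roi_name], planned, roi_name)
    if "registration_roi" in data and data["registration_roi"] is not None:
        manifest.registration_roi = _resolve_roi(
            data["registration_roi"], manifest.mesh("postop_mandible"), "registration_roi"
        )
    return manifest


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_results(records, path, columns=None, float_format: str = "%.2f") -> pd.DataFrame:
    """Write per-case measurement records as a CSV table (2-decimal mm/deg).

    ``records`` is an iterable of mappings sharing one schema. An empty
    collection yields a header-only file, for which ``columns`` must be
    given.
    """
    records = list(records)
    if records:
        keys = list(records[0].keys())
        for i, r in enumerate(records):
            if list(r.keys()) != keys:
                raise ValueError(f"record {i} does not share the common schema")
        df = pd.DataFrame(records, columns=keys)
    elif columns is not None:
        df = pd.DataFrame(columns=list(columns))
    else:
        raise ValueError("empty record collection requires explicit columns for the header")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
    return df
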