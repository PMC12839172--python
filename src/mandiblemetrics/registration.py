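"""Rigid alignment of the postoperative scene to the preoperative plan.

Trimmed point-to-point ICP: iterate nearest-target-vertex
correspondences for a deterministic subsample of source vertices, drop
the worst fraction by distance, solve the rigid least-squares problem,
and repeat until the correspondence RMS stabilizes. Trimming makes the
alignment robust to the region where surgery changed the anatomy; the
remaining (unresected) anatomy drives the fit.

Everything is deterministic for fixed inputs and parameters: the
subsample is farthest-point sampling started from a seed-derived vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DegenerateGeometryError, RigidTransform, rigid_fit

__all__ = ["ICPParams", "RegistrationResult", "icp_register", "transform_scene",
           "farthest_point_indices"]


@dataclass
class ICPParams:
    max_iterations: int = 100
    rms_change_tol: float = 1e-4  # mm
    trim_fraction: float = 0.10
    init: RigidTransform = field(default_factory=RigidTransform.identity)
    sample_size: int | None = 5000  # None: use every source vertex
    sample_method: str = "farthest"  # or "random"
    seed: int = 0
    principal_axes_init: bool = False

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rms_change_tol <= 0:
            raise ValueError("rms_change_tol must be > 0")


@dataclass
class RegistrationResult:
    transform: RigidTransform  # maps postoperative coordinates into planned coordinates
    final_rms: float
    iterations_used: int
    converged: bool


def farthest_point_indices(points: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Deterministic farthest-point subsample of ``k`` indices.

    Starts from a seed-selected vertex and greedily adds the point
    farthest from the selected set (max-min distance).
    """
    n = points.shape[0]
    if k >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    chosen = np.empty(k, dtype=int)
    chosen[0] = start
    dist = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, k):
        idx = int(np.argmax(dist))
        chosen[i] = idx
        np.minimum(dist, np.linalg.norm(points - points[idx], axis=1), out=dist)
    return np.sort(chosen)


def _principal_axes_transform(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    """Coarse pre-alignment by centroids and covariance eigenvectors."""

    def axes(p):
        c = p.mean(axis=0)
        _, _, vt = np.linalg.svd(p - c, full_matrices=False)
        R = vt.T
        if np.linalg.det(R) < 0:
            R[:, 2] *= -1
        return c, R
    cs, Rs = axes(src)
    ct, Rt = axes(tgt)
    R = Rt @ Rs.T
    return RigidTransform(R, ct - R @ cs)


def icp_register(source, target, params: ICPParams | None = None) -> RegistrationResult:
    """Register ``source`` (postoperative) onto ``target`` (planned).

    Returns a transform mapping source coordinates into target
    coordinates. Non-convergence within ``max_iterations`` is reported
    via ``converged=False``, not an exception.
    """
    params = params or ICPParams()
    src_all = np.asarray(source.vertices, dtype=float)
    tgt = np.asarray(target.vertices, dtype=float)
    if src_all.shape[0] < 3 or tgt.shape[0] < 3:
        raise DegenerateGeometryError("both meshes must have at least 3 vertices")

    if params.sample_size is None or params.sample_size >= src_all.shape[0]:
        sample = np.arange(src_all.shape[0])
    elif params.sample_method == "farthest":
        sample = farthest_point_indices(src_all, params.sample_size, seed=params.seed)
    elif params.sample_method == "random":
        rng = np.random.default_rng(params.seed)
        sample = np.sort(rng.choice(src_all.shape[0],
                                    min(params.sample_size, src_all.shape[0]),
                                    replace=False))
    else:
        raise ValueError(f"unknown sample_method: {params.sample_method}")
    src = src_all[sample]

    tree = cKDTree(tgt)
    T = params.init
    if params.principal_axes_init:
        T = _principal_axes_transform(src_all, tgt)

    n_keep = max(3, int(np.ceil(src.shape[0] * (1.0 - params.trim_fraction))))
    prev_rms = np.inf
    rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        moved = T.apply(src)
        dist, nn = tree.query(moved, k=1)
        if params.trim_fraction > 0:
            keep = np.argpartition(dist, n_keep - 1)[:n_keep]
        else:
            keep = slice(None)
        pairs_src = src[keep]
        pairs_tgt = tgt[nn[keep]]
        T = rigid_fit(pairs_src, pairs_tgt)
        resid = T.apply(pairs_src) - pairs_tgt
        rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        if abs(prev_rms - rms) < params.rms_change_tol:
            converged = True
            break
        prev_rms = rms
    return RegistrationResult(transform=T, final_rms=rms,
                              iterations_used=iterations, converged=converged)


def transform_scene(bundle, transform: RigidTransform):
    """Apply a rigid transform to a collection of meshes and patches.

    ``bundle`` is a mapping role -> TriangleMesh or PlanarPatch; fitted
    planes are mapped along with their meshes (planarity residuals are
    rigid invariants and carried over unchanged).
    """
    from .geometry import PlanarPatch  # local import to avoid cycle at module load

    out = {}
    for role, obj in bundle.items():
        if isinstance(obj, PlanarPatch):
            out[role] = PlanarPatch(
                mesh=obj.mesh.transformed(transform),
                fitted_plane=transform.apply_plane(obj.fitted_plane),
                rms_residual=obj.rms_residual,
            )
        else:
            out[role] = obj.transformed(transform)
    return out


def params_with_init(params: ICPParams, init: RigidTransform) -> ICPParams:
    return replace(params, init=init)
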