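"""Case- and cohort-level orchestration.

``run_case`` executes the full measurement chain for one case: build the
anatomical frame from the skull landmarks, register the postoperative
scene onto the plan, compute resection-plane deviations for the anterior
and posterior planes, extract mandibular landmarks and compare the
cephalometric measures. ``run_cohort`` maps it over many cases (failures
are per-case, never cohort-fatal) and aggregates the two summary tables
with their group tests. ``run_agreement`` computes ICC reliability
reports for repeated-measurement tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reconstruction, resection
from .geometry import PlanarPatch
from .mesh_io import CaseManifest, load_manifest
from .phantom_truth import SyntheticCase
from .reference_frame import SkullLandmarks, build_frame
from .registration import ICPParams, icp_register, transform_scene
from .stats import icc, icc_band

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "CaseRecord", "run_case", "run_cohort", "run_agreement"]


@dataclass
class PipelineConfig:
    icp: ICPParams = field(default_factory=ICPParams)
    planarity_tol: float = 1.0        # mm, patch planarity gate
    border_fit_tol: float = 2.0       # mm, border band rms gate
    project_axial_to_frankfort: bool = False
    exclude: tuple = ()               # ((case_id, label), ...) echoed by aggregation
    seed: int = 0

    def __post_init__(self):
        if self.planarity_tol <= 0 or self.border_fit_tol <= 0:
            raise ValueError("tolerances must be positive")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["icp"]["init"] = None  # transforms are not part of the identity
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class CaseRecord:
    case_id: str
    plate_type: str
    operated_side: str
    n_segments: int
    registration_rms: float
    registration_iterations: int
    registration_converged: bool
    deviations: dict           # label -> resection.PlaneDeviation
    measures_planned: dict
    measures_postop: dict
    measure_difference: dict
    failed: bool = False
    failure_stage: str = ""
    failure_reason: str = ""

    @classmethod
    def failure(cls, case_id, stage, reason, plate_type="", operated_side="", n_segments=0):
        return cls(case_id=case_id, plate_type=plate_type, operated_side=operated_side,
                   n_segments=n_segments, registration_rms=float("nan"),
                   registration_iterations=0, registration_converged=False,
                   deviations={}, measures_planned={}, measures_postop={},
                   measure_difference={}, failed=True, failure_stage=stage,
                   failure_reason=reason)


# ---------------------------------------------------------------------------
# normalized case inputs
# ---------------------------------------------------------------------------


@dataclass
class _CaseInputs:
    case_id: str
    planned_mandible: object
    planned_patches: dict      # label -> TriangleMesh
    postop_mandible: object
    achieved_patches: dict     # label -> TriangleMesh
    landmarks: SkullLandmarks
    tumor_centroid: np.ndarray
    rois: dict
    operated_side: str
    plate_type: str
    n_segments: int
    registration_roi: np.ndarray | None = None
    registration_roi_target: np.ndarray | None = None


def _normalize_inputs(case) -> _CaseInputs:
    if isinstance(case, (str, Path)):
        case = load_manifest(case)
    if isinstance(case, CaseManifest):
        return _CaseInputs(
            case_id=case.case_id,
            planned_mandible=case.mesh("planned_mandible"),
            planned_patches={
                "anterior": case.mesh("planned_patch_anterior"),
                "posterior": case.mesh("planned_patch_posterior"),
            },
            postop_mandible=case.mesh("postop_mandible"),
            achieved_patches={
                "anterior": case.mesh("achieved_patch_anterior"),
                "posterior": case.mesh("achieved_patch_posterior"),
            },
            landmarks=SkullLandmarks.from_dict(case.landmarks),
            tumor_centroid=case.tumor_centroid,
            rois=case.rois,
            operated_side=case.operated_side,
            plate_type=case.plate_type,
            n_segments=case.n_segments,
            registration_roi=case.registration_roi,
        )
    if isinstance(case, SyntheticCase):
        planned = case.planned
        return _CaseInputs(
            case_id=case.case_id,
            planned_mandible=planned.mandible,
            planned_patches={lab: info.mesh for lab, info in planned.patches.items()},
            postop_mandible=case.postop_meshes["postop_mandible"],
            achieved_patches={
                "anterior": case.postop_meshes["achieved_patch_anterior"],
                "posterior": case.postop_meshes["achieved_patch_posterior"],
            },
            landmarks=SkullLandmarks.from_dict(planned.landmarks),
            tumor_centroid=planned.tumor_centroid,
            rois=planned.rois,
            operated_side=planned.spec.operated_side,
            plate_type=case.plate_type,
            n_segments=case.n_segments,
            registration_roi=case.registration_roi,
        )
    raise TypeError(f"cannot analyze object of type {type(case)!r}")


# ---------------------------------------------------------------------------
# case pipeline
# ---------------------------------------------------------------------------


def _measure_model(mesh, rois, frame, config, operated_side):
    borders = {}
    for side in ("L", "R"):
        borders[side] = reconstruction.fit_border_planes(
            mesh, rois[f"posterior_border_{side}"], rois[f"inferior_border_{side}"],
            border_fit_tol=config.border_fit_tol,
        )
    landmarks = reconstruction.MandibleLandmarks(
        condyle_lateral_L=reconstruction.find_condyle_lateral(
            mesh, "left", frame, rois["condyle_L"]),
        condyle_lateral_R=reconstruction.find_condyle_lateral(
            mesh, "right", frame, rois["condyle_R"]),
        gonion_L=reconstruction.find_gonion(mesh, borders["L"], frame, side="left"),
        gonion_R=reconstruction.find_gonion(mesh, borders["R"], frame, side="right"),
        pogonion=reconstruction.find_pogonion(mesh, frame),
    )
    landmarks.validate_sides(frame)
    measures = reconstruction.measure_mandible(
        landmarks, borders["L"], borders["R"], frame, operated_side,
    )
    if config.project_axial_to_frankfort:
        # axial angles measured on lines projected into the Frankfort plane
        nf = frame.frankfort.normal

        def proj(v):
            return v - np.dot(v, nf) * nf
        from .geometry import angle_line_plane
        gon = {"L": landmarks.gonion_L, "R": landmarks.gonion_R}
        op = "R" if operated_side in ("right", "front") else "L"
        nonop = "L" if op == "R" else "R"
        measures.axial_angle_op = angle_line_plane(
            proj(landmarks.pogonion - gon[op]), frame.midsagittal)
        measures.axial_angle_nonop = angle_line_plane(
            proj(landmarks.pogonion - gon[nonop]), frame.midsagittal)
    return landmarks, borders, measures


def run_case(case, config: PipelineConfig | None = None) -> CaseRecord:
    """Analyze one case (manifest path, CaseManifest or SyntheticCase)."""
    config = config or PipelineConfig()
    try:
        inputs = _normalize_inputs(case)
    except Exception as exc:  # noqa: BLE001
        cid = getattr(case, "case_id", str(case))
        return CaseRecord.failure(cid, "load_inputs", str(exc))

    meta = dict(plate_type=inputs.plate_type, operated_side=inputs.operated_side,
                n_segments=inputs.n_segments)
    try:
        frame = build_frame(inputs.landmarks)
    except Exception as exc:  # noqa: BLE001
        return CaseRecord.failure(inputs.case_id, "build_frame", str(exc), **meta)

    try:
        source = inputs.postop_mandible
        target = inputs.planned_mandible
        if inputs.registration_roi is None:
            reg = icp_register(source, target, config.icp)
        else:
            # Registration mask: a coarse whole-mesh pass for initialization,
            # then refinement driven only by the masked (stable) anatomy on
            # both sides of the correspondence, untrimmed — the mask already
            # excludes non-corresponding structures.
            from dataclasses import replace as _dc_replace
            from types import SimpleNamespace
            coarse = icp_register(source, target, config.icp)
            roi = np.asarray(inputs.registration_roi, dtype=int)
            sub_source = SimpleNamespace(vertices=np.asarray(source.vertices)[roi])
            troi = roi if inputs.registration_roi_target is None else np.asarray(
                inputs.registration_roi_target, dtype=int)
            sub_target = SimpleNamespace(vertices=np.asarray(target.vertices)[troi])
            refine = _dc_replace(config.icp, trim_fraction=0.0, sample_size=None,
                                 rms_change_tol=min(config.icp.rms_change_tol, 1e-10),
                                 max_iterations=max(config.icp.max_iterations, 300),
                                 init=coarse.transform)
            reg = icp_register(sub_source, sub_target, refine)
        bundle = {"postop_mandible": inputs.postop_mandible,
                  **{f"achieved_{k}": v for k, v in inputs.achieved_patches.items()}}
        moved = transform_scene(bundle, reg.transform)
    except Exception as exc:  # noqa: BLE001
        return CaseRecord.failure(inputs.case_id, "icp_register", str(exc), **meta)

    deviations = {}
    try:
        for label in ("anterior", "posterior"):
            pair = resection.ResectionPatchPair(
                planned=PlanarPatch.from_mesh(inputs.planned_patches[label],
                                              max_planarity_tol=config.planarity_tol),
                achieved=PlanarPatch.from_mesh(moved[f"achieved_{label}"],
                                               max_planarity_tol=config.planarity_tol),
                label=label, case_id=inputs.case_id,
            )
            deviations[label] = resection.plane_deviation(
                pair, frame, inputs.tumor_centroid)
    except Exception as exc:  # noqa: BLE001
        return CaseRecord.failure(inputs.case_id, "plane_deviation", str(exc), **meta)

    try:
        _, _, measures_planned = _measure_model(
            inputs.planned_mandible, inputs.rois, frame, config, inputs.operated_side)
        _, _, measures_postop = _measure_model(
            moved["postop_mandible"], inputs.rois, frame, config, inputs.operated_side)
        difference = reconstruction.compare_measures(measures_planned, measures_postop)
    except Exception as exc:  # noqa: BLE001
        return CaseRecord.failure(inputs.case_id, "fit_border_planes/landmarks",
                                  str(exc), **meta)

    return CaseRecord(
        case_id=inputs.case_id,
        plate_type=inputs.plate_type,
        operated_side=inputs.operated_side,
        n_segments=inputs.n_segments,
        registration_rms=reg.final_rms,
        registration_iterations=reg.iterations_used,
        registration_converged=reg.converged,
        deviations=deviations,
        measures_planned=measures_planned.as_dict(),
        measures_postop=measures_postop.as_dict(),
        measure_difference=difference,
    )


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    records: list
    resection_table: pd.DataFrame
    reconstruction_table: pd.DataFrame
    n_failed: int

    def failed_cases(self):
        return [r for r in self.records if r.failed]


def run_cohort(cases, config: PipelineConfig | None = None) -> CohortResult:
    """Analyze many cases and aggregate the two summary tables.

    ``cases`` is an iterable of manifest paths / manifests / synthetic
    cases, or a directory containing ``*.yaml`` manifests. Failed cases
    are recorded and excluded from aggregation; if every case fails an
    error is raised.
    """
    config = config or PipelineConfig()
    if isinstance(cases, (str, Path)) and Path(cases).is_dir():
        cases = sorted(Path(cases).glob("*.yaml"))
    records = [run_case(c, config) for c in cases]
    ok = [r for r in records if not r.failed]
    if not ok:
        raise RuntimeError("all cases failed; nothing to aggregate")
    for r in records:
        if r.failed:
            logger.warning("case %s failed at %s: %s",
                           r.case_id, r.failure_stage, r.failure_reason)

    deviations = [d for r in ok for d in r.deviations.values()]
    resection_table = resection.aggregate_resection(deviations, exclude=config.exclude)
    reconstruction_table = reconstruction.aggregate_reconstruction(
        [r.measure_difference for r in ok], [r.plate_type for r in ok])
    return CohortResult(records=records, resection_table=resection_table,
                        reconstruction_table=reconstruction_table,
                        n_failed=len(records) - len(ok))


def write_cohort_tables(result: CohortResult, out_dir, config: PipelineConfig,
                        float_format: str = "%.2f") -> dict:
    """Write the two cohort tables (plus per-case records) as CSV files;
    every file embeds the config hash and seed in a comment header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# mandiblemetrics config_hash={config.config_hash()} seed={config.seed}\n"
    paths = {}

    def emit(name, df):
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format=float_format, lineterminator="\n")
        paths[name] = path

    emit("resection_accuracy.csv", result.resection_table)
    emit("reconstruction_accuracy.csv", result.reconstruction_table)
    case_rows = []
    for r in result.records:
        row = {"case_id": r.case_id, "plate_type": r.plate_type,
               "operated_side": r.operated_side, "failed": r.failed,
               "failure_stage": r.failure_stage,
               "registration_rms": r.registration_rms}
        for label, dev in r.deviations.items():
            for role in resection.KEY_POINT_ROLES:
                row[f"{label}_d_{role}"] = dev.distance(role)
            row[f"{label}_angle"] = dev.angle
            row[f"{label}_shift"] = dev.shift_direction
        for k, v in r.measure_difference.items():
            row[f"mad_{k}"] = v
        case_rows.append(row)
    emit("case_records.csv", pd.DataFrame(case_rows))
    return paths


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def run_agreement(ratings_by_measurement: dict,
                  form: str = "two_way_absolute_single") -> pd.DataFrame:
    """ICC reliability report for repeated measurements.

    ``ratings_by_measurement`` maps a measurement name to an
    (n_subjects, n_raters/sessions) matrix. Returns one row per
    measurement with the ICC and its qualitative band.
    """
    rows = []
    for name, matrix in ratings_by_measurement.items():
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError(f"measurement {name!r}: need >= 2 raters/sessions")
        value = icc(m, form=form)
        rows.append({"measurement": name, "n_subjects": m.shape[0],
                     "n_raters": m.shape[1], "icc": value, "band": icc_band(value)})
    return pd.DataFrame(rows)
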