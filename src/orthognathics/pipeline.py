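"""Per-patient analysis pipeline and cohort summaries.

For each osteotomized segment the pipeline derives two rigid motions:

* *surgical displacement* — preoperative -> postoperative position, and
* *surgical accuracy*    — 3D-planned  -> postoperative position,

and factors each into the six clinically reported quantities in the
anatomical frame built from the patient's cranial reference landmarks.
Proximal (condyle-bearing) segments are not planned preoperatively, so they
yield only displacement-derived autorotation/flare measures.

Two analysis modes exist.  In *direct* mode the postoperative landmark
triangles are given and motions come from closed-form Procrustes fits; in
*registration* mode the motions are recovered from per-segment volumes
(intensity registration) or meshes (trimmed ICP for the proximal segments).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .frames import (AnatomicalFrame, CephalometricLandmarkSet, MovementReport,
                     ProximalReport, build_frame, decompose, proximal_measures)
from .geometry import (SEGMENT_IDS, SEGMENT_VERTEX_ORDER, RigidTransform,
                       SegmentTriangle, compose, invert, procrustes_rigid,
                       transform_triangle)
from .registration import (SurfaceMesh, VolumeImage, register_surfaces_icp,
                           register_volumes_rigid)

__all__ = [
    "PatientCase",
    "CaseResult",
    "CohortSummary",
    "triangle_from_landmarks",
    "transfer_triangle",
    "compute_case",
    "summarize_cohort",
    "round_half_up",
]

logger = logging.getLogger(__name__)

#: Segments whose position is planned preoperatively (accuracy is defined).
PLANNED_SEGMENTS = ("maxilla", "mandible_distal")
PROXIMAL_SEGMENTS = ("proximal_left", "proximal_right")


def triangle_from_landmarks(landmarks: CephalometricLandmarkSet,
                            segment_id: str,
                            state_label: str = "preop") -> SegmentTriangle:
    """Build a segment triangle from its three landmarks, in the fixed
    per-segment vertex order; bilateral ramus landmarks take the segment's
    side suffix."""
    names = SEGMENT_VERTEX_ORDER[segment_id]
    if segment_id.startswith("proximal_"):
        side = segment_id.split("_", 1)[1]
        names = tuple(f"{n}_{side}" for n in names)
    verts = np.vstack([landmarks[n] for n in names])
    return SegmentTriangle(segment_id, verts, state_label)


def transfer_triangle(tri_preop: SegmentTriangle,
                      plan: RigidTransform) -> SegmentTriangle:
    """Carry a preoperative triangle to its planned position (the landmarks
    move with the segment, so no re-identification is needed)."""
    return transform_triangle(plan, tri_preop, state_label="planned")


@dataclass
class PatientCase:
    """All inputs needed to analyse one patient.

    ``planning_transforms`` maps planned segments to their preop->planned
    rigid motion from the virtual plan.  Exactly one postoperative data route
    must be populated: ``triangles_postop`` (direct mode) or
    ``volumes``/``meshes`` (registration mode, per-segment
    ``(preop, postop)`` pairs).
    """

    case_id: str
    landmarks_preop: CephalometricLandmarkSet
    planning_transforms: dict[str, RigidTransform]
    triangles_postop: dict[str, SegmentTriangle] | None = None
    volumes: dict[str, tuple[VolumeImage, VolumeImage]] | None = None
    meshes: dict[str, tuple[SurfaceMesh, SurfaceMesh]] | None = None

    def __post_init__(self):
        for seg, t in self.planning_transforms.items():
            if seg not in SEGMENT_IDS:
                raise ValueError(f"unknown planned segment {seg!r}")
            if not isinstance(t, RigidTransform):
                raise TypeError(f"plan for {seg!r} is not a RigidTransform")
        if self.triangles_postop is None and not (self.volumes or self.meshes):
            raise ValueError(
                f"case {self.case_id!r}: no postoperative data "
                "(triangles, volumes or meshes required)"
            )

    @property
    def mode(self) -> str:
        return "direct" if self.triangles_postop is not None else "registration"


@dataclass
class CaseResult:
    """Per-segment movement reports for one analysed patient."""

    case_id: str
    frame: AnatomicalFrame
    displacement: dict[str, MovementReport] = field(default_factory=dict)
    accuracy: dict[str, MovementReport] = field(default_factory=dict)
    proximal: dict[str, ProximalReport] = field(default_factory=dict)


def _postop_motion_direct(case: PatientCase, segment: str,
                          tri_source: SegmentTriangle) -> RigidTransform | None:
    tri_post = case.triangles_postop.get(segment)
    if tri_post is None:
        return None
    return procrustes_rigid(tri_source, tri_post).transform


def compute_case(case: PatientCase,
                 frame: AnatomicalFrame | None = None) -> CaseResult:
    """Analyse one patient: recover per-segment motions and decompose them.

    Displacement translations are reported for the preoperative triangle
    centroid, accuracy translations for the planned triangle centroid, so a
    segment rotated about its own centre reports zero translation.

    Missing segment data is skipped with a logged warning; a degenerate
    landmark triangle raises for that segment.
    """
    frame = frame or build_frame(case.landmarks_preop)
    result = CaseResult(case_id=case.case_id, frame=frame)

    for segment in PLANNED_SEGMENTS:
        try:
            tri_pre = triangle_from_landmarks(case.landmarks_preop, segment)
        except KeyError:
            logger.warning("case %s: segment %s skipped (landmarks missing)",
                           case.case_id, segment)
            continue
        plan = case.planning_transforms.get(segment)
        if plan is None:
            logger.warning("case %s: segment %s skipped (no planning transform)",
                           case.case_id, segment)
            continue
        tri_planned = transfer_triangle(tri_pre, plan)

        if case.mode == "direct":
            disp = _postop_motion_direct(case, segment, tri_pre)
            if disp is None:
                logger.warning("case %s: segment %s skipped (no postop triangle)",
                               case.case_id, segment)
                continue
            acc = procrustes_rigid(tri_planned,
                                   case.triangles_postop[segment]).transform
        else:
            pair = (case.volumes or {}).get(segment)
            if pair is None:
                logger.warning("case %s: segment %s skipped (no volumes)",
                               case.case_id, segment)
                continue
            pre_vol, post_vol = pair
            disp = register_volumes_rigid(pre_vol, post_vol, init=plan).transform
            acc = compose(disp, invert(plan))

        result.displacement[segment] = decompose(
            disp, frame, segment, about=tri_pre.centroid)
        result.accuracy[segment] = decompose(
            acc, frame, segment, about=tri_planned.centroid)

    for segment in PROXIMAL_SEGMENTS:
        side = segment.split("_", 1)[1]
        if case.mode == "direct":
            try:
                tri_pre = triangle_from_landmarks(case.landmarks_preop, segment)
            except KeyError:
                logger.warning("case %s: segment %s skipped (landmarks missing)",
                               case.case_id, segment)
                continue
            disp = _postop_motion_direct(case, segment, tri_pre)
            if disp is None:
                logger.warning("case %s: segment %s skipped (no postop triangle)",
                               case.case_id, segment)
                continue
        else:
            pair = (case.meshes or {}).get(segment)
            if pair is None:
                logger.warning("case %s: segment %s skipped (no meshes)",
                               case.case_id, segment)
                continue
            pre_mesh, post_mesh = pair
            disp = register_surfaces_icp(pre_mesh, post_mesh).transform
        result.proximal[side] = proximal_measures(disp, frame, side)

    return result


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (the convention of printed clinical tables;
    banker's rounding would flip exact .5 cells)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComponentSummary:
    mean: float
    abs_mean: float
    n_negative: int
    n_positive: int

    def __post_init__(self):
        if abs(self.mean) > self.abs_mean + 1e-12:
            raise ValueError("|mean| cannot exceed the absolute mean")


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level mean / absolute-mean rows plus directional counts."""

    segment_id: str
    n: int
    components: dict[str, ComponentSummary]

    def rounded(self, decimals: int = 2) -> dict[str, dict[str, float]]:
        return {
            comp: {
                "mean": round_half_up(cs.mean, decimals),
                "abs_mean": round_half_up(cs.abs_mean, decimals),
                "n_negative": cs.n_negative,
                "n_positive": cs.n_positive,
            }
            for comp, cs in self.components.items()
        }


def summarize_cohort(reports: list[MovementReport]) -> CohortSummary:
    """Mean, absolute mean and strict sign counts per component.

    All reports must describe the same segment.  Zeros count as neither
    negative nor positive (the directional "k out of n" counts are strict).
    """
    if not reports:
        raise ValueError("cannot summarize an empty cohort")
    segment_ids = {r.segment_id for r in reports}
    if len(segment_ids) != 1:
        raise ValueError(f"mixed segments in cohort: {sorted(segment_ids)}")
    comps = {}
    for comp in MovementReport.COMPONENTS:
        values = np.array([getattr(r, comp) for r in reports], dtype=float)
        comps[comp] = ComponentSummary(
            mean=float(values.mean()),
            abs_mean=float(np.abs(values).mean()),
            n_negative=int((values < 0).sum()),
            n_positive=int((values > 0).sum()),
        )
    return CohortSummary(segment_id=segment_ids.pop(), n=len(reports),
                         components=comps)
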