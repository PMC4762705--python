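"""Fully synthetic patients: phantom skulls, planned surgery, execution error
and landmark-identification noise.

The phantom is geometric, not anatomical: each bone structure (cranial base,
maxilla, distal mandible, two proximal segments) is a cluster of Gaussian
intensity blobs plus a blobby surface mesh, laid out at realistic
cephalometric positions (bilateral porions/orbitale, dental arches, rami).
Blob clusters can be rendered onto a voxel grid in any rigid pose *exactly*
(the blob centres are transformed analytically), so registration tests have
interpolation-free ground truth.

A simulated surgery applies a per-segment planning transform, then a random
execution-error transform (rotation about the segment centroid) drawn from an
:class:`ErrorModel`; landmark positions in every state can be perturbed by
independent identification noise.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .frames import (AnatomicalFrame, CephalometricLandmarkSet, build_frame,
                     recompose, MovementReport)
from .geometry import (SEGMENT_IDS, RigidTransform, SegmentTriangle, apply,
                       compose)
from .pipeline import (PLANNED_SEGMENTS, PROXIMAL_SEGMENTS, PatientCase,
                       compute_case, triangle_from_landmarks)
from .registration import RegionMask, SurfaceMesh, VolumeImage

__all__ = [
    "ErrorModel",
    "SyntheticPhantom",
    "SyntheticCase",
    "generate_phantom",
    "render_structures",
    "segment_volume_pair",
    "simulate_surgery",
    "generate_cohort",
    "simulate_observer_sessions",
]

# Canonical landmark layout (mm): sella at the origin, +x toward the
# patient's right, +y anterior, +z cranial.  Frankfort plane ~ z = -15.
_CANONICAL_LANDMARKS = {
    "sella": (0.0, 0.0, 0.0),
    "nasion": (0.0, 40.0, 2.0),
    "porion_left": (-42.0, -8.0, -15.0),
    "porion_right": (42.0, -8.0, -15.0),
    "orbitale_left": (-28.0, 28.0, -15.0),
    "orbitale_right": (28.0, 28.0, -15.0),
    "mesial_cusp_16": (24.0, 14.0, -50.0),
    "mesial_cusp_26": (-24.0, 14.0, -50.0),
    "upper_incisor": (0.0, 42.0, -48.0),
    "mesial_cusp_46": (23.0, 14.0, -58.0),
    "mesial_cusp_36": (-23.0, 14.0, -58.0),
    "lower_incisor": (0.0, 40.0, -60.0),
    "condor_left": (-45.0, -10.0, -20.0),
    "condor_right": (45.0, -10.0, -20.0),
    "c_point_left": (-44.0, -6.0, -30.0),
    "c_point_right": (44.0, -6.0, -30.0),
    "gonion_left": (-40.0, -5.0, -65.0),
    "gonion_right": (40.0, -5.0, -65.0),
}

#: Landmarks belonging to each movable segment; the rest are cranial.
_SEGMENT_LANDMARKS = {
    "maxilla": ("mesial_cusp_16", "upper_incisor", "mesial_cusp_26"),
    "mandible_distal": ("mesial_cusp_46", "lower_incisor", "mesial_cusp_36"),
    "proximal_left": ("condor_left", "c_point_left", "gonion_left"),
    "proximal_right": ("condor_right", "c_point_right", "gonion_right"),
}


@dataclass(frozen=True)
class ErrorModel:
    """Execution-error and landmark-noise magnitudes.

    Translations are (AP, LR, UD) in mm, rotations (pitch, roll, yaw) in
    degrees, both in the phantom's anatomical frame; rotations act about the
    segment centroid.  The defaults emulate the dispersion reported for
    wafer-transferred bimaxillary surgery (AP absolute mean ~1.4 mm with a
    posterior bias, pitch absolute mean ~2.7 deg).
    """

    translation_mean: tuple[float, float, float] = (-0.5, 0.0, 0.0)
    translation_sd: tuple[float, float, float] = (1.5, 0.6, 1.8)
    rotation_mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_sd: tuple[float, float, float] = (3.0, 1.2, 1.2)
    landmark_noise_sd: float = 0.1

    def __post_init__(self):
        for nm in ("translation_sd", "rotation_sd"):
            if any(v < 0 for v in getattr(self, nm)):
                raise ValueError(f"{nm} must be non-negative")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be non-negative")

    def zero_noise(self) -> "ErrorModel":
        return replace(self, landmark_noise_sd=0.0)


@dataclass(frozen=True)
class _BlobCluster:
    centers: np.ndarray      # (n, 3) mm
    radii: np.ndarray        # (n,) mm
    intensities: np.ndarray  # (n,)

    def transformed(self, t: RigidTransform) -> "_BlobCluster":
        return _BlobCluster(apply(t, self.centers), self.radii, self.intensities)


@dataclass(frozen=True)
class SyntheticPhantom:
    """A seeded phantom skull: landmarks, per-segment meshes, a cranial-base
    subvolume with its registration mask, and the analytic blob model."""

    seed: int
    landmarks: CephalometricLandmarkSet
    meshes: dict[str, SurfaceMesh]
    volume: VolumeImage
    cranial_mask: RegionMask
    structures: dict[str, _BlobCluster]
    frame: AnatomicalFrame = field(repr=False, default=None)


def _arch_points(a: np.ndarray, apex: np.ndarray, b: np.ndarray,
                 n: int) -> np.ndarray:
    """Points along a quadratic Bezier dental arch from molar to molar."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    ctrl = 2.0 * apex - 0.5 * (a + b)  # Bezier control so the curve hits apex
    return ((1 - t) ** 2) * a + 2 * t * (1 - t) * ctrl + (t ** 2) * b


def _blobby_mesh(centers: np.ndarray, radii: np.ndarray) -> SurfaceMesh:
    import trimesh

    parts = [trimesh.creation.icosphere(subdivisions=2, radius=float(r))
             .apply_translation(c) for c, r in zip(centers, radii)]
    m = trimesh.util.concatenate(parts)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


def generate_phantom(seed: int = 0, spacing: float = 0.4,
                     jitter_sd: float = 0.4) -> SyntheticPhantom:
    """Generate a deterministic phantom skull.

    ``jitter_sd`` (mm) perturbs the canonical landmark layout so phantoms are
    bilaterally symmetric only within noise, as real anatomy is.  The volume
    is a small field of view around the cranial base at ``spacing`` mm
    (64 voxels per axis at the 0.4 mm default), with ``cranial_mask`` marking
    the surgically unaffected blob structure inside it.
    """
    rng = np.random.default_rng(seed)
    landmarks = CephalometricLandmarkSet({
        name: np.asarray(pos) + rng.normal(0.0, jitter_sd, 3)
        for name, pos in _CANONICAL_LANDMARKS.items()
    })

    structures: dict[str, _BlobCluster] = {}

    # cranial base: irregular blob scatter around/behind sella and forehead
    n_cranial = 40
    c_centers = np.array([0.0, 8.0, -8.0]) + rng.normal(0, 1, (n_cranial, 3)) \
        * np.array([7.0, 7.0, 5.0])
    structures["cranial_base"] = _BlobCluster(
        c_centers, rng.uniform(1.5, 3.0, n_cranial),
        rng.uniform(0.5, 1.0, n_cranial))

    for seg, upper in (("maxilla", True), ("mandible_distal", False)):
        names = _SEGMENT_LANDMARKS[seg]
        molar_r = landmarks[names[0]]
        incisor = landmarks[names[1]]
        molar_l = landmarks[names[2]]
        teeth = _arch_points(molar_r, incisor, molar_l, 10)
        structures[seg] = _BlobCluster(
            teeth, rng.uniform(2.0, 3.0, len(teeth)),
            rng.uniform(0.6, 1.0, len(teeth)))

    for seg in PROXIMAL_SEGMENTS:
        names = _SEGMENT_LANDMARKS[seg]
        tri = np.vstack([landmarks[n] for n in names])
        mids = np.vstack([tri, tri.mean(axis=0),
                          0.5 * (tri[0] + tri[2]), 0.5 * (tri[1] + tri[2])])
        structures[seg] = _BlobCluster(
            mids, rng.uniform(2.0, 4.0, len(mids)),
            rng.uniform(0.6, 1.0, len(mids)))

    meshes = {}
    for seg in SEGMENT_IDS:
        cl = structures[seg]
        # spheres scaled down a little so mesh parts rarely interpenetrate
        meshes[seg] = _blobby_mesh(cl.centers, 0.8 * cl.radii)

    half = 32 * spacing  # 64 voxels per axis
    lo = np.array([0.0, 8.0, -8.0]) - half
    hi = np.array([0.0, 8.0, -8.0]) + half
    volume = render_structures({"cranial_base": structures["cranial_base"]},
                               lo, hi, spacing)
    mask = RegionMask(_occupancy(structures["cranial_base"], volume))

    return SyntheticPhantom(seed=seed, landmarks=landmarks, meshes=meshes,
                            volume=volume, cranial_mask=mask,
                            structures=structures,
                            frame=build_frame(landmarks))


def _grid_world(lo: np.ndarray, hi: np.ndarray, spacing: float):
    nx, ny, nz = (np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 8))
    xs = lo[0] + spacing * np.arange(nx)
    ys = lo[1] + spacing * np.arange(ny)
    zs = lo[2] + spacing * np.arange(nz)
    return xs, ys, zs


def render_structures(structures: dict[str, _BlobCluster],
                      lo, hi, spacing: float,
                      poses: dict[str, RigidTransform] | None = None,
                      ) -> VolumeImage:
    """Render blob clusters onto a voxel grid covering [lo, hi] (mm).

    ``poses`` optionally moves each cluster rigidly before rendering; motion
    is applied to the blob centres analytically, so there is no resampling
    error.  Array index order is [z, y, x]; origin is ``lo``.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    xs, ys, zs = _grid_world(lo, hi, spacing)
    vol = np.zeros((len(zs), len(ys), len(xs)), dtype=np.float32)
    for name, cl in structures.items():
        if poses and name in poses:
            cl = cl.transformed(poses[name])
        for c, r, a in zip(cl.centers, cl.radii, cl.intensities):
            dx2 = (xs - c[0]) ** 2
            dy2 = (ys - c[1]) ** 2
            dz2 = (zs - c[2]) ** 2
            d2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
            vol += (a * np.exp(-0.5 * d2 / r ** 2)).astype(np.float32)
    return VolumeImage(vol, spacing, lo)


def _occupancy(cl: _BlobCluster, volume: VolumeImage,
               threshold: float = 0.05) -> np.ndarray:
    xs = volume.origin[0] + volume.spacing * np.arange(volume.shape[2])
    ys = volume.origin[1] + volume.spacing * np.arange(volume.shape[1])
    zs = volume.origin[2] + volume.spacing * np.arange(volume.shape[0])
    occ = np.zeros(volume.shape, dtype=bool)
    for c, r, a in zip(cl.centers, cl.radii, cl.intensities):
        d2 = ((zs - c[2]) ** 2)[:, None, None] \
            + ((ys - c[1]) ** 2)[None, :, None] \
            + ((xs - c[0]) ** 2)[None, None, :]
        occ |= a * np.exp(-0.5 * d2 / r ** 2) > threshold
    return occ


def segment_volume_pair(phantom: SyntheticPhantom, segment: str,
                        motion: RigidTransform, spacing: float = 0.8,
                        margin: float = 6.0,
                        ) -> tuple[VolumeImage, VolumeImage]:
    """Render a segment's blob structure before and after a rigid motion on a
    shared grid covering both poses (plus ``margin`` mm)."""
    cl = phantom.structures[segment]
    moved = cl.transformed(motion)
    all_centers = np.vstack([cl.centers, moved.centers])
    pad = margin + float(cl.radii.max()) * 2.0
    lo = all_centers.min(axis=0) - pad
    hi = all_centers.max(axis=0) + pad
    pre = render_structures({segment: cl}, lo, hi, spacing)
    post = render_structures({segment: moved}, lo, hi, spacing)
    return pre, post


@dataclass(frozen=True)
class SyntheticCase:
    """A simulated patient plus its ground truth.

    ``case`` is the observable input (with identification noise applied);
    the ``true_*`` fields hold noise-free landmark positions per state, and
    the ground-truth transforms are the exact per-segment motions: ``plan``
    (preop->planned), ``execution_error`` (planned->postop) and
    ``displacement`` (their composition, preop->postop).
    """

    case_id: str
    seed: int
    error_model: ErrorModel
    case: PatientCase
    plan: dict[str, RigidTransform]
    execution_error: dict[str, RigidTransform]
    displacement: dict[str, RigidTransform]
    true_landmarks_preop: CephalometricLandmarkSet
    true_triangles_postop: dict[str, SegmentTriangle]
    phantom: SyntheticPhantom = field(repr=False, default=None)


def _error_transform(model: ErrorModel, rng: np.random.Generator,
                     frame: AnatomicalFrame, centroid: np.ndarray,
                     ) -> RigidTransform:
    d_ap, d_lr, d_ud = (np.asarray(model.translation_mean)
                        + rng.normal(0, 1, 3) * np.asarray(model.translation_sd))
    pitch, roll, yaw = (np.asarray(model.rotation_mean)
                        + rng.normal(0, 1, 3) * np.asarray(model.rotation_sd))
    move = recompose(MovementReport("maxilla", d_ap=d_ap, d_lr=d_lr, d_ud=d_ud,
                                    pitch=pitch, roll=roll, yaw=yaw), frame)
    # rotate about the segment centroid, then translate
    rot = move.rotation
    return RigidTransform(rot, centroid - rot @ centroid + move.translation)


def _noisy(points: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.array(points, dtype=float)
    return points + rng.normal(0.0, sd, np.shape(points))


def simulate_surgery(phantom: SyntheticPhantom,
                     plan: dict[str, RigidTransform],
                     error_model: ErrorModel | None = None,
                     seed: int = 0,
                     case_id: str = "synthetic",
                     mode: str = "direct",
                     volume_spacing: float = 0.8) -> SyntheticCase:
    """Apply a virtual plan plus a random execution error to a phantom.

    ``plan`` maps planned segments (maxilla, distal mandible) to their
    preop->planned motions; proximal segments are never planned and receive
    an execution-error motion only.  Rotational errors act about the planned
    segment centroid.  ``mode`` selects the observable data route: ``direct``
    attaches postoperative landmark triangles, ``registration`` attaches
    per-segment volume pairs (planned segments) and mesh pairs (proximal
    segments) rendered at ``volume_spacing`` mm.
    """
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    frame = phantom.frame

    plans: dict[str, RigidTransform] = {}
    errors: dict[str, RigidTransform] = {}
    displacements: dict[str, RigidTransform] = {}
    true_post_triangles: dict[str, SegmentTriangle] = {}

    for segment in SEGMENT_IDS:
        seg_plan = plan.get(segment, RigidTransform.identity())
        tri_pre = triangle_from_landmarks(phantom.landmarks, segment)
        planned_centroid = apply(seg_plan, tri_pre.centroid)
        err = _error_transform(error_model, rng, frame, planned_centroid)
        disp = compose(err, seg_plan)
        plans[segment] = seg_plan
        errors[segment] = err
        displacements[segment] = disp
        true_post_triangles[segment] = SegmentTriangle(
            segment, apply(disp, tri_pre.vertices), "postop")

    sd = error_model.landmark_noise_sd
    noisy_preop = CephalometricLandmarkSet(
        {k: _noisy(v, sd, rng) for k, v in phantom.landmarks.items()})

    triangles_postop = None
    volumes = None
    meshes = None
    if mode == "direct":
        triangles_postop = {
            seg: SegmentTriangle(seg, _noisy(tri.vertices, sd, rng), "postop")
            for seg, tri in true_post_triangles.items()
        }
    elif mode == "registration":
        volumes = {seg: segment_volume_pair(phantom, seg, displacements[seg],
                                            spacing=volume_spacing)
                   for seg in PLANNED_SEGMENTS}
        meshes = {seg: (phantom.meshes[seg],
                        phantom.meshes[seg].transformed(displacements[seg]))
                  for seg in PROXIMAL_SEGMENTS}
    else:
        raise ValueError(f"mode must be direct|registration, got {mode!r}")

    case = PatientCase(
        case_id=case_id,
        landmarks_preop=noisy_preop,
        planning_transforms={s: plans[s] for s in PLANNED_SEGMENTS},
        triangles_postop=triangles_postop,
        volumes=volumes,
        meshes=meshes,
    )
    return SyntheticCase(
        case_id=case_id, seed=seed, error_model=error_model, case=case,
        plan=plans, execution_error=errors, displacement=displacements,
        true_landmarks_preop=phantom.landmarks,
        true_triangles_postop=true_post_triangles,
        phantom=phantom,
    )


def _random_plan(rng: np.random.Generator, frame: AnatomicalFrame,
                 translation_sd: float, rotation_sd: float,
                 ) -> RigidTransform:
    d_ap, d_lr, d_ud = rng.normal([4.0, 0.0, -2.0],
                                  [translation_sd, translation_sd / 2,
                                   translation_sd])
    pitch, roll, yaw = rng.normal(0.0, rotation_sd, 3)
    return recompose(MovementReport("maxilla", d_ap=d_ap, d_lr=d_lr,
                                    d_ud=d_ud, pitch=pitch, roll=roll,
                                    yaw=yaw), frame)


def generate_cohort(n_cases: int = 10, seed: int = 0,
                    error_model: ErrorModel | None = None,
                    plan_translation_sd: float = 2.0,
                    plan_rotation_sd: float = 2.0,
                    mode: str = "direct") -> list[SyntheticCase]:
    """A cohort of independent synthetic patients.

    Each patient gets a fresh phantom, a random advancement-style plan
    (between-patient translation SD ``plan_translation_sd`` mm around a
    typical 4 mm advancement with 2 mm impaction) and an execution error from
    ``error_model``.  Per-case seeds derive deterministically from ``seed``.
    """
    error_model = error_model or ErrorModel()
    root = np.random.SeedSequence(seed)
    cases = []
    for i, child in enumerate(root.spawn(n_cases)):
        sub = int(child.generate_state(1)[0] % (2 ** 31))
        phantom = generate_phantom(seed=sub)
        rng = np.random.default_rng(sub + 1)
        plan = {seg: _random_plan(rng, phantom.frame, plan_translation_sd,
                                  plan_rotation_sd)
                for seg in PLANNED_SEGMENTS}
        cases.append(simulate_surgery(
            phantom, plan, error_model, seed=sub + 2,
            case_id=f"case{i + 1:02d}", mode=mode))
    return cases


def _session_components(result) -> dict[str, float]:
    out = {}
    for seg, rep in result.displacement.items():
        for comp in MovementReport.COMPONENTS:
            out[f"{seg}:{comp}"] = getattr(rep, comp)
    for side, rep in result.proximal.items():
        out[f"proximal_{side}:autorotation"] = rep.autorotation
        out[f"proximal_{side}:flare"] = rep.flare
    return out


def simulate_observer_sessions(cases: list[SyntheticCase],
                               landmark_noise_sd: float = 0.1,
                               n_sessions: int = 3,
                               seed: int = 0):
    """Emulate repeated observer analyses of a synthetic cohort.

    Each session re-draws landmark identification noise around the true
    landmark positions of every case and reruns the direct-mode analysis;
    the per-segment displacement components are assembled into a
    :class:`~orthognathics.observer_stats.MeasurementGrid`.  Session labels
    follow the three-session validation design when ``n_sessions`` is 3.
    """
    from .observer_stats import SESSION_LABELS, MeasurementGrid

    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    labels = list(SESSION_LABELS) if n_sessions == 3 else \
        [f"session{i + 1}" for i in range(n_sessions)]
    rng = np.random.default_rng(seed)
    records = []
    for sc in cases:
        for label in labels:
            lm = CephalometricLandmarkSet(
                {k: _noisy(v, landmark_noise_sd, rng)
                 for k, v in sc.true_landmarks_preop.items()})
            tris = {seg: SegmentTriangle(
                        seg, _noisy(tri.vertices, landmark_noise_sd, rng),
                        "postop")
                    for seg, tri in sc.true_triangles_postop.items()}
            session_case = PatientCase(
                case_id=sc.case_id,
                landmarks_preop=lm,
                planning_transforms=sc.case.planning_transforms,
                triangles_postop=tris,
            )
            result = compute_case(session_case)
            for comp, value in _session_components(result).items():
                records.append((sc.case_id, label, comp, value))
    return MeasurementGrid.from_records(records)
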