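"""Anatomical coordinate frame and clinical decomposition of rigid motions.

The frame emulates the natural head position: the up/down axis is the normal
of the Frankfort plane (through both porions and the orbitale points), the
left/right axis runs from the left to the right porion, and anterior/posterior
completes the right-handed set toward nasion.  Segment motions expressed in
this frame are factored into the six clinically reported quantities:
anterior/posterior, left/right and up/down translations plus pitch, roll and
yaw.

Sign conventions
----------------
* translation: anterior positive, toward the patient's right positive,
  cranial positive;
* pitch: positive = anti-clockwise seen from the patient's right
  (right-hand rotation about the left->right axis; incisal edges move
  cranially/anteriorly);
* roll: positive = anti-clockwise seen from anterior (right-hand rotation
  about the anterior axis);
* yaw: positive = anti-clockwise seen from above (right-hand rotation about
  the cranial axis).

The Euler factorisation is intrinsic yaw -> roll -> pitch (about the up/down,
then anterior/posterior, then left/right axis).  At the few-degree rotations
this tool measures, the choice of order is far below observer variation (the
order effect scales with products of the angles); the singular configuration
of this sequence is |roll| = 90 deg and is reported as an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, _as_point, apply

__all__ = [
    "REFERENCE_LANDMARKS",
    "SEGMENT_LANDMARKS",
    "LANDMARK_VOCABULARY",
    "BILATERAL_LANDMARKS",
    "MissingLandmarkError",
    "GimbalLockError",
    "CephalometricLandmarkSet",
    "AnatomicalFrame",
    "MovementReport",
    "ProximalReport",
    "build_frame",
    "decompose",
    "recompose",
    "proximal_measures",
]

#: Cranial reference landmarks used to construct the head frame.
REFERENCE_LANDMARKS = (
    "nasion", "sella", "porion_left", "porion_right",
    "orbitale_left", "orbitale_right",
)

#: Landmarks placed on each osteotomized segment (triangle vertices).
SEGMENT_LANDMARKS = (
    "upper_incisor", "mesial_cusp_16", "mesial_cusp_26",
    "lower_incisor", "mesial_cusp_36", "mesial_cusp_46",
    "condor_left", "condor_right", "c_point_left", "c_point_right",
    "gonion_left", "gonion_right",
)

LANDMARK_VOCABULARY = REFERENCE_LANDMARKS + SEGMENT_LANDMARKS

#: Base names that require a side tag.
BILATERAL_LANDMARKS = ("porion", "orbitale", "condor", "c_point", "gonion")

_FRAME_REQUIRED = ("nasion", "sella", "porion_left", "porion_right")


class MissingLandmarkError(KeyError):
    """A landmark required for the requested construction is absent."""


class GimbalLockError(ValueError):
    """Euler factorisation is singular (|roll| within tolerance of 90 deg)."""


class CephalometricLandmarkSet:
    """Mapping of canonical landmark names to 3D positions (mm).

    Names are canonical lowercase with side suffixes for bilateral landmarks
    (``porion_left`` ...); :mod:`orthognathics.io` handles synonyms and
    free-form input.
    """

    def __init__(self, landmarks: dict[str, np.ndarray]):
        self._points: dict[str, np.ndarray] = {}
        for name, p in landmarks.items():
            key = str(name).strip().lower()
            if key not in LANDMARK_VOCABULARY:
                raise ValueError(
                    f"unknown landmark {name!r}; known landmarks: "
                    + ", ".join(LANDMARK_VOCABULARY)
                )
            self._points[key] = _as_point(p, key)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[name]
        except KeyError:
            raise MissingLandmarkError(
                f"landmark {name!r} is missing from this set"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def __len__(self) -> int:
        return len(self._points)

    def __iter__(self):
        return iter(self._points)

    def items(self):
        return self._points.items()

    def get(self, name: str, default=None):
        return self._points.get(name, default)

    def transformed(self, t: RigidTransform) -> "CephalometricLandmarkSet":
        return CephalometricLandmarkSet(
            {k: apply(t, v) for k, v in self._points.items()}
        )

    def subset(self, names) -> "CephalometricLandmarkSet":
        return CephalometricLandmarkSet({n: self[n] for n in names})


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical axes with origin at sella.

    ``axis_lr`` points toward the patient's right, ``axis_ap`` anteriorly and
    ``axis_ud`` cranially; ``axis_lr x axis_ap = axis_ud``.
    """

    origin: np.ndarray
    axis_lr: np.ndarray
    axis_ap: np.ndarray
    axis_ud: np.ndarray

    def __post_init__(self):
        o = _as_point(self.origin, "origin")
        axes = []
        for nm in ("axis_lr", "axis_ap", "axis_ud"):
            a = _as_point(getattr(self, nm), nm)
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                raise ValueError(f"{nm} is not unit length")
            axes.append(a)
        lr, ap, ud = axes
        if max(abs(lr @ ap), abs(lr @ ud), abs(ap @ ud)) > 1e-9:
            raise ValueError("frame axes are not mutually orthogonal")
        if np.linalg.norm(np.cross(lr, ap) - ud) > 1e-9:
            raise ValueError("frame is not right-handed (lr x ap != ud)")
        for nm, a in zip(("origin", "axis_lr", "axis_ap", "axis_ud"),
                         (o, lr, ap, ud)):
            a.setflags(write=False)
            object.__setattr__(self, nm, a)

    @property
    def basis(self) -> np.ndarray:
        """World-from-frame rotation; columns are (lr, ap, ud)."""
        return np.column_stack([self.axis_lr, self.axis_ap, self.axis_ud])


@dataclass(frozen=True)
class MovementReport:
    """The six clinically reported quantities for one segment.

    Translations in mm (anterior/right/cranial positive), rotations in
    degrees with the sign conventions in the module docstring.
    """

    segment_id: str
    d_ap: float
    d_lr: float
    d_ud: float
    pitch: float
    roll: float
    yaw: float

    def __post_init__(self):
        for nm in ("pitch", "roll", "yaw"):
            v = getattr(self, nm)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{nm} = {v} outside (-180, 180]")

    def as_dict(self) -> dict[str, float]:
        return {
            "d_ap": self.d_ap, "d_lr": self.d_lr, "d_ud": self.d_ud,
            "pitch": self.pitch, "roll": self.roll, "yaw": self.yaw,
        }

    #: Canonical component order used in all tabular output.
    COMPONENTS = ("d_ap", "d_lr", "d_ud", "pitch", "roll", "yaw")


@dataclass(frozen=True)
class ProximalReport:
    """Rotational measures of a condyle-bearing proximal segment.

    ``autorotation`` is the pitch-like component (rotation about the
    left/right axis), ``flare`` the yaw-like component (rotation about the
    up/down axis); both follow the sign conventions of
    :class:`MovementReport`.
    """

    side: str
    autorotation: float
    flare: float

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for nm in ("autorotation", "flare"):
            v = getattr(self, nm)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{nm} = {v} outside (-180, 180]")

    COMPONENTS = ("autorotation", "flare")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError(f"degenerate frame: {what} has (near-)zero length")
    return v / n


def build_frame(landmarks: CephalometricLandmarkSet) -> AnatomicalFrame:
    """Construct the anatomical frame from cranial reference landmarks.

    Requires nasion, sella, both porions and at least one orbitale.  The
    Frankfort plane is fitted by least squares through the porions and all
    available orbitale points; its cranially oriented unit normal is the
    up/down axis.  The left-to-right porion direction, projected into the
    plane, gives the left/right axis, and the anterior axis completes the
    right-handed set (checked to point toward nasion).  Origin is sella.
    """
    for name in _FRAME_REQUIRED:
        if name not in landmarks:
            raise MissingLandmarkError(
                f"cannot build anatomical frame: landmark {name!r} is missing"
            )
    orbitale = [landmarks[n] for n in ("orbitale_left", "orbitale_right")
                if n in landmarks]
    if not orbitale:
        raise MissingLandmarkError(
            "cannot build anatomical frame: need at least one orbitale landmark"
        )
    por_l = landmarks["porion_left"]
    por_r = landmarks["porion_right"]
    nasion = landmarks["nasion"]
    sella = landmarks["sella"]

    if np.linalg.norm(por_r - por_l) < 1e-9:
        raise ValueError("degenerate frame: porions coincide")

    pts = np.vstack([por_l, por_r] + orbitale)
    centroid = pts.mean(axis=0)
    # plane normal = singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[-1]
    if np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) < 1e-9:
        raise ValueError("degenerate frame: Frankfort plane points are collinear")
    if normal @ (nasion - centroid) < 0:  # orient cranially (nasion side)
        normal = -normal
    ud = _unit(normal, "Frankfort normal")

    lr_raw = por_r - por_l
    lr = _unit(lr_raw - (lr_raw @ ud) * ud, "porion axis projected to plane")
    ap = np.cross(ud, lr)  # unit by construction; lr x ap = ud
    if ap @ (nasion - centroid) <= 0:
        raise ValueError(
            "inconsistent landmarks: anterior axis does not point toward nasion "
            "(porion sides likely swapped)"
        )
    return AnatomicalFrame(origin=sella, axis_lr=lr, axis_ap=ap, axis_ud=ud)


_GIMBAL_TOL_DEG = 1e-6


def _frame_rotation(t: RigidTransform, frame: AnatomicalFrame) -> np.ndarray:
    b = frame.basis
    return b.T @ t.rotation @ b


def _euler_deg(r_frame: np.ndarray) -> tuple[float, float, float]:
    """(yaw, roll, pitch) of a frame-coordinate rotation, intrinsic ZYX."""
    # middle angle of the sequence: roll = asin(-R[2,0]); singular at +/-90
    sin_roll = float(np.clip(-r_frame[2, 0], -1.0, 1.0))
    roll = np.degrees(np.arcsin(sin_roll))
    if 90.0 - abs(roll) < _GIMBAL_TOL_DEG:
        raise GimbalLockError(
            f"Euler factorisation singular: |roll| = {abs(roll):.9f} deg; "
            "yaw and pitch are not separable in this configuration"
        )
    yaw, roll, pitch = Rotation.from_matrix(r_frame).as_euler("ZYX", degrees=True)
    return float(yaw), float(roll), float(pitch)


def decompose(t: RigidTransform, frame: AnatomicalFrame,
              segment_id: str = "maxilla",
              about: np.ndarray | None = None) -> MovementReport:
    """Factor a rigid motion into the six clinically reported quantities.

    Parameters
    ----------
    t:
        The segment motion (e.g. planned -> postoperative).
    frame:
        Anatomical frame in which to express the motion.
    segment_id:
        Recorded on the report.
    about:
        Optional reference point (mm, world coordinates).  When given, the
        reported translation is the displacement ``t(about) - about`` of that
        point — the pipeline passes the segment-triangle centroid, so the
        translation reads as "how far the segment moved" independent of where
        the rotation axis sits.  When omitted, the raw translation vector of
        ``t`` is reported.  The rotation part is unaffected either way.
    """
    if about is None:
        d_world = t.translation
    else:
        about = _as_point(about, "about")
        d_world = apply(t, about) - about
    yaw, roll, pitch = _euler_deg(_frame_rotation(t, frame))
    return MovementReport(
        segment_id=segment_id,
        d_ap=float(d_world @ frame.axis_ap),
        d_lr=float(d_world @ frame.axis_lr),
        d_ud=float(d_world @ frame.axis_ud),
        pitch=pitch, roll=roll, yaw=yaw,
    )


def recompose(report: MovementReport, frame: AnatomicalFrame) -> RigidTransform:
    """Inverse of :func:`decompose` (with ``about=None``) under the fixed
    intrinsic yaw->roll->pitch sequence."""
    r_frame = Rotation.from_euler(
        "ZYX", [report.yaw, report.roll, report.pitch], degrees=True
    ).as_matrix()
    b = frame.basis
    rot = b @ r_frame @ b.T
    trans = (report.d_lr * frame.axis_lr
             + report.d_ap * frame.axis_ap
             + report.d_ud * frame.axis_ud)
    return RigidTransform(rot, trans)


def proximal_measures(t: RigidTransform, frame: AnatomicalFrame,
                      side: str) -> ProximalReport:
    """Autorotation and flare of a proximal segment's motion.

    Autorotation is the rotation about the left/right axis (the segment
    swinging about the condylar hinge axis); flare the rotation about the
    up/down axis (the gonial region swinging laterally).  Same Euler sequence
    and signs as :func:`decompose`.
    """
    yaw, _roll, pitch = _euler_deg(_frame_rotation(t, frame))
    return ProximalReport(side=side, autorotation=pitch, flare=yaw)
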