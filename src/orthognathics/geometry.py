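"""Rigid-body geometry: points, segment triangles and proper rigid transforms.

All coordinates are millimetres.  A :class:`RigidTransform` is a proper rigid
motion (rotation + translation, no scaling, no reflection); the least-squares
fit between two corresponding landmark triangles is solved in closed form by
the Kabsch/SVD construction in :func:`procrustes_rigid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEGMENT_IDS",
    "STATE_LABELS",
    "SEGMENT_VERTEX_ORDER",
    "DegenerateTriangleError",
    "Point3",
    "SegmentTriangle",
    "RigidTransform",
    "FitResult",
    "procrustes_rigid",
    "compose",
    "invert",
    "apply",
]

#: Jaw segments produced by a Le Fort I osteotomy + bilateral sagittal split.
SEGMENT_IDS = ("maxilla", "mandible_distal", "proximal_left", "proximal_right")

STATE_LABELS = ("preop", "planned", "postop")

#: Fixed vertex order per segment.  Procrustes correspondence relies on this
#: convention; readers and the synthetic generator all emit it.
SEGMENT_VERTEX_ORDER = {
    "maxilla": ("mesial_cusp_16", "upper_incisor", "mesial_cusp_26"),
    "mandible_distal": ("mesial_cusp_46", "lower_incisor", "mesial_cusp_36"),
    "proximal_left": ("condor", "c_point", "gonion"),
    "proximal_right": ("condor", "c_point", "gonion"),
}

#: Triangles with area at or below this (mm^2) are rejected as degenerate.
DEGENERATE_AREA_MM2 = 1e-6


class DegenerateTriangleError(ValueError):
    """Raised when a landmark triple is (near-)collinear and unusable."""


def _as_point(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite components: {a}")
    return a


def Point3(x: float, y: float, z: float) -> np.ndarray:
    """A 3D point in millimetres, represented as a float ndarray of shape (3,)."""
    return _as_point((x, y, z))


def triangle_area(vertices: np.ndarray) -> float:
    """Area (mm^2) of the triangle spanned by three stacked vertices."""
    v = np.asarray(vertices, dtype=float)
    return 0.5 * float(np.linalg.norm(np.cross(v[1] - v[0], v[2] - v[0])))


@dataclass(frozen=True)
class SegmentTriangle:
    """Ordered landmark triple encoding a jaw segment's position and orientation.

    Parameters
    ----------
    segment_id:
        One of :data:`SEGMENT_IDS`.
    vertices:
        (3, 3) array, one landmark per row, ordered by the fixed per-segment
        convention in :data:`SEGMENT_VERTEX_ORDER`.
    state_label:
        ``preop``, ``planned`` or ``postop``.
    """

    segment_id: str
    vertices: np.ndarray
    state_label: str = "preop"

    def __post_init__(self):
        if self.segment_id not in SEGMENT_IDS:
            raise ValueError(
                f"unknown segment_id {self.segment_id!r}; expected one of {SEGMENT_IDS}"
            )
        if self.state_label not in STATE_LABELS:
            raise ValueError(
                f"unknown state_label {self.state_label!r}; expected one of {STATE_LABELS}"
            )
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"vertices must be (3, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("triangle vertices must be finite")
        if triangle_area(v) <= DEGENERATE_AREA_MM2:
            raise DegenerateTriangleError(
                f"landmarks of segment {self.segment_id!r} are collinear "
                f"(area {triangle_area(v):.3g} mm^2); unusable configuration"
            )
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def area(self) -> float:
        return triangle_area(self.vertices)

    def with_state(self, state_label: str) -> "SegmentTriangle":
        return SegmentTriangle(self.segment_id, self.vertices.copy(), state_label)


_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``.

    The rotation must be orthonormal with determinant +1 (no scaling, no
    reflection), enforced at construction to within 1e-9.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = _as_point(self.translation, "translation")
        if r.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {r.shape}")
        if not np.all(np.isfinite(r)):
            raise ValueError("rotation must be finite")
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL * 10):
            raise ValueError("rotation is not orthonormal")
        det = float(np.linalg.det(r))
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1 (improper transform)")
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    # convenience aliases for the module functions
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def __call__(self, p):
        return apply(self, p)


@dataclass(frozen=True)
class FitResult:
    """A fitted rigid transform plus its root-mean-square vertex residual (mm)."""

    transform: RigidTransform
    rmsd: float

    def __post_init__(self):
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform mapping ``x`` to ``a(b(x))``."""
    return RigidTransform(a.rotation @ b.rotation,
                          a.rotation @ b.translation + a.translation)


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse motion: ``compose(t, invert(t))`` is the identity."""
    rt = t.rotation.T
    return RigidTransform(rt, -rt @ t.translation)


def apply(t: RigidTransform, p) -> np.ndarray:
    """Apply ``t`` to a point (3,) or a stack of points (n, 3)."""
    a = np.asarray(p, dtype=float)
    if a.ndim == 1:
        return t.rotation @ a + t.translation
    return a @ t.rotation.T + t.translation


def transform_triangle(t: RigidTransform, tri: SegmentTriangle,
                       state_label: str | None = None) -> SegmentTriangle:
    """Apply a rigid transform to every vertex of a segment triangle."""
    return SegmentTriangle(tri.segment_id, apply(t, tri.vertices),
                           state_label or tri.state_label)


def procrustes_rigid(source: SegmentTriangle, target: SegmentTriangle) -> FitResult:
    """Least-squares proper rigid fit taking ``source`` vertices onto ``target``.

    Solves ``min sum_i ||R s_i + t - g_i||^2`` over rotations with det +1 via
    the Kabsch/SVD construction: with centred vertex matrices S and G and
    cross-covariance ``H = S^T G``, ``H = U diag(s) V^T`` gives
    ``R = V diag(1, 1, det(V U^T)) U^T``; the sign correction on the smallest
    singular direction forbids reflections, so a mirrored target yields the
    best *proper* rotation and a non-zero residual rather than a flip.

    Returns
    -------
    FitResult
        The fitted transform and the RMS vertex residual after applying it.

    Raises
    ------
    ValueError
        If the two triangles belong to different segments.
    DegenerateTriangleError
        Never from here directly; degenerate triangles cannot be constructed.
    """
    if source.segment_id != target.segment_id:
        raise ValueError(
            f"segment mismatch: {source.segment_id!r} vs {target.segment_id!r}"
        )
    s = source.vertices
    g = target.vertices
    cs = s.mean(axis=0)
    cg = g.mean(axis=0)
    h = (s - cs).T @ (g - cg)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cg - rot @ cs
    fit = RigidTransform(rot, trans)
    residual = apply(fit, s) - g
    rmsd = float(np.sqrt(np.mean(np.sum(residual ** 2, axis=1))))
    return FitResult(fit, rmsd)
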