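import numpy as np
import pytest

from orthognathics.frames import (CephalometricLandmarkSet, GimbalLockError,
                                  MissingLandmarkError, MovementReport,
                                  build_frame, decompose, proximal_measures,
                                  recompose)
from orthognathics.geometry import RigidTransform, apply

from _oracles import axis_angle_matrix, random_proper_rotation

# canonical configuration: porions span the x-axis, Frankfort plane = z = 0,
# nasion anterior on +y and slightly cranial
CANONICAL = {
    "nasion": (0.0, 40.0, 5.0),
    "sella": (0.0, 0.0, 8.0),
    "porion_left": (-42.0, -8.0, 0.0),
    "porion_right": (42.0, -8.0, 0.0),
    "orbitale_left": (-28.0, 28.0, 0.0),
    "orbitale_right": (28.0, 28.0, 0.0),
}


def canonical_landmarks(transform: RigidTransform | None = None):
    pts = {k: np.asarray(v, dtype=float) for k, v in CANONICAL.items()}
    if transform is not None:
        pts = {k: apply(transform, v) for k, v in pts.items()}
    return CephalometricLandmarkSet(pts)


class TestBuildFrame:
    def test_canonical_configuration_gives_world_axes(self):
        fr = build_frame(canonical_landmarks())
        np.testing.assert_allclose(fr.axis_lr, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.axis_ap, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fr.axis_ud, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(fr.origin, CANONICAL["sella"], atol=1e-12)

    def test_rigidly_rotated_configuration_rotates_axes(self, rng):
        for _ in range(25):
            rot = random_proper_rotation(rng)
            t = RigidTransform(rot, rng.uniform(-20, 20, 3))
            fr = build_frame(canonical_landmarks(t))
            np.testing.assert_allclose(fr.axis_lr, rot @ [1, 0, 0], atol=1e-9)
            np.testing.assert_allclose(fr.axis_ap, rot @ [0, 1, 0], atol=1e-9)
            np.testing.assert_allclose(fr.axis_ud, rot @ [0, 0, 1], atol=1e-9)

    def test_translation_moves_origin_not_axes(self):
        t = RigidTransform(np.eye(3), [10.0, 10.0, 10.0])
        fr = build_frame(canonical_landmarks(t))
        np.testing.assert_allclose(fr.axis_lr, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.origin,
                                   np.asarray(CANONICAL["sella"]) + 10,
                                   atol=1e-12)

    def test_axes_orthonormal_right_handed(self, phantom):
        fr = phantom.frame
        b = fr.basis
        np.testing.assert_allclose(b.T @ b, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(np.cross(fr.axis_lr, fr.axis_ap),
                                   fr.axis_ud, atol=1e-9)

    def test_missing_required_landmark_is_named(self):
        pts = {k: v for k, v in CANONICAL.items() if k != "sella"}
        with pytest.raises(MissingLandmarkError, match="sella"):
            build_frame(CephalometricLandmarkSet(pts))

    def test_one_orbitale_suffices(self):
        pts = {k: v for k, v in CANONICAL.items() if k != "orbitale_left"}
        fr = build_frame(CephalometricLandmarkSet(pts))
        assert abs(np.linalg.norm(fr.axis_ud) - 1) < 1e-9

    def test_coincident_porions_rejected(self):
        pts = dict(CANONICAL)
        pts["porion_left"] = pts["porion_right"]
        with pytest.raises(ValueError, match="porions"):
            build_frame(CephalometricLandmarkSet(pts))


class TestDecompose:
    def test_identity_transform_reports_all_zero(self, frame):
        rep = decompose(RigidTransform.identity(), frame)
        assert all(abs(v) < 1e-12 for v in rep.as_dict().values())

    def test_pure_pitch_rotation(self, frame):
        rot = axis_angle_matrix(frame.axis_lr, 5.0)
        rep = decompose(RigidTransform(rot), frame)
        assert rep.pitch == pytest.approx(5.0, abs=1e-9)
        for comp in ("d_ap", "d_lr", "d_ud", "roll", "yaw"):
            assert abs(getattr(rep, comp)) < 1e-9

    def test_pure_roll_and_yaw_signs(self, frame):
        rep = decompose(RigidTransform(axis_angle_matrix(frame.axis_ap, 4.0)),
                        frame)
        assert rep.roll == pytest.approx(4.0, abs=1e-9)
        rep = decompose(RigidTransform(axis_angle_matrix(frame.axis_ud, -2.0)),
                        frame)
        assert rep.yaw == pytest.approx(-2.0, abs=1e-9)

    def test_posterior_translation_is_negative_ap(self, frame):
        t = RigidTransform(np.eye(3), -2.0 * frame.axis_ap)
        rep = decompose(t, frame)
        assert rep.d_ap == pytest.approx(-2.0, abs=1e-9)
        for comp in ("d_lr", "d_ud", "pitch", "roll", "yaw"):
            assert abs(getattr(rep, comp)) < 1e-9

    def test_cranial_translation_is_positive_ud(self, frame):
        rep = decompose(RigidTransform(np.eye(3), 1.5 * frame.axis_ud), frame)
        assert rep.d_ud == pytest.approx(1.5, abs=1e-9)

    def test_translation_independent_of_frame_origin(self, frame):
        from dataclasses import replace

        t = RigidTransform(np.eye(3), [1.0, -2.0, 0.5])
        shifted = replace(frame, origin=frame.origin + [30, -10, 5])
        a = decompose(t, frame)
        b = decompose(t, shifted)
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_round_trip_on_random_reports(self, frame, rng):
        """decompose(recompose(r)) == r to 1e-9 for angles under 45 deg."""
        for _ in range(1000):
            rep = MovementReport(
                "maxilla",
                d_ap=rng.uniform(-5, 5), d_lr=rng.uniform(-5, 5),
                d_ud=rng.uniform(-5, 5),
                pitch=rng.uniform(-45, 45), roll=rng.uniform(-45, 45),
                yaw=rng.uniform(-45, 45))
            back = decompose(recompose(rep, frame), frame)
            for comp, want in rep.as_dict().items():
                assert abs(getattr(back, comp) - want) < 1e-9

    def test_recompose_trivial_cases(self, frame):
        zero = MovementReport("maxilla", 0, 0, 0, 0, 0, 0)
        t = recompose(zero, frame)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        t = recompose(MovementReport("maxilla", 0, 0, 0, pitch=5.0, roll=0,
                                     yaw=0), frame)
        np.testing.assert_allclose(t.rotation,
                                   axis_angle_matrix(frame.axis_lr, 5.0),
                                   atol=1e-12)

    def test_gimbal_lock_raises(self, frame):
        t = RigidTransform(axis_angle_matrix(frame.axis_ap, 90.0))
        with pytest.raises(GimbalLockError):
            decompose(t, frame)

    def test_about_point_reports_that_points_displacement(self, frame):
        c = np.array([5.0, -30.0, -48.0])
        rot = axis_angle_matrix(frame.axis_lr, 3.0)
        t = RigidTransform(rot, c - rot @ c)  # pure rotation about c
        rep = decompose(t, frame, about=c)
        assert abs(rep.d_ap) < 1e-9 and abs(rep.d_ud) < 1e-9
        assert rep.pitch == pytest.approx(3.0, abs=1e-9)


class TestProximalMeasures:
    def test_identity_gives_zero(self, frame):
        rep = proximal_measures(RigidTransform.identity(), frame, "left")
        assert rep.autorotation == pytest.approx(0, abs=1e-12)
        assert rep.flare == pytest.approx(0, abs=1e-12)

    def test_lr_rotation_is_autorotation(self, frame):
        t = RigidTransform(axis_angle_matrix(frame.axis_lr, 3.0))
        rep = proximal_measures(t, frame, "left")
        assert rep.autorotation == pytest.approx(3.0, abs=1e-9)
        assert abs(rep.flare) < 1e-9

    def test_ud_rotation_is_flare(self, frame):
        t = RigidTransform(axis_angle_matrix(frame.axis_ud, 2.0))
        rep = proximal_measures(t, frame, "right")
        assert rep.flare == pytest.approx(2.0, abs=1e-9)
        assert abs(rep.autorotation) < 1e-9
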