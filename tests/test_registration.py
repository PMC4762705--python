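import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from orthognathics.geometry import RigidTransform, compose
from orthognathics.registration import (RegionMask, SurfaceMesh, VolumeImage,
                                        crop_to_mask, register_surfaces_icp,
                                        register_volumes_rigid)
from orthognathics.synthetic import render_structures

from _oracles import axis_angle_matrix


def rotation_error_deg(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.degrees(np.linalg.norm(
        Rotation.from_matrix(a.T @ b).as_rotvec())))


def rerender(phantom, pose: RigidTransform) -> VolumeImage:
    """Cranial-base volume with the blob model moved rigidly — analytic, so
    there is no interpolation error in the ground truth."""
    vol = phantom.volume
    lo = vol.origin
    hi = vol.origin + vol.spacing * (np.array(vol.shape)[::-1] - 1)
    return render_structures({"cranial_base": phantom.structures["cranial_base"]},
                             lo, hi, vol.spacing, poses={"cranial_base": pose})


class TestVolumeRegistration:
    def test_self_registration_is_identity(self, phantom):
        fit = register_volumes_rigid(phantom.volume, phantom.volume)
        # within 0.05 voxel translation / 0.1 degree rotation
        assert np.linalg.norm(fit.transform.translation) < 0.05 * 0.4
        assert rotation_error_deg(fit.transform.rotation, np.eye(3)) < 0.1

    def test_integer_voxel_shift_recovered_within_half_voxel(self, phantom):
        shift = RigidTransform(np.eye(3), [0.8, -0.4, 1.2])  # 2, -1, 3 voxels
        moved = rerender(phantom, shift)
        fit = register_volumes_rigid(phantom.volume, moved)
        err = np.linalg.norm(fit.transform.translation - shift.translation)
        assert err < 0.2  # half of the 0.4 mm voxel

    def test_rotation_plus_translation_recovered(self, phantom):
        vol = phantom.volume
        c = vol.origin + vol.spacing * (np.array(vol.shape)[::-1] - 1) / 2
        rot = axis_angle_matrix([0.2, 0.3, 0.93], 5.0)
        truth = RigidTransform(rot, c - rot @ c + np.array([2.0, 0.5, -1.0]))
        moved = rerender(phantom, truth)
        fit = register_volumes_rigid(vol, moved)
        assert rotation_error_deg(fit.transform.rotation, truth.rotation) < 0.5
        center_err = np.linalg.norm(
            (fit.transform.rotation @ c + fit.transform.translation)
            - (truth.rotation @ c + truth.translation))
        assert center_err < 0.2

    def test_forward_and_backward_fits_are_mutually_inverse(self, phantom):
        shift = RigidTransform(axis_angle_matrix([0, 0, 1], 2.0), [1.0, 0, 0.5])
        moved = rerender(phantom, shift)
        fwd = register_volumes_rigid(phantom.volume, moved).transform
        bwd = register_volumes_rigid(moved, phantom.volume).transform
        round_trip = compose(fwd, bwd)
        assert np.linalg.norm(round_trip.translation) < 0.1
        assert rotation_error_deg(round_trip.rotation, np.eye(3)) < 0.2
        for t in (fwd, bwd):
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_mask_restricts_metric_to_stable_subvolume(self, phantom):
        """With the jaw structure moved and the cranial base fixed, masking
        the metric to the cranial base recovers the identity."""
        lo = np.array([-35.0, -15.0, -60.0])
        hi = np.array([35.0, 50.0, 5.0])
        both = {k: phantom.structures[k] for k in ("cranial_base", "maxilla")}
        pre = render_structures(both, lo, hi, 1.0)
        jaw_move = RigidTransform(np.eye(3), [0.0, 3.0, -2.0])
        post = render_structures(both, lo, hi, 1.0, poses={"maxilla": jaw_move})
        from orthognathics.synthetic import _occupancy

        mask = RegionMask(_occupancy(both["cranial_base"], pre))
        fit = register_volumes_rigid(pre, post, mask=mask)
        assert np.linalg.norm(fit.transform.translation) < 0.1
        assert rotation_error_deg(fit.transform.rotation, np.eye(3)) < 0.2

    def test_empty_mask_rejected(self, phantom):
        with pytest.raises(ValueError, match="empty"):
            RegionMask(np.zeros(phantom.volume.shape, dtype=bool))

    def test_mask_shape_mismatch_rejected(self, phantom):
        mask = RegionMask(np.ones((8, 8, 8), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            register_volumes_rigid(phantom.volume, phantom.volume, mask=mask)


class TestSurfaceRegistration:
    def test_self_registration_identity(self, phantom):
        mesh = phantom.meshes["proximal_left"]
        fit = register_surfaces_icp(mesh, mesh)
        assert np.linalg.norm(fit.transform.translation) < 1e-9
        assert rotation_error_deg(fit.transform.rotation, np.eye(3)) < 1e-9
        assert fit.rmsd < 1e-9

    def test_known_transform_recovered(self, phantom, frame):
        mesh = phantom.meshes["proximal_right"]
        rot = axis_angle_matrix(frame.axis_lr, 3.0)
        c = mesh.vertices.mean(axis=0)
        truth = RigidTransform(rot, c - rot @ c + np.array([1.0, -0.5, 0.5]))
        fit = register_surfaces_icp(mesh, mesh.transformed(truth))
        assert rotation_error_deg(fit.transform.rotation, truth.rotation) < 1e-2
        assert np.linalg.norm(fit.transform.translation - truth.translation) < 1e-3

    def test_subsampled_noisy_mesh_recovered(self, phantom, rng):
        """70% vertex subsample with 0.1 mm noise still recovers the motion
        within 0.2 mm / 0.5 deg."""
        mesh = phantom.meshes["proximal_left"]
        rot = axis_angle_matrix([0.1, 0.2, 0.97], 2.0)
        c = mesh.vertices.mean(axis=0)
        truth = RigidTransform(rot, c - rot @ c + np.array([0.8, 0.3, -0.5]))
        moved = mesh.transformed(truth)

        keep = np.sort(rng.choice(len(mesh.vertices),
                                  int(0.7 * len(mesh.vertices)), replace=False))
        remap = -np.ones(len(mesh.vertices), dtype=int)
        remap[keep] = np.arange(len(keep))
        faces = mesh.faces[np.all(remap[mesh.faces] >= 0, axis=1)]
        sub = SurfaceMesh(mesh.vertices[keep]
                          + rng.normal(0, 0.1, (len(keep), 3)),
                          remap[faces])
        fit = register_surfaces_icp(sub, moved)
        assert rotation_error_deg(fit.transform.rotation, truth.rotation) < 0.5
        c_err = np.linalg.norm(
            (fit.transform.rotation @ c + fit.transform.translation)
            - (truth.rotation @ c + truth.translation))
        assert c_err < 0.2

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))


class TestCropToMask:
    def test_full_mask_returns_identical_volume(self, phantom):
        mask = RegionMask(np.ones(phantom.volume.shape, dtype=bool))
        out = crop_to_mask(phantom.volume, mask)
        np.testing.assert_array_equal(out.array, phantom.volume.array)
        np.testing.assert_allclose(out.origin, phantom.volume.origin)

    def test_single_voxel_mask(self, phantom):
        m = np.zeros(phantom.volume.shape, dtype=bool)
        m[10, 20, 30] = True
        out = crop_to_mask(phantom.volume, RegionMask(m))
        # padded up to the 8-voxel minimum, but voxel [0,0,0] holds the value
        assert out.array[0, 0, 0] == phantom.volume.array[10, 20, 30]
        expected_origin = phantom.volume.origin \
            + phantom.volume.spacing * np.array([30, 20, 10])
        np.testing.assert_allclose(out.origin, expected_origin)

    def test_masked_mean_matches_brute_force(self, phantom):
        vol = phantom.volume
        m = np.zeros(vol.shape, dtype=bool)
        m[: vol.shape[0] // 2] = True  # half-volume mask
        out = crop_to_mask(vol, RegionMask(m), sentinel=np.nan)
        brute = vol.array[m].mean()
        # sentinel voxels were filled with 0 and the mask is a clean half-box,
        # so the cropped array mean equals the brute-force masked mean
        assert out.array.mean() == pytest.approx(brute, rel=1e-6)
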