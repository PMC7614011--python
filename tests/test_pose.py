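import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import fetalrecon as fr
from fetalrecon import (AtlasReference, DegenerateConfigurationError,
                        LandmarkMissingError, LandmarkSet, RigidTransform,
                        extract_landmarks, point_register, reorient_to_atlas)
from fetalrecon.core import LabelMap, centered_affine
from tests.conftest import DESK_ACQ


def rotation_error_rad(R1, R2):
    """Small-angle-accurate rotation distance (the arccos of a trace loses
    ~1e-8 of precision near zero)."""
    return np.linalg.norm(R1.T @ R2 - np.eye(3)) / np.sqrt(2)


def random_rigid(rng, max_trans=30.0):
    v = rng.normal(size=3)
    v = v / np.linalg.norm(v)
    angle = rng.uniform(0, 180)
    return RigidTransform.from_axis_angle(
        v, angle, translation=rng.uniform(-max_trans, max_trans, 3))


def dense_difference_centroid(outer, inner, step=0.25):
    """Independent oracle: centroid of (outer minus inner) ellipsoid region
    by dense numerical integration."""
    c, a = np.asarray(outer.center), np.asarray(outer.semi_axes)
    axes = [np.arange(c[i] - a[i], c[i] + a[i] + step, step) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    keep = outer.contains(pts) & ~inner.contains(pts)
    return pts[keep].mean(axis=0)


class TestExtractLandmarks:
    def test_centroids_match_dense_integration_oracle(self, desk_phantom):
        """Thorax/abdomen centroids are computed on the set difference
        (minus heart/liver); compare with analytic dense integration."""
        spec, img, glob, organs = desk_phantom
        lms = extract_landmarks(organs)
        expected = {
            "thorax": dense_difference_centroid(spec.thorax, spec.heart),
            "abdomen": dense_difference_centroid(spec.abdomen, spec.liver),
            "heart": np.asarray(spec.heart.center, float),
            "liver": np.asarray(spec.liver.center, float),
        }
        for i, name in enumerate(("thorax", "abdomen", "heart", "liver")):
            err = np.linalg.norm(lms.points[i] - expected[name])
            assert err < spec.voxel_mm, (name, err)

    def test_subtraction_happens_before_centroid(self):
        """With an overlapping heart label, the thorax centroid must shift
        away from the heart."""
        data = np.zeros((20, 20, 20), dtype=np.int16)
        data[2:18, 2:18, 2:18] = 1           # thorax cube
        data[3:9, 3:9, 3:9] = 3              # heart inside it
        data[12:14, 2:4, 2:4] = 2            # token abdomen
        data[15:17, 2:4, 2:4] = 4            # token liver
        lm = LabelMap(data, centered_affine((20, 20, 20), 1.0),
                      labels={"background": 0, "thorax": 1, "abdomen": 2,
                              "heart": 3, "liver": 4})
        lms = extract_landmarks(lm)
        union = lm.voxel_to_world(
            np.argwhere((data == 1) | (data == 3)).mean(axis=0))
        heart_c = lms.points[2]
        # the thorax centroid is computed on thorax-minus-heart, hence
        # farther from the heart than the whole-region centroid
        assert np.linalg.norm(lms.points[0] - heart_c) \
            > np.linalg.norm(union - heart_c) + 0.1

    def test_equivariance_under_rigid_motion(self, desk_phantom, rng):
        spec, img, glob, organs = desk_phantom
        P = random_rigid(rng, max_trans=5.0)
        moved = organs.resample_to(organs.affine, organs.shape, transform=P)
        lms = extract_landmarks(organs)
        lms_moved = extract_landmarks(moved)
        err = np.linalg.norm(lms_moved.points - P.apply(lms.points), axis=1)
        assert err.max() < spec.voxel_mm

    def test_empty_label_raises(self, desk_phantom):
        _, _, _, organs = desk_phantom
        data = organs.data.copy()
        data[data == organs.labels["heart"]] = organs.labels["thorax"]
        broken = LabelMap(data, organs.affine, labels=dict(organs.labels))
        with pytest.raises(LandmarkMissingError):
            extract_landmarks(broken)


class TestPointRegister:
    SQUARE = np.array([[0.0, 0, 0], [30, 0, 0], [0, 25, 0], [5, 5, 20]])

    def test_identity_when_target_equals_source(self):
        T = point_register(self.SQUARE, self.SQUARE)
        assert np.allclose(T.R, np.eye(3), atol=1e-12)
        assert np.allclose(T.t, 0, atol=1e-12)

    def test_exact_recovery_of_random_rigid(self, rng):
        for _ in range(100):
            P = random_rigid(rng)
            T = point_register(self.SQUARE, P.apply(self.SQUARE))
            assert rotation_error_rad(T.R, P.R) < 1e-9
            assert np.linalg.norm(T.t - P.t) < 1e-9

    def test_noisy_case_matches_numerical_minimiser(self, rng):
        """The closed-form solution attains the optimum found by direct
        numerical minimisation over a rotation parameterisation."""
        for trial in range(5):
            P = random_rigid(rng)
            target = P.apply(self.SQUARE) + rng.normal(0, 2.0, (4, 3))
            T = point_register(self.SQUARE, target)

            def resid(params):
                R = Rotation.from_rotvec(params[:3]).as_matrix()
                return np.sum((self.SQUARE @ R.T + params[3:] - target) ** 2)

            x0 = np.concatenate([
                Rotation.from_matrix(T.R).as_rotvec() + rng.normal(0, 0.1, 3),
                T.t + rng.normal(0, 1.0, 3)])
            res = minimize(resid, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14,
                                    "maxiter": 20000})
            ours = resid(np.concatenate(
                [Rotation.from_matrix(T.R).as_rotvec(), T.t]))
            assert ours <= res.fun + 1e-6

    def test_agrees_with_scipy_align_vectors(self, rng):
        P = random_rigid(rng)
        target = P.apply(self.SQUARE) + rng.normal(0, 1.0, (4, 3))
        T = point_register(self.SQUARE, target)
        sc, tc = self.SQUARE.mean(0), target.mean(0)
        R_sp, _ = Rotation.align_vectors(target - tc, self.SQUARE - sc)
        assert np.allclose(T.R, R_sp.as_matrix(), atol=1e-9)

    def test_equivariance_under_conjugation(self, rng):
        """Conjugating both point sets by a rigid Q conjugates the output."""
        src = self.SQUARE
        tgt = random_rigid(rng).apply(src) + rng.normal(0, 0.5, (4, 3))
        T = point_register(src, tgt)
        Q = random_rigid(rng)
        T2 = point_register(Q.apply(src), Q.apply(tgt))
        expected = Q.compose(T).compose(Q.inverse())
        assert rotation_error_rad(T2.R, expected.R) < 1e-7
        assert np.linalg.norm(T2.t - expected.t) < 1e-6

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateConfigurationError):
            point_register(line, line + 1.0)

    def test_no_reflection_even_for_mirrored_target(self):
        mirrored = self.SQUARE * np.array([-1.0, 1.0, 1.0])
        T = point_register(self.SQUARE, mirrored)
        assert np.linalg.det(T.R) == pytest.approx(1.0, abs=1e-12)


class TestReorientToAtlas:
    def _stack_and_atlas(self, desk_phantom, pose=None):
        _, img, glob, organs = desk_phantom
        pose = pose or RigidTransform.identity()
        st = fr.simulate_stack(img, pose, DESK_ACQ, seed=11,
                               labels=(glob, organs))
        return st, AtlasReference.from_organ_labels(organs)

    def test_landmarks_at_atlas_give_identity(self, desk_phantom):
        st, atlas = self._stack_and_atlas(desk_phantom)
        lms = LandmarkSet(atlas.points.copy())
        out, T = reorient_to_atlas(st, lms, atlas)
        assert np.allclose(T.R, np.eye(3), atol=1e-9)
        assert np.allclose(T.t, 0.0, atol=1e-9)
        assert np.allclose(out.affine, st.affine, atol=1e-6)

    def test_header_only_update(self, desk_phantom, rng):
        _, img, glob, organs = desk_phantom
        c = fr.trunk_centroid(glob)
        P = RigidTransform.from_axis_angle([0, 1, 1], 70, center=c)
        st = fr.simulate_stack(img, P, DESK_ACQ, seed=12,
                               labels=(glob, organs))
        atlas = AtlasReference.from_organ_labels(organs)
        lms = extract_landmarks(st.truth_organs)
        out, T = reorient_to_atlas(st, lms, atlas)
        assert out.data is st.data  # voxel bytes untouched
        assert np.allclose(out.affine, T.matrix @ st.affine, atol=1e-12)

    def test_centroids_land_on_atlas_points(self, desk_phantom):
        spec, img, glob, organs = desk_phantom
        c = fr.trunk_centroid(glob)
        P = RigidTransform.from_axis_angle([1, 0, 1], 110, center=c,
                                           translation=[6, -4, 9])
        st = fr.simulate_stack(img, P, DESK_ACQ, seed=13,
                               labels=(glob, organs))
        atlas = AtlasReference.from_organ_labels(organs)
        lms = extract_landmarks(st.truth_organs)
        out, T = reorient_to_atlas(st, lms, atlas)
        moved = extract_landmarks(out.truth_organs)
        err = np.linalg.norm(moved.points - atlas.points, axis=1)
        assert err.max() < 2 * spec.voxel_mm

    def test_idempotence(self, desk_phantom):
        spec, img, glob, organs = desk_phantom
        c = fr.trunk_centroid(glob)
        P = RigidTransform.from_axis_angle([0, 1, 0], 95, center=c)
        st = fr.simulate_stack(img, P, DESK_ACQ, seed=14,
                               labels=(glob, organs))
        atlas = AtlasReference.from_organ_labels(organs)
        once, _ = reorient_to_atlas(st, extract_landmarks(st.truth_organs),
                                    atlas)
        again, T2 = reorient_to_atlas(
            once, extract_landmarks(once.truth_organs), atlas)
        ang, trans = T2.distance_to(RigidTransform.identity())
        assert ang < 1.0 and trans < spec.voxel_mm

    def test_atlas_json_roundtrip(self, tmp_path, desk_phantom):
        _, _, _, organs = desk_phantom
        atlas = AtlasReference.from_organ_labels(organs)
        path = str(tmp_path / "atlas.json")
        atlas.save(path)
        back = AtlasReference.load(path)
        assert np.allclose(back.points, atlas.points, atol=1e-12)
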