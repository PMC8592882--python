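"""Vector geometry and Kabsch superposition against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from nacgeo.geometry import (
    RigidTransform,
    angle,
    distance,
    kabsch,
    pairwise_rmsd,
    superpose,
)
from oracles import quaternion_rmsd

finite_coord = st.floats(-100.0, 100.0, allow_nan=False)
vec3 = st.tuples(finite_coord, finite_coord, finite_coord)


class TestDistanceAngle:
    def test_axis_distance(self):
        assert distance((0, 0, 0), (3, 0, 0)) == pytest.approx(3.0)

    def test_coincident_points(self):
        assert distance((1.5, -2.0, 7.0), (1.5, -2.0, 7.0)) == 0.0

    @given(a=vec3, b=vec3)
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, a, b):
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert distance(a, b) == pytest.approx(brute, abs=1e-12)

    @pytest.mark.parametrize(
        "a,v,c,expected",
        [
            ((-1, 0, 0), (0, 0, 0), (1, 0, 0), 180.0),
            ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_reference_angles(self, a, v, c, expected):
        assert angle(a, v, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_arm_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @given(a=vec3, v=vec3, c=vec3)
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_acos_of_normalized_dot(self, a, v, c):
        u1 = np.array(a) - np.array(v)
        u2 = np.array(c) - np.array(v)
        n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
        if n1 < 1e-9 or n2 < 1e-9:
            return
        expected = np.degrees(np.arccos(np.clip(u1 @ u2 / (n1 * n2), -1, 1)))
        assert angle(a, v, c) == pytest.approx(expected, abs=1e-9)


class TestKabsch:
    def test_identity(self, rng):
        X = rng.normal(size=(10, 3))
        tf, rmsd = kabsch(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.apply(X), X, atol=1e-10)

    def test_rigid_copy_recovers_zero_rmsd(self, rng):
        X = rng.normal(size=(12, 3)) * 5
        R = Rotation.random(random_state=np.random.default_rng(4)).as_matrix()
        moved = X @ R.T + np.array([3.0, -7.0, 11.0])
        tf, rmsd = kabsch(moved, X)
        assert rmsd < 1e-9
        assert np.allclose(tf.apply(moved), X, atol=1e-8)

    def test_rotation_is_proper(self, rng):
        # mirror-image pairs would need a reflection; det must stay +1
        X = rng.normal(size=(8, 3))
        Y = X.copy()
        Y[:, 0] *= -1
        tf, _ = kabsch(X, Y)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            P = rng.normal(size=(n, 3)) * 10
            Q = rng.normal(size=(n, 3)) * 10
            _, r1 = kabsch(P, Q)
            r2 = quaternion_rmsd(P, Q)
            assert r1 == pytest.approx(r2, abs=1e-8)

    def test_rmsd_invariant_under_rigid_pretransform(self, rng):
        P = rng.normal(size=(15, 3)) * 4
        Q = rng.normal(size=(15, 3)) * 4
        _, base = kabsch(P, Q)
        for seed in range(5):
            R = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
            _, r = kabsch(P @ R.T + seed, Q)
            assert r == pytest.approx(base, abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_warns_but_solves(self):
        X = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        Y = np.column_stack([np.zeros(5), np.arange(5.0), np.zeros(5)])
        with pytest.warns(UserWarning, match="degenerate"):
            _, rmsd = kabsch(X, Y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_superpose_returns_transformed_coords(self, rng):
        X = rng.normal(size=(6, 3))
        Y = rng.normal(size=(6, 3))
        moved, rmsd = superpose(X, Y)
        assert np.sqrt(((moved - Y) ** 2).sum(axis=1).mean()) == pytest.approx(rmsd, abs=1e-10)


class TestRigidTransform:
    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose(self, rng):
        R1 = Rotation.random(random_state=np.random.default_rng(1)).as_matrix()
        R2 = Rotation.random(random_state=np.random.default_rng(2)).as_matrix()
        t1, t2 = rng.normal(size=3), rng.normal(size=3)
        a = RigidTransform(R1, t1)
        b = RigidTransform(R2, t2)
        X = rng.normal(size=(7, 3))
        assert np.allclose(a.compose(b).apply(X), a.apply(b.apply(X)), atol=1e-10)


class TestPairwiseRmsd:
    def test_identical_frames_zero(self, rng):
        frame = rng.normal(size=(9, 3))
        coords = np.stack([frame] * 4)
        D = pairwise_rmsd(coords)
        assert np.allclose(D, 0.0, atol=1e-9)

    def test_rigidly_moved_frame_is_zero_distance(self, rng):
        f0 = rng.normal(size=(10, 3)) * 3
        R = Rotation.random(random_state=np.random.default_rng(9)).as_matrix()
        f1 = f0 @ R.T + 2.0
        f2 = rng.normal(size=(10, 3)) * 3
        D = pairwise_rmsd(np.stack([f0, f1, f2]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert D[0, 2] > 0.1

    def test_matches_per_pair_kabsch(self, rng):
        coords = rng.normal(size=(6, 8, 3)) * 5
        D = pairwise_rmsd(coords)
        assert np.allclose(D, D.T, atol=1e-12)
        assert np.allclose(np.diag(D), 0.0)
        for i in range(6):
            for j in range(i + 1, 6):
                _, r = kabsch(coords[i], coords[j])
                assert D[i, j] == pytest.approx(r, abs=1e-9)

    def test_selection_restricts_metric(self, two_frame_trajectory):
        D = pairwise_rmsd(two_frame_trajectory, "name CA")
        # frame 2 is a pure translation of frame 1
        assert D[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_empty_selection_errors(self, two_frame_trajectory):
        with pytest.raises(ValueError, match="empty selection"):
            with pytest.warns(UserWarning):
                pairwise_rmsd(two_frame_trajectory, "resname XXX")
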