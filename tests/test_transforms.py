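"""Homogeneous transforms and the closed-form absolute-orientation fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tspr.transforms import HomogeneousTransform, compose, fit_rigid, fit_similarity

# the worked example's step and final matrices, printed at 4 decimals
M1_PRINTED = np.array(
    [
        [0.1533, -0.9604, 0.2326, 207.9560],
        [0.9635, 0.0930, -0.2511, 5.6186],
        [0.2195, 0.2626, 0.9396, -56.8884],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
M2_PRINTED = np.array(
    [
        [0.9059, -0.0172, -0.2012, 30.4818],
        [0.0630, 0.9026, 0.2068, -30.5599],
        [0.1919, -0.2155, 0.8821, 38.3209],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


def random_similarity(rng, scale=True):
    r = Rotation.random(random_state=rng).as_matrix()
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    t = rng.uniform(-50, 50, 3)
    return HomogeneousTransform.from_parts(r, t, scale=s)


class TestHomogeneousTransform:
    def test_last_row_is_enforced(self):
        bad = np.eye(4)
        bad[3, 0] = 0.1
        with pytest.raises(ValueError):
            HomogeneousTransform(bad)

    def test_identity_apply(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        np.testing.assert_array_equal(HomogeneousTransform.identity().apply(pts), pts)

    def test_pure_translation_moves_origin(self):
        t = HomogeneousTransform.translation((1.0, 2.0, 3.0))
        np.testing.assert_allclose(t.apply((0.0, 0.0, 0.0)), [1.0, 2.0, 3.0])

    def test_first_step_matrix_maps_origin_to_its_translation_column(self):
        t = HomogeneousTransform(M1_PRINTED)
        np.testing.assert_allclose(t.apply((0.0, 0.0, 0.0)), [207.9560, 5.6186, -56.8884])

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(3)
        t = random_similarity(rng)
        pts = rng.normal(size=(20, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_decompose_similarity_recovers_parts(self):
        rng = np.random.default_rng(4)
        r = Rotation.random(random_state=rng).as_matrix()
        t = HomogeneousTransform.from_parts(r, (1.0, -2.0, 3.0), scale=1.7)
        s, r_out, tvec = t.decompose_similarity()
        assert s == pytest.approx(1.7, abs=1e-12)
        np.testing.assert_allclose(r_out @ r_out.T, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(r_out, r, atol=1e-12)
        np.testing.assert_allclose(tvec, [1.0, -2.0, 3.0])

    def test_second_step_scale_matches_row_norm(self):
        # independent oracle: uniform scale = norm of any linear-block row
        t = HomogeneousTransform(M2_PRINTED)
        row_norms = np.linalg.norm(M2_PRINTED[:3, :3], axis=1)
        assert t.scale == pytest.approx(row_norms.mean(), abs=2e-4)
        assert t.scale == pytest.approx(0.928, abs=1e-3)


angles = st.floats(-180.0, 180.0, allow_nan=False)
coords = st.floats(-100.0, 100.0, allow_nan=False)


class TestSimilarityProperties:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(rx=angles, ry=angles, rz=angles,
           s=st.floats(0.5, 2.0), tx=coords, ty=coords, tz=coords)
    def test_from_parts_decompose_roundtrip(self, rx, ry, rz, s, tx, ty, tz):
        r = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
        t = HomogeneousTransform.from_parts(r, (tx, ty, tz), scale=s)
        s_out, r_out, t_out = t.decompose_similarity(atol=1e-9)
        assert s_out == pytest.approx(s, rel=1e-9)
        np.testing.assert_allclose(r_out, r, atol=1e-9)
        np.testing.assert_allclose(t_out, [tx, ty, tz], atol=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(rx=angles, s=st.floats(0.5, 2.0), tx=coords, ty=coords, tz=coords)
    def test_inverse_composes_to_identity(self, rx, s, tx, ty, tz):
        r = Rotation.from_euler("x", rx, degrees=True).as_matrix()
        t = HomogeneousTransform.from_parts(r, (tx, ty, tz), scale=s)
        np.testing.assert_allclose(compose(t, [t.inverse()]).m, np.eye(4), atol=1e-9)


class TestCompose:
    def test_identity_composition(self):
        out = compose(HomogeneousTransform.identity(), [HomogeneousTransform.identity()])
        np.testing.assert_array_equal(out.m, np.eye(4))

    def test_apply_order_matches_sequential_application(self):
        rng = np.random.default_rng(7)
        t1, t2 = random_similarity(rng), random_similarity(rng)
        pts = rng.normal(size=(100, 3))
        np.testing.assert_allclose(
            compose(t1, [t2]).apply(pts), t2.apply(t1.apply(pts)), atol=1e-9
        )

    def test_associativity(self):
        rng = np.random.default_rng(8)
        a, b, c = (random_similarity(rng) for _ in range(3))
        left = compose(compose(a, [b]), [c])
        right = compose(a, [b, c])
        np.testing.assert_allclose(left.m, right.m, atol=1e-12)

    def test_printed_step_matrices_compose_to_final(self):
        # spot entries of the final printed matrix (row 1)
        final = compose(HomogeneousTransform(M1_PRINTED), [HomogeneousTransform(M2_PRINTED)])
        assert final.m[0, 0] == pytest.approx(0.0782, abs=2e-3)
        assert final.m[0, 3] == pytest.approx(230.2195, abs=2e-3)


class TestFitRigid:
    def test_self_fit_is_identity(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        t = fit_rigid(pts, pts)
        np.testing.assert_allclose(t.m, np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("method", ["svd", "quaternion"])
    def test_exact_recovery_of_known_transform(self, method):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3)) * 20
        truth = random_similarity(rng, scale=False)
        t = fit_rigid(pts, truth.apply(pts), method=method)
        np.testing.assert_allclose(t.m, truth.m, atol=1e-9)

    def test_svd_and_quaternion_agree(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = rng.normal(size=(8, 3)) * 10
            t = rng.normal(size=(8, 3)) * 10
            a = fit_rigid(m, t, method="svd")
            b = fit_rigid(m, t, method="quaternion")
            np.testing.assert_allclose(a.m, b.m, atol=1e-9)

    def test_mirror_image_yields_proper_rotation_with_residual(self):
        # asymmetric tetrahedron vs its reflection: best PROPER rotation
        # cannot fit exactly, and the result must never be a reflection
        tet = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 1]])
        mirrored = tet * np.array([-1.0, 1.0, 1.0])
        t = fit_rigid(tet, mirrored)
        _, r, _ = t.decompose_similarity()
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        residual = np.linalg.norm(t.apply(tet) - mirrored)
        assert residual > 0.1

    def test_brute_force_rotation_grid_agreement(self):
        # independent oracle: exhaustive search over a 6-degree Euler grid
        # with the optimal (centroid) translation for each candidate
        rng = np.random.default_rng(11)
        m = rng.normal(size=(5, 3)) * 10
        t = rng.normal(size=(5, 3)) * 10
        dm = m - m.mean(axis=0)
        dt = t - t.mean(axis=0)
        step = 6
        eul = np.stack(
            np.meshgrid(
                np.arange(-180, 180, step),
                np.arange(-90, 91, step),
                np.arange(-180, 180, step),
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        rots = Rotation.from_euler("zyx", eul, degrees=True).as_matrix()
        rotated = np.einsum("rij,nj->rni", rots, dm)
        costs = np.sum((rotated - dt) ** 2, axis=(1, 2))
        best_grid = costs.min()
        fitted = fit_rigid(m, t)
        fit_cost = np.sum((fitted.apply(m) - t) ** 2)
        # closed form must be at least as good as the best grid candidate
        assert fit_cost <= best_grid + 1e-9

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            fit_rigid(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            fit_rigid(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_rigid(line, line + 1.0)


class TestFitSimilarity:
    def test_pure_scale(self):
        pts = np.random.default_rng(6).normal(size=(10, 3))
        t = fit_similarity(pts, 2.0 * pts)
        assert t.scale == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(t.m[:3, :3] / t.scale, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_known_similarity(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 3)) * 15
        truth = random_similarity(rng)
        t = fit_similarity(pts, truth.apply(pts))
        np.testing.assert_allclose(t.m, truth.m, atol=1e-9)

    def test_zero_variance_moving_set_raises(self):
        m = np.ones((5, 3))
        with pytest.raises(ValueError):
            fit_similarity(m, np.random.default_rng(0).normal(size=(5, 3)))
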