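"""Synthetic head phantom: analytic geometry, determinism, ground truth."""

import numpy as np
import pytest

from tspr.phantom import (
    DefectSpec,
    PhantomSpec,
    ROISpec,
    derive_subject,
    generate_atlas,
    similarity_about_center,
)
from tspr.volumes import Volume

from conftest import SUBJECT_GRID


def analytic_membership(spec):
    """Independent per-voxel membership test of the head solid."""
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    cx, cy, cz = spec.center
    ax, ay, az = spec.head_semiaxes
    inside = np.zeros(spec.shape, dtype=bool)
    y_apex = cy - ay - spec.nose_length
    y_base = cy - ay + 12.0
    eyes = []
    for sx in (-1.0, 1.0):
        dx0, dz0 = sx * spec.eye_offset[0], spec.eye_offset[1]
        inner = max(1.0 - (dx0 / ax) ** 2 - (dz0 / az) ** 2, 0.0)
        eyes.append((cx + dx0, cy - ay * np.sqrt(inner), cz + dz0))
    for i in range(nz):
        z = i * dz
        for j in range(ny):
            y = j * dy
            for k in range(nx):
                x = k * dx
                ell = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1
                nose = False
                if y_apex <= y <= y_base:
                    r = spec.nose_radius * (y - y_apex) / (y_base - y_apex)
                    nose = (x - cx) ** 2 + (z - cz) ** 2 <= r**2
                ok = ell or nose
                if ok:
                    for ex, ey, ez in eyes:
                        if (x - ex) ** 2 + (y - ey) ** 2 + (z - ez) ** 2 <= spec.eye_radius**2:
                            ok = False
                            break
                inside[i, j, k] = ok
    return inside


class TestGenerateAtlas:
    def test_noise_free_atlas_matches_analytic_solid(self):
        # small grid so the brute-force triple loop stays quick
        spec = PhantomSpec(shape=(32, 48, 48), spacing=(2.0, 2.0, 2.0), rois=[])
        vol, _ = generate_atlas(spec)
        np.testing.assert_array_equal(vol.data >= 50.0, analytic_membership(spec))

    def test_same_seed_is_deterministic(self):
        spec = PhantomSpec(noise_sigma=5.0, seed=11)
        a1, _ = generate_atlas(spec)
        a2, _ = generate_atlas(spec)
        np.testing.assert_array_equal(a1.data, a2.data)

    def test_nose_tip_is_most_anterior_voxel(self, atlas_volume, phantom_spec):
        iz, iy, ix = np.nonzero(atlas_volume.data >= 50.0)
        j_min = iy.min()
        tips = np.nonzero(iy == j_min)[0]
        cx, _, cz = phantom_spec.center
        # all most-anterior voxels cluster at the nose axis
        assert np.allclose(ix[tips], cx, atol=2.0)
        assert np.allclose(iz[tips], cz, atol=2.0)

    def test_labels_match_table(self, atlas_labels):
        present = set(np.unique(atlas_labels.labels)) - {0}
        assert present == set(atlas_labels.table)
        assert "pituitary" in atlas_labels.table.values()

    def test_roi_outside_head_raises(self):
        spec = PhantomSpec(rois=[ROISpec("stray", "sphere", (5.0, 5.0, 5.0), 3.0)])
        with pytest.raises(ValueError, match="outside the head"):
            generate_atlas(spec)


class TestDeriveSubject:
    def test_identity_parameters_reproduce_atlas(self, atlas_pair):
        atlas, labels = atlas_pair
        subject, sub_labels, truth = derive_subject(atlas, labels)
        np.testing.assert_allclose(subject.data, atlas.data, atol=1e-9)
        np.testing.assert_array_equal(sub_labels.labels, labels.labels)
        np.testing.assert_allclose(truth.transform.m, np.eye(4), atol=1e-12)

    def test_roi_centroids_map_through_ground_truth(self, atlas_pair):
        atlas, labels = atlas_pair
        subject, sub_labels, truth = derive_subject(
            atlas, labels, scale=0.93, rotation_deg=(0, 0, 10), translation=(20, 5, 0),
            **SUBJECT_GRID,
        )
        for lid in labels.table:
            src = np.column_stack(np.nonzero(labels.labels == lid))
            dst = np.column_stack(np.nonzero(sub_labels.labels == lid))
            c_src = atlas.index_to_physical(src).mean(axis=0)
            c_dst = Volume(
                sub_labels.labels, sub_labels.spacing, sub_labels.origin
            ).index_to_physical(dst).mean(axis=0)
            assert np.linalg.norm(truth.transform.apply(c_src) - c_dst) <= 1.0

    def test_missing_region_defect_is_local(self, atlas_pair):
        import tspr

        atlas, labels = atlas_pair
        clean, _, _ = derive_subject(atlas, labels, scale=0.95)
        center, radius = (64.0, 25.0, 40.0), 9.0
        defect, _, _ = derive_subject(
            atlas, labels, scale=0.95,
            defects=[DefectSpec("missing_region", center, radius)],
        )
        params = tspr.ContourParams(threshold=50.0)
        c_clean = tspr.surface_from_volume(clean, params)
        c_def = tspr.surface_from_volume(defect, params)
        # surface points unchanged outside a safety ball around the defect
        # (the disk opening lets the crater influence a few mm past its rim)
        def outside(cloud):
            d = np.linalg.norm(cloud.points - np.asarray(center), axis=1)
            pts = cloud.points[d > radius + 6.0]
            return set(map(tuple, np.round(pts, 6)))

        assert outside(c_clean) == outside(c_def)
        assert len(c_def) != len(c_clean)  # the defect did change the surface

    def test_bulge_defect_adds_foreground(self, atlas_pair):
        atlas, labels = atlas_pair
        bulged, _, _ = derive_subject(
            atlas, labels, defects=[DefectSpec("bulge", (110.0, 64.0, 48.0), 8.0)]
        )
        clean, _, _ = derive_subject(atlas, labels)
        assert (bulged.data >= 50).sum() > (clean.data >= 50).sum()

    def test_out_of_range_parameters_raise(self, atlas_pair):
        atlas, labels = atlas_pair
        with pytest.raises(ValueError):
            derive_subject(atlas, labels, scale=0.3)
        with pytest.raises(ValueError):
            derive_subject(atlas, labels, rotation_deg=(270, 0, 0))
        with pytest.raises(ValueError, match="outside the subject grid"):
            derive_subject(atlas, labels, translation=(500.0, 0.0, 0.0))

    def test_invalid_defect_spec(self):
        with pytest.raises(ValueError):
            DefectSpec("dent", (0, 0, 0), 5.0)
        with pytest.raises(ValueError):
            DefectSpec("bulge", (0, 0, 0), -1.0)


class TestSimilarityAboutCenter:
    def test_center_plus_translation_is_fixed_point_image(self):
        t = similarity_about_center((10.0, 20.0, 30.0), scale=1.3,
                                    rotation_deg=(10, 20, 30), translation=(1, 2, 3))
        np.testing.assert_allclose(t.apply((10.0, 20.0, 30.0)), [11.0, 22.0, 33.0])

    def test_pure_scale_about_center(self):
        t = similarity_about_center((0.0, 0.0, 0.0), scale=2.0)
        np.testing.assert_allclose(t.apply((1.0, 1.0, 1.0)), [2.0, 2.0, 2.0])
        assert t.scale == pytest.approx(2.0)
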