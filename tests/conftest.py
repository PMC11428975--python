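"""Shared fixtures: one session-scoped phantom pair drives most tests."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tspr
from tspr.phantom import PhantomSpec, derive_subject, generate_atlas

# subject grid large enough that no transform in the test suite truncates
# the head (a deliberately truncated subject is a separate scenario)
SUBJECT_GRID = dict(out_shape=(128, 160, 160), out_origin=(-16.0, -16.0, -16.0))
THRESHOLD = 50.0  # phantom foreground is 100 on a 0 background


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def atlas_pair(phantom_spec):
    return generate_atlas(phantom_spec)


@pytest.fixture(scope="session")
def atlas_volume(atlas_pair):
    return atlas_pair[0]


@pytest.fixture(scope="session")
def atlas_labels(atlas_pair):
    return atlas_pair[1]


@pytest.fixture(scope="session")
def atlas_surface(atlas_volume):
    return tspr.surface_from_volume(atlas_volume, tspr.ContourParams(threshold=THRESHOLD))


@pytest.fixture(scope="session")
def subject_case(atlas_pair):
    """A representative derived subject: scale 0.93, 10 deg yaw, 20/5 mm shift."""
    atlas, labels = atlas_pair
    subject, sub_labels, truth = derive_subject(
        atlas, labels, scale=0.93, rotation_deg=(0.0, 0.0, 10.0),
        translation=(20.0, 5.0, 0.0), **SUBJECT_GRID,
    )
    return subject, sub_labels, truth


@pytest.fixture(scope="session")
def subject_surface(subject_case):
    return tspr.surface_from_volume(subject_case[0], tspr.ContourParams(threshold=THRESHOLD))


def rotation_error_deg(estimate, truth) -> float:
    """Geodesic angle between the rotation parts of two similarity transforms."""
    _, r_e, _ = estimate.decompose_similarity()
    _, r_t, _ = truth.decompose_similarity()
    return float(np.degrees(np.linalg.norm(Rotation.from_matrix(r_e @ r_t.T).as_rotvec())))


def scale_error_pct(estimate, truth) -> float:
    return float(abs(estimate.scale - truth.scale) / truth.scale * 100.0)


def center_displacement_mm(estimate, truth, center) -> float:
    c = np.asarray(center, dtype=float)
    return float(np.linalg.norm(estimate.apply(c) - truth.apply(c)))
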