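"""Synthetic head phantom with known ground-truth transforms.

The phantom emulates the geometry the registration pipeline relies on: a
convex cranium (ellipsoid), a protruding nose (cone on the anterior face,
so the nose tip is the global anterior extreme), two eye-socket
depressions (spherical caps carved at the anterior surface), and a small
set of embedded ROI structures by anatomical role — a midline sphere
("pituitary"), a pair of tubes ("optic nerves"), and a lateral slab
("temporalis").  A subject volume is derived from the atlas by a known
uniform-scale similarity transform about the head centre, optionally
followed by local defects (a zeroed region such as missing teeth, or a
bulge such as a post-traumatic protrusion) and additive Gaussian noise —
mirroring how clinical series differ from an atlas in positioning, head
size, slice spacing and local pathology.

Axis conventions match the rest of the package: arrays are (z, y, x), the
face points toward −y (anterior), +z is toward the top of the head.
Foreground intensity is 100 on a 0 background, so threshold 50 recovers
the analytic solid exactly at zero noise.  All randomness is confined to
the noise fields and controlled by integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .transforms import HomogeneousTransform
from .volumes import LabelVolume, Volume

__all__ = [
    "ROISpec",
    "DefectSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_atlas",
    "derive_subject",
    "similarity_about_center",
]

FOREGROUND = 100.0


@dataclass
class ROISpec:
    """One labelled structure: a sphere, a tube (capsule) or a box.

    ``center`` is physical (x, y, z) mm.  For spheres ``size`` is the
    radius; for boxes the (hx, hy, hz) half-sizes; tubes run from
    ``center`` to ``end`` with radius ``size``.
    """

    name: str
    kind: str  # sphere | tube | box
    center: tuple[float, float, float]
    size: float | tuple[float, float, float]
    end: tuple[float, float, float] | None = None

    def mask(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        if self.kind == "sphere":
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= float(self.size) ** 2
        if self.kind == "box":
            hx, hy, hz = self.size
            return (
                (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)
            )
        if self.kind == "tube":
            if self.end is None:
                raise ValueError("tube ROI requires an end point")
            a = np.asarray(self.center, float)
            b = np.asarray(self.end, float)
            ab = b - a
            den = float(ab @ ab)
            px, py, pz = x - a[0], y - a[1], z - a[2]
            t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / den, 0.0, 1.0)
            dx = px - t * ab[0]
            dy = py - t * ab[1]
            dz = pz - t * ab[2]
            return dx * dx + dy * dy + dz * dz <= float(self.size) ** 2
        raise ValueError(f"unknown ROI kind {self.kind!r}")


@dataclass
class DefectSpec:
    """A local departure from the clean head: ``missing_region`` zeroes a
    sphere of tissue (e.g. missing teeth), ``bulge`` adds a foreground
    sphere (e.g. a post-traumatic protrusion)."""

    kind: str  # missing_region | bulge
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.kind not in ("missing_region", "bulge"):
            raise ValueError("defect kind must be 'missing_region' or 'bulge'")
        if not self.radius > 0:
            raise ValueError("defect radius must be positive")


def _default_rois() -> list[ROISpec]:
    # centred on the default 128x128x96 mm head (centre (64, 64, 48))
    return [
        ROISpec("pituitary", "sphere", (64.0, 60.0, 56.0), 5.0),
        ROISpec("optic_nerve_right", "tube", (58.0, 58.0, 58.0), 2.5, end=(52.0, 40.0, 58.0)),
        ROISpec("optic_nerve_left", "tube", (69.0, 58.0, 58.0), 2.5, end=(75.0, 40.0, 58.0)),
        ROISpec("temporalis_left", "box", (93.0, 64.0, 54.0), (5.0, 10.0, 7.0)),
    ]


@dataclass
class PhantomSpec:
    """Geometry and noise of the synthetic head atlas.

    Defaults give a 128 x 128 x 96 mm head volume at 1 mm isotropic
    spacing — small enough for sub-minute end-to-end runs while keeping
    facial features several voxels wide.
    """

    shape: tuple[int, int, int] = (96, 128, 128)  # (z, y, x)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (dz, dy, dx)
    head_semiaxes: tuple[float, float, float] = (42.0, 43.0, 40.0)  # (x, y, z) mm
    nose_length: float = 18.0
    nose_radius: float = 12.0
    eye_offset: tuple[float, float] = (17.0, 15.0)  # lateral and upward from nose level
    eye_radius: float = 10.0
    rois: list[ROISpec] = field(default_factory=_default_rois)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.head_semiaxes) or self.nose_length <= 0:
            raise ValueError("all phantom sizes must be positive")

    @property
    def center(self) -> tuple[float, float, float]:
        """Head centre in physical (x, y, z) mm (grid centre)."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.spacing
        return ((nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0, (nz - 1) * dz / 2.0)


@dataclass
class GroundTruth:
    """The generator's exact atlas-to-subject similarity transform plus the
    ROI label volumes in both spaces."""

    transform: HomogeneousTransform
    atlas_labels: LabelVolume
    subject_labels: LabelVolume


def _coords(shape, spacing, origin=(0.0, 0.0, 0.0)):
    nz, ny, nx = shape
    dz, dy, dx = spacing
    z = origin[2] + np.arange(nz)[:, None, None] * dz
    y = origin[1] + np.arange(ny)[None, :, None] * dy
    x = origin[0] + np.arange(nx)[None, None, :] * dx
    return x, y, z


def head_solid(spec: PhantomSpec) -> np.ndarray:
    """Analytic membership of the head solid on the atlas grid:
    (ellipsoid ∪ nose cone) minus the two eye-socket spheres."""
    x, y, z = _coords(spec.shape, spec.spacing)
    cx, cy, cz = spec.center
    ax, ay, az = spec.head_semiaxes
    ell = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    # nose: cone with apex on the anterior midline, protruding past the ellipsoid
    y_apex = cy - ay - spec.nose_length
    y_base = cy - ay + 12.0  # base plane inside the ellipsoid, keeps the union connected
    frac = np.clip((y - y_apex) / (y_base - y_apex), 0.0, None)
    nose = (y >= y_apex) & (y <= y_base) & (
        (x - cx) ** 2 + (z - cz) ** 2 <= (spec.nose_radius * frac) ** 2
    )

    solid = ell | nose
    ex, ez = spec.eye_offset
    for sx in (-1.0, 1.0):
        dx0, dz0 = sx * ex, ez
        inner = 1.0 - (dx0 / ax) ** 2 - (dz0 / az) ** 2
        y_surf = cy - ay * np.sqrt(max(inner, 0.0))
        eye = (x - (cx + dx0)) ** 2 + (y - y_surf) ** 2 + (z - (cz + dz0)) ** 2
        solid &= eye > spec.eye_radius**2
    return solid


def generate_atlas(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Render the atlas volume (foreground 100, background 0, optional
    Gaussian noise) and its ROI label volume; deterministic per seed."""
    solid = head_solid(spec)
    x, y, z = _coords(spec.shape, spec.spacing)
    labels = np.zeros(spec.shape, dtype=np.int32)
    table: dict[int, str] = {}
    for lid, roi in enumerate(spec.rois, start=1):
        m = roi.mask(x, y, z)
        if not m.any():
            raise ValueError(f"ROI {roi.name!r} covers no voxel")
        if (m & ~solid).any():
            raise ValueError(f"ROI {roi.name!r} extends outside the head")
        labels[m] = lid
        table[lid] = roi.name
    data = np.where(solid, FOREGROUND, 0.0)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    vol = Volume(data, spec.spacing, (0.0, 0.0, 0.0), "mr_arbitrary")
    return vol, LabelVolume(labels, spec.spacing, table)


def similarity_about_center(
    center,
    scale: float = 1.0,
    rotation_deg=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
) -> HomogeneousTransform:
    """Similarity transform ``p -> c + t + s R (p - c)`` with intrinsic
    rotations applied x-then-y-then-z (R = Rz Ry Rx), angles in degrees."""
    rx, ry, rz = np.radians(np.asarray(rotation_deg, dtype=float))
    cx_, sx_ = np.cos(rx), np.sin(rx)
    cy_, sy_ = np.cos(ry), np.sin(ry)
    cz_, sz_ = np.cos(rz), np.sin(rz)
    rmx = np.array([[1, 0, 0], [0, cx_, -sx_], [0, sx_, cx_]])
    rmy = np.array([[cy_, 0, sy_], [0, 1, 0], [-sy_, 0, cy_]])
    rmz = np.array([[cz_, -sz_, 0], [sz_, cz_, 0], [0, 0, 1]])
    r = rmz @ rmy @ rmx
    c = np.asarray(center, dtype=float)
    t = c + np.asarray(translation, dtype=float) - scale * (r @ c)
    return HomogeneousTransform.from_parts(r, t, scale=scale)


def derive_subject(
    atlas: Volume,
    labels: LabelVolume,
    scale: float = 1.0,
    rotation_deg=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
    defects=(),
    noise_sigma: float = 0.0,
    seed: int = 0,
    out_shape: tuple[int, int, int] | None = None,
    out_spacing: tuple[float, float, float] | None = None,
    out_origin: tuple[float, float, float] | None = None,
) -> tuple[Volume, LabelVolume, GroundTruth]:
    """Derive a subject volume from the atlas by a known similarity map.

    The transform scales/rotates about the atlas physical centre and then
    translates; the subject grid may use a different shape and spacing
    (anisotropic slice thickness included).  Defects are applied *after*
    the transform, in subject space, and noise last, so the stored
    :class:`GroundTruth` transform is exact for the defect-free anatomy.
    """
    if not 0.5 <= scale <= 2.0:
        raise ValueError("scale must lie in [0.5, 2]")
    if np.max(np.abs(rotation_deg)) > 180.0:
        raise ValueError("rotation magnitudes must be <= 180 degrees")
    nz, ny, nx = atlas.shape
    dz, dy, dx = atlas.spacing
    center = ((nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0, (nz - 1) * dz / 2.0)
    t = similarity_about_center(center, scale, rotation_deg, translation)

    out_shape = out_shape or atlas.shape
    out_spacing = out_spacing or atlas.spacing
    out_origin = atlas.origin if out_origin is None else tuple(float(o) for o in out_origin)
    sub_grid = Volume(np.zeros(out_shape, dtype=np.int8), out_spacing, out_origin)

    ii, jj, kk = np.meshgrid(
        np.arange(out_shape[0]), np.arange(out_shape[1]), np.arange(out_shape[2]),
        indexing="ij",
    )
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    xyz = sub_grid.index_to_physical(idx)
    src_ijk = atlas.physical_to_index(t.inverse().apply(xyz)).T  # (3, N) in (i, j, k)

    data = ndimage.map_coordinates(
        np.asarray(atlas.data, float), src_ijk, order=1, mode="constant", cval=0.0
    ).reshape(out_shape)
    lab = ndimage.map_coordinates(
        labels.labels, src_ijk, order=0, mode="constant", cval=0
    ).reshape(out_shape)

    if not (data > FOREGROUND / 2).any():
        raise ValueError("transform pushes the head entirely outside the subject grid")

    x, y, z = _coords(out_shape, out_spacing, out_origin)
    for d in defects:
        cx, cy, cz = d.center
        sphere = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= d.radius**2
        data[sphere] = 0.0 if d.kind == "missing_region" else FOREGROUND
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=out_shape)

    subject = Volume(data, out_spacing, out_origin, atlas.intensity_kind)
    subject_labels = LabelVolume(lab.astype(np.int32), out_spacing, labels.table, out_origin)
    truth = GroundTruth(t, labels, subject_labels)
    return subject, subject_labels, truth
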