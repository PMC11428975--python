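"""Feature sampling for the two registration steps.

Step one registers the "eye–nose triangle": the exterior surface is
projected orthographically along the anterior–posterior axis into a
face-on depth map, a rectangle over the face is sampled on a uniform
4 x 7 node grid (28 points), and each node takes the depth of its nearest
occupied depth-map cell.

Step two registers the "circular contour": an axial band (slab) of the
exterior surface bracketing the eye–nose region, which constrains the
head's spatial scale.

Grid nodes are enumerated in a *viewer-consistent* order (rows ascending,
columns along the viewer's horizontal), so that node (r, c) on the atlas
face and node (r, c) on the subject face sample the same anatomical spot
regardless of which direction each head faces.  When both grids are
complete this index pairing gives the first registration a closed-form
starting estimate — the headless counterpart of the operator's coarse
mouse alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import PointCloud

__all__ = [
    "DepthMap",
    "FeatureGridSpec",
    "BandSpec",
    "project_depth",
    "sample_feature_grid",
    "select_band",
    "check_band_balance",
    "nose_tip",
    "face_rect_from_nose",
]

_AXES = {"x": 0, "y": 1, "z": 2}
# projection plane (u, v) axes for each view axis
_PLANE = {"x": ("y", "z"), "y": ("x", "z"), "z": ("x", "y")}


@dataclass
class DepthMap:
    """Orthographic depth map of a surface cloud.

    ``depth[iv, iu]`` holds, for each occupied cell of the projection
    plane, the coordinate along ``view_axis`` of the surface point nearest
    the viewer (NaN where no point projects).  ``side="low"`` views from
    the −axis direction (depth = min coordinate), ``side="high"`` from the
    +axis direction (depth = max coordinate).
    """

    depth: np.ndarray
    u0: float
    v0: float
    cell_size: float
    view_axis: str = "y"
    side: str = "low"

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.depth)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) physical coordinates of occupied cell centres."""
        iv, iu = np.nonzero(self.occupied)
        return self.u0 + iu * self.cell_size, self.v0 + iv * self.cell_size

    def to_xyz(self, u: np.ndarray, v: np.ndarray, depth: np.ndarray) -> np.ndarray:
        ua, va = _PLANE[self.view_axis]
        out = np.empty((len(np.atleast_1d(u)), 3))
        out[:, _AXES[ua]] = u
        out[:, _AXES[va]] = v
        out[:, _AXES[self.view_axis]] = depth
        return out


@dataclass
class FeatureGridSpec:
    """Uniform node grid over a rectangle of the projection plane.

    ``rect = (u0, v0, u1, v1)`` in mm; ``rows`` span v, ``cols`` span u.
    The default 4 x 7 yields the 28 facial feature points.
    """

    rect: tuple[float, float, float, float]
    rows: int = 4
    cols: int = 7
    capture_radius: float | None = None  # default: 2 * cell_size

    def __post_init__(self) -> None:
        u0, v0, u1, v1 = self.rect
        if not (u1 > u0 and v1 > v0):
            raise ValueError(f"rect must have positive area, got {self.rect}")
        if self.rows * self.cols < 3:
            raise ValueError("grid must provide at least 3 nodes")


@dataclass
class BandSpec:
    """An axial slab of the surface: points with lo <= coordinate <= hi."""

    axis: str = "z"
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {tuple(_AXES)}")
        if not self.lo < self.hi:
            raise ValueError(f"band requires lo < hi, got [{self.lo}, {self.hi}]")


def project_depth(
    cloud: PointCloud,
    view_axis: str = "y",
    cell_size: float = 1.0,
    side: str = "low",
    despeckle: float | None = None,
) -> DepthMap:
    """Orthographic nearest-surface depth map of a cloud.

    Points are binned into ``cell_size`` cells of the projection plane;
    each occupied cell keeps the extreme coordinate along ``view_axis``
    (min for ``side="low"``, max for ``side="high"``) — the surface point
    nearest the viewer.

    A column that happens to contain no near-surface point (a grazing or
    noisy column of a thin contour cloud) would otherwise show the *far*
    side of the body.  Cells whose depth deviates from their 3x3
    neighbourhood median by more than ``despeckle`` (default
    ``4 * cell_size``) are therefore discarded; pass ``despeckle=np.inf``
    to keep every cell.
    """
    if len(cloud) == 0:
        raise ValueError("cannot project an empty cloud")
    if view_axis not in _AXES or side not in ("low", "high"):
        raise ValueError("view_axis must be x/y/z and side 'low' or 'high'")
    ua, va = _PLANE[view_axis]
    u, v = cloud.axis(ua), cloud.axis(va)
    d = cloud.axis(view_axis)
    u0, v0 = float(u.min()), float(v.min())
    iu = np.floor((u - u0) / cell_size + 0.5).astype(int)
    iv = np.floor((v - v0) / cell_size + 0.5).astype(int)
    grid = np.full((iv.max() + 1, iu.max() + 1), np.nan)
    order = np.argsort(d)
    if side == "low":
        order = order[::-1]  # write nearest (smallest) last so it wins
    grid[iv[order], iu[order]] = d[order]

    if despeckle is None:
        despeckle = 4.0 * cell_size
    if np.isfinite(despeckle):
        from scipy.ndimage import median_filter

        fill = np.inf if side == "low" else -np.inf
        dd = np.where(np.isfinite(grid), grid, fill)
        med = median_filter(dd, size=3, mode="constant", cval=fill)
        bad = np.isfinite(grid) & ~(np.abs(grid - med) <= despeckle)
        grid[bad] = np.nan
    return DepthMap(grid, u0, v0, float(cell_size), view_axis, side)


def sample_feature_grid(
    depth: DepthMap, spec: FeatureGridSpec, return_node_ids: bool = False
):
    """Sample up to ``rows * cols`` 3D feature points from a depth map.

    Nodes are spread uniformly over the rectangle (endpoints included);
    each node takes the depth of its nearest occupied cell within the
    capture radius and nodes with no surface in reach are dropped.  With
    full coverage the cloud has exactly ``rows * cols`` points (28 at the
    4 x 7 default).

    With ``return_node_ids=True`` also returns the flat (viewer-order)
    node index of each kept point, so two grids sampled on corresponding
    rectangles can be paired node-by-node even when some nodes dropped.
    """
    u0, v0, u1, v1 = spec.rect
    us = np.linspace(u0, u1, spec.cols)
    if depth.side == "high":
        us = us[::-1]  # viewer-consistent column order
    vs = np.linspace(v0, v1, spec.rows)
    nodes = np.column_stack([np.tile(us, spec.rows), np.repeat(vs, spec.cols)])

    cu, cv = depth.cell_centers()
    if len(cu) == 0:
        raise ValueError("depth map has no occupied cells")
    radius = 2.0 * depth.cell_size if spec.capture_radius is None else spec.capture_radius
    dist, idx = cKDTree(np.column_stack([cu, cv])).query(nodes)
    keep = dist <= radius + 1e-12
    if not keep.any():
        raise ValueError("feature region off surface: no node captured a depth cell")
    iv, iu = np.nonzero(depth.occupied)
    depths = depth.depth[iv[idx[keep]], iu[idx[keep]]]
    cloud = PointCloud(depth.to_xyz(nodes[keep, 0], nodes[keep, 1], depths))
    if return_node_ids:
        return cloud, np.nonzero(keep)[0]
    return cloud


def select_band(cloud: PointCloud, spec: BandSpec) -> PointCloud:
    """Subset of the cloud inside the slab; preserves provenance."""
    if len(cloud) == 0:
        raise ValueError("cannot select a band from an empty cloud")
    coord = cloud.axis(spec.axis)
    mask = (coord >= spec.lo) & (coord <= spec.hi)
    if not mask.any():
        raise ValueError(f"band [{spec.lo}, {spec.hi}] along {spec.axis} selects no points")
    return cloud.select(mask)


def check_band_balance(a: PointCloud, b: PointCloud, max_ratio: float = 3.0) -> None:
    """Warn when the two band clouds are badly unbalanced.

    The second registration assumes both bands hold approximately the same
    anatomy; a point-count ratio beyond ``max_ratio`` usually means the
    slabs were chosen inconsistently.
    """
    ratio = max(len(a), len(b)) / max(1, min(len(a), len(b)))
    if ratio > max_ratio:
        warnings.warn(
            f"band point counts differ by {ratio:.1f}x (> {max_ratio}x); the two bands "
            "should cover approximately the same anatomy",
            stacklevel=2,
        )


def nose_tip(depth: DepthMap) -> tuple[float, float, float]:
    """(u, v, depth) of the nearest-to-viewer point of a face-on depth map —
    the nose tip when the face points at the viewer.

    The extremum is taken on a 3x3 median-filtered copy of the map, so a
    single noisy cell cannot masquerade as the tip.
    """
    from scipy.ndimage import median_filter

    occ = depth.occupied
    if not occ.any():
        raise ValueError("depth map has no occupied cells")
    low = depth.side == "low"
    d = np.where(occ, depth.depth, np.inf if low else -np.inf)
    med = median_filter(d, size=3, mode="constant", cval=np.inf if low else -np.inf)
    med = np.where(occ & np.isfinite(med), med, np.inf if low else -np.inf)
    iv, iu = np.unravel_index(np.argmin(med) if low else np.argmax(med), med.shape)
    return (
        depth.u0 + iu * depth.cell_size,
        depth.v0 + iv * depth.cell_size,
        float(depth.depth[iv, iu]),
    )


def face_rect_from_nose(
    depth: DepthMap,
    half_width: float = 24.0,
    below: float = 8.0,
    above: float = 26.0,
) -> tuple[float, float, float, float]:
    """A face rectangle anchored on the nose tip.

    The nose tip is the global nearest-to-viewer cell of a face-on depth
    map.  The rectangle spans ``half_width`` mm either side of it
    horizontally and from ``below`` mm under to ``above`` mm over it
    vertically — a headless convenience standing in for the interactive
    rectangle selection; it is not a facial-landmark detector.
    """
    u, v, _ = nose_tip(depth)
    return (u - half_width, v - below, u + half_width, v + above)
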