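"""Slice-wise exterior body-contour extraction.

Clinical head series carry clutter (headrest, ear pads, streak artifacts)
around the body, so the exterior surface is extracted slice by slice with a
fixed morphological recipe:

1. binarize at a body/air threshold (air and tissue separate cleanly in
   both CT and MR);
2. fill the closed interior region;
3. expand the canvas (so border-touching structures keep a connected outer
   background);
4. remove impurities with a binary opening;
5. reduce the canvas back;
6. erode and subtract, leaving a boundary ring of the body.

The per-slice rings, converted to physical coordinates, concatenate into
the 3D exterior surface point cloud that the registration consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .pointcloud import PointCloud
from .volumes import Volume

__all__ = ["ContourParams", "binarize_slice", "extract_exterior_contour", "surface_from_volume"]

#: default body/air threshold for CT volumes, in Hounsfield units
CT_DEFAULT_THRESHOLD = -300.0


@dataclass
class ContourParams:
    """Parameters of the six-step contour recipe.

    ``threshold=None`` selects Otsu's method per slice (the default for MR
    and photographic volumes); CT volumes default to −300 HU.  Structuring
    elements are disks; ``pad`` defaults to ``opening_radius + 1``.
    """

    threshold: float | None = None
    opening_radius: int = 3
    erosion_radius: int = 1
    pad: int | None = None

    def resolved_pad(self) -> int:
        return self.opening_radius + 1 if self.pad is None else self.pad

    def resolve_threshold(self, slice2d: np.ndarray) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        lo, hi = float(np.min(slice2d)), float(np.max(slice2d))
        if lo == hi:  # constant slice: nothing to separate
            return hi + 1.0
        return float(threshold_otsu(np.asarray(slice2d, dtype=float)))

    @classmethod
    def for_volume(cls, v: Volume, **kw) -> "ContourParams":
        p = cls(**kw)
        if p.threshold is None and v.intensity_kind == "ct_hu":
            p.threshold = CT_DEFAULT_THRESHOLD
        return p


def binarize_slice(slice2d: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask, true where intensity >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(slice2d) >= threshold


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    # complement of the background flood-filled from the border;
    # 4-connectivity for the background, 8-connectivity for the foreground
    return ndimage.binary_fill_holes(mask, structure=_CROSS)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def body_mask(slice2d: np.ndarray, params: ContourParams) -> np.ndarray:
    """Steps 1-5: the filled, opened, largest-component body region."""
    thr = params.resolve_threshold(slice2d)
    mask = binarize_slice(slice2d, thr)
    mask = _fill_holes(mask)
    pad = params.resolved_pad()
    mask = np.pad(mask, pad, mode="constant", constant_values=False)
    if params.opening_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(params.opening_radius))
    mask = mask[pad:-pad, pad:-pad] if pad else mask
    return _largest_component(mask)


def extract_exterior_contour(slice2d: np.ndarray, params: ContourParams | None = None) -> np.ndarray:
    """The exterior boundary ring of one slice (steps 1-6).

    Returns the body mask minus its erosion: a ring whose thickness equals
    the erosion radius.  An empty post-opening mask yields an empty ring
    with a warning, not an error — clinical series may contain slices with
    no body at all.
    """
    params = params or ContourParams()
    body = body_mask(np.asarray(slice2d), params)
    if not body.any():
        warnings.warn("slice contains no body after opening; empty contour", stacklevel=2)
        return body
    if params.erosion_radius > 0:
        eroded = ndimage.binary_erosion(body, structure=disk(params.erosion_radius))
    else:
        eroded = body
    return body & ~eroded


def surface_from_volume(v: Volume, params: ContourParams | None = None) -> PointCloud:
    """Exterior-surface point cloud of a whole volume.

    Runs the contour recipe on every slice and concatenates the contour
    voxels converted to physical (x, y, z) mm, with per-point provenance
    ``(slice, row, col)``.
    """
    params = params or ContourParams.for_volume(v)
    points, prov = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-slice emptiness is normal at the stack ends
        for i in range(v.shape[0]):
            ring = extract_exterior_contour(v.data[i], params)
            rr, cc = np.nonzero(ring)
            if rr.size:
                idx = np.column_stack([np.full(rr.size, i), rr, cc])
                prov.append(idx)
                points.append(v.index_to_physical(idx))
    if not points:
        raise ValueError("no body surface found in any slice")
    return PointCloud(np.vstack(points), provenance=np.vstack(prov))
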