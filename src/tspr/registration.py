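"""ICP registration and the two-step progressive (TSPR) pipeline.

The classical iterative-closest-point loop alternates nearest-neighbour
correspondence search with a closed-form transform fit.  Because the fit
is recomputed from the *original* moving set at every iteration, the RMS
objective is provably non-increasing, but a single-stage run started far
from the optimum readily locks onto a spurious local minimum (nose matched
to ear, face matched back-to-front).

The two-step progressive scheme avoids this by registering different
feature regions in sequence:

1. *spatial orientation* — rigid ICP between the 28-point facial feature
   grids, run once;
2. *spatial scale* — similarity ICP between the circular contour bands,
   with the moving band first pushed through the accumulated transform;
   this step may repeat progressively (a small bounded number of times —
   repeating the orientation step instead would over-register).

The final transform is the composition, in order of action, of the first
step and every scale step.

Following statsmodels conventions the pipeline is exposed as a model
object (:class:`TSPRRegistration`) whose :meth:`~TSPRRegistration.fit`
returns a :class:`TSPRResults` carrying the per-step transforms, RMS
histories and a ``summary()`` table; :func:`tspr_register` is the
one-call functional equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .features import (
    BandSpec,
    FeatureGridSpec,
    check_band_balance,
    face_rect_from_nose,
    nose_tip,
    project_depth,
    sample_feature_grid,
    select_band,
)
from .pointcloud import PointCloud
from .transforms import HomogeneousTransform, compose, fit_rigid, fit_similarity

__all__ = [
    "RegistrationResult",
    "TSPRResults",
    "TSPRRegistration",
    "nearest_correspondences",
    "icp",
    "tspr_register",
    "MAX_SCALE_STEPS",
]

#: guard against over-registration: the scale step may repeat at most this often
MAX_SCALE_STEPS = 5


def _pts(x) -> np.ndarray:
    return x.points if isinstance(x, PointCloud) else np.atleast_2d(np.asarray(x, dtype=float))


def _patch(depth, rect) -> PointCloud:
    """All occupied depth-map cells inside a rectangle, as 3D points."""
    u0, v0, u1, v1 = rect
    cu, cv = depth.cell_centers()
    sel = (cu >= u0) & (cu <= u1) & (cv >= v0) & (cv <= v1)
    iv, iu = np.nonzero(depth.occupied)
    d = depth.depth[iv[sel], iu[sel]]
    return PointCloud(depth.to_xyz(cu[sel], cv[sel], d))


def nearest_correspondences(moving, target) -> tuple[np.ndarray, np.ndarray]:
    """For each moving point, the index of its nearest target point and the
    Euclidean distance.  Exact ties break to the lowest target index."""
    m, t = _pts(moving), _pts(target)
    if len(m) == 0 or len(t) == 0:
        raise ValueError("point sets must be nonempty")
    tree = cKDTree(t)
    k = min(2, len(t))
    dist, idx = tree.query(m, k=k)
    if k == 1:
        return np.atleast_1d(idx), np.atleast_1d(dist)
    tied = dist[:, 0] == dist[:, 1]
    best = idx[:, 0].copy()
    if tied.any():
        for i in np.nonzero(tied)[0]:
            cands = tree.query_ball_point(m[i], dist[i, 0] + 1e-12)
            best[i] = min(cands)
    return best, dist[:, 0]


@dataclass
class RegistrationResult:
    """Outcome of one ICP run.

    ``rms_history`` records the root-mean-square correspondence distance
    after each transform update and is non-increasing by construction.
    """

    transform: HomogeneousTransform
    rms: float
    iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def icp(
    moving,
    target,
    mode: str = "rigid",
    max_iter: int = 100,
    tol: float = 1e-4,
    init: HomogeneousTransform | None = None,
) -> RegistrationResult:
    """Iterative closest point in ``rigid`` or ``similarity`` mode.

    Each iteration matches the currently-transformed moving points to
    their nearest targets and refits the transform *from the original
    moving set*, which guarantees a monotone RMS objective.  Iteration
    stops when the RMS improves by less than ``tol`` (mm) or after
    ``max_iter`` rounds.
    """
    if mode not in ("rigid", "similarity"):
        raise ValueError("mode must be 'rigid' or 'similarity'")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not tol > 0:
        raise ValueError("tol must be positive")
    m, t = _pts(moving), _pts(target)
    fit = fit_rigid if mode == "rigid" else fit_similarity
    transform = init or HomogeneousTransform.identity()
    current = transform.apply(m)
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        idx, _ = nearest_correspondences(current, t)
        matched = t[idx]
        transform = fit(m, matched)
        current = transform.apply(m)
        rms = float(np.sqrt(np.mean(np.sum((current - matched) ** 2, axis=1))))
        history.append(rms)
        if len(history) > 1 and abs(history[-2] - history[-1]) < tol:
            converged = True
            break
    return RegistrationResult(transform, history[-1], len(history), converged, history)


def surface_rms(moving, target) -> float:
    """RMS nearest-neighbour distance from each moving point to the target."""
    _, dist = nearest_correspondences(moving, target)
    return float(np.sqrt(np.mean(dist**2)))


@dataclass
class TSPRResults:
    """Fitted two-step registration.

    Attributes
    ----------
    m1 : first-step (orientation) transform
    m2_list : the similarity transforms of each scale step, in order
    final : the composed transform, ``compose(m1, m2_list)`` exactly
    step_results : the per-step ICP diagnostics
    """

    m1: HomogeneousTransform
    m2_list: list[HomogeneousTransform]
    final: HomogeneousTransform
    step_results: list[RegistrationResult]
    feature_counts: tuple[int, int]
    band_counts: tuple[int, int]

    @property
    def n_progressive(self) -> int:
        """Total number of progressive registrations (orientation + scale)."""
        return 1 + len(self.m2_list)

    @property
    def scale(self) -> float:
        return self.final.scale

    @property
    def final_rms(self) -> float:
        return self.step_results[-1].rms

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, res in enumerate(self.step_results):
            s, _, tvec = res.transform.decompose_similarity()
            rows.append(
                {
                    "step": "orientation (rigid)" if i == 0 else f"scale {i} (similarity)",
                    "iterations": res.iterations,
                    "rms_mm": res.rms,
                    "converged": res.converged,
                    "scale": s,
                    "rotation_deg": res.transform.rotation_angle_deg(),
                    "|t|_mm": float(np.linalg.norm(tvec)),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        with np.printoptions(precision=4, suppress=True):
            head = self.summary().to_string(index=False, float_format=lambda x: f"{x:.4f}")
            return (
                "Two-step progressive registration\n"
                f"{head}\n"
                f"final transform (scale {self.scale:.4f}):\n{self.final.m}"
            )


class TSPRRegistration:
    """Two-step progressive registration model.

    Built from the atlas (moving) and subject (target) exterior-surface
    clouds together with the feature specifications of both steps; the
    atlas is always the moving set so the clinical data stay untouched.

    Parameters
    ----------
    atlas_surface, subject_surface
        Exterior-surface clouds (``PointCloud``), physical mm.
    atlas_grid, subject_grid
        Facial feature rectangles (:class:`FeatureGridSpec`), one per
        cloud, expressed in each cloud's own coordinates.
    atlas_band, subject_band
        Circular-contour slabs (:class:`BandSpec`) for the scale step.
    view_axis, atlas_side, subject_side
        Depth-map projection for the feature grids: the anterior-posterior
        axis and, per cloud, which side the face is seen from.
    cell_size
        Depth-map cell size in mm.
    """

    def __init__(
        self,
        atlas_surface: PointCloud,
        subject_surface: PointCloud,
        atlas_grid: FeatureGridSpec,
        subject_grid: FeatureGridSpec,
        atlas_band: BandSpec,
        subject_band: BandSpec,
        view_axis: str = "y",
        atlas_side: str = "low",
        subject_side: str = "low",
        cell_size: float = 1.0,
        patch_margin: float = 10.0,
    ) -> None:
        self.atlas_surface = atlas_surface
        self.subject_surface = subject_surface
        self.atlas_grid = atlas_grid
        self.subject_grid = subject_grid
        self.atlas_band = atlas_band
        self.subject_band = subject_band
        self.view_axis = view_axis
        self.atlas_side = atlas_side
        self.subject_side = subject_side
        self.cell_size = cell_size
        self.patch_margin = patch_margin

    @classmethod
    def from_surfaces(
        cls,
        atlas_surface: PointCloud,
        subject_surface: PointCloud,
        view_axis: str = "y",
        atlas_side: str = "low",
        subject_side: str = "low",
        cell_size: float = 1.0,
        band_below: float = 5.0,
        band_above: float = 30.0,
        band_margin: float = 15.0,
    ) -> "TSPRRegistration":
        """Build a model with nose-anchored feature windows.

        Each cloud's face rectangle and circular-contour band are placed
        relative to its own nose tip (the nearest-to-viewer point of the
        face-on depth map), standing in for the operator's interactive
        region selection.  The subject band is widened by ``band_margin``
        mm on each side so that the moving band, once scaled and tilted
        onto the subject, stays inside the target band (edge clamping
        would bias the scale step); the default covers ~10% head-size
        difference plus ~10 degrees of tilt.
        """
        da = project_depth(atlas_surface, view_axis, cell_size, atlas_side)
        ds = project_depth(subject_surface, view_axis, cell_size, subject_side)
        _, va, _ = nose_tip(da)
        _, vs, _ = nose_tip(ds)
        band_axis = {"y": "z", "z": "y", "x": "z"}[view_axis]
        return cls(
            atlas_surface,
            subject_surface,
            FeatureGridSpec(face_rect_from_nose(da)),
            FeatureGridSpec(face_rect_from_nose(ds)),
            BandSpec(band_axis, va - band_below, va + band_above),
            BandSpec(band_axis, vs - band_below - band_margin, vs + band_above + band_margin),
            view_axis=view_axis,
            atlas_side=atlas_side,
            subject_side=subject_side,
            cell_size=cell_size,
        )

    def _features(self):
        da = project_depth(self.atlas_surface, self.view_axis, self.cell_size, self.atlas_side)
        ds = project_depth(self.subject_surface, self.view_axis, self.cell_size, self.subject_side)
        fa, ids_a = sample_feature_grid(da, self.atlas_grid, return_node_ids=True)
        fs, ids_s = sample_feature_grid(ds, self.subject_grid, return_node_ids=True)
        if len(fa) < 3 or len(fs) < 3:
            raise ValueError("feature grids must yield at least 3 points each")
        # the target patch is expanded so that the moving patch, once
        # rotated/scaled onto it, never spills past the target's crop edge
        # (edge clamping would bias the fit)
        u0, v0, u1, v1 = self.subject_grid.rect
        m = self.patch_margin
        return (
            fa, ids_a, fs, ids_s,
            _patch(da, self.atlas_grid.rect),
            _patch(ds, (u0 - m, v0 - m, u1 + m, v1 + m)),
        )

    @staticmethod
    def _paired_init(fa, ids_a, fs, ids_s) -> HomogeneousTransform | None:
        """Closed-form rigid fit pairing grid nodes present in both grids."""
        common, ia, isub = np.intersect1d(ids_a, ids_s, return_indices=True)
        if len(common) < 3:
            return None
        try:
            return fit_rigid(fa.points[ia], fs.points[isub])
        except ValueError:  # collinear node subsets
            return None

    def fit(
        self,
        n_scale_steps: int = 1,
        max_iter: int = 100,
        tol: float = 1e-4,
    ) -> TSPRResults:
        """Run the two-step registration.

        ``n_scale_steps`` repeats the similarity (scale) step progressively;
        it is capped at ``MAX_SCALE_STEPS`` to guard against
        over-registration.
        """
        if n_scale_steps < 1:
            raise ValueError("n_scale_steps must be >= 1")
        if n_scale_steps > MAX_SCALE_STEPS:
            raise ValueError(
                f"n_scale_steps={n_scale_steps} exceeds the over-registration guard "
                f"({MAX_SCALE_STEPS})"
            )
        fa, ids_a, fs, ids_s, patch_a, patch_s = self._features()
        # Orientation step: the sampled grids are index-paired samples of
        # corresponding rectangles, so their closed-form rigid fit gives the
        # starting estimate (the headless counterpart of the operator's
        # coarse mouse alignment); rigid ICP over the dense eye-nose face
        # patches — the surface the grids discretely sample — then resolves
        # the tilt components the sparse grid cannot pin down.
        init = self._paired_init(fa, ids_a, fs, ids_s)
        res1 = icp(patch_a, patch_s, mode="rigid", max_iter=max_iter, tol=tol, init=init)
        m1 = res1.transform

        band_a = select_band(self.atlas_surface, self.atlas_band)
        band_s = select_band(self.subject_surface, self.subject_band)
        check_band_balance(band_a, band_s)

        accumulated = m1
        m2_list: list[HomogeneousTransform] = []
        step_results = [res1]
        for _ in range(n_scale_steps):
            moved = accumulated.apply(band_a.points)
            res = icp(moved, band_s, mode="similarity", max_iter=max_iter, tol=tol)
            m2_list.append(res.transform)
            step_results.append(res)
            accumulated = res.transform @ accumulated
        final = compose(m1, m2_list)
        return TSPRResults(
            m1, m2_list, final, step_results, (len(fa), len(fs)), (len(band_a), len(band_s))
        )


def tspr_register(
    atlas_surface: PointCloud,
    subject_surface: PointCloud,
    atlas_grid: FeatureGridSpec,
    subject_grid: FeatureGridSpec,
    atlas_band: BandSpec,
    subject_band: BandSpec,
    n_scale_steps: int = 1,
    **kwargs,
) -> TSPRResults:
    """Functional one-call form of :class:`TSPRRegistration`.

    Keyword arguments split between the model (``view_axis``,
    ``atlas_side``, ``subject_side``, ``cell_size``) and the ICP loop
    (``max_iter``, ``tol``).
    """
    fit_kw = {k: kwargs.pop(k) for k in ("max_iter", "tol") if k in kwargs}
    model = TSPRRegistration(
        atlas_surface, subject_surface, atlas_grid, subject_grid, atlas_band, subject_band,
        **kwargs,
    )
    return model.fit(n_scale_steps=n_scale_steps, **fit_kw)
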