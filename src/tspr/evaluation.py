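"""Atlas ROI mapping into subject space and recall-based scoring.

Once the final transform is known, every atlas structure can be carried
into the subject volume and compared against reference annotations.  The
score is the per-slice *recall*: on axial slice ``i``,

    recall_i = |mapped_i ∩ reference_i| / |reference_i|

with areas measured in voxels (numerator and denominator share the grid,
so the ratio is unit-free).  Slices with an empty reference are skipped.
The per-series summary reports max, min, median and mean recall and the
normal-approximation 95% confidence interval

    mean ± 1.96 * s / sqrt(n)

with ``s`` the sample (n−1) standard deviation; the interval is omitted
for series of fewer than two slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transforms import HomogeneousTransform
from .volumes import LabelVolume, Volume

__all__ = [
    "ROIMask",
    "RecallSeries",
    "RecallSummary",
    "map_roi",
    "recall_per_slice",
    "summarize_recall",
]


@dataclass
class ROIMask:
    """Boolean ROI support congruent with the subject volume grid."""

    grid: np.ndarray
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("ROI mask must be 3D")


def map_roi(
    labels: LabelVolume,
    roi_ids,
    t: HomogeneousTransform,
    subject: Volume,
    roi_name: str | None = None,
) -> ROIMask:
    """Map atlas labels into the subject grid through a transform.

    A subject voxel is inside the mapped ROI when its physical centre,
    pulled back through the *inverse* transform, lands (nearest-neighbour)
    on an atlas voxel carrying one of ``roi_ids``.  Pull-style resampling
    leaves no holes at scale factors away from 1, unlike pushing atlas
    voxels forward.  ``roi_ids`` may mix label ids and structure names.
    """
    ids = labels.ids_for_names(np.atleast_1d(roi_ids))
    if not ids:
        raise ValueError("roi_ids must be nonempty")
    nz, ny, nx = subject.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=False
    )
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    xyz = subject.index_to_physical(idx)
    atlas_vol = labels.as_volume()
    ijk = atlas_vol.physical_to_index(t.inverse().apply(xyz))
    ijk = np.rint(ijk).astype(int)
    inb = np.all((ijk >= 0) & (ijk < np.asarray(labels.shape)), axis=1)
    hit = np.zeros(len(ijk), dtype=bool)
    if inb.any():
        vals = labels.labels[ijk[inb, 0], ijk[inb, 1], ijk[inb, 2]]
        hit[inb] = np.isin(vals, ids)
    grid = hit.reshape(subject.shape)
    name = roi_name or "+".join(labels.table[i] for i in ids)
    if not grid.any():
        warnings.warn(f"ROI {name!r} maps entirely outside the subject volume", stacklevel=2)
    return ROIMask(grid, name)


@dataclass
class RecallSeries:
    """Per-slice recall values: parallel arrays of slice index and recall."""

    slices: np.ndarray
    recalls: np.ndarray

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=int)
        self.recalls = np.asarray(self.recalls, dtype=float)
        if self.slices.shape != self.recalls.shape or self.slices.ndim != 1:
            raise ValueError("slices and recalls must be parallel 1D arrays")
        if len(np.unique(self.slices)) != len(self.slices):
            raise ValueError("slice indices must be unique")
        if ((self.recalls < 0) | (self.recalls > 1)).any():
            raise ValueError("recall values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.slices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"slice": self.slices, "recall": self.recalls})


@dataclass
class RecallSummary:
    """Distribution summary of a recall series (values on [0, 1])."""

    max: float
    min: float
    median: float
    mean: float
    n: int
    ci95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {"max": self.max, "min": self.min, "median": self.median, "mean": self.mean,
             "n": self.n}
        if self.ci95 is not None:
            d["ci_lo"], d["ci_hi"] = self.ci95
        return d


def _grid(x) -> np.ndarray:
    return x.grid if isinstance(x, ROIMask) else np.asarray(x, dtype=bool)


def recall_per_slice(mapped, reference, slice_range=None) -> RecallSeries:
    """Per-slice recall of a mapped ROI against a reference ROI.

    Only slices whose reference area is positive contribute; restrict to
    ``slice_range=(lo, hi)`` (inclusive) to mirror an annotated layer
    range.
    """
    m, r = _grid(mapped), _grid(reference)
    if m.shape != r.shape:
        raise ValueError(f"mask shapes differ: {m.shape} vs {r.shape}")
    ref_area = r.sum(axis=(1, 2))
    slices = np.nonzero(ref_area > 0)[0]
    if slice_range is not None:
        lo, hi = slice_range
        slices = slices[(slices >= lo) & (slices <= hi)]
    if len(slices) == 0:
        raise ValueError("no slice with positive reference area")
    inter = (m[slices] & r[slices]).sum(axis=(1, 2))
    return RecallSeries(slices, inter / ref_area[slices])


def summarize_recall(series) -> RecallSummary:
    """Max/min/median/mean of a recall series plus the 95% CI.

    Accepts a :class:`RecallSeries` or any sequence of recall values.  The
    median is the middle order statistic (mean of the middle two for even
    n); the confidence interval uses the sample standard deviation and the
    fixed normal quantile 1.96, and is absent for n < 2.
    """
    vals = series.recalls if isinstance(series, RecallSeries) else np.asarray(series, float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty recall series")
    ci = None
    if vals.size >= 2:
        half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
        ci = (float(vals.mean() - half), float(vals.mean() + half))
    return RecallSummary(
        max=float(vals.max()),
        min=float(vals.min()),
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        n=int(vals.size),
        ci95=ci,
    )
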