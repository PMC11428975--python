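"""Point clouds in physical (x, y, z) millimetre coordinates."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PointCloud"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class PointCloud:
    """An (N, 3) set of points, optionally with per-point voxel provenance
    ``(slice, row, col)`` recording which contour voxel produced each point."""

    points: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance)
            if self.provenance.shape != self.points.shape:
                raise ValueError("provenance must be one (slice, row, col) triple per point")

    def __len__(self) -> int:
        return len(self.points)

    def axis(self, name: str) -> np.ndarray:
        return self.points[:, _AXES[name]]

    def select(self, mask: np.ndarray) -> "PointCloud":
        prov = None if self.provenance is None else self.provenance[mask]
        return PointCloud(self.points[mask], prov)

    def transformed(self, t) -> "PointCloud":
        return PointCloud(t.apply(self.points), self.provenance)

    # -- CSV interchange (x,y,z header, mm) -------------------------------
    def to_csv(self, path) -> None:
        header = "x,y,z"
        np.savetxt(Path(path), self.points, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "PointCloud":
        pts = np.loadtxt(Path(path), delimiter=",", skiprows=1, ndmin=2)
        return cls(pts[:, :3])
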