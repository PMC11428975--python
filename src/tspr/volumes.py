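"""Volumes, label volumes, I/O and isotropic resampling.

Conventions used throughout the package:

* arrays are indexed ``(slice, row, col)`` = ``(z, y, x)``, 0-based;
* physical coordinates are ``(x, y, z)`` in millimetres;
* voxel centres sit at ``origin + index * spacing``: voxel ``(i, j, k)``
  maps to ``origin + (k * dx, j * dy, i * dz)``.

Volumes round-trip through NIfTI (via nibabel) or through a directory of
equally-sized greyscale PNG slices accompanied by a JSON spacing sidecar
(``spacing.json`` with keys ``dz``, ``dy``, ``dx``).  PNG slices are stacked
in ascending lexicographic filename order.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "resample_isotropic",
    "resample_labels_isotropic",
]

INTENSITY_KINDS = ("ct_hu", "mr_arbitrary", "photo_grey")

_SIDECAR = "spacing.json"


@dataclass
class Volume:
    """A 3D scalar grid with per-axis physical spacing and origin.

    Parameters
    ----------
    data
        3D array indexed ``(slice, row, col)``.
    spacing
        ``(dz, dy, dx)`` in mm, all strictly positive.
    origin
        Physical ``(x, y, z)`` of voxel ``(0, 0, 0)``, mm.
    intensity_kind
        One of ``ct_hu`` (Hounsfield units), ``mr_arbitrary``, ``photo_grey``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = "mr_arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive numbers, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.intensity_kind not in INTENSITY_KINDS:
            raise ValueError(f"intensity_kind must be one of {INTENSITY_KINDS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (i, j, k) to (N, 3) physical (x, y, z)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        dz, dy, dx = self.spacing
        xyz = np.column_stack([idx[:, 2] * dx, idx[:, 1] * dy, idx[:, 0] * dz])
        xyz += np.asarray(self.origin)
        return xyz[0] if np.ndim(indices) == 1 else xyz

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_physical`; returns fractional (i, j, k)."""
        p = np.atleast_2d(np.asarray(xyz, dtype=float)) - np.asarray(self.origin)
        dz, dy, dx = self.spacing
        ijk = np.column_stack([p[:, 2] / dz, p[:, 1] / dy, p[:, 0] / dx])
        return ijk[0] if np.ndim(xyz) == 1 else ijk


@dataclass
class LabelVolume:
    """Integer-labelled grid congruent with a :class:`Volume`.

    Label 0 is background; every nonzero id present in the grid must appear
    in ``table`` (id -> structure name).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    table: dict[int, str]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label grid must have an integer dtype")
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.table = {int(k): str(v) for k, v in self.table.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} present in grid but absent from table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids_for_names(self, names) -> list[int]:
        """Resolve structure names (or ids) to label ids, case-insensitively."""
        by_name = {v.lower(): k for k, v in self.table.items()}
        out = []
        for n in names:
            if isinstance(n, (int, np.integer)):
                if int(n) not in self.table:
                    raise KeyError(
                        f"unknown label id {n}; available: {sorted(self.table.items())}"
                    )
                out.append(int(n))
            elif str(n).lower() in by_name:
                out.append(by_name[str(n).lower()])
            else:
                raise KeyError(
                    f"unknown structure {n!r}; available: {sorted(self.table.values())}"
                )
        return out

    def as_volume(self) -> Volume:
        return Volume(self.labels, self.spacing, self.origin, "mr_arbitrary")


# ---------------------------------------------------------------------------
# I/O


def _affine(v) -> np.ndarray:
    dz, dy, dx = v.spacing
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = v.origin
    return aff


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz).

    The array is stored in (x, y, z) order with a diagonal affine carrying
    spacing and origin, so the grid, spacing and origin round-trip.
    """
    path = Path(path)
    img = nib.Nifti1Image(np.ascontiguousarray(v.data.transpose(2, 1, 0)), _affine(v))
    img.header["descrip"] = f"intensity_kind={v.intensity_kind}".encode()
    nib.save(img, str(path))


def _read_nifti(path: Path, spacing_override, intensity_kind):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    aff = img.affine
    dx, dy, dz = (float(np.linalg.norm(aff[:3, k])) for k in range(3))
    spacing = spacing_override or (dz, dy, dx)
    origin = tuple(float(o) for o in aff[:3, 3])
    if intensity_kind is None:
        m = re.search(rb"intensity_kind=(\w+)", bytes(img.header["descrip"].tobytes()))
        intensity_kind = m.group(1).decode() if m else "mr_arbitrary"
    return Volume(data, spacing, origin, intensity_kind)


def _read_png_stack(path: Path, spacing_override, intensity_kind):
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise FileNotFoundError(f"no PNG slices found in {path}")
    spacing = spacing_override
    if spacing is None:
        sidecar = path / _SIDECAR
        if not sidecar.exists():
            raise FileNotFoundError(
                f"PNG stack {path} has no {_SIDECAR} sidecar and no spacing override"
            )
        meta = json.loads(sidecar.read_text())
        try:
            spacing = (float(meta["dz"]), float(meta["dy"]), float(meta["dx"]))
        except KeyError as exc:
            raise KeyError(f"{sidecar} must define dz, dy and dx") from exc
    slices = []
    for f in files:
        arr = np.asarray(Image.open(f).convert("F"))
        if slices and arr.shape != slices[0].shape:
            raise ValueError(
                f"inconsistent slice dimensions: {f.name} is {arr.shape}, "
                f"expected {slices[0].shape}"
            )
        slices.append(arr)
    return Volume(np.stack(slices), spacing, (0.0, 0.0, 0.0), intensity_kind or "photo_grey")


def read_volume(path, spacing_override=None, intensity_kind=None) -> Volume:
    """Read a NIfTI file or a directory of greyscale PNG slices.

    PNG stacks are ordered by ascending filename and require a
    ``spacing.json`` sidecar (keys ``dz``, ``dy``, ``dx``) unless
    ``spacing_override`` is given; an explicit override always wins.
    """
    path = Path(path)
    if path.is_dir():
        return _read_png_stack(path, spacing_override, intensity_kind)
    return _read_nifti(path, spacing_override, intensity_kind)


def write_label_volume(lv: LabelVolume, path, table_path=None) -> None:
    """Write labels as integer NIfTI, and the id->name table as 2-column CSV
    next to it (``<stem>_table.csv``) unless ``table_path`` is given."""
    path = Path(path)
    write_volume(Volume(lv.labels.astype(np.int32), lv.spacing, lv.origin), path)
    if table_path is None:
        stem = path.name[: -len("".join(path.suffixes))] if path.suffixes else path.name
        table_path = path.with_name(stem + "_table.csv")
    lines = ["id,name"] + [f"{k},{v}" for k, v in sorted(lv.table.items())]
    Path(table_path).write_text("\n".join(lines) + "\n")


def read_label_volume(path, table_path=None) -> LabelVolume:
    path = Path(path)
    v = read_volume(path)
    if table_path is None:
        stem = path.name[: -len("".join(path.suffixes))] if path.suffixes else path.name
        table_path = path.with_name(stem + "_table.csv")
    table = {}
    for line in Path(table_path).read_text().splitlines()[1:]:
        if line.strip():
            k, name = line.split(",", 1)
            table[int(k)] = name.strip()
    return LabelVolume(np.rint(v.data).astype(np.int32), v.spacing, table, v.origin)


# ---------------------------------------------------------------------------
# Resampling


def _iso_grid(shape, spacing, target):
    # output spans the closed extent between first and last voxel centres
    new_shape, coords = [], []
    for n, sp in zip(shape, spacing):
        extent = (n - 1) * sp
        m = int(np.floor(extent / target + 1e-9)) + 1
        new_shape.append(m)
        coords.append(np.arange(m) * (target / sp))
    return tuple(new_shape), coords


def resample_isotropic(v: Volume, target_spacing: float, order: int = 1) -> Volume:
    """Resample to equal spacing on all axes over the same physical extent.

    The output grid runs from the first to the last input voxel centre
    (closed extent, no extrapolation) with ``floor(extent / spacing) + 1``
    samples per axis.  Interpolation is linear by default; pass ``order=0``
    for nearest-neighbour (label grids).
    """
    if not (np.isfinite(target_spacing) and target_spacing > 0):
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    new_shape, axes = _iso_grid(v.shape, v.spacing, float(target_spacing))
    grid = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=float), np.stack(grid), order=order, mode="nearest"
    )
    if np.issubdtype(v.data.dtype, np.integer) and order == 0:
        out = np.rint(out).astype(v.data.dtype)
    return Volume(out, (target_spacing,) * 3, v.origin, v.intensity_kind)


def resample_labels_isotropic(lv: LabelVolume, target_spacing: float) -> LabelVolume:
    """Nearest-neighbour isotropic resampling of a label grid."""
    v = resample_isotropic(lv.as_volume(), target_spacing, order=0)
    labels = np.rint(v.data).astype(lv.labels.dtype)
    present = set(np.unique(labels).tolist()) - {0}
    dropped = set(lv.table) - present
    if dropped:
        warnings.warn(f"labels {sorted(dropped)} vanished during resampling", stacklevel=2)
    return LabelVolume(labels, v.spacing, lv.table, v.origin)
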