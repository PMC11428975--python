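"""Homogeneous 4x4 transforms and closed-form point-set fits.

The registration pipeline works entirely in physical (x, y, z) millimetre
coordinates with the column-vector convention: a point ``p`` is augmented to
``(x, y, z, 1)`` and mapped by left-multiplication with the 4x4 matrix.  Two
transform classes are supported:

* *rigid* — upper-left 3x3 block is a proper rotation (``det R = +1``);
* *similarity* — upper-left block is ``s * R`` with one uniform scale
  ``s > 0``.

The closed-form least-squares fits are the classical absolute-orientation
solutions: Horn's unit-quaternion method and the Kabsch/Umeyama SVD method
(with the reflection guard), which agree to machine precision on
non-degenerate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HomogeneousTransform",
    "compose",
    "fit_rigid",
    "fit_similarity",
]


@dataclass(frozen=True)
class HomogeneousTransform:
    """A 4x4 homogeneous transform; the last row is always [0, 0, 0, 1]."""

    m: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row of a homogeneous transform must be [0, 0, 0, 1]")
        m = m.copy()
        m[3] = (0.0, 0.0, 0.0, 1.0)
        m.flags.writeable = False
        object.__setattr__(self, "m", m)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "HomogeneousTransform":
        return cls(np.eye(4))

    @classmethod
    def from_parts(
        cls,
        rotation: np.ndarray,
        translation: np.ndarray,
        scale: float = 1.0,
    ) -> "HomogeneousTransform":
        """Build ``p -> scale * R @ p + t``."""
        m = np.eye(4)
        m[:3, :3] = float(scale) * np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def translation(cls, t) -> "HomogeneousTransform":
        return cls.from_parts(np.eye(3), t)

    # -- action -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array (or a single 3-vector) of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[-1] != 3:
            raise ValueError("points must have 3 coordinates")
        out = pts @ self.m[:3, :3].T + self.m[:3, 3]
        return out[0] if np.ndim(points) == 1 else out

    def __matmul__(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        """Matrix product: ``(A @ B).apply(p) == A.apply(B.apply(p))``."""
        return HomogeneousTransform(self.m @ other.m)

    def inverse(self) -> "HomogeneousTransform":
        a = self.m[:3, :3]
        t = self.m[:3, 3]
        a_inv = np.linalg.inv(a)
        out = np.eye(4)
        out[:3, :3] = a_inv
        out[:3, 3] = -a_inv @ t
        return HomogeneousTransform(out)

    # -- decomposition ----------------------------------------------------
    def decompose_similarity(self, atol: float = 1e-3) -> tuple[float, np.ndarray, np.ndarray]:
        """Split into (scale, rotation, translation); requires ``A = s R``.

        The scale is recovered as ``det(A) ** (1/3)`` (positive for a valid
        similarity) and the rotation is checked for orthonormality within
        ``atol`` — loose enough by default to accept matrices printed at a
        few decimals.
        """
        a = self.m[:3, :3]
        det = np.linalg.det(a)
        if det <= 0:
            raise ValueError("linear block has non-positive determinant; not a similarity")
        s = det ** (1.0 / 3.0)
        r = a / s
        if not np.allclose(r @ r.T, np.eye(3), atol=atol):
            raise ValueError("linear block is not a uniform scaling of a rotation")
        return s, r, self.m[:3, 3].copy()

    @property
    def scale(self) -> float:
        return self.decompose_similarity()[0]

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        _, r, _ = self.decompose_similarity()
        c = (np.trace(r) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        with np.printoptions(precision=4, suppress=True):
            return f"HomogeneousTransform(\n{self.m}\n)"


def compose(first: HomogeneousTransform, rest) -> HomogeneousTransform:
    """Compose transforms in order of *action*: apply ``first``, then each
    element of ``rest`` in sequence.

    Under the column-vector convention this is the reversed matrix product
    ``rest[-1] @ ... @ rest[0] @ first``.
    """
    out = first
    for t in rest:
        out = t @ out
    return out


def _check_paired(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.ndim != 2 or moving.shape[1] != 3 or target.shape != moving.shape:
        raise ValueError(
            f"paired point sets must both be (N, 3); got {moving.shape} and {target.shape}"
        )
    if len(moving) < 3:
        raise ValueError("at least 3 point pairs are required")
    return moving, target


def _weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be a nonnegative length-N vector with positive sum")
    return w / w.sum()


def _cross_covariance(moving, target, w):
    cm = w @ moving
    ct = w @ target
    dm = moving - cm
    dt = target - ct
    # Sigma maps moving deviations to target deviations: dt ~ R @ dm
    sigma = (dt * w[:, None]).T @ dm
    var_m = float(np.sum(w * np.einsum("ij,ij->i", dm, dm)))
    return cm, ct, sigma, var_m


def _rotation_svd(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(sigma)
    if s[1] <= max(s[0], 1.0) * 1e-9:
        raise ValueError("degenerate (collinear or coincident) point configuration")
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:  # pragma: no cover - guarded by the rank check
        raise ValueError("degenerate point configuration")
    corr = np.diag([1.0, 1.0, d])
    return u @ corr @ vt, s * np.diag(corr)


def _rotation_quaternion(sigma: np.ndarray) -> np.ndarray:
    """Horn's method: the optimal rotation is the eigenvector of the 4x4
    symmetric matrix built from the cross-covariance with the largest
    eigenvalue, read as a unit quaternion (w, x, y, z).

    Horn's derivation accumulates moving x target; our ``sigma`` maps
    moving deviations to target deviations (target x moving), hence the
    transpose.
    """
    sigma = sigma.T
    a = sigma - sigma.T
    delta = np.array([a[1, 2], a[2, 0], a[0, 1]])
    n = np.empty((4, 4))
    n[0, 0] = np.trace(sigma)
    n[0, 1:] = delta
    n[1:, 0] = delta
    n[1:, 1:] = sigma + sigma.T - np.trace(sigma) * np.eye(3)
    vals, vecs = np.linalg.eigh(n)
    w, x, y, z = vecs[:, np.argmax(vals)]
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def fit_rigid(
    moving: np.ndarray,
    target: np.ndarray,
    weights=None,
    method: str = "svd",
) -> HomogeneousTransform:
    """Least-squares rigid transform mapping ``moving`` onto ``target``.

    Points are paired by index.  ``method`` selects the quaternion
    eigen-solution (``"quaternion"``) or SVD Procrustes with the reflection
    guard (``"svd"``); the two agree to machine precision.  The returned
    rotation always has determinant +1 (mirror-image inputs yield the best
    proper rotation, never a reflection).
    """
    moving, target = _check_paired(moving, target)
    w = _weights(weights, len(moving))
    cm, ct, sigma, _ = _cross_covariance(moving, target, w)
    if method == "svd":
        r, _ = _rotation_svd(sigma)
    elif method == "quaternion":
        _rotation_svd(sigma)  # rank / degeneracy check
        r = _rotation_quaternion(sigma)
    else:
        raise ValueError(f"unknown method {method!r}")
    t = ct - r @ cm
    return HomogeneousTransform.from_parts(r, t)


def fit_similarity(
    moving: np.ndarray,
    target: np.ndarray,
    weights=None,
) -> HomogeneousTransform:
    """Least-squares uniform-scale similarity transform (Umeyama).

    Solves ``min_{s, R, t} sum_i w_i || s R m_i + t - t_i ||^2`` with one
    global scale ``s > 0``.
    """
    moving, target = _check_paired(moving, target)
    w = _weights(weights, len(moving))
    cm, ct, sigma, var_m = _cross_covariance(moving, target, w)
    if var_m <= 0:
        raise ValueError("moving point set has zero variance; scale is undefined")
    r, s_corr = _rotation_svd(sigma)
    s = float(np.sum(s_corr)) / var_m
    if s <= 0:
        raise ValueError("estimated scale is non-positive; degenerate configuration")
    t = ct - s * (r @ cm)
    return HomogeneousTransform.from_parts(r, t, scale=s)
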