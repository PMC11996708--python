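"""Rigid transforms and right-handed coordinate frames.

All world coordinates are millimetres.  A :class:`Frame` stores its axes as
*rows* (row 0 = X, row 1 = Y, row 2 = Z, unit vectors in world coordinates);
the referential wrist frame has X pointing radially, Y proximally and Z
dorsally.  A :class:`RigidTransform` maps neutral-configuration points to
posed-configuration points: ``x' = R x + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ORTHO_TOL = 1e-9


def _check_rotation(matrix: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {matrix.shape}")
    if not np.allclose(matrix.T @ matrix, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if not np.isclose(np.linalg.det(matrix), 1.0, atol=tol):
        raise ValueError("matrix is not a proper rotation (det != +1)")
    return matrix


def orthonormalize(matrix: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (closest in Frobenius norm)."""
    u, _, vt = np.linalg.svd(np.asarray(matrix, dtype=float))
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        u[:, -1] *= -1
        rot = u @ vt
    return rot


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        return cls(matrix[:3, :3], matrix[:3, 3])

    @classmethod
    def about_point(cls, rotation: np.ndarray, point: np.ndarray,
                    extra_translation: np.ndarray | None = None) -> "RigidTransform":
        """Rotation about ``point`` followed by an optional translation."""
        rotation = np.asarray(rotation, dtype=float)
        point = np.asarray(point, dtype=float)
        t = point - rotation @ point
        if extra_translation is not None:
            t = t + np.asarray(extra_translation, dtype=float)
        return cls(rotation, t)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            orthonormalize(self.rotation @ other.rotation),
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass(frozen=True)
class Frame:
    """Origin plus right-handed orthonormal axis triad (rows X, Y, Z)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        axes = np.asarray(self.axes, dtype=float)
        _check_rotation(axes.T, tol=1e-8)  # rows orthonormal
        if np.linalg.det(axes) < 0:
            raise ValueError("frame is left-handed (det = -1)")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.zeros(3), np.eye(3))

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express world points in this frame's coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.axes + self.origin

    def express_transform(self, transform: RigidTransform) -> RigidTransform:
        """Re-express a world-coordinate rigid motion in this frame.

        If ``T`` maps world points ``x -> R x + t``, the same motion acting on
        frame coordinates ``ξ = B (x - o)`` is the conjugated transform
        ``ξ -> B R Bᵀ ξ + B (R o + t - o)`` with ``B`` the axis rows.
        """
        b = self.axes
        rot = orthonormalize(b @ transform.rotation @ b.T)
        t = b @ (transform.rotation @ self.origin + transform.translation - self.origin)
        return RigidTransform(rot, t)


def rot_x(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_AXIS_ROT = {"x": rot_x, "y": rot_y, "z": rot_z}


def axis_rotation(axis: str, deg: float) -> np.ndarray:
    """Rotation matrix about a referential axis ('x', 'y' or 'z')."""
    try:
        return _AXIS_ROT[axis.lower()](deg)
    except KeyError:
        raise ValueError(f"unknown axis {axis!r}") from None
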