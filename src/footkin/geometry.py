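"""Small rigid-body geometry helpers shared by the skeleton and contact modules.

Conventions: right-handed lab frame with X anterior (toe direction), Y medial
(for a right foot) and Z up; lengths in meters, angles in radians.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError

__all__ = [
    "rodrigues",
    "compose_axis_rotations",
    "is_rotation",
    "polar_rotation",
    "EllipsoidSurface",
]


def rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for ``angle`` radians about unit ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (3,):
        raise DimensionError(f"axis must be a 3-vector, got shape {axis.shape}")
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    k = axis / np.linalg.norm(axis)
    K = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def compose_axis_rotations(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Compose ordered rotations about ``axes`` (first axis applied first).

    ``R = R(a_0, th_0) @ R(a_1, th_1) @ ...`` — intrinsic composition: each
    later axis is interpreted in the already-rotated frame.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if axes.shape[0] != angles.shape[0]:
        raise DimensionError(
            f"{axes.shape[0]} axes but {angles.shape[0]} angles"
        )
    R = np.eye(3)
    for ax, th in zip(axes, angles):
        R = R @ rodrigues(ax, th)
    return R


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    """True if ``R`` is orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
    )


def polar_rotation(A: np.ndarray) -> np.ndarray:
    """Rotation factor of the polar decomposition ``A = R S`` (det(A) > 0)."""
    U, _, Vt = np.linalg.svd(np.asarray(A, dtype=float))
    R = U @ Vt
    if np.linalg.det(R) < 0:  # proper rotation only
        U = U.copy()
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


@dataclass
class EllipsoidSurface:
    """An ellipsoid in its owning segment's frame.

    ``center`` (m), ``semi_axes`` (three strictly positive lengths, m) and an
    orthonormal ``orientation`` whose columns are the principal directions.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if not np.all(self.semi_axes > 0):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if not is_rotation(self.orientation, tol=1e-9):
            raise ValueError("ellipsoid orientation must be orthonormal (det +1)")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "EllipsoidSurface":
        """The same surface expressed after the rigid motion ``x -> R x + t``."""
        return EllipsoidSurface(
            center=np.asarray(R) @ self.center + np.asarray(t),
            semi_axes=self.semi_axes.copy(),
            orientation=np.asarray(R) @ self.orientation,
        )

    def surface_point(self, direction: np.ndarray) -> np.ndarray:
        """Surface point in the radial ``direction`` (need not be unit)."""
        d = np.asarray(direction, dtype=float)
        u = d / np.linalg.norm(d)
        return self.center + self.orientation @ (self.semi_axes * u)

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "semi_axes": self.semi_axes.tolist(),
            "orientation": self.orientation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipsoidSurface":
        return cls(
            center=np.array(d["center"], dtype=float),
            semi_axes=np.array(d["semi_axes"], dtype=float),
            orientation=np.array(d.get("orientation", np.eye(3)), dtype=float),
        )
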