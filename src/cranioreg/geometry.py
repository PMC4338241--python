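"""Rigid transforms, landmark sets and analytic region descriptors.

Everything is expressed in millimetres in a right-handed frame
(x = left->right, y = posterior->anterior, z = inferior->superior).
Rigid transforms carry a proper rotation (det = +1, no scaling) and a
translation; they map points of a moving frame into a reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "LandmarkSet",
    "Ball",
    "CappedCylinder",
    "rotation_angle_deg",
]


def _as_point(x) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {p.shape}")
    return p


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t`` (rotation + translation, no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_point(self.translation)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal (tol 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a rotation vector in degrees and a translation in mm."""
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        return cls(R, translation)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        max_rotation_deg: float,
        max_translation_mm: float,
    ) -> "RigidTransform":
        """Sample uniformly: axis uniform on the sphere, angle ~ U[0, max],
        translation direction uniform, magnitude ~ U[0, max]."""
        if max_rotation_deg < 0 or max_translation_mm < 0:
            raise ValueError("bounds must be nonnegative")
        axis = rng.normal(size=3)
        n = np.linalg.norm(axis)
        axis = axis / n if n > 0 else np.array([1.0, 0.0, 0.0])
        angle = rng.uniform(0.0, max_rotation_deg)
        tdir = rng.normal(size=3)
        n = np.linalg.norm(tdir)
        tdir = tdir / n if n > 0 else np.array([1.0, 0.0, 0.0])
        tmag = rng.uniform(0.0, max_translation_mm)
        return cls.from_rotvec(axis * angle, tdir * tmag)

    # -- algebra -----------------------------------------------------
    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        return rotation_angle_deg(self.rotation)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return np.allclose(self.rotation, other.rotation, atol=atol) and np.allclose(
            self.translation, other.translation, atol=atol
        )


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic rotation angle of a rotation matrix, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


class LandmarkSet(dict):
    """Named anatomical points (name -> 3-vector in mm). A thin dict subclass."""

    def __init__(self, points=None):
        super().__init__()
        if points:
            for k, v in dict(points).items():
                self[k] = _as_point(v)

    def __setitem__(self, key, value):
        super().__setitem__(key, _as_point(value))

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: transform.apply(v) for k, v in self.items()})

    def as_array(self, names=None) -> np.ndarray:
        names = list(self.keys()) if names is None else list(names)
        return np.array([self[n] for n in names], dtype=float)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self)


# ---------------------------------------------------------------------------
# Analytic region descriptors (ball / capped cylinder) used both for the
# phantom's reference atlas and for face selection on meshes.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ball:
    center: np.ndarray
    radius: float
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return np.linalg.norm(pts - self.center, axis=1) <= self.radius

    def transformed(self, transform: RigidTransform) -> "Ball":
        return Ball(transform.apply(self.center), self.radius, self.label)

    def with_radius_scale(self, scale: float) -> "Ball":
        return Ball(self.center, self.radius * scale, self.label)

    @property
    def reference_point(self) -> np.ndarray:
        return self.center


@dataclass(frozen=True)
class CappedCylinder:
    """Solid cylinder between axis endpoints ``p0`` and ``p1`` with given radius."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "p0", _as_point(self.p0))
        object.__setattr__(self, "p1", _as_point(self.p1))
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if np.allclose(self.p0, self.p1):
            raise ValueError("cylinder axis endpoints coincide")

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        axis = self.p1 - self.p0
        L2 = axis @ axis
        s = (pts - self.p0) @ axis / L2
        foot = self.p0 + np.outer(s, axis)
        radial = np.linalg.norm(pts - foot, axis=1)
        return (s >= 0.0) & (s <= 1.0) & (radial <= self.radius)

    def transformed(self, transform: RigidTransform) -> "CappedCylinder":
        return CappedCylinder(
            transform.apply(self.p0), transform.apply(self.p1), self.radius, self.label
        )

    def with_radius_scale(self, scale: float) -> "CappedCylinder":
        return CappedCylinder(self.p0, self.p1, self.radius * scale, self.label)

    @property
    def reference_point(self) -> np.ndarray:
        return 0.5 * (self.p0 + self.p1)
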