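"""Spatial transforms: rigid maps, dense displacement fields and chains.

A transform maps reference-space world coordinates (mm) to template-space
world coordinates.  Chains apply their entries in list order; the empty chain
is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import Volume3D
from .errors import GeometryError

__all__ = [
    "RigidTransform",
    "DeformationField",
    "TransformChain",
    "compose",
    "euler_to_matrix",
]


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _drx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[0, 0, 0], [0, -s, -c], [0, c, -s]])


def _dry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0, c], [0, 0, 0], [-c, 0, -s]])


def _drz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, -c, 0], [c, -s, 0], [0, 0, 0]])


def euler_to_matrix(angles) -> np.ndarray:
    """Rotation matrix for intrinsic XYZ Euler angles (radians)."""
    a, b, g = angles
    return _rx(a) @ _ry(b) @ _rz(g)


def euler_matrix_derivatives(angles) -> list[np.ndarray]:
    """d(R)/d(angle_k) for intrinsic XYZ Euler angles."""
    a, b, g = angles
    return [
        _drx(a) @ _ry(b) @ _rz(g),
        _rx(a) @ _dry(b) @ _rz(g),
        _rx(a) @ _ry(b) @ _drz(g),
    ]


def matrix_to_euler(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix` (gimbal-safe for |b| < pi/2)."""
    b = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
    if abs(np.cos(b)) > 1e-9:
        a = np.arctan2(-R[1, 2], R[2, 2])
        g = np.arctan2(-R[0, 1], R[0, 0])
    else:  # degenerate: fold everything into the first angle
        a = np.arctan2(R[2, 1], R[1, 1])
        g = 0.0
    return np.array([a, b, g])


@dataclass
class RigidTransform:
    """Translation + rotation about a fixed world center.

    Maps ``p -> center + R (p - center) + translation`` with ``R`` the
    intrinsic XYZ Euler rotation.  Translation in mm, angles in radians.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.rotation)

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        p = pts.reshape(-1, 3)
        out = self.center + (p - self.center) @ self.matrix.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        """Exact closed-form inverse, same center."""
        R = self.matrix
        Rinv = R.T
        # inverse map: q -> center + Rinv (q - center) - Rinv t
        return RigidTransform(
            translation=-Rinv @ self.translation,
            rotation=matrix_to_euler(Rinv),
            center=self.center,
        )

    def is_identity(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.translation, 0, atol=atol) and np.allclose(
            self.rotation, 0, atol=atol
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass
class DeformationField:
    """Dense displacement field ``p -> p + u(p)`` on a regular node grid.

    ``displacements`` has shape (3, n0, n1, n2) in mm; grid geometry
    (``spacing``, ``origin``, ``direction``) matches the pyramid level the
    field was solved on.  Off-grid evaluation interpolates trilinearly;
    points outside the grid take the nearest-border displacement.
    """

    displacements: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[0] != 3:
            raise GeometryError("displacements must have shape (3, n0, n1, n2)")
        if not np.all(np.isfinite(self.displacements)):
            raise GeometryError("displacement field must be finite")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[1:]

    def displacement_at(self, pts) -> np.ndarray:
        """Interpolated displacement (mm) at world points (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        p = pts.reshape(-1, 3)
        idx = ((p - self.origin) @ self.direction) / self.spacing
        coords = idx.T  # (3, N)
        u = np.stack(
            [
                map_coordinates(self.displacements[c], coords, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )
        return u[0] if single else u

    def apply(self, pts) -> np.ndarray:
        return np.asarray(pts, dtype=float) + self.displacement_at(pts)

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.displacements**2).sum(axis=0)).max())

    def approximate_inverse(self, iterations: int = 20) -> "DeformationField":
        """Fixed-point inverse: find w with w(x) = -u(x + w(x)).

        Converges for smooth fields with displacement gradients below 1;
        adequate for the gentle deformations this package targets.
        """
        pts = _grid_points(self)
        w = np.zeros_like(pts)
        for _ in range(iterations):
            w = -self.displacement_at(pts + w)
        disp = w.T.reshape(self.displacements.shape)
        return DeformationField(
            displacements=disp,
            spacing=self.spacing,
            origin=self.origin,
            direction=self.direction,
        )

    @classmethod
    def zeros_like_grid(cls, vol: Volume3D) -> "DeformationField":
        return cls(
            displacements=np.zeros((3, *vol.shape)),
            spacing=vol.spacing,
            origin=vol.origin,
            direction=vol.direction,
        )


class TransformChain:
    """Ordered sequence of rigid transforms and deformation fields.

    Entries are applied in list order; the empty chain is the identity map.
    """

    def __init__(self, steps=None):
        self.steps: list = list(steps) if steps is not None else []

    def __len__(self):
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def append(self, step):
        self.steps.append(step)

    def apply(self, pts) -> np.ndarray:
        """Map world points (..., 3) through every step in order."""
        out = np.asarray(pts, dtype=float)
        for step in self.steps:
            out = step.apply(out)
        return out

    def then(self, other: "TransformChain") -> "TransformChain":
        return TransformChain(self.steps + list(other.steps))


def _grid_points(f: DeformationField) -> np.ndarray:
    idx = np.indices(f.grid_shape).reshape(3, -1).T
    return f.origin + (idx * f.spacing) @ f.direction.T


def compose(chain: TransformChain, point) -> np.ndarray:
    """Apply ``chain`` to one point or an array of points (world mm)."""
    return chain.apply(point)
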