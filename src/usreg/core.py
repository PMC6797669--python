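"""Core domain types: volumes, masks and landmark sets.

Geometry convention
-------------------
All world coordinates are expressed in a single fixed LPS millimetre frame
(the native frame of ITK-style headers).  Voxel indices are 0-based and
node-centered: the world position of index ``i = (i0, i1, i2)`` is

    world(i) = origin + direction @ (spacing * i)

Arrays are stored index-order ``(i0, i1, i2)`` matching the (x, y, z) axes of
the direction matrix, i.e. ``data[i, j, k]`` sits at ``world((i, j, k))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import CorrespondenceError, GeometryError

__all__ = ["Volume3D", "Mask3D", "LandmarkSet", "same_geometry"]


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {v.size}")
    return v


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (n0, n1, n2)
        Scalar intensities (arbitrary units). Stored as float32 for floating
        input, integer dtypes kept as-is.
    spacing : array-like of 3 floats
        Voxel edge lengths in mm, all positive.
    origin : array-like of 3 floats
        World position (mm) of voxel index (0, 0, 0).
    direction : array-like, shape (3, 3), optional
        Orthonormal axis-direction matrix with determinant +1 (identity by
        default).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype.kind == "f" and self.data.dtype != np.float32:
            self.data = self.data.astype(np.float32)
        if self.data.ndim != 3:
            raise GeometryError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 2:
            raise GeometryError("volume needs >= 2 samples per axis")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix is not orthonormal")
        if np.linalg.det(self.direction) < 0:
            raise GeometryError("direction matrix must have determinant +1")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def world_to_index(self, pts) -> np.ndarray:
        """Map world points (..., 3) to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing

    def grid_world_points(self) -> np.ndarray:
        """World coordinates of every voxel, shape (n0*n1*n2, 3), C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.index_to_world(idx)

    def same_geometry_as(self, other: "Volume3D | Mask3D", atol: float = 1e-6) -> bool:
        return same_geometry(self, other, atol=atol)

    def copy_geometry(self) -> dict:
        return {
            "spacing": self.spacing.copy(),
            "origin": self.origin.copy(),
            "direction": self.direction.copy(),
        }


@dataclass
class Mask3D(Volume3D):
    """A binary or probability grid congruent with a source :class:`Volume3D`.

    ``kind='binary'`` data contains only {0, 1}; ``kind='probability'`` data
    lies in [0, 1].
    """

    kind: Literal["binary", "probability"] = "binary"

    def __post_init__(self):
        super().__post_init__()
        d = self.data
        if self.kind == "binary":
            vals = np.unique(d)
            if not np.all(np.isin(vals, (0, 1))):
                raise GeometryError("binary mask contains values other than {0, 1}")
        else:
            if d.min() < -1e-6 or d.max() > 1 + 1e-6:
                raise GeometryError("probability mask values must lie in [0, 1]")

    @classmethod
    def like(cls, ref: Volume3D, data: np.ndarray, kind: str = "binary") -> "Mask3D":
        """Build a mask sharing ``ref``'s geometry."""
        return cls(
            data=data,
            spacing=ref.spacing,
            origin=ref.origin,
            direction=ref.direction,
            kind=kind,
        )

    def binarize(self, threshold: float = 0.5) -> "Mask3D":
        return Mask3D.like(self, (np.asarray(self.data) >= threshold).astype(np.uint8), kind="binary")

    @property
    def volume_mm3(self) -> float:
        return float(np.sum(self.data > 0.5)) * self.voxel_volume


def same_geometry(a: Volume3D, b: Volume3D, atol: float = 1e-6) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
        and np.allclose(a.direction, b.direction, atol=atol)
    )


def require_same_geometry(a: Volume3D, b: Volume3D, what: str = "operands"):
    if not same_geometry(a, b):
        raise GeometryError(f"{what} have mismatched geometry")


@dataclass
class LandmarkSet:
    """An ordered list of world-coordinate points (mm).

    Point order is the correspondence key: the i-th point of one set matches
    the i-th point of its paired set.
    """

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("landmark coordinates must be finite")
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != len(self.points):
                raise CorrespondenceError("labels and points differ in length")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @classmethod
    def from_points(cls, pts: Sequence, labels=None) -> "LandmarkSet":
        return cls(points=np.asarray(pts, dtype=float), labels=labels)


def require_paired(a: LandmarkSet, b: LandmarkSet):
    """Raise unless the two sets can be put in index correspondence."""
    if len(a) != len(b):
        raise CorrespondenceError(
            f"paired landmark sets differ in size: {len(a)} vs {len(b)}"
        )
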