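"""Voxel phantom and analytic source-capsule geometry.

Coordinates are right-handed and in cm.  Voxel ``(i, j, k)`` occupies the
half-open box ``[origin + i*spacing, origin + (i+1)*spacing)`` with 0-based
indices; the same convention is shared by dose grids and by the ray
traversal in :mod:`brachymc.tallies`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "VoxelPhantom", "SourceCapsule", "rotation_between"]


@dataclass(frozen=True)
class GridGeometry:
    """Shape/spacing/origin metadata shared by phantoms and dose grids."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # cm
    origin: tuple[float, float, float]  # cm, corner of voxel (0,0,0)

    def __post_init__(self):
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> np.ndarray:
        """(2, 3) array: lower and upper corners, cm."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return np.stack([lo, hi])

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (self.origin[axis]
                + (np.arange(n) + 0.5) * self.spacing[axis])

    def center_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.voxel_centers(a) for a in range(3)),
                           indexing="ij")

    def voxel_of(self, point) -> tuple[int, int, int] | None:
        """Index of the voxel containing ``point``, or None if outside."""
        p = np.asarray(point, dtype=float)
        idx = np.floor((p - np.asarray(self.origin))
                       / np.asarray(self.spacing)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            return None
        return tuple(int(i) for i in idx)

    @staticmethod
    def centered(shape, spacing) -> "GridGeometry":
        """Grid of given shape/spacing centered on the origin."""
        shape = tuple(int(n) for n in np.atleast_1d(shape) * np.ones(3, int))
        spacing = tuple(float(s)
                        for s in np.atleast_1d(spacing) * np.ones(3))
        origin = tuple(-n * s / 2 for n, s in zip(shape, spacing))
        return GridGeometry(shape, spacing, origin)


@dataclass
class VoxelPhantom:
    """Material-id + density grids with spacing/origin metadata."""

    geometry: GridGeometry
    material_ids: np.ndarray  # (nx, ny, nz) int, indexes ``materials``
    densities: np.ndarray  # (nx, ny, nz) g/cm3
    materials: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.material_ids = np.ascontiguousarray(self.material_ids,
                                                 dtype=np.int32)
        self.densities = np.ascontiguousarray(self.densities, dtype=np.float64)
        if self.material_ids.shape != self.geometry.shape:
            raise ValueError("material grid shape mismatch")
        if self.densities.shape != self.geometry.shape:
            raise ValueError("density grid shape mismatch")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be > 0")
        if self.material_ids.min() < 0 or (
                self.materials
                and self.material_ids.max() >= len(self.materials)):
            raise ValueError("material id outside the material list")

    @property
    def voxel_volume(self) -> float:
        return self.geometry.voxel_volume

    @staticmethod
    def homogeneous(geometry: GridGeometry, material: str,
                    density: float) -> "VoxelPhantom":
        return VoxelPhantom(
            geometry=geometry,
            material_ids=np.zeros(geometry.shape, dtype=np.int32),
            densities=np.full(geometry.shape, density),
            materials=[material],
        )


def rotation_between(a, b) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto ``b``.

    Rotation about the axis normal to both (identity if parallel; a flip
    about a perpendicular axis if anti-parallel).
    """
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # anti-parallel: rotate pi about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


@dataclass
class SourceCapsule:
    """Analytic HDR source: active core + coaxial capsule + cable stub.

    The capsule axis is local +z; the core is centered on the local origin.
    ``position``/``rotation`` place the local frame in the world; rotation
    maps local coordinates to world coordinates.
    """

    core_radius: float  # cm
    core_half_length: float  # cm
    capsule_radius: float  # cm (outer)
    capsule_half_length: float  # cm (outer, includes end caps)
    core_material: str = "iridium"
    capsule_material: str = "steel316"
    cable_radius: float = 0.0  # cm; 0 disables the cable
    cable_length: float = 0.0  # cm, extends in -z below the capsule
    cable_material: str = "steel316"
    core_density: float | None = None  # g/cm3; None -> material nominal
    capsule_density: float | None = None
    cable_density: float | None = None
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    name: str = "capsule"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        for v in (self.core_radius, self.core_half_length,
                  self.capsule_radius, self.capsule_half_length):
            if v <= 0:
                raise ValueError("capsule dimensions must be > 0")
        if (self.core_radius >= self.capsule_radius
                or self.core_half_length >= self.capsule_half_length):
            raise ValueError("core must lie strictly inside the capsule")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    @property
    def bounding_radius(self) -> float:
        """Radius of a local-frame sphere containing all solids."""
        zmax = max(self.capsule_half_length,
                   self.capsule_half_length + self.cable_length)
        return float(np.hypot(max(self.capsule_radius, self.cable_radius),
                              zmax))

    def region_at_local(self, p) -> str | None:
        """'core' | 'capsule' | 'cable' | None for a local-frame point."""
        x, y, z = p
        r2 = x * x + y * y
        if (r2 <= self.core_radius**2
                and abs(z) <= self.core_half_length):
            return "core"
        if (r2 <= self.capsule_radius**2
                and abs(z) <= self.capsule_half_length):
            return "capsule"
        if (self.cable_radius > 0.0 and r2 <= self.cable_radius**2
                and -self.capsule_half_length - self.cable_length <= z
                <= -self.capsule_half_length):
            return "cable"
        return None

    def to_world(self, p_local) -> np.ndarray:
        return self.rotation @ np.asarray(p_local, float) + self.position

    def params_array(self) -> np.ndarray:
        """Flat parameter vector consumed by the transport kernels."""
        return np.array([
            self.core_radius, self.core_half_length,
            self.capsule_radius, self.capsule_half_length,
            self.cable_radius, self.cable_length,
        ])

    def placed(self, position, rotation=None, name=None) -> "SourceCapsule":
        """Copy of this capsule at a new position/orientation."""
        out = SourceCapsule(
            core_radius=self.core_radius,
            core_half_length=self.core_half_length,
            capsule_radius=self.capsule_radius,
            capsule_half_length=self.capsule_half_length,
            core_material=self.core_material,
            capsule_material=self.capsule_material,
            cable_radius=self.cable_radius,
            cable_length=self.cable_length,
            cable_material=self.cable_material,
            core_density=self.core_density,
            capsule_density=self.capsule_density,
            cable_density=self.cable_density,
            position=np.asarray(position, float),
            rotation=np.eye(3) if rotation is None else rotation,
            name=self.name if name is None else name,
        )
        return out
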