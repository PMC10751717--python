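"""Clinical-pipeline stages: contour-based material assignment with
intensity-range segmentation, full-scatter shell padding, and cumulative
dose-volume histograms with the standard prostate/OAR metrics.

Structures are stacks of closed planar polygons in patient coordinates
(one or more polygons per grid slice plane).  Membership is evaluated at
voxel centers (no partial-volume weighting), matching voxel-level DVH
granularity.  Structure/material rules are applied in listed order with
later rules overwriting earlier ones, so list the default body rule first
and more specific structures after it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import GridGeometry, VoxelPhantom
from .materials import load_material

__all__ = [
    "Structure", "StructureSet", "MaterialRule", "DVHCurve", "DVHMetrics",
    "point_in_polygon", "structure_mask", "assign_materials",
    "add_scatter_shell", "cumulative_dvh", "dvh_metrics",
    "structures_to_json", "structures_from_json",
]


@dataclass
class Structure:
    """One contoured volume: closed planar polygons stacked in z."""

    name: str
    contours: list[tuple[float, np.ndarray]]  # (z_cm, (N,2) xy polygon cm)
    role: str = "target"  # target | oar | body | bone

    def __post_init__(self):
        cleaned = []
        for z, poly in self.contours:
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
                raise ValueError(
                    f"structure {self.name!r}: polygon needs >= 3 xy points")
            # drop an explicit closing point; closure is implicit
            if np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            cleaned.append((float(z), poly))
        self.contours = cleaned


@dataclass
class StructureSet:
    structures: list[Structure] = field(default_factory=list)

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]


def point_in_polygon(px: np.ndarray, py: np.ndarray,
                     poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray casting) point-in-polygon test."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = ((y1 > py) != (y2 > py))
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def structure_mask(structure: Structure,
                   geometry: GridGeometry) -> np.ndarray:
    """Voxel-center membership mask of a structure on a grid.

    Contours are matched to the grid slice planes (z axis) within half a
    slice spacing; multiple polygons on one slice combine by union.
    """
    mask = np.zeros(geometry.shape, dtype=bool)
    zc = geometry.voxel_centers(2)
    xs = geometry.voxel_centers(0)
    ys = geometry.voxel_centers(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    tol = geometry.spacing[2] / 2.0
    for z, poly in structure.contours:
        k = int(np.argmin(np.abs(zc - z)))
        if abs(zc[k] - z) > tol + 1e-9:
            continue  # contour plane not on this grid
        mask[:, :, k] |= point_in_polygon(gx, gy, poly)
    return mask


@dataclass
class MaterialRule:
    """Material assignment for one structure (or the whole grid).

    ``structure=None`` applies everywhere (the default body rule).
    ``intensity_ranges`` optionally re-assigns voxels inside the structure
    whose image intensity falls in [lo, hi) — e.g. a cortical-bone
    threshold inside the body contour.
    """

    structure: str | None
    material: str
    density: float | None = None  # None -> material nominal
    intensity_ranges: list[tuple[float, float, str, float | None]] = field(
        default_factory=list)


def assign_materials(intensity: np.ndarray, geometry: GridGeometry,
                     structures: StructureSet,
                     rules: list[MaterialRule]) -> VoxelPhantom:
    """Segmentation: contour membership plus intensity-range thresholds.

    Rules are applied in order (later rules overwrite earlier ones).
    Raises if any voxel is matched by no rule.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != geometry.shape:
        raise ValueError("intensity grid shape mismatch")
    mat_names: list[str] = []

    def mat_id(name: str) -> int:
        if name not in mat_names:
            mat_names.append(name)
        return mat_names.index(name)

    ids = np.full(geometry.shape, -1, dtype=np.int32)
    rho = np.zeros(geometry.shape)
    for rule in rules:
        if rule.structure is None:
            sel = np.ones(geometry.shape, dtype=bool)
        else:
            sel = structure_mask(structures[rule.structure], geometry)
        dens = rule.density or load_material(rule.material).density
        ids[sel] = mat_id(rule.material)
        rho[sel] = dens
        for lo, hi, mname, mdens in rule.intensity_ranges:
            sub = sel & (intensity >= lo) & (intensity < hi)
            ids[sub] = mat_id(mname)
            rho[sub] = mdens or load_material(mname).density
    unmatched = int((ids < 0).sum())
    if unmatched:
        raise ValueError(
            f"{unmatched} voxels matched by no material rule and outside "
            "the body; add a default body rule")
    return VoxelPhantom(geometry=geometry, material_ids=ids, densities=rho,
                        materials=mat_names)


def add_scatter_shell(phantom: VoxelPhantom, thickness: float,
                      material: str = "water",
                      density: float | None = None) -> VoxelPhantom:
    """Pad the phantom on all faces by ``thickness`` cm of ``material``.

    Ensures full scatter conditions around the imaged volume; the scoring
    region (a separate grid) is unchanged.  The pad is rounded up to whole
    voxels per axis.
    """
    if thickness < 0:
        raise ValueError("shell thickness must be >= 0")
    if thickness == 0:
        return phantom
    g = phantom.geometry
    pads = [int(np.ceil(thickness / s - 1e-9)) for s in g.spacing]
    new_shape = tuple(n + 2 * p for n, p in zip(g.shape, pads))
    new_origin = tuple(o - p * s
                       for o, p, s in zip(g.origin, pads, g.spacing))
    mats = list(phantom.materials)
    if material not in mats:
        mats.append(material)
    mid = mats.index(material)
    dens = density or load_material(material).density
    ids = np.full(new_shape, mid, dtype=np.int32)
    rho = np.full(new_shape, dens)
    sl = tuple(slice(p, p + n) for p, n in zip(pads, g.shape))
    ids[sl] = phantom.material_ids
    rho[sl] = phantom.densities
    return VoxelPhantom(
        geometry=GridGeometry(new_shape, g.spacing, new_origin),
        material_ids=ids, densities=rho, materials=mats)


# ---------------------------------------------------------------------------
# Dose-volume histograms
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction (%) receiving at least each dose."""

    dose_gy: np.ndarray
    volume_pct: np.ndarray
    voxel_volume: float  # cm3
    n_voxels: int
    structure: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.volume_pct) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")
        if abs(self.volume_pct[0] - 100.0) > 1e-9:
            raise ValueError("cumulative DVH must start at 100% at 0 Gy")

    @property
    def total_volume(self) -> float:
        return self.voxel_volume * self.n_voxels

    def volume_at(self, dose: float) -> float:
        """Volume fraction (%) receiving >= ``dose`` Gy (step lookup)."""
        idx = np.searchsorted(self.dose_gy, dose, side="right") - 1
        if idx < 0:
            return 100.0
        if idx >= len(self.volume_pct):
            return 0.0
        return float(self.volume_pct[idx])

    def dose_at(self, volume_pct: float) -> float:
        """Greatest dose received by at least ``volume_pct`` % (linear
        interpolation on the inverse curve)."""
        v = self.volume_pct
        d = self.dose_gy
        if volume_pct > v[0]:
            return 0.0
        # v is non-increasing; walk from the high-dose end
        return float(np.interp(volume_pct, v[::-1], d[::-1]))


def cumulative_dvh(dose_gy: np.ndarray, structure_mask: np.ndarray,
                   voxel_volume: float, resolution: float = 0.01,
                   structure: str = "") -> DVHCurve:
    """Cumulative DVH of a structure from a dose grid in Gy."""
    vals = np.asarray(dose_gy, dtype=float)[np.asarray(structure_mask,
                                                       dtype=bool)]
    if vals.size == 0:
        raise ValueError(f"structure {structure!r} is empty on this grid")
    dmax = float(vals.max())
    levels = np.arange(0.0, dmax + 2 * resolution, resolution)
    frac = np.array([(vals >= d).sum() for d in levels],
                    dtype=float) / vals.size * 100.0
    return DVHCurve(dose_gy=levels, volume_pct=frac,
                    voxel_volume=voxel_volume, n_voxels=int(vals.size),
                    structure=structure)


@dataclass
class DVHMetrics:
    v100: float  # % of volume receiving >= 100% of prescription
    v150: float
    v200: float
    d90: float  # Gy, minimum dose to the hottest 90% of the volume
    d50: float
    d2cc: float | None  # Gy; None when the structure is smaller than 2 cm3


def dvh_metrics(curve: DVHCurve, prescription: float) -> DVHMetrics:
    """Standard DVH indexes from a cumulative curve.

    Vx = volume % receiving at least x% of the prescription;
    Dy = greatest dose received by at least y% of the volume;
    D2cc = greatest dose received by at least 2 cm3 (undefined, with a
    flag, for structures smaller than 2 cm3).
    """
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    v100 = curve.volume_at(1.00 * prescription)
    v150 = curve.volume_at(1.50 * prescription)
    v200 = curve.volume_at(2.00 * prescription)
    d90 = curve.dose_at(90.0)
    d50 = curve.dose_at(50.0)
    if curve.total_volume < 2.0:
        d2cc = None
    else:
        d2cc = curve.dose_at(100.0 * 2.0 / curve.total_volume)
    return DVHMetrics(v100=v100, v150=v150, v200=v200, d90=d90, d50=d50,
                      d2cc=d2cc)


# ---------------------------------------------------------------------------
# Structure JSON dialect (mm at the file boundary, like DICOM RTSTRUCT)
# ---------------------------------------------------------------------------

def structures_to_json(sset: StructureSet, path) -> None:
    doc = {
        "format_version": 1,
        "kind": "brachymc-structures",
        "structures": [
            {
                "name": s.name, "role": s.role,
                "contours": [
                    {"z_mm": z * 10.0,
                     "points_mm": (poly * 10.0).tolist()}
                    for z, poly in s.contours
                ],
            } for s in sset.structures
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def structures_from_json(path) -> StructureSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "brachymc-structures":
        raise ValueError(f"{path}: not a brachymc structure file")
    if doc.get("format_version", 1) > 1:
        raise ValueError(f"{path}: structure format newer than supported")
    out = []
    for s in doc["structures"]:
        contours = [(c["z_mm"] / 10.0, np.asarray(c["points_mm"]) / 10.0)
                    for c in s["contours"]]
        out.append(Structure(name=s["name"], contours=contours,
                             role=s.get("role", "target")))
    return StructureSet(structures=out)
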