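"""Scoring machinery: track-length kerma estimator, analogue kerma scorer,
cylindrical cells and history-by-history Type A uncertainty.

The track-length kerma estimator (TLKE) scores, for every straight photon
flight segment, ``w * l * E * (muen/rho)(E, voxel material) / V`` in each
traversed voxel (eV/g per history): collisional kerma via the equivalence
of fluence and path length per unit volume.  The analogue scorer instead
deposits the energy transferred to electrons at the interaction voxel only.
Both are unbiased estimators of collisional kerma; the TLKE converges much
faster because every crossing photon contributes.

Collisional kerma approximates absorbed dose only under charged-particle
equilibrium; for Ir-192 this holds beyond about 2 mm from a source, so
voxels closer than that carry a metadata flag rather than being masked.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .geometry import GridGeometry

__all__ = [
    "TrackSegment", "DoseGrid", "CylinderCell", "TallySet",
    "siddon_traverse", "tlke_score", "analogue_score",
    "finalize_uncertainty", "cell_tlke", "CPE_FLAG_RADIUS_CM",
]

#: radius within which kerma != dose is not guaranteed (CPE caveat)
CPE_FLAG_RADIUS_CM = 0.2


@dataclass(frozen=True)
class TrackSegment:
    """Length of one ray inside one voxel."""

    voxel: tuple[int, int, int]
    length: float  # cm

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("segment length must be >= 0")


def siddon_traverse(p0, p1, geometry: GridGeometry) -> list[TrackSegment]:
    """Exact per-voxel chord lengths of the segment ``p0 -> p1``.

    Voxels outside the grid are skipped; ordering follows the ray.  Voxel
    attribution on shared planes follows the half-open box convention;
    corner grazes produce zero-length segments which are dropped.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0.0:
        return []
    u = d / length
    lo, hi = geometry.extent
    t0, t1 = 0.0, length
    for ax in range(3):
        if abs(u[ax]) < 1e-15:
            if not (lo[ax] <= p0[ax] < hi[ax]):
                return []
        else:
            ta = (lo[ax] - p0[ax]) / u[ax]
            tb = (hi[ax] - p0[ax]) / u[ax]
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
    if t0 >= t1:
        return []
    # all plane crossings inside (t0, t1)
    ts = [t0, t1]
    org = np.asarray(geometry.origin)
    sp = np.asarray(geometry.spacing)
    for ax in range(3):
        if abs(u[ax]) < 1e-15:
            continue
        xa = p0[ax] + u[ax] * t0
        xb = p0[ax] + u[ax] * t1
        ia = int(np.ceil((min(xa, xb) - org[ax]) / sp[ax]))
        ib = int(np.floor((max(xa, xb) - org[ax]) / sp[ax]))
        for i in range(ia, ib + 1):
            t = (org[ax] + i * sp[ax] - p0[ax]) / u[ax]
            if t0 < t < t1:
                ts.append(t)
    ts = sorted(ts)
    segs = []
    shape = geometry.shape
    for a, b in zip(ts[:-1], ts[1:]):
        seg = b - a
        if seg <= 1e-14 * length:
            continue  # corner graze
        mid = p0 + u * (0.5 * (a + b))
        idx = np.floor((mid - org) / sp).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
            continue
        segs.append(TrackSegment(tuple(int(i) for i in idx), seg))
    return segs


@dataclass
class DoseGrid:
    """Per-voxel kerma accumulators over histories (eV/g per history).

    Uses history-by-history accumulation: scores of one history are pooled
    in ``history_buffer`` (tagged by history id) and flushed into the
    ``sum`` / ``sum_sq`` accumulators when the next history touches the
    voxel, so correlated contributions (splitting progeny, multiple
    crossings) are grouped into one statistical unit.
    """

    geometry: GridGeometry
    materials: list[str] = field(default_factory=lambda: ["water"])
    material_ids: np.ndarray | None = None
    densities: np.ndarray | None = None
    accum_sum: np.ndarray = None
    accum_sum_sq: np.ndarray = None
    history_buffer: np.ndarray = None
    history_tag: np.ndarray = None
    n_histories: int = 0

    def __post_init__(self):
        shape = self.geometry.shape
        if self.material_ids is None:
            self.material_ids = np.zeros(shape, dtype=np.int32)
        self.material_ids = np.ascontiguousarray(self.material_ids,
                                                 dtype=np.int32)
        if self.densities is not None:
            self.densities = np.ascontiguousarray(self.densities,
                                                  dtype=np.float64)
        for name in ("accum_sum", "accum_sum_sq", "history_buffer"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape))
        if self.history_tag is None:
            self.history_tag = np.full(shape, -1, dtype=np.int64)

    @property
    def voxel_volume(self) -> float:
        return self.geometry.voxel_volume

    def _score(self, idx, value, history):
        i = np.ravel_multi_index(idx, self.geometry.shape)
        K.score_tagged(self.accum_sum.ravel(), self.accum_sum_sq.ravel(),
                       self.history_buffer.ravel(),
                       self.history_tag.ravel(), int(i), float(value),
                       int(history))

    def flush(self):
        """Fold any open history buffers into the accumulators."""
        K.flush_tagged(self.accum_sum.ravel(), self.accum_sum_sq.ravel(),
                       self.history_buffer.ravel(),
                       self.history_tag.ravel())

    def cpe_flag(self, source_positions) -> np.ndarray:
        """Voxels whose center lies within the CPE caveat radius of any
        source position (kerma-equals-dose not guaranteed there)."""
        xs, ys, zs = self.geometry.center_grid()
        flag = np.zeros(self.geometry.shape, dtype=bool)
        for p in np.atleast_2d(source_positions):
            r2 = (xs - p[0]) ** 2 + (ys - p[1]) ** 2 + (zs - p[2]) ** 2
            flag |= r2 < CPE_FLAG_RADIUS_CM**2
        return flag


def tlke_score(grid: DoseGrid, segments: list[TrackSegment], energy: float,
               weight: float, muen_lookup, history: int = 0) -> DoseGrid:
    """Track-length kerma contribution of one flight (eV/g).

    ``muen_lookup(material_name, energy)`` must return muen/rho in cm2/g.
    """
    inv_v = 1.0 / grid.voxel_volume
    for seg in segments:
        mat = grid.materials[grid.material_ids[seg.voxel]]
        muen = muen_lookup(mat, energy)
        grid._score(seg.voxel,
                    weight * seg.length * energy * muen * inv_v * 1000.0,
                    history)
    return grid


def analogue_score(grid: DoseGrid, point, energy_transferred: float,
                   weight: float, history: int = 0) -> DoseGrid:
    """Analogue deposit of the transferred energy at the interaction voxel."""
    if grid.densities is None:
        raise ValueError("analogue scoring needs per-voxel densities")
    idx = grid.geometry.voxel_of(point)
    if idx is None:
        return grid
    rho = grid.densities[idx]
    grid._score(idx,
                weight * energy_transferred * 1000.0
                / (rho * grid.voxel_volume), history)
    return grid


def finalize_uncertainty(grid: DoseGrid, coverage_factor: int = 1):
    """Per-voxel mean, standard error and relative Type A uncertainty.

    Returns ``(mean, relative_uncertainty, annotation)`` with the relative
    uncertainty scaled by ``coverage_factor`` (k=1 default, k=2 available);
    voxels with zero mean carry NaN relative uncertainty.
    """
    n = grid.n_histories
    if n < 2:
        raise ValueError("uncertainty undefined for fewer than 2 histories")
    grid.flush()
    mean = grid.accum_sum / n
    var = np.maximum(grid.accum_sum_sq - grid.accum_sum**2 / n, 0.0) / (n - 1)
    se = np.sqrt(var / n) * coverage_factor
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean > 0, se / np.where(mean > 0, mean, 1.0), np.nan)
    return mean, rel, f"k={coverage_factor}"


@dataclass
class CylinderCell:
    """Coaxial ring/cylinder scoring cell (axis = capsule z at the origin)."""

    inner_radius: float  # cm
    outer_radius: float  # cm
    half_height: float  # cm
    material: str = "air"

    def __post_init__(self):
        if not (self.outer_radius > self.inner_radius >= 0.0):
            raise ValueError("cell needs outer > inner >= 0")
        if self.half_height <= 0:
            raise ValueError("cell height must be > 0")

    @property
    def volume(self) -> float:
        return float(np.pi * (self.outer_radius**2 - self.inner_radius**2)
                     * 2.0 * self.half_height)

    def chord(self, p0, direction, length: float) -> float:
        """Exact chord of a straight segment inside the cell, cm."""
        p0 = np.asarray(p0, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        return float(K.ring_chord(p0[0], p0[1], p0[2], d[0], d[1], d[2],
                                  float(length), self.inner_radius**2,
                                  self.outer_radius**2, self.half_height))


def cell_tlke(cell: CylinderCell, p0, direction, length: float,
              energy: float, weight: float, muen_lookup) -> float:
    """TLKE contribution (eV/g) of one ray to a cylindrical cell."""
    chord = cell.chord(p0, direction, length)
    if chord == 0.0:
        return 0.0
    muen = muen_lookup(cell.material, energy)
    return weight * chord * energy * muen / cell.volume * 1000.0


@dataclass
class TallySet:
    """Bundle of tallies attached to a transport run."""

    tlke: DoseGrid | None = None
    analogue: DoseGrid | None = None
    cells: list[CylinderCell] = field(default_factory=list)
    cell_scores: np.ndarray | None = None
    muen_lookup: object = None

    def __post_init__(self):
        if self.cells and self.cell_scores is None:
            self.cell_scores = np.zeros(len(self.cells))
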