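"""Source-term machinery: capsule emission, phase-space files and the
dwell-plan source with time-weighted sampling and particle splitting.

A treatment plan is a set of dwell positions (point + orientation + dwell
time, grouped into catheters).  The plan source replays a phase-space file
(PSF) recorded at the capsule surface: each PSF record is split into
``split_factor`` clones of weight ``1/split_factor``, and each clone is
independently assigned a dwell position sampled with probability
proportional to dwell time, then rigidly transformed there.  All clones of
one record form one statistical history.

Plan files are a documented JSON dialect mirroring DICOM RTPLAN fields
(catheters -> control points with positions in mm and dwell times);
positions are converted to cm at the file boundary.
"""
from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import SourceCapsule, rotation_between
from .materials import EmissionSpectrum, sample_emission
from .transport import Photon

__all__ = [
    "PhaseSpaceRecord", "DwellPosition", "Plan", "PsfFormatError",
    "emit_primary", "psf_write", "psf_read", "dwell_weights",
    "plan_source_next", "catheter_orientation", "load_source_config",
    "plan_to_json", "plan_from_json", "plan_kernel_arrays",
]

_PSF_MAGIC = b"BPSF"
_PSF_VERSION = 1
_REC = struct.Struct("<8f")  # energy, weight, x, y, z, ux, uy, uz


class PsfFormatError(ValueError):
    """Corrupt or inconsistent phase-space file."""


@dataclass(frozen=True)
class PhaseSpaceRecord:
    """One stored particle at the capsule reference surface (local frame)."""

    energy: float  # keV
    position: tuple[float, float, float]  # cm
    direction: tuple[float, float, float]
    weight: float = 1.0

    def __post_init__(self):
        if self.energy < 1.0:
            raise ValueError("record energy below the 1 keV cut-off")
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-5:
            raise ValueError("record direction must be a unit vector")


@dataclass
class DwellPosition:
    """One stopping point of the stepping source."""

    position: np.ndarray  # cm, patient/phantom frame
    orientation: np.ndarray  # 3x3, maps capsule axis (+z) to the tangent
    dwell_time: float  # s
    catheter_id: str = "cath-1"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.dwell_time < 0:
            raise ValueError("dwell time must be >= 0")
        if not np.allclose(self.orientation @ self.orientation.T,
                           np.eye(3), atol=1e-6):
            raise ValueError("orientation must be orthonormal")


@dataclass
class Plan:
    """Dwell positions plus prescription for absolute normalization."""

    dwells: list[DwellPosition]
    prescription_dose: float  # Gy
    prescription_point: np.ndarray  # cm
    total_reference_air_kerma: float | None = None  # U*s (uGy m2)
    name: str = "plan"

    def __post_init__(self):
        self.prescription_point = np.asarray(self.prescription_point,
                                             dtype=float)
        if not self.dwells or all(d.dwell_time <= 0 for d in self.dwells):
            raise ValueError("plan needs at least one dwell with time > 0")

    @property
    def total_time(self) -> float:
        return float(sum(d.dwell_time for d in self.dwells))

    @property
    def catheters(self) -> dict[str, list[DwellPosition]]:
        out: dict[str, list[DwellPosition]] = {}
        for d in self.dwells:
            out.setdefault(d.catheter_id, []).append(d)
        return out


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def emit_primary(capsule: SourceCapsule, spectrum: EmissionSpectrum,
                 rng: np.random.Generator) -> Photon:
    """Primary photon: uniform in the core volume, isotropic, weight 1.

    Position/direction are in the capsule local frame.
    """
    r = capsule.core_radius * np.sqrt(rng.random())
    phi = 2 * np.pi * rng.random()
    z = (2 * rng.random() - 1) * capsule.core_half_length
    w = 2 * rng.random() - 1
    sphi = 2 * np.pi * rng.random()
    rho = np.sqrt(max(0.0, 1 - w * w))
    return Photon(
        position=np.array([r * np.cos(phi), r * np.sin(phi), z]),
        direction=np.array([rho * np.cos(sphi), rho * np.sin(sphi), w]),
        energy=sample_emission(spectrum, rng),
        weight=1.0,
    )


# ---------------------------------------------------------------------------
# Phase-space files: versioned binary, little-endian fixed-width records
# ---------------------------------------------------------------------------

def psf_write(records, path, capsule_id: str = "unknown",
              spectrum_id: str = "ir192", n_primaries: int = 0,
              seed: int = 0) -> None:
    """Write records (iterable of PhaseSpaceRecord) with a versioned header."""
    records = list(records)
    header = json.dumps({
        "format_version": _PSF_VERSION, "capsule_id": capsule_id,
        "spectrum_id": spectrum_id, "n_primaries": int(n_primaries),
        "n_records": len(records), "seed": int(seed),
    }).encode()
    with open(path, "wb") as f:
        f.write(_PSF_MAGIC)
        f.write(struct.pack("<HI", _PSF_VERSION, len(header)))
        f.write(header)
        for r in records:
            f.write(_REC.pack(r.energy, r.weight, *r.position, *r.direction))


def psf_read(path):
    """Read a phase-space file -> (records, header dict); validates layout."""
    raw = Path(path).read_bytes()
    if raw[:4] != _PSF_MAGIC:
        raise PsfFormatError(f"{path}: bad magic at offset 0")
    ver, hlen = struct.unpack_from("<HI", raw, 4)
    if ver > _PSF_VERSION:
        raise PsfFormatError(
            f"{path}: format version {ver} newer than supported "
            f"{_PSF_VERSION}")
    try:
        header = json.loads(raw[10:10 + hlen].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise PsfFormatError(f"{path}: corrupt header at offset 10: {exc}")
    body = raw[10 + hlen:]
    if len(body) % _REC.size:
        raise PsfFormatError(
            f"{path}: truncated record at offset {10 + hlen + len(body) - len(body) % _REC.size}")
    n = len(body) // _REC.size
    if n != header.get("n_records", n):
        raise PsfFormatError(
            f"{path}: header declares {header['n_records']} records, "
            f"file holds {n}")
    records = []
    for i in range(n):
        e, w, x, y, z, ux, uy, uz = _REC.unpack_from(body, i * _REC.size)
        records.append(PhaseSpaceRecord(e, (x, y, z), (ux, uy, uz), w))
    return records, header


# ---------------------------------------------------------------------------
# Dwell-plan sampling
# ---------------------------------------------------------------------------

def dwell_weights(plan: Plan) -> np.ndarray:
    """Per-dwell sampling probability: dwell time / total time."""
    times = np.array([d.dwell_time for d in plan.dwells], dtype=float)
    total = times.sum()
    if total <= 0:
        raise ValueError("all dwell times are zero")
    return times / total


def plan_source_next(plan: Plan, psf_stream, split_factor: int,
                     rng: np.random.Generator):
    """Next batch of photons for one PSF record (one statistical history).

    Reads one record from ``psf_stream`` (an iterator of
    PhaseSpaceRecord); emits ``split_factor`` clones of weight
    ``w/split_factor``, each independently assigned a dwell position and
    rigidly transformed.  Raises StopIteration when the stream is
    exhausted.
    """
    if split_factor < 1:
        raise ValueError("split factor must be >= 1")
    rec = next(psf_stream)
    weights = dwell_weights(plan)
    out = []
    for _ in range(split_factor):
        d = plan.dwells[rng.choice(len(plan.dwells), p=weights)]
        pos = d.orientation @ np.asarray(rec.position) + d.position
        direction = d.orientation @ np.asarray(rec.direction)
        out.append(Photon(position=pos, direction=direction,
                          energy=rec.energy,
                          weight=rec.weight / split_factor))
    return out


def catheter_orientation(dwell_positions) -> list[np.ndarray]:
    """Orientations along one catheter from its dwell positions.

    The catheter tangent at each dwell is the central difference of the
    neighbouring dwell positions (one-sided at the ends); the orientation
    is the minimal rotation taking the capsule axis (+z) onto the tangent.
    """
    pts = [np.asarray(p, dtype=float) for p in dwell_positions]
    if len(pts) < 2:
        raise ValueError("need at least 2 dwells to define a tangent")
    rots = []
    for i in range(len(pts)):
        a = pts[max(0, i - 1)]
        b = pts[min(len(pts) - 1, i + 1)]
        tangent = b - a
        norm = np.linalg.norm(tangent)
        if norm < 1e-12:
            raise ValueError(
                f"coincident neighbouring dwells around index {i}: "
                "tangent undefined")
        rots.append(rotation_between([0.0, 0.0, 1.0], tangent / norm))
    return rots


def plan_kernel_arrays(plan: Plan):
    """(cumulative weights, positions, flat rotations) for the kernels."""
    w = dwell_weights(plan)
    cum = np.cumsum(w)
    cum[-1] = 1.0
    pos = np.stack([d.position for d in plan.dwells])
    rot = np.stack([d.orientation.ravel() for d in plan.dwells])
    return cum, pos, rot


# ---------------------------------------------------------------------------
# Plan JSON dialect (positions in mm, like DICOM RTPLAN; cm internally)
# ---------------------------------------------------------------------------

def plan_to_json(plan: Plan, path) -> None:
    doc = {
        "format_version": 1,
        "kind": "brachymc-plan",
        "name": plan.name,
        "prescription": {
            "dose_gy": plan.prescription_dose,
            "point_mm": (plan.prescription_point * 10.0).tolist(),
        },
        "total_reference_air_kerma_uGy_m2":
            plan.total_reference_air_kerma,
        "catheters": [
            {
                "id": cid,
                "control_points": [
                    {
                        "position_mm": (d.position * 10.0).tolist(),
                        "orientation": d.orientation.tolist(),
                        "dwell_time_s": d.dwell_time,
                    } for d in dwells
                ],
            } for cid, dwells in plan.catheters.items()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def plan_from_json(path) -> Plan:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") != "brachymc-plan":
        raise ValueError(f"{path}: not a brachymc plan file")
    if doc.get("format_version", 1) > 1:
        raise ValueError(f"{path}: plan format newer than supported")
    dwells = []
    for cath in doc["catheters"]:
        for cp in cath["control_points"]:
            dwells.append(DwellPosition(
                position=np.asarray(cp["position_mm"]) / 10.0,
                orientation=np.asarray(cp["orientation"]),
                dwell_time=cp["dwell_time_s"],
                catheter_id=cath["id"],
            ))
    return Plan(
        dwells=dwells,
        prescription_dose=doc["prescription"]["dose_gy"],
        prescription_point=np.asarray(
            doc["prescription"]["point_mm"]) / 10.0,
        total_reference_air_kerma=doc.get(
            "total_reference_air_kerma_uGy_m2"),
        name=doc.get("name", "plan"),
    )


# ---------------------------------------------------------------------------
# Shipped source-capsule configurations
# ---------------------------------------------------------------------------

def load_source_config(name_or_path) -> SourceCapsule:
    """Load a capsule description from a shipped name or a YAML path."""
    import importlib.resources
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        doc = yaml.safe_load(p.read_text())
    else:
        res = importlib.resources.files("brachymc").joinpath(
            "data", "sources", f"{name_or_path}.yaml")
        try:
            doc = yaml.safe_load(res.read_text())
        except FileNotFoundError:
            raise KeyError(
                f"unknown source configuration {name_or_path!r}") from None
    cable = doc.get("cable") or {}
    return SourceCapsule(
        core_radius=doc["core"]["radius"],
        core_half_length=doc["core"]["half_length"],
        capsule_radius=doc["capsule"]["radius"],
        capsule_half_length=doc["capsule"]["half_length"],
        core_material=doc["core"].get("material", "iridium"),
        capsule_material=doc["capsule"].get("material", "steel316"),
        cable_radius=cable.get("radius", 0.0),
        cable_length=cable.get("length", 0.0),
        cable_material=cable.get("material", "steel316"),
        core_density=doc["core"].get("density"),
        capsule_density=doc["capsule"].get("density"),
        cable_density=cable.get("density"),
        name=doc.get("name", str(name_or_path)),
    )
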