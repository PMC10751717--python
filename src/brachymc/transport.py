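"""Readable per-photon transport: the reference implementation.

The production path is the compiled engine (:mod:`brachymc.engine`); this
module implements the same physics step by step on plain objects, for unit
testing, small scenes and as executable documentation.  Physics regime:
photon-only transport with a 1 keV cut-off and no electron transport —
photoelectric absorption deposits the full photon energy locally (atomic
relaxation quanta fall below the cut-off in low-Z media), Compton deposits
the electron share locally and follows the scattered photon, Rayleigh is
elastic.  Pair production is omitted (negligible yield above its 1022 keV
threshold for the Ir-192 spectrum).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SourceCapsule, VoxelPhantom
from .materials import (XsTable, form_factor_squared, load_material,
                        load_table)
from .tallies import TallySet, analogue_score, siddon_traverse, tlke_score

__all__ = ["Photon", "TransportConfig", "HistoryResult", "woodcock_step",
           "select_interaction", "sample_compton", "sample_rayleigh",
           "transport_history", "MEC2_KEV"]

MEC2_KEV = 510.99895
_HC = 12.39842  # keV * Angstrom


@dataclass
class Photon:
    """Transport state of one photon."""

    position: np.ndarray
    direction: np.ndarray
    energy: float  # keV
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class TransportConfig:
    """Transport parameters: 1 keV photon cut-off, no electron transport."""

    photon_cutoff: float = 1.0  # keV
    majorant_margin: float = 1.001
    rng_seed: int = 0
    histories_per_batch: int = 10000

    def __post_init__(self):
        if self.photon_cutoff < 1.0:
            raise ValueError("photon cut-off must be >= 1 keV")
        if self.majorant_margin < 1.0:
            raise ValueError("majorant margin must be >= 1")


@dataclass
class HistoryResult:
    """Energy bookkeeping of one terminated history (keV, weighted)."""

    emitted: float
    escaped: float
    transferred: float
    n_interactions: int = 0
    interaction_sites: list = field(default_factory=list)


def _rotate(direction, cos_theta, phi):
    u = np.asarray(direction, dtype=float)
    sint = np.sqrt(max(0.0, 1.0 - cos_theta**2))
    if abs(u[2]) > 0.99999999:
        sign = 1.0 if u[2] > 0 else -1.0
        out = np.array([sint * np.cos(phi), sint * np.sin(phi) * sign,
                        cos_theta * sign])
    else:
        rho = np.sqrt(u[0] ** 2 + u[1] ** 2)
        out = np.array([
            u[0] * cos_theta
            + sint * (u[0] * u[2] * np.cos(phi) - u[1] * np.sin(phi)) / rho,
            u[1] * cos_theta
            + sint * (u[1] * u[2] * np.cos(phi) + u[0] * np.sin(phi)) / rho,
            u[2] * cos_theta - rho * sint * np.cos(phi),
        ])
    return out / np.linalg.norm(out)


def sample_compton(energy: float, rng: np.random.Generator):
    """Klein-Nishina sample of (scattered energy keV, cos theta).

    Rejection on the scattered-energy fraction k = E'/E in
    [1/(1+2 E/mc2), 1]; the angle follows from the Compton kinematic
    relation E' = E / (1 + (E/mc2)(1 - cos theta)).
    """
    e = energy / MEC2_KEV
    kmin = 1.0 / (1.0 + 2.0 * e)
    gmax = max(2.0, kmin + 1.0 / kmin)
    while True:
        k = kmin + (1.0 - kmin) * rng.random()
        cost = 1.0 - (1.0 / k - 1.0) / e
        g = k + 1.0 / k - (1.0 - cost * cost)
        if rng.random() * gmax <= g:
            return energy * k, cost


def sample_rayleigh(energy: float, material: str,
                    rng: np.random.Generator) -> float:
    """Cosine of the elastic (coherent) scattering angle.

    Thomson angular factor modulated by the squared molecular form factor
    of the material; the energy is unchanged by construction.
    """
    mat = load_material(material)
    xe = energy / _HC
    x2 = np.concatenate([[0.0], np.logspace(-6, np.log10(xe * xe), 257)])
    f2 = form_factor_squared(mat, np.sqrt(x2))
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (f2[1:] + f2[:-1]) * np.diff(x2))])
    while True:
        target = rng.random() * cum[-1]
        x2s = np.interp(target, cum, x2)
        cost = 1.0 - 2.0 * x2s / (xe * xe)
        if rng.random() <= 0.5 * (1.0 + cost * cost):
            return float(cost)


def select_interaction(energy: float, table: XsTable,
                       rng: np.random.Generator) -> str:
    """photoelectric / compton / rayleigh, proportional to the partials."""
    pe = table.lookup(energy, "photoelectric")
    co = table.lookup(energy, "compton")
    ra = table.lookup(energy, "rayleigh")
    u = rng.random() * (pe + co + ra)
    if u < pe:
        return "photoelectric"
    if u < pe + co:
        return "compton"
    return "rayleigh"


def _majorant(phantom: VoxelPhantom, tables: dict[str, XsTable],
              energy: float, margin: float) -> float:
    mu = 0.0
    for i, name in enumerate(phantom.materials):
        sel = phantom.material_ids == i
        if not np.any(sel):
            continue
        mu = max(mu, float(phantom.densities[sel].max())
                 * tables[name].lookup(energy, "total"))
    return mu * margin


def woodcock_step(photon: Photon, phantom: VoxelPhantom,
                  tables: dict[str, XsTable], rng: np.random.Generator,
                  margin: float = 1.001):
    """Advance to the next real interaction or to the phantom exit.

    Delta (Woodcock) tracking: path lengths are sampled against the
    majorant linear attenuation; tentative collisions are accepted with
    probability mu(x)/mu_majorant, else the flight continues unchanged.

    Returns ``("interact", point, (i,j,k), flight_segments)`` or
    ``("exit", point, None, flight_segments)`` where ``flight_segments``
    is the list of straight legs flown (each ``(p_start, length)``), for
    track-length scoring by the caller.
    """
    mu_maj = _majorant(phantom, tables, photon.energy, margin)
    lo, hi = phantom.geometry.extent
    p = photon.position.copy()
    u = photon.direction
    legs = []
    if np.any(p < lo) or np.any(p >= hi):
        return "exit", p, None, legs
    while True:
        t_box = np.inf
        for ax in range(3):
            if u[ax] > 1e-30:
                t_box = min(t_box, (hi[ax] - p[ax]) / u[ax])
            elif u[ax] < -1e-30:
                t_box = min(t_box, (lo[ax] - p[ax]) / u[ax])
        t = -np.log(rng.random()) / mu_maj
        if t >= t_box:
            legs.append((p.copy(), float(t_box)))
            return "exit", p + u * t_box, None, legs
        legs.append((p.copy(), float(t)))
        p = p + u * t
        idx = phantom.geometry.voxel_of(p)
        if idx is None:
            return "exit", p, None, legs
        name = phantom.materials[phantom.material_ids[idx]]
        mu_real = (phantom.densities[idx]
                   * tables[name].lookup(photon.energy, "total"))
        if mu_real > mu_maj * (1.0 + 1e-9):
            raise RuntimeError(
                f"majorant {mu_maj} below real attenuation {mu_real} "
                f"at voxel {idx}")
        if rng.random() * mu_maj <= mu_real:
            return "interact", p, idx, legs


def _track_capsule_py(photon: Photon, capsule: SourceCapsule,
                      tables: dict[str, XsTable], cfg: TransportConfig,
                      rng: np.random.Generator):
    """Local-frame delta tracking through the capsule solids.

    Returns (photon, transferred_energy); ``photon.alive`` False if
    absorbed.  Positions in/out are in the capsule local frame.
    """
    mats = {"core": (capsule.core_material, capsule.core_density
                     or load_material(capsule.core_material).density),
            "capsule": (capsule.capsule_material, capsule.capsule_density
                        or load_material(capsule.capsule_material).density),
            "cable": (capsule.cable_material, capsule.cable_density
                      or load_material(capsule.cable_material).density)}
    rb = max(capsule.capsule_radius, capsule.cable_radius)
    zlo = -capsule.capsule_half_length - capsule.cable_length
    zhi = capsule.capsule_half_length
    transferred = 0.0
    while True:
        mu_maj = max(rho * tables[m].lookup(photon.energy, "total")
                     for m, rho in mats.values()) * cfg.majorant_margin
        p, u = photon.position, photon.direction
        # distance to bounding-cylinder exit
        a = u[0] ** 2 + u[1] ** 2
        if a > 1e-30:
            b = p[0] * u[0] + p[1] * u[1]
            c = p[0] ** 2 + p[1] ** 2 - rb * rb
            disc = max(0.0, b * b - a * c)
            t_r = (-b + np.sqrt(disc)) / a
        else:
            t_r = np.inf
        if u[2] > 1e-30:
            t_z = (zhi - p[2]) / u[2]
        elif u[2] < -1e-30:
            t_z = (zlo - p[2]) / u[2]
        else:
            t_z = np.inf
        t_exit = max(0.0, min(t_r, t_z))
        t = -np.log(rng.random()) / mu_maj
        if t >= t_exit:
            photon.position = p + u * (t_exit + 1e-9)
            return photon, transferred
        photon.position = p + u * t
        region = capsule.region_at_local(photon.position)
        if region is None:
            continue
        name, rho = mats[region]
        mu_real = rho * tables[name].lookup(photon.energy, "total")
        if rng.random() * mu_maj > mu_real:
            continue
        kind = select_interaction(photon.energy, tables[name], rng)
        if kind == "photoelectric":
            transferred += photon.weight * photon.energy
            photon.alive = False
            return photon, transferred
        if kind == "compton":
            enew, cost = sample_compton(photon.energy, rng)
            transferred += photon.weight * (photon.energy - enew)
            if enew < cfg.photon_cutoff:
                transferred += photon.weight * enew
                photon.alive = False
                return photon, transferred
            photon.energy = enew
            photon.direction = _rotate(photon.direction, cost,
                                       2 * np.pi * rng.random())
        else:
            cost = sample_rayleigh(photon.energy, name, rng)
            photon.direction = _rotate(photon.direction, cost,
                                       2 * np.pi * rng.random())


def transport_history(primary: Photon, phantom: VoxelPhantom,
                      capsule: SourceCapsule | None, tallies: TallySet,
                      config: TransportConfig, rng: np.random.Generator,
                      history: int = 0) -> HistoryResult:
    """Track a primary photon (and its scattered descendants) to the end.

    Scores the attached tallies and returns the per-history energy ledger
    (emitted = escaped + transferred, exactly, by construction of the
    sampling: every branch either redirects, transfers, or escapes).
    """
    tables = {m: load_table(m) for m in phantom.materials}
    if capsule is not None:
        for m in (capsule.core_material, capsule.capsule_material,
                  capsule.cable_material):
            tables.setdefault(m, load_table(m))
    muen_lookup = tallies.muen_lookup or (
        lambda mat, e: tables[mat].lookup(e, "muen"))
    photon = Photon(primary.position.copy(), primary.direction.copy(),
                    primary.energy, primary.weight, True)
    result = HistoryResult(emitted=photon.weight * photon.energy,
                           escaped=0.0, transferred=0.0)
    if capsule is not None:
        # primary assumed born in the capsule local frame
        photon, transferred = _track_capsule_py(photon, capsule, tables,
                                                config, rng)
        result.transferred += transferred
        if not photon.alive:
            return result
        photon.position = capsule.to_world(photon.position)
        photon.direction = capsule.rotation @ photon.direction
    while photon.alive:
        if not np.all(np.isfinite(photon.position)) or not np.isfinite(
                photon.energy):
            raise RuntimeError(f"non-finite photon state: {photon}")
        status, point, idx, legs = woodcock_step(
            photon, phantom, tables, rng, config.majorant_margin)
        for start, length in legs:
            end = start + photon.direction * length
            if tallies.tlke is not None:
                segs = siddon_traverse(start, end, tallies.tlke.geometry)
                tlke_score(tallies.tlke, segs, photon.energy, photon.weight,
                           muen_lookup, history)
            for ci, cell in enumerate(tallies.cells):
                chord = cell.chord(start, photon.direction, length)
                if chord > 0.0:
                    muen = muen_lookup(cell.material, photon.energy)
                    tallies.cell_scores[ci] += (
                        photon.weight * chord * photon.energy * muen
                        / cell.volume * 1000.0)
        if status == "exit":
            result.escaped += photon.weight * photon.energy
            photon.alive = False
            break
        result.n_interactions += 1
        result.interaction_sites.append(point.copy())
        photon.position = point
        name = phantom.materials[phantom.material_ids[idx]]
        kind = select_interaction(photon.energy, tables[name], rng)
        if kind == "photoelectric":
            etrans = photon.energy
            if tallies.analogue is not None:
                analogue_score(tallies.analogue, point, etrans,
                               photon.weight, history)
            result.transferred += photon.weight * etrans
            photon.alive = False
        elif kind == "compton":
            enew, cost = sample_compton(photon.energy, rng)
            etrans = photon.energy - enew
            terminate = enew < config.photon_cutoff
            if terminate:
                etrans = photon.energy
            if tallies.analogue is not None and etrans > 0:
                analogue_score(tallies.analogue, point, etrans,
                               photon.weight, history)
            result.transferred += photon.weight * etrans
            if terminate:
                photon.alive = False
            else:
                photon.energy = enew
                photon.direction = _rotate(photon.direction, cost,
                                           2 * np.pi * rng.random())
        else:
            cost = sample_rayleigh(photon.energy, name, rng)
            photon.direction = _rotate(photon.direction, cost,
                                       2 * np.pi * rng.random())
    return result
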