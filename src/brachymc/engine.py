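"""Packing layer between the object API and the compiled kernels.

Builds flat array bundles (material tables on the shared log-energy grid,
form-factor cumulatives, phantom/scoring-grid arrays, majorant curves) and
drives the :mod:`brachymc._kernels` runs.  Seeds for the kernel PCG32
streams are derived from a run seed through numpy ``SeedSequence`` so that
every run is reproducible and batch decomposition is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .geometry import SourceCapsule, VoxelPhantom
from .materials import (EmissionSpectrum, XsTable, load_material, load_table,
                        form_factor_squared)

__all__ = ["MaterialsPack", "kernel_seeds", "CharacterizeResult",
           "run_characterize", "run_capsule_scene", "run_plan_scene",
           "generate_psf_records"]

_FF_GRID_POINTS = 256


def kernel_seeds(seed: int, n: int = 1) -> np.ndarray:
    """Derive ``n`` (state, stream) uint64 pairs from an integer seed."""
    ss = np.random.SeedSequence(seed)
    raw = ss.generate_state(2 * n, dtype=np.uint64)
    return raw.reshape(n, 2)


@dataclass
class MaterialsPack:
    """Material tables resampled to one uniform log-energy grid."""

    names: list[str]
    loge0: float
    dloge: float
    ne: int
    log_tot: np.ndarray
    log_pe: np.ndarray
    log_co: np.ndarray
    log_ra: np.ndarray
    log_muen: np.ndarray
    ff_x2: np.ndarray
    ff_cum: np.ndarray
    nominal_density: np.ndarray
    index: dict = field(default_factory=dict)

    @property
    def inv_dloge(self) -> float:
        return 1.0 / self.dloge

    def id_of(self, name: str) -> int:
        return self.index[name]

    @staticmethod
    def build(names: list[str],
              tables: dict[str, XsTable] | None = None) -> "MaterialsPack":
        tables = tables or {}
        tabs = [tables.get(n) or load_table(n) for n in names]
        grid = tabs[0].energy_grid
        loge = np.log(grid)
        dl = np.diff(loge)
        if not np.allclose(dl, dl.mean(), rtol=1e-3):
            raise ValueError("material grid must be log-uniform")
        dl = np.full_like(dl, (loge[-1] - loge[0]) / (len(grid) - 1))
        ne = len(grid)
        nm = len(names)
        packs = {k: np.empty((nm, ne)) for k in
                 ("tot", "pe", "co", "ra", "muen")}
        for i, t in enumerate(tabs):
            if len(t.energy_grid) != ne or not np.allclose(
                    t.energy_grid, grid):
                t = t.resample(grid)
            packs["tot"][i] = np.log(t.mu_rho_total)
            packs["pe"][i] = np.log(t.mu_rho_photoelectric)
            packs["co"][i] = np.log(t.mu_rho_compton)
            packs["ra"][i] = np.log(t.mu_rho_rayleigh)
            packs["muen"][i] = np.log(t.muen_rho)
        # squared-form-factor cumulative over x^2 (shared grid, starts at 0)
        x2max = (grid[-1] / K.HC_KEV_ANGSTROM) ** 2
        x2 = np.concatenate([[0.0],
                             np.logspace(-6, np.log10(x2max),
                                         _FF_GRID_POINTS - 1)])
        ff_cum = np.empty((nm, _FF_GRID_POINTS))
        dens = np.empty(nm)
        for i, n in enumerate(names):
            mat = load_material(n)
            f2 = form_factor_squared(mat, np.sqrt(x2))
            ff_cum[i] = np.concatenate(
                [[0.0], np.cumsum(0.5 * (f2[1:] + f2[:-1]) * np.diff(x2))])
            dens[i] = mat.density
        return MaterialsPack(
            names=list(names), loge0=float(loge[0]), dloge=float(dl[0]),
            ne=ne, log_tot=packs["tot"], log_pe=packs["pe"],
            log_co=packs["co"], log_ra=packs["ra"], log_muen=packs["muen"],
            ff_x2=x2, ff_cum=ff_cum, nominal_density=dens,
            index={n: i for i, n in enumerate(names)},
        )


def _spectrum_arrays(spectrum: EmissionSpectrum):
    e = spectrum.energies.astype(np.float64)
    p = spectrum.intensities.astype(np.float64)
    cum = np.cumsum(p / p.sum())
    cum[-1] = 1.0
    return e, cum


def _capsule_arrays(capsule: SourceCapsule, pack: MaterialsPack):
    cp = capsule.params_array()
    mats = np.array([pack.id_of(capsule.core_material),
                     pack.id_of(capsule.capsule_material),
                     pack.id_of(capsule.cable_material)], dtype=np.int64)
    rho = np.array([
        capsule.core_density or load_material(capsule.core_material).density,
        capsule.capsule_density
        or load_material(capsule.capsule_material).density,
        (capsule.cable_density
         or load_material(capsule.cable_material).density)
        if capsule.cable_radius > 0 else 0.0,
    ])
    return cp, mats, rho, mats.copy()  # ff material ids == table ids


def majorant_curve(phantom: VoxelPhantom, pack: MaterialsPack,
                   margin: float = 1.001) -> np.ndarray:
    """log of the majorant linear attenuation on the shared energy grid."""
    mu_max = np.full(pack.ne, 1e-30)
    for name in phantom.materials:
        m = pack.id_of(name)
        sel = phantom.material_ids == phantom.materials.index(name)
        if not np.any(sel):
            continue
        rho_max = float(phantom.densities[sel].max())
        mu_max = np.maximum(mu_max, rho_max * np.exp(pack.log_tot[m]))
    return np.log(mu_max * margin)


@dataclass
class CharacterizeResult:
    """Per-history ring-cell kerma (eV/g) with Type A statistics."""

    mean: np.ndarray
    std_error: np.ndarray
    n_histories: int

    @property
    def relative_uncertainty(self) -> np.ndarray:
        return np.where(self.mean > 0, self.std_error / self.mean, np.nan)


def run_characterize(capsule: SourceCapsule | None,
                     spectrum: EmissionSpectrum,
                     rings: list,
                     mode: str,
                     n_histories: int,
                     seed: int,
                     environment_material: str = "water",
                     sphere_radius: float = 40.0,
                     cutoff: float = 1.0,
                     kill_scatter: bool = False,
                     extra_materials: tuple = ()) -> CharacterizeResult:
    """Vacuum (``mode='sk'``) or full-scatter sphere (``mode='lambda'``) run.

    ``rings`` is a list of :class:`brachymc.tallies.CylinderCell` coaxial
    with the capsule.  Returns per-history eV/g kerma in each cell.
    """
    names = ["water", "air", "iridium", "steel316"]
    for m in extra_materials:
        if m not in names:
            names.append(m)
    if capsule is not None:
        for m in (capsule.core_material, capsule.capsule_material,
                  capsule.cable_material):
            if m not in names:
                names.append(m)
    pack = MaterialsPack.build(names)
    if capsule is None:
        cap = SourceCapsule(core_radius=0.03, core_half_length=0.175,
                            capsule_radius=0.045, capsule_half_length=0.195)
        cp, cmats, crho, cff = _capsule_arrays(cap, pack)
        use_capsule = 0
    else:
        cp, cmats, crho, cff = _capsule_arrays(capsule, pack)
        use_capsule = 1
    e_arr, cum = _spectrum_arrays(spectrum)
    nring = len(rings)
    rin2 = np.array([r.inner_radius**2 for r in rings])
    rout2 = np.array([r.outer_radius**2 for r in rings])
    hh = np.array([r.half_height for r in rings])
    rmat = np.array([pack.id_of(r.material) for r in rings], dtype=np.int64)
    rinv = np.array([1.0 / r.volume for r in rings])
    rsum = np.zeros(nring)
    rsum2 = np.zeros(nring)
    rbuf = np.zeros(nring)
    rtag = np.full(nring, -1, dtype=np.int64)
    sstate, sseq = kernel_seeds(seed)[0]
    K.run_characterize(
        n_histories, sstate, sseq, 0 if mode == "sk" else 1,
        cp, cmats, crho, cff, use_capsule, e_arr, cum,
        pack.log_tot, pack.log_pe, pack.log_co, pack.log_ra, pack.log_muen,
        pack.ff_x2, pack.ff_cum, pack.loge0, pack.inv_dloge, pack.ne,
        cutoff, 1 if kill_scatter else 0,
        pack.id_of(environment_material),
        load_material(environment_material).density,
        pack.id_of(environment_material), sphere_radius,
        rin2, rout2, hh, rmat, rinv, rsum, rsum2, rbuf, rtag)
    n = n_histories
    mean = rsum / n
    var = np.maximum(rsum2 - rsum**2 / n, 0.0) / (n - 1)
    return CharacterizeResult(mean=mean, std_error=np.sqrt(var / n),
                              n_histories=n)


def _grid_arrays(grid):
    """Flat kernel arrays for a DoseGrid."""
    g = grid.geometry
    shape = np.array(g.shape, dtype=np.int64)
    spacing = np.array(g.spacing)
    origin = np.array(g.origin)
    return shape, spacing, origin


def run_capsule_scene(scene, n_histories: int, seed: int,
                      tlke_grid=None, analogue_grid=None,
                      kill_scatter: bool = False,
                      cutoff: float = 1.0,
                      majorant_margin: float = 1.001) -> int:
    """Run a single-capsule-in-phantom scene, filling the given DoseGrids.

    ``scene`` provides ``phantom`` (VoxelPhantom), ``capsule``
    (SourceCapsule or None for a bare point source at ``capsule.position``),
    and ``spectrum``.  Returns the number of histories run.
    """
    phantom = scene.phantom
    capsule = scene.capsule
    names = list(dict.fromkeys(
        phantom.materials
        + ([capsule.core_material, capsule.capsule_material,
            capsule.cable_material] if capsule is not None
           else ["iridium", "steel316"])
        + ["water", "air"]))
    pack = MaterialsPack.build(names)
    # phantom material ids remapped into the pack's indexing
    remap = np.array([pack.id_of(m) for m in phantom.materials],
                     dtype=np.int64)
    ph_mat = remap[phantom.material_ids].ravel()
    ph_rho = phantom.densities.ravel()
    ph_shape, ph_spacing, ph_origin = (
        np.array(phantom.geometry.shape, dtype=np.int64),
        np.array(phantom.geometry.spacing), np.array(phantom.geometry.origin))
    mu_maj_log = majorant_curve(phantom, pack, majorant_margin)
    e_arr, cum = _spectrum_arrays(scene.spectrum)
    if capsule is not None:
        cp, cmats, crho, cff = _capsule_arrays(capsule, pack)
        use_capsule = 1
        src_pos = np.asarray(capsule.position, dtype=float)
        src_rot = np.asarray(capsule.rotation, dtype=float).ravel()
    else:
        cap = SourceCapsule(core_radius=0.03, core_half_length=0.175,
                            capsule_radius=0.045, capsule_half_length=0.195)
        cp, cmats, crho, cff = _capsule_arrays(cap, pack)
        use_capsule = 0
        src_pos = np.asarray(getattr(scene, "source_position",
                                     np.zeros(3)), dtype=float)
        src_rot = np.eye(3).ravel()
    ref = tlke_grid if tlke_grid is not None else analogue_grid
    if ref is None:
        raise ValueError("at least one scoring grid is required")
    g_shape, g_spacing, g_origin = _grid_arrays(ref)
    g_mat = np.array([pack.id_of(m) for m in ref.materials],
                     dtype=np.int64)[ref.material_ids].ravel()
    g_inv_vol = 1.0 / ref.geometry.voxel_volume

    def _acc(grid):
        if grid is None:
            z = np.zeros(1)
            return 0, z, z.copy(), z.copy(), np.full(1, -1, np.int64)
        return (1, grid.accum_sum.ravel(), grid.accum_sum_sq.ravel(),
                grid.history_buffer.ravel(), grid.history_tag.ravel())

    do_tlke, tl_sum, tl_sum2, tl_buf, tl_tag = _acc(tlke_grid)
    do_an, a_sum, a_sum2, a_buf, a_tag = _acc(analogue_grid)
    a_rho = (analogue_grid.densities.ravel()
             if analogue_grid is not None
             and analogue_grid.densities is not None else ph_rho)
    if do_an and len(a_rho) != len(a_sum):
        raise ValueError("analogue grid needs per-voxel densities")
    err = np.zeros(1, dtype=np.int64)
    sstate, sseq = kernel_seeds(seed)[0]
    K.run_capsule_scene(
        n_histories, sstate, sseq, cp, cmats, crho, cff, use_capsule,
        src_pos, src_rot, e_arr, cum,
        ph_shape, ph_spacing, ph_origin, ph_mat, ph_rho, mu_maj_log,
        pack.log_tot, pack.log_pe, pack.log_co, pack.log_ra, pack.log_muen,
        np.arange(len(names), dtype=np.int64), pack.ff_x2, pack.ff_cum,
        pack.loge0, pack.inv_dloge, pack.ne, cutoff,
        1 if kill_scatter else 0,
        do_tlke, g_shape, g_spacing, g_origin, g_mat, g_inv_vol,
        tl_sum, tl_sum2, tl_buf, tl_tag,
        do_an, a_rho, a_sum, a_sum2, a_buf, a_tag, err)
    if err[0] > 0:
        raise RuntimeError(
            f"majorant consistency violated in {err[0]} steps")
    for grid, arrs in ((tlke_grid, (tl_sum, tl_sum2)),
                       (analogue_grid, (a_sum, a_sum2))):
        if grid is not None:
            grid.accum_sum[...] = arrs[0].reshape(grid.geometry.shape)
            grid.accum_sum_sq[...] = arrs[1].reshape(grid.geometry.shape)
            grid.n_histories += n_histories
    return n_histories


def generate_psf_records(capsule: SourceCapsule, spectrum: EmissionSpectrum,
                         n_primaries: int, seed: int,
                         cutoff: float = 1.0):
    """Capsule-exit phase-space records (local frame). Returns arrays."""
    names = list(dict.fromkeys(
        [capsule.core_material, capsule.capsule_material,
         capsule.cable_material, "water", "air"]))
    pack = MaterialsPack.build(names)
    cp, cmats, crho, cff = _capsule_arrays(capsule, pack)
    e_arr, cum = _spectrum_arrays(spectrum)
    out_e = np.empty(n_primaries)
    out_pos = np.empty((n_primaries, 3))
    out_dir = np.empty((n_primaries, 3))
    out_w = np.empty(n_primaries)
    sstate, sseq = kernel_seeds(seed)[0]
    n = K.generate_psf(n_primaries, sstate, sseq, cp, cmats, crho, cff,
                       e_arr, cum, pack.log_tot, pack.log_pe, pack.log_co,
                       pack.log_ra, pack.ff_x2, pack.ff_cum, pack.loge0,
                       pack.inv_dloge, pack.ne, cutoff, out_e, out_pos,
                       out_dir, out_w)
    return (out_e[:n].copy(), out_pos[:n].copy(), out_dir[:n].copy(),
            out_w[:n].copy())


def run_plan_scene(phantom: VoxelPhantom, psf, plan_arrays,
                   n_histories: int, seed: int,
                   tlke_grid=None, analogue_grid=None,
                   split_factor: int = 10, cutoff: float = 1.0,
                   majorant_margin: float = 1.001) -> int:
    """Dwell-plan run from phase-space arrays.

    ``psf`` is the tuple from :func:`generate_psf_records`;
    ``plan_arrays`` is ``(dwell_cum_weights, dwell_positions_cm,
    dwell_rotations_flat)``.
    """
    psf_e, psf_pos, psf_dir, psf_w = psf
    dwell_cum, dwell_pos, dwell_rot = plan_arrays
    names = list(dict.fromkeys(phantom.materials + ["water", "air"]))
    pack = MaterialsPack.build(names)
    remap = np.array([pack.id_of(m) for m in phantom.materials],
                     dtype=np.int64)
    ph_mat = remap[phantom.material_ids].ravel()
    ph_rho = phantom.densities.ravel()
    ph_shape = np.array(phantom.geometry.shape, dtype=np.int64)
    ph_spacing = np.array(phantom.geometry.spacing)
    ph_origin = np.array(phantom.geometry.origin)
    mu_maj_log = majorant_curve(phantom, pack, majorant_margin)
    ref = tlke_grid if tlke_grid is not None else analogue_grid
    if ref is None:
        raise ValueError("at least one scoring grid is required")
    g_shape, g_spacing, g_origin = _grid_arrays(ref)
    g_mat = np.array([pack.id_of(m) for m in ref.materials],
                     dtype=np.int64)[ref.material_ids].ravel()
    g_inv_vol = 1.0 / ref.geometry.voxel_volume

    def _acc(grid):
        if grid is None:
            z = np.zeros(1)
            return 0, z, z.copy(), z.copy(), np.full(1, -1, np.int64)
        return (1, grid.accum_sum.ravel(), grid.accum_sum_sq.ravel(),
                grid.history_buffer.ravel(), grid.history_tag.ravel())

    do_tlke, tl_sum, tl_sum2, tl_buf, tl_tag = _acc(tlke_grid)
    do_an, a_sum, a_sum2, a_buf, a_tag = _acc(analogue_grid)
    a_rho = (analogue_grid.densities.ravel()
             if analogue_grid is not None
             and analogue_grid.densities is not None else ph_rho)
    err = np.zeros(1, dtype=np.int64)
    sstate, sseq = kernel_seeds(seed)[0]
    K.run_plan_scene(
        n_histories, sstate, sseq, psf_e, psf_pos, psf_dir, psf_w,
        int(split_factor), dwell_cum, dwell_pos, dwell_rot,
        ph_shape, ph_spacing, ph_origin, ph_mat, ph_rho, mu_maj_log,
        pack.log_tot, pack.log_pe, pack.log_co, pack.log_ra, pack.log_muen,
        np.arange(len(names), dtype=np.int64), pack.ff_x2, pack.ff_cum,
        pack.loge0, pack.inv_dloge, pack.ne, cutoff,
        do_tlke, g_shape, g_spacing, g_origin, g_mat, g_inv_vol,
        tl_sum, tl_sum2, tl_buf, tl_tag,
        do_an, a_rho, a_sum, a_sum2, a_buf, a_tag, err)
    if err[0] > 0:
        raise RuntimeError(
            f"majorant consistency violated in {err[0]} steps")
    for grid, arrs in ((tlke_grid, (tl_sum, tl_sum2)),
                       (analogue_grid, (a_sum, a_sum2))):
        if grid is not None:
            grid.accum_sum[...] = arrs[0].reshape(grid.geometry.shape)
            grid.accum_sum_sq[...] = arrs[1].reshape(grid.geometry.shape)
            grid.n_histories += n_histories
    return n_histories
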