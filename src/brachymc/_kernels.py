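"""Compiled (numba) transport and scoring kernels.

Everything here operates on flat numpy arrays packed by
:mod:`brachymc.engine`; the readable object-level API lives in
:mod:`brachymc.transport` and :mod:`brachymc.tallies` and uses the same
sampling routines, so the compiled path and the reference path share one
set of physics formulas.

Random numbers: PCG32 (64-bit state, 64-bit stream), one named generator per
history stream.  Per-run child streams are derived deterministically from the
run seed by the engine via numpy ``SeedSequence``, so batch decomposition
does not change results.
"""
from __future__ import annotations

import numpy as np
from numba import njit, uint32, uint64

# interaction channel codes
PHOTOELECTRIC = 0
COMPTON = 1
RAYLEIGH = 2

MEC2 = 510.99895  # keV
HC_KEV_ANGSTROM = 12.39842  # keV * Angstrom

_U64_MULT = uint64(6364136223846793005)


# ---------------------------------------------------------------------------
# PCG32
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def pcg_u32(s):
    old = s[0]
    s[0] = old * _U64_MULT + s[1]
    xorshifted = uint32(((old >> uint64(18)) ^ old) >> uint64(27))
    rot = uint32(old >> uint64(59))
    return uint32((xorshifted >> rot)
                  | (xorshifted << ((uint32(32) - rot) & uint32(31))))


@njit(cache=True)
def pcg_seed(s, initstate, initseq):
    s[1] = (uint64(initseq) << uint64(1)) | uint64(1)
    s[0] = uint64(0)
    pcg_u32(s)
    s[0] = s[0] + uint64(initstate)
    pcg_u32(s)


@njit(cache=True, inline="always")
def rand(s):
    """Uniform double in (0, 1)."""
    return (np.float64(pcg_u32(s)) + 0.5) * (1.0 / 4294967296.0)


# ---------------------------------------------------------------------------
# Table lookups (uniform log-energy grid)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def interp_log(table, m, loge, loge0, inv_dloge, ne):
    """exp(linear interp) of ``table[m]`` at log-energy ``loge``."""
    t = (loge - loge0) * inv_dloge
    if t <= 0.0:
        t = 0.0
    elif t >= ne - 1:
        t = ne - 1.000001
    i = int(t)
    f = t - i
    return np.exp(table[m, i] * (1.0 - f) + table[m, i + 1] * f)


@njit(cache=True, inline="always")
def interp_1d(vec, loge, loge0, inv_dloge, ne):
    t = (loge - loge0) * inv_dloge
    if t <= 0.0:
        t = 0.0
    elif t >= ne - 1:
        t = ne - 1.000001
    i = int(t)
    f = t - i
    return np.exp(vec[i] * (1.0 - f) + vec[i + 1] * f)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def sample_line(cum, u):
    """Index of the first cumulative entry >= u (binary search)."""
    lo = 0
    hi = len(cum) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def sample_kn(energy, s):
    """Klein-Nishina sample: returns (scattered energy keV, cos theta)."""
    e = energy / MEC2
    kmin = 1.0 / (1.0 + 2.0 * e)
    gmax = kmin + 1.0 / kmin
    if gmax < 2.0:
        gmax = 2.0
    while True:
        k = kmin + (1.0 - kmin) * rand(s)
        cost = 1.0 - (1.0 / k - 1.0) / e
        g = k + 1.0 / k - (1.0 - cost * cost)
        if rand(s) * gmax <= g:
            return energy * k, cost


@njit(cache=True)
def sample_rayleigh_cos(energy, m, ff_x2, ff_cum, s):
    """Cosine of the coherent scattering angle.

    ``ff_cum[m]`` is the cumulative integral of the squared molecular form
    factor over x^2 on the shared grid ``ff_x2`` (x in 1/Angstrom);
    acceptance-corrected with the Thomson factor (1 + cos^2)/2.
    """
    xe = energy / HC_KEV_ANGSTROM
    x2max = xe * xe
    n = len(ff_x2)
    # cumulative value at x2max (linear interp, clamp)
    if x2max >= ff_x2[n - 1]:
        cmax = ff_cum[m, n - 1]
    else:
        lo = 0
        hi = n - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if ff_x2[mid] < x2max:
                lo = mid + 1
            else:
                hi = mid
        i = lo if lo > 0 else 1
        f = (x2max - ff_x2[i - 1]) / (ff_x2[i] - ff_x2[i - 1])
        cmax = ff_cum[m, i - 1] * (1.0 - f) + ff_cum[m, i] * f
    while True:
        target = rand(s) * cmax
        lo = 0
        hi = n - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if ff_cum[m, mid] < target:
                lo = mid + 1
            else:
                hi = mid
        i = lo if lo > 0 else 1
        dc = ff_cum[m, i] - ff_cum[m, i - 1]
        f = 0.0 if dc <= 0.0 else (target - ff_cum[m, i - 1]) / dc
        x2 = ff_x2[i - 1] * (1.0 - f) + ff_x2[i] * f
        if x2 > x2max:
            x2 = x2max
        cost = 1.0 - 2.0 * x2 / x2max
        if rand(s) * 1.0 <= 0.5 * (1.0 + cost * cost):
            return cost


@njit(cache=True, inline="always")
def rotate_direction(ux, uy, uz, cost, phi, out):
    """Rotate unit vector u by polar angle (cost) and azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    if abs(uz) > 0.99999999:
        sign = 1.0 if uz > 0.0 else -1.0
        out[0] = sint * cphi
        out[1] = sint * sphi * sign
        out[2] = cost * sign
    else:
        rho = np.sqrt(ux * ux + uy * uy)
        out[0] = ux * cost + sint * (ux * uz * cphi - uy * sphi) / rho
        out[1] = uy * cost + sint * (uy * uz * cphi + ux * sphi) / rho
        out[2] = uz * cost - rho * sint * cphi
    # renormalize to keep |u| = 1 over long chains
    norm = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2)
    out[0] /= norm
    out[1] /= norm
    out[2] /= norm


@njit(cache=True, inline="always")
def select_channel(mats_pe, mats_co, mats_ra, m, loge, loge0, inv_dloge, ne,
                   s):
    pe = interp_log(mats_pe, m, loge, loge0, inv_dloge, ne)
    co = interp_log(mats_co, m, loge, loge0, inv_dloge, ne)
    ra = interp_log(mats_ra, m, loge, loge0, inv_dloge, ne)
    u = rand(s) * (pe + co + ra)
    if u < pe:
        return PHOTOELECTRIC
    if u < pe + co:
        return COMPTON
    return RAYLEIGH


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def cylinder_exit(px, py, pz, dx, dy, dz, radius, zlo, zhi):
    """Distance to exit a finite cylinder from an interior point."""
    a = dx * dx + dy * dy
    if a > 1e-30:
        b = px * dx + py * dy
        c = px * px + py * py - radius * radius
        disc = b * b - a * c
        if disc <= 0.0:
            t_r = 0.0
        else:
            t_r = (-b + np.sqrt(disc)) / a
    else:
        t_r = 1e30
    if dz > 1e-30:
        t_z = (zhi - pz) / dz
    elif dz < -1e-30:
        t_z = (zlo - pz) / dz
    else:
        t_z = 1e30
    t = t_r if t_r < t_z else t_z
    return t if t > 0.0 else 0.0


@njit(cache=True, inline="always")
def interval_cylinder(px, py, dx, dy, r2):
    """(t0, t1) where the ray is inside the infinite cylinder x^2+y^2<=r2."""
    a = dx * dx + dy * dy
    c = px * px + py * py - r2
    if a <= 1e-30:
        if c <= 0.0:
            return -1e30, 1e30
        return 1.0, 0.0  # empty
    b = px * dx + py * dy
    disc = b * b - a * c
    if disc <= 0.0:
        return 1.0, 0.0  # empty
    sq = np.sqrt(disc)
    return (-b - sq) / a, (-b + sq) / a


@njit(cache=True)
def ring_chord(px, py, pz, dx, dy, dz, length, rin2, rout2, hh):
    """Chord length of segment inside the coaxial ring |z|<=hh, rin<r<rout."""
    # z-slab interval
    if dz > 1e-30:
        s0 = (-hh - pz) / dz
        s1 = (hh - pz) / dz
    elif dz < -1e-30:
        s0 = (hh - pz) / dz
        s1 = (-hh - pz) / dz
    else:
        if abs(pz) <= hh:
            s0, s1 = -1e30, 1e30
        else:
            return 0.0
    lo = 0.0 if s0 < 0.0 else s0
    hi = length if s1 > length else s1
    if lo >= hi:
        return 0.0
    o0, o1 = interval_cylinder(px, py, dx, dy, rout2)
    a0 = o0 if o0 > lo else lo
    a1 = o1 if o1 < hi else hi
    outer = a1 - a0 if a1 > a0 else 0.0
    if outer <= 0.0:
        return 0.0
    if rin2 <= 0.0:
        return outer
    i0, i1 = interval_cylinder(px, py, dx, dy, rin2)
    b0 = i0 if i0 > a0 else a0
    b1 = i1 if i1 < a1 else a1
    inner = b1 - b0 if b1 > b0 else 0.0
    return outer - inner


@njit(cache=True, inline="always")
def box_exit(px, py, pz, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2):
    """Distance to exit an axis-aligned box from an interior point."""
    t = 1e30
    if dx > 1e-30:
        tt = (hi0 - px) / dx
        if tt < t:
            t = tt
    elif dx < -1e-30:
        tt = (lo0 - px) / dx
        if tt < t:
            t = tt
    if dy > 1e-30:
        tt = (hi1 - py) / dy
        if tt < t:
            t = tt
    elif dy < -1e-30:
        tt = (lo1 - py) / dy
        if tt < t:
            t = tt
    if dz > 1e-30:
        tt = (hi2 - pz) / dz
        if tt < t:
            t = tt
    elif dz < -1e-30:
        tt = (lo2 - pz) / dz
        if tt < t:
            t = tt
    return t if t > 0.0 else 0.0


# ---------------------------------------------------------------------------
# History-tagged scoring (history-by-history variance accumulation)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def score_tagged(sum_, sum2, buf, tag, idx, val, hist):
    if tag[idx] != hist:
        b = buf[idx]
        if tag[idx] >= 0:
            sum_[idx] += b
            sum2[idx] += b * b
        buf[idx] = val
        tag[idx] = hist
    else:
        buf[idx] += val


@njit(cache=True)
def flush_tagged(sum_, sum2, buf, tag):
    for i in range(len(buf)):
        if tag[i] >= 0:
            b = buf[i]
            sum_[i] += b
            sum2[i] += b * b
            buf[i] = 0.0
            tag[i] = -1


# ---------------------------------------------------------------------------
# Siddon traversal scoring of one straight segment on a scoring grid
# ---------------------------------------------------------------------------

@njit(cache=True)
def siddon_score_segment(px, py, pz, dx, dy, dz, length, weight, energy,
                         g_shape, g_spacing, g_origin, g_mat, g_inv_vol,
                         muen_log, loge, loge0, inv_dloge, ne,
                         sum_, sum2, buf, tag, hist):
    """Track-length kerma scoring of a straight segment across the grid.

    Adds weight * l * E * (muen/rho)(E, voxel material) / V (eV/g) to every
    traversed voxel of the current history buffer.
    """
    nx, ny, nz = g_shape[0], g_shape[1], g_shape[2]
    sx, sy, sz = g_spacing[0], g_spacing[1], g_spacing[2]
    ox, oy, oz = g_origin[0], g_origin[1], g_origin[2]
    hx, hy, hz = ox + nx * sx, oy + ny * sy, oz + nz * sz
    # clip [0, length] to the box (slab method)
    t0 = 0.0
    t1 = length
    for ax in range(3):
        if ax == 0:
            p, d, lo, hi = px, dx, ox, hx
        elif ax == 1:
            p, d, lo, hi = py, dy, oy, hy
        else:
            p, d, lo, hi = pz, dz, oz, hz
        if abs(d) < 1e-30:
            if p < lo or p >= hi:
                return
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return
    eps = 1e-12 * (1.0 + abs(t1))
    tcur = t0
    # entry voxel (nudge inward along the ray)
    tprobe = t0 + eps
    ix = int(np.floor((px + dx * tprobe - ox) / sx))
    iy = int(np.floor((py + dy * tprobe - oy) / sy))
    iz = int(np.floor((pz + dz * tprobe - oz) / sz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    # parametric distances to the next plane along each axis
    if dx > 1e-30:
        tmx = ((ix + 1) * sx + ox - px) / dx
        dtx = sx / dx
        stx = 1
    elif dx < -1e-30:
        tmx = (ix * sx + ox - px) / dx
        dtx = -sx / dx
        stx = -1
    else:
        tmx = 1e30
        dtx = 1e30
        stx = 0
    if dy > 1e-30:
        tmy = ((iy + 1) * sy + oy - py) / dy
        dty = sy / dy
        sty = 1
    elif dy < -1e-30:
        tmy = (iy * sy + oy - py) / dy
        dty = -sy / dy
        sty = -1
    else:
        tmy = 1e30
        dty = 1e30
        sty = 0
    if dz > 1e-30:
        tmz = ((iz + 1) * sz + oz - pz) / dz
        dtz = sz / dz
        stz = 1
    elif dz < -1e-30:
        tmz = (iz * sz + oz - pz) / dz
        dtz = -sz / dz
        stz = -1
    else:
        tmz = 1e30
        dtz = 1e30
        stz = 0
    last_mat = -1
    muen = 0.0
    while tcur < t1 - eps:
        # next boundary
        tn = tmx
        axis = 0
        if tmy < tn:
            tn = tmy
            axis = 1
        if tmz < tn:
            tn = tmz
            axis = 2
        tstop = tn if tn < t1 else t1
        seg = tstop - tcur
        if seg > 0.0:
            idx = (ix * ny + iy) * nz + iz
            m = g_mat[idx]
            if m != last_mat:
                muen = interp_log(muen_log, m, loge, loge0, inv_dloge, ne)
                last_mat = m
            val = weight * seg * energy * muen * g_inv_vol * 1000.0
            score_tagged(sum_, sum2, buf, tag, idx, val, hist)
        tcur = tstop
        if tn >= t1:
            break
        if axis == 0:
            ix += stx
            tmx += dtx
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += sty
            tmy += dty
            if iy < 0 or iy >= ny:
                break
        else:
            iz += stz
            tmz += dtz
            if iz < 0 or iz >= nz:
                break


@njit(cache=True, inline="always")
def deposit_point(px, py, pz, value, g_shape, g_spacing, g_origin, g_rho,
                  g_inv_vol, sum_, sum2, buf, tag, hist):
    """Analogue deposit of ``value`` (weight * keV) at a point -> eV/g."""
    ix = int(np.floor((px - g_origin[0]) / g_spacing[0]))
    iy = int(np.floor((py - g_origin[1]) / g_spacing[1]))
    iz = int(np.floor((pz - g_origin[2]) / g_spacing[2]))
    if (ix < 0 or iy < 0 or iz < 0 or ix >= g_shape[0] or iy >= g_shape[1]
            or iz >= g_shape[2]):
        return
    idx = (ix * g_shape[1] + iy) * g_shape[2] + iz
    val = value * 1000.0 * g_inv_vol / g_rho[idx]
    score_tagged(sum_, sum2, buf, tag, idx, val, hist)


# ---------------------------------------------------------------------------
# Capsule-frame tracking (Woodcock inside the capsule bounding cylinder)
# ---------------------------------------------------------------------------

@njit(cache=True)
def classify_capsule(px, py, pz, cp):
    """Region code at a local-frame point: 0 core, 1 capsule, 2 cable, -1."""
    r2 = px * px + py * py
    if r2 <= cp[0] * cp[0] and abs(pz) <= cp[1]:
        return 0
    if r2 <= cp[2] * cp[2] and abs(pz) <= cp[3]:
        return 1
    if cp[4] > 0.0 and r2 <= cp[4] * cp[4]:
        if -cp[3] - cp[5] <= pz <= -cp[3]:
            return 2
    return -1


@njit(cache=True)
def track_capsule(state, cp, cap_mats, cap_rho, mats_tot, mats_pe, mats_co,
                  mats_ra, ff_x2, ff_cum, cap_ff_mats,
                  loge0, inv_dloge, ne, cutoff, s, newdir):
    """Track a photon through the capsule solids in the local frame.

    ``state`` = [x, y, z, ux, uy, uz, E, w]; mutated in place.  Returns True
    if the photon leaves the bounding cylinder alive, False if absorbed.
    """
    rb = cp[2] if cp[2] > cp[4] else cp[4]
    zlo = -cp[3] - cp[5]
    zhi = cp[3]
    loge = np.log(state[6])
    # majorant over the three capsule media at the current energy
    mu_maj = 0.0
    for r in range(3):
        if cap_rho[r] > 0.0:
            mu = cap_rho[r] * interp_log(mats_tot, cap_mats[r], loge, loge0,
                                         inv_dloge, ne)
            if mu > mu_maj:
                mu_maj = mu
    mu_maj *= 1.000001
    while True:
        t_exit = cylinder_exit(state[0], state[1], state[2], state[3],
                               state[4], state[5], rb, zlo, zhi)
        t = -np.log(rand(s)) / mu_maj if mu_maj > 0.0 else 1e30
        if t >= t_exit:
            adv = t_exit + 1e-9
            state[0] += state[3] * adv
            state[1] += state[4] * adv
            state[2] += state[5] * adv
            return True
        state[0] += state[3] * t
        state[1] += state[4] * t
        state[2] += state[5] * t
        region = classify_capsule(state[0], state[1], state[2], cp)
        if region < 0:
            continue  # vacuum gap inside the bounding cylinder
        m = cap_mats[region]
        mu_real = cap_rho[region] * interp_log(mats_tot, m, loge, loge0,
                                               inv_dloge, ne)
        if rand(s) * mu_maj > mu_real:
            continue  # virtual collision
        ch = select_channel(mats_pe, mats_co, mats_ra, m, loge, loge0,
                            inv_dloge, ne, s)
        if ch == PHOTOELECTRIC:
            return False
        if ch == COMPTON:
            enew, cost = sample_kn(state[6], s)
            if enew < cutoff:
                return False
            state[6] = enew
            loge = np.log(enew)
            rotate_direction(state[3], state[4], state[5], cost,
                             2.0 * np.pi * rand(s), newdir)
            state[3] = newdir[0]
            state[4] = newdir[1]
            state[5] = newdir[2]
            # energy changed: refresh majorant
            mu_maj = 0.0
            for r in range(3):
                if cap_rho[r] > 0.0:
                    mu = cap_rho[r] * interp_log(mats_tot, cap_mats[r], loge,
                                                 loge0, inv_dloge, ne)
                    if mu > mu_maj:
                        mu_maj = mu
            mu_maj *= 1.000001
        else:
            cost = sample_rayleigh_cos(state[6], cap_ff_mats[region], ff_x2,
                                       ff_cum, s)
            rotate_direction(state[3], state[4], state[5], cost,
                             2.0 * np.pi * rand(s), newdir)
            state[3] = newdir[0]
            state[4] = newdir[1]
            state[5] = newdir[2]


@njit(cache=True)
def emit_in_core(state, cp, energies, cumint, s):
    """Uniform position in the core, isotropic direction, spectrum energy."""
    r = cp[0] * np.sqrt(rand(s))
    phi = 2.0 * np.pi * rand(s)
    state[0] = r * np.cos(phi)
    state[1] = r * np.sin(phi)
    state[2] = (2.0 * rand(s) - 1.0) * cp[1]
    w = 2.0 * rand(s) - 1.0
    sphi = 2.0 * np.pi * rand(s)
    rho = np.sqrt(max(0.0, 1.0 - w * w))
    state[3] = rho * np.cos(sphi)
    state[4] = rho * np.sin(sphi)
    state[5] = w
    state[6] = energies[sample_line(cumint, rand(s))]
    state[7] = 1.0


# ---------------------------------------------------------------------------
# TG-43 characterization runs (vacuum / full-scatter sphere + ring cells)
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_characterize(n_hist, seed_state, seed_seq, mode,
                     cp, cap_mats, cap_rho, cap_ff_mats, use_capsule,
                     energies, cumint,
                     mats_tot, mats_pe, mats_co, mats_ra, mats_muen,
                     ff_x2, ff_cum, loge0, inv_dloge, ne, cutoff,
                     kill_scatter,
                     env_mat, env_rho, env_ff_mat, sphere_radius,
                     ring_rin2, ring_rout2, ring_hh, ring_mat, ring_inv_vol,
                     ring_sum, ring_sum2, ring_buf, ring_tag):
    """Source characterization run.

    mode 0: vacuum surroundings (air-kerma strength geometry).
    mode 1: homogeneous sphere of ``env_mat`` (dose-rate-constant geometry).
    Ring cells are coaxial with the capsule (axis = z, centered at origin).
    Scores are eV/g per history.
    """
    s = np.empty(2, dtype=np.uint64)
    pcg_seed(s, seed_state, seed_seq)
    state = np.empty(8, dtype=np.float64)
    newdir = np.empty(3, dtype=np.float64)
    nring = len(ring_rin2)
    for hist in range(n_hist):
        emit_in_core(state, cp, energies, cumint, s)
        if use_capsule == 1:
            if not track_capsule(state, cp, cap_mats, cap_rho, mats_tot,
                                 mats_pe, mats_co, mats_ra, ff_x2, ff_cum,
                                 cap_ff_mats, loge0, inv_dloge, ne, cutoff,
                                 s, newdir):
                continue
        else:
            state[0] = 0.0
            state[1] = 0.0
            state[2] = 0.0
        alive = True
        while alive:
            loge = np.log(state[6])
            if mode == 0:
                seg = 1.0e3  # vacuum: fly far past the scoring cells
                t_int = 1e30
            else:
                mu = env_rho * interp_log(mats_tot, env_mat, loge, loge0,
                                          inv_dloge, ne)
                t_int = -np.log(rand(s)) / mu
                # distance to sphere surface
                pd = (state[0] * state[3] + state[1] * state[4]
                      + state[2] * state[5])
                pp = (state[0] ** 2 + state[1] ** 2 + state[2] ** 2)
                disc = pd * pd + sphere_radius * sphere_radius - pp
                t_sph = (-pd + np.sqrt(disc)) if disc > 0.0 else 0.0
                seg = t_int if t_int < t_sph else t_sph
            for rr in range(nring):
                chord = ring_chord(state[0], state[1], state[2], state[3],
                                   state[4], state[5], seg, ring_rin2[rr],
                                   ring_rout2[rr], ring_hh[rr])
                if chord > 0.0:
                    muen = interp_log(mats_muen, ring_mat[rr], loge, loge0,
                                      inv_dloge, ne)
                    val = (state[7] * chord * state[6] * muen
                           * ring_inv_vol[rr] * 1000.0)
                    score_tagged(ring_sum, ring_sum2, ring_buf, ring_tag,
                                 rr, val, hist)
            state[0] += state[3] * seg
            state[1] += state[4] * seg
            state[2] += state[5] * seg
            if mode == 0 or seg < t_int:
                break  # escaped (vacuum ray, or left the sphere)
            if kill_scatter == 1:
                break  # primary-only mode: terminate at the interaction
            ch = select_channel(mats_pe, mats_co, mats_ra, env_mat, loge,
                                loge0, inv_dloge, ne, s)
            if ch == PHOTOELECTRIC:
                alive = False
            elif ch == COMPTON:
                enew, cost = sample_kn(state[6], s)
                if enew < cutoff:
                    alive = False
                else:
                    state[6] = enew
                    rotate_direction(state[3], state[4], state[5], cost,
                                     2.0 * np.pi * rand(s), newdir)
                    state[3] = newdir[0]
                    state[4] = newdir[1]
                    state[5] = newdir[2]
            else:
                cost = sample_rayleigh_cos(state[6], env_ff_mat, ff_x2,
                                           ff_cum, s)
                rotate_direction(state[3], state[4], state[5], cost,
                                 2.0 * np.pi * rand(s), newdir)
                state[3] = newdir[0]
                state[4] = newdir[1]
                state[5] = newdir[2]
    flush_tagged(ring_sum, ring_sum2, ring_buf, ring_tag)
    return n_hist


# ---------------------------------------------------------------------------
# Voxel-phantom run (Woodcock tracking + TLKE / analogue scoring grids)
# ---------------------------------------------------------------------------

@njit(cache=True)
def transport_in_phantom(state, hist, ph_shape, ph_spacing, ph_origin,
                         ph_mat, ph_rho, mu_maj_log,
                         mats_tot, mats_pe, mats_co, mats_ra,
                         mat_ff, ff_x2, ff_cum,
                         loge0, inv_dloge, ne, cutoff, kill_scatter,
                         do_tlke, g_shape, g_spacing, g_origin, g_mat,
                         g_inv_vol, mats_muen,
                         tl_sum, tl_sum2, tl_buf, tl_tag,
                         do_analogue, a_rho, a_sum, a_sum2, a_buf, a_tag,
                         newdir, s, err):
    """Track one photon through the voxel phantom, scoring both tallies."""
    lo0 = ph_origin[0]
    lo1 = ph_origin[1]
    lo2 = ph_origin[2]
    hi0 = lo0 + ph_shape[0] * ph_spacing[0]
    hi1 = lo1 + ph_shape[1] * ph_spacing[1]
    hi2 = lo2 + ph_shape[2] * ph_spacing[2]
    if (state[0] < lo0 or state[0] >= hi0 or state[1] < lo1
            or state[1] >= hi1 or state[2] < lo2 or state[2] >= hi2):
        return  # born outside the phantom box: no contribution
    while True:
        if state[6] < cutoff:
            return
        loge = np.log(state[6])
        mu_maj = interp_1d(mu_maj_log, loge, loge0, inv_dloge, ne)
        t_box = box_exit(state[0], state[1], state[2], state[3], state[4],
                         state[5], lo0, lo1, lo2, hi0, hi1, hi2)
        t = -np.log(rand(s)) / mu_maj
        escaped = t >= t_box
        seg = t_box if escaped else t
        if do_tlke == 1:
            siddon_score_segment(state[0], state[1], state[2], state[3],
                                 state[4], state[5], seg, state[7], state[6],
                                 g_shape, g_spacing, g_origin, g_mat,
                                 g_inv_vol, mats_muen, loge, loge0,
                                 inv_dloge, ne, tl_sum, tl_sum2, tl_buf,
                                 tl_tag, hist)
        state[0] += state[3] * seg
        state[1] += state[4] * seg
        state[2] += state[5] * seg
        if escaped:
            return
        ix = int(np.floor((state[0] - lo0) / ph_spacing[0]))
        iy = int(np.floor((state[1] - lo1) / ph_spacing[1]))
        iz = int(np.floor((state[2] - lo2) / ph_spacing[2]))
        if (ix < 0 or iy < 0 or iz < 0 or ix >= ph_shape[0]
                or iy >= ph_shape[1] or iz >= ph_shape[2]):
            return
        vidx = (ix * ph_shape[1] + iy) * ph_shape[2] + iz
        m = ph_mat[vidx]
        mu_real = ph_rho[vidx] * interp_log(mats_tot, m, loge, loge0,
                                            inv_dloge, ne)
        if mu_real > mu_maj * 1.0000001:
            err[0] += 1
            return
        if rand(s) * mu_maj > mu_real:
            continue  # virtual collision
        ch = select_channel(mats_pe, mats_co, mats_ra, m, loge, loge0,
                            inv_dloge, ne, s)
        if ch == PHOTOELECTRIC:
            if do_analogue == 1:
                deposit_point(state[0], state[1], state[2],
                              state[7] * state[6], g_shape, g_spacing,
                              g_origin, a_rho, g_inv_vol, a_sum, a_sum2,
                              a_buf, a_tag, hist)
            return
        if ch == COMPTON:
            enew, cost = sample_kn(state[6], s)
            etrans = state[6] - enew
            if enew < cutoff:
                etrans = state[6]  # residual absorbed locally
            if do_analogue == 1 and etrans > 0.0:
                deposit_point(state[0], state[1], state[2],
                              state[7] * etrans, g_shape, g_spacing,
                              g_origin, a_rho, g_inv_vol, a_sum, a_sum2,
                              a_buf, a_tag, hist)
            if enew < cutoff or kill_scatter == 1:
                return
            state[6] = enew
            rotate_direction(state[3], state[4], state[5], cost,
                             2.0 * np.pi * rand(s), newdir)
        else:
            if kill_scatter == 1:
                return
            cost = sample_rayleigh_cos(state[6], mat_ff[m], ff_x2, ff_cum, s)
            rotate_direction(state[3], state[4], state[5], cost,
                             2.0 * np.pi * rand(s), newdir)
        state[3] = newdir[0]
        state[4] = newdir[1]
        state[5] = newdir[2]


@njit(cache=True)
def run_capsule_scene(n_hist, seed_state, seed_seq,
                      cp, cap_mats, cap_rho, cap_ff_mats, use_capsule,
                      src_pos, src_rot,
                      energies, cumint,
                      ph_shape, ph_spacing, ph_origin, ph_mat, ph_rho,
                      mu_maj_log,
                      mats_tot, mats_pe, mats_co, mats_ra, mats_muen,
                      mat_ff, ff_x2, ff_cum, loge0, inv_dloge, ne, cutoff,
                      kill_scatter,
                      do_tlke, g_shape, g_spacing, g_origin, g_mat, g_inv_vol,
                      tl_sum, tl_sum2, tl_buf, tl_tag,
                      do_analogue, a_rho, a_sum, a_sum2, a_buf, a_tag, err):
    """Single-capsule-in-phantom run (benchmark test-case geometry)."""
    s = np.empty(2, dtype=np.uint64)
    pcg_seed(s, seed_state, seed_seq)
    state = np.empty(8, dtype=np.float64)
    newdir = np.empty(3, dtype=np.float64)
    for hist in range(n_hist):
        emit_in_core(state, cp, energies, cumint, s)
        if use_capsule == 1:
            if not track_capsule(state, cp, cap_mats, cap_rho, mats_tot,
                                 mats_pe, mats_co, mats_ra, ff_x2, ff_cum,
                                 cap_ff_mats, loge0, inv_dloge, ne, cutoff,
                                 s, newdir):
                continue
        else:
            state[0] = 0.0
            state[1] = 0.0
            state[2] = 0.0
        # local -> world
        px = (src_rot[0] * state[0] + src_rot[1] * state[1]
              + src_rot[2] * state[2]) + src_pos[0]
        py = (src_rot[3] * state[0] + src_rot[4] * state[1]
              + src_rot[5] * state[2]) + src_pos[1]
        pz = (src_rot[6] * state[0] + src_rot[7] * state[1]
              + src_rot[8] * state[2]) + src_pos[2]
        ux = (src_rot[0] * state[3] + src_rot[1] * state[4]
              + src_rot[2] * state[5])
        uy = (src_rot[3] * state[3] + src_rot[4] * state[4]
              + src_rot[5] * state[5])
        uz = (src_rot[6] * state[3] + src_rot[7] * state[4]
              + src_rot[8] * state[5])
        state[0] = px
        state[1] = py
        state[2] = pz
        state[3] = ux
        state[4] = uy
        state[5] = uz
        transport_in_phantom(state, hist, ph_shape, ph_spacing, ph_origin,
                             ph_mat, ph_rho, mu_maj_log, mats_tot, mats_pe,
                             mats_co, mats_ra, mat_ff, ff_x2, ff_cum,
                             loge0, inv_dloge, ne, cutoff, kill_scatter,
                             do_tlke, g_shape, g_spacing, g_origin, g_mat,
                             g_inv_vol, mats_muen, tl_sum, tl_sum2, tl_buf,
                             tl_tag, do_analogue, a_rho, a_sum, a_sum2,
                             a_buf, a_tag, newdir, s, err)
    flush_tagged(tl_sum, tl_sum2, tl_buf, tl_tag)
    flush_tagged(a_sum, a_sum2, a_buf, a_tag)
    return n_hist


@njit(cache=True)
def generate_psf(n_hist, seed_state, seed_seq, cp, cap_mats, cap_rho,
                 cap_ff_mats, energies, cumint, mats_tot, mats_pe, mats_co,
                 mats_ra, ff_x2, ff_cum, loge0, inv_dloge, ne, cutoff,
                 out_e, out_pos, out_dir, out_w):
    """Emit ``n_hist`` primaries, track through the capsule, store survivors.

    Records are in the capsule local frame at the bounding-cylinder surface.
    Returns the number of stored records.
    """
    s = np.empty(2, dtype=np.uint64)
    pcg_seed(s, seed_state, seed_seq)
    state = np.empty(8, dtype=np.float64)
    newdir = np.empty(3, dtype=np.float64)
    n_out = 0
    for _ in range(n_hist):
        emit_in_core(state, cp, energies, cumint, s)
        if track_capsule(state, cp, cap_mats, cap_rho, mats_tot, mats_pe,
                         mats_co, mats_ra, ff_x2, ff_cum, cap_ff_mats,
                         loge0, inv_dloge, ne, cutoff, s, newdir):
            out_e[n_out] = state[6]
            out_pos[n_out, 0] = state[0]
            out_pos[n_out, 1] = state[1]
            out_pos[n_out, 2] = state[2]
            out_dir[n_out, 0] = state[3]
            out_dir[n_out, 1] = state[4]
            out_dir[n_out, 2] = state[5]
            out_w[n_out] = state[7]
            n_out += 1
    return n_out


@njit(cache=True)
def run_plan_scene(n_hist, seed_state, seed_seq,
                   psf_e, psf_pos, psf_dir, psf_w, split_factor,
                   dwell_cum, dwell_pos, dwell_rot,
                   ph_shape, ph_spacing, ph_origin, ph_mat, ph_rho,
                   mu_maj_log,
                   mats_tot, mats_pe, mats_co, mats_ra, mats_muen,
                   mat_ff, ff_x2, ff_cum, loge0, inv_dloge, ne, cutoff,
                   do_tlke, g_shape, g_spacing, g_origin, g_mat, g_inv_vol,
                   tl_sum, tl_sum2, tl_buf, tl_tag,
                   do_analogue, a_rho, a_sum, a_sum2, a_buf, a_tag, err):
    """Dwell-plan run: PSF replay with particle splitting.

    History ``h`` reads PSF record ``h mod len(psf)`` (the stream restarts
    when exhausted), emits ``split_factor`` clones of weight w/split, each
    independently assigned a dwell position sampled from the dwell-time
    weights and rigidly transformed by that dwell's orientation.  All clones
    of a record share one statistical history.
    """
    s = np.empty(2, dtype=np.uint64)
    pcg_seed(s, seed_state, seed_seq)
    state = np.empty(8, dtype=np.float64)
    newdir = np.empty(3, dtype=np.float64)
    n_psf = len(psf_e)
    for hist in range(n_hist):
        rec = hist % n_psf
        for _ in range(split_factor):
            d = sample_line(dwell_cum, rand(s))
            # local record -> world via dwell transform
            lx = psf_pos[rec, 0]
            ly = psf_pos[rec, 1]
            lz = psf_pos[rec, 2]
            vx = psf_dir[rec, 0]
            vy = psf_dir[rec, 1]
            vz = psf_dir[rec, 2]
            state[0] = (dwell_rot[d, 0] * lx + dwell_rot[d, 1] * ly
                        + dwell_rot[d, 2] * lz) + dwell_pos[d, 0]
            state[1] = (dwell_rot[d, 3] * lx + dwell_rot[d, 4] * ly
                        + dwell_rot[d, 5] * lz) + dwell_pos[d, 1]
            state[2] = (dwell_rot[d, 6] * lx + dwell_rot[d, 7] * ly
                        + dwell_rot[d, 8] * lz) + dwell_pos[d, 2]
            state[3] = (dwell_rot[d, 0] * vx + dwell_rot[d, 1] * vy
                        + dwell_rot[d, 2] * vz)
            state[4] = (dwell_rot[d, 3] * vx + dwell_rot[d, 4] * vy
                        + dwell_rot[d, 5] * vz)
            state[5] = (dwell_rot[d, 6] * vx + dwell_rot[d, 7] * vy
                        + dwell_rot[d, 8] * vz)
            state[6] = psf_e[rec]
            state[7] = psf_w[rec] / split_factor
            transport_in_phantom(state, hist, ph_shape, ph_spacing,
                                 ph_origin, ph_mat, ph_rho, mu_maj_log,
                                 mats_tot, mats_pe, mats_co, mats_ra,
                                 mat_ff, ff_x2, ff_cum, loge0, inv_dloge,
                                 ne, cutoff, 0, do_tlke, g_shape, g_spacing,
                                 g_origin, g_mat, g_inv_vol, mats_muen,
                                 tl_sum, tl_sum2, tl_buf, tl_tag,
                                 do_analogue, a_rho, a_sum, a_sum2, a_buf,
                                 a_tag, newdir, s, err)
    flush_tagged(tl_sum, tl_sum2, tl_buf, tl_tag)
    flush_tagged(a_sum, a_sum2, a_buf, a_tag)
    return n_hist
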