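"""Numba kernels: forces, neighbor search, and the Langevin integrator.

All kernels work in reduced units (sigma = 1, k_B T = 1, bead mass = 1) and
are deliberately free of Python objects so the integration loop stays jitted
end to end.  Randomness is counter-based: every Gaussian kick is a pure hash
of (seed, step, bead, axis), so trajectories are bitwise reproducible
independent of call order or threading.
"""

import numpy as np
from numba import njit

FORCE_CAP = 1.0e4       # cap on a single pair force below r = 0.5 sigma
CAP_RADIUS = 0.5

# pair interaction modes
PAIR_BY_TYPE = 0        # eps/cutoff looked up from type-pair matrices
PAIR_INTRA_INTER = 1    # compression stage: same-chain vs different-chain


# --------------------------------------------------------------------------
# counter-based RNG (splitmix64 finalizer + Box-Muller)
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def gaussian_at(seed, step, bead, axis):
    """Standard normal deviate, a pure function of its four integer keys."""
    key = (
        np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
        ^ np.uint64(step) * np.uint64(0xC2B2AE3D27D4EB4F)
        ^ np.uint64(bead) * np.uint64(0x165667B19E3779F9)
        ^ np.uint64(axis)
    )
    h1 = _splitmix64(key)
    h2 = _splitmix64(h1)
    u1 = (np.float64(h1 >> np.uint64(11)) + 1.0) * 1.1102230246251565e-16
    u2 = np.float64(h2 >> np.uint64(11)) * 1.1102230246251565e-16
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True, inline="always")
def gauss3_at(seed, step, bead):
    """Three standard normal deviates keyed by (seed, step, bead).

    Two Box-Muller pairs from a 4-hash chain; deterministic and
    order-independent like :func:`gaussian_at` but ~2x cheaper per
    component (the thermostat sweep is the hot loop).
    """
    key = (
        np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
        ^ np.uint64(step) * np.uint64(0xC2B2AE3D27D4EB4F)
        ^ np.uint64(bead) * np.uint64(0x165667B19E3779F9)
    )
    h1 = _splitmix64(key)
    h2 = _splitmix64(h1)
    h3 = _splitmix64(h2)
    h4 = _splitmix64(h3)
    u1 = (np.float64(h1 >> np.uint64(11)) + 1.0) * 1.1102230246251565e-16
    u2 = np.float64(h2 >> np.uint64(11)) * 1.1102230246251565e-16
    u3 = (np.float64(h3 >> np.uint64(11)) + 1.0) * 1.1102230246251565e-16
    u4 = np.float64(h4 >> np.uint64(11)) * 1.1102230246251565e-16
    r1 = np.sqrt(-2.0 * np.log(u1))
    a1 = 6.283185307179586 * u2
    r2 = np.sqrt(-2.0 * np.log(u3))
    a2 = 6.283185307179586 * u4
    return r1 * np.cos(a1), r1 * np.sin(a1), r2 * np.cos(a2)


# --------------------------------------------------------------------------
# neighbor search
# --------------------------------------------------------------------------

@njit(cache=True)
def brute_force_pairs(pos, chain_id, cutoff):
    """O(N^2) candidate pairs within cutoff, bonded neighbors excluded."""
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue
            d0 = pos[i, 0] - pos[j, 0]
            d1 = pos[i, 1] - pos[j, 1]
            d2 = pos[i, 2] - pos[j, 2]
            if d0 * d0 + d1 * d1 + d2 * d2 < cut2:
                cnt += 1
    out_i = np.empty(cnt, np.int64)
    out_j = np.empty(cnt, np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue
            d0 = pos[i, 0] - pos[j, 0]
            d1 = pos[i, 1] - pos[j, 1]
            d2 = pos[i, 2] - pos[j, 2]
            if d0 * d0 + d1 * d1 + d2 * d2 < cut2:
                out_i[k] = i
                out_j[k] = j
                k += 1
    return out_i, out_j


@njit(cache=True)
def cell_list_pairs(pos, chain_id, mobile, cutoff):
    """Candidate pairs within cutoff via a linked-cell grid.

    Bonded (consecutive same-chain) pairs and immobile-immobile pairs are
    excluded; the list is otherwise identical to the brute-force scan.
    """
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    lo0 = np.min(pos[:, 0])
    lo1 = np.min(pos[:, 1])
    lo2 = np.min(pos[:, 2])
    hi0 = np.max(pos[:, 0])
    hi1 = np.max(pos[:, 1])
    hi2 = np.max(pos[:, 2])
    nc0 = max(1, int((hi0 - lo0) / cutoff) + 1)
    nc1 = max(1, int((hi1 - lo1) / cutoff) + 1)
    nc2 = max(1, int((hi2 - lo2) / cutoff) + 1)
    ncell = nc0 * nc1 * nc2
    cell_of = np.empty(n, np.int64)
    for i in range(n):
        c0 = int((pos[i, 0] - lo0) / cutoff)
        c1 = int((pos[i, 1] - lo1) / cutoff)
        c2 = int((pos[i, 2] - lo2) / cutoff)
        if c0 >= nc0:
            c0 = nc0 - 1
        if c1 >= nc1:
            c1 = nc1 - 1
        if c2 >= nc2:
            c2 = nc2 - 1
        cell_of[i] = (c0 * nc1 + c1) * nc2 + c2
    # counting sort of beads by cell
    head = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        head[cell_of[i] + 1] += 1
    for c in range(ncell):
        head[c + 1] += head[c]
    order = np.empty(n, np.int64)
    fill = head.copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    # single pass with generous capacity; exact two-pass fallback on overflow
    cap = 96 * n + 1024
    out_i = np.empty(cap, np.int64)
    out_j = np.empty(cap, np.int64)
    total = -1
    for phase in range(2):
        k = 0
        if phase == 1:
            out_i = np.empty(total, np.int64)
            out_j = np.empty(total, np.int64)
        for i in range(n):
            ci = cell_of[i]
            c2i = ci % nc2
            rem = ci // nc2
            c1i = rem % nc1
            c0i = rem // nc1
            for d0 in range(-1, 2):
                a0 = c0i + d0
                if a0 < 0 or a0 >= nc0:
                    continue
                for d1 in range(-1, 2):
                    a1 = c1i + d1
                    if a1 < 0 or a1 >= nc1:
                        continue
                    for d2 in range(-1, 2):
                        a2 = c2i + d2
                        if a2 < 0 or a2 >= nc2:
                            continue
                        cc = (a0 * nc1 + a1) * nc2 + a2
                        for idx in range(head[cc], head[cc + 1]):
                            j = order[idx]
                            if j <= i:
                                continue
                            if chain_id[i] == chain_id[j] and j - i == 1:
                                continue
                            if not mobile[i] and not mobile[j]:
                                continue
                            dd0 = pos[i, 0] - pos[j, 0]
                            dd1 = pos[i, 1] - pos[j, 1]
                            dd2 = pos[i, 2] - pos[j, 2]
                            if dd0 * dd0 + dd1 * dd1 + dd2 * dd2 < cut2:
                                if k < cap:
                                    out_i[k] = i
                                    out_j[k] = j
                                k += 1
        if k <= cap:
            return out_i[:k], out_j[:k]
        # overflow: redo with exact capacity
        cap = k
        total = k
    return out_i[:total], out_j[:total]


# --------------------------------------------------------------------------
# force/energy terms
# --------------------------------------------------------------------------

@njit(cache=True)
def spring_forces(pos, bonds, k_spring, forces):
    """Harmonic bonds with rest length sigma = 1.  Returns (energy, ok)."""
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        d0 = pos[j, 0] - pos[i, 0]
        d1 = pos[j, 1] - pos[i, 1]
        d2 = pos[j, 2] - pos[i, 2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if r < 1e-12:
            return e, False
        dr = r - 1.0
        e += 0.5 * k_spring * dr * dr
        f = k_spring * dr / r
        forces[i, 0] += f * d0
        forces[i, 1] += f * d1
        forces[i, 2] += f * d2
        forces[j, 0] -= f * d0
        forces[j, 1] -= f * d1
        forces[j, 2] -= f * d2
    return e, True


@njit(cache=True)
def bending_forces(pos, triples, k_bend, forces):
    """Cosine bending U = k_bend * (1 - cos theta) per interior bead."""
    e = 0.0
    for t in range(triples.shape[0]):
        i = triples[t, 0]
        j = triples[t, 1]
        k = triples[t, 2]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 < 1e-12 or n2 < 1e-12:
            return e, False
        e1x, e1y, e1z = b1x / n1, b1y / n1, b1z / n1
        e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
        c = e1x * e2x + e1y * e2y + e1z * e2z
        e += k_bend * (1.0 - c)
        # F = -dU/dr = k_bend * d(cos)/dr
        g1x = -(e2x - c * e1x) / n1
        g1y = -(e2y - c * e1y) / n1
        g1z = -(e2z - c * e1z) / n1
        g3x = (e1x - c * e2x) / n2
        g3y = (e1y - c * e2y) / n2
        g3z = (e1z - c * e2z) / n2
        forces[i, 0] += k_bend * g1x
        forces[i, 1] += k_bend * g1y
        forces[i, 2] += k_bend * g1z
        forces[k, 0] += k_bend * g3x
        forces[k, 1] += k_bend * g3y
        forces[k, 2] += k_bend * g3z
        forces[j, 0] -= k_bend * (g1x + g3x)
        forces[j, 1] -= k_bend * (g1y + g3y)
        forces[j, 2] -= k_bend * (g1z + g3z)
    return e, True


@njit(cache=True)
def lj_pair_forces(
    pos, pair_i, pair_j, type_idx, chain_id,
    eps_mat, cut_mat, lj_shifted,
    pair_mode, eps_intra, cut_intra, eps_inter, cut_inter,
    f_cap, forces,
):
    """Truncated Lennard-Jones over a candidate pair list.

    eps/cutoff come either from the type-pair matrices or, during the
    compression protocol, from the same-chain/different-chain override.
    Returns (energy, number_of_capped_forces).
    """
    e = 0.0
    ncap = 0
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        if pair_mode == PAIR_BY_TYPE:
            ti = type_idx[i]
            tj = type_idx[j]
            eps = eps_mat[ti, tj]
            rc = cut_mat[ti, tj]
        else:
            if chain_id[i] == chain_id[j]:
                eps = eps_intra
                rc = cut_intra
            else:
                eps = eps_inter
                rc = cut_inter
        if eps == 0.0:
            continue
        d0 = pos[i, 0] - pos[j, 0]
        d1 = pos[i, 1] - pos[j, 1]
        d2 = pos[i, 2] - pos[j, 2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= rc * rc or r2 < 1e-20:
            continue
        sr2 = 1.0 / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        u = 4.0 * eps * (sr12 - sr6)
        # repulsive-only pairs (cutoff at the LJ minimum) are always
        # energy-shifted (WCA): pure excluded volume must be non-negative
        if lj_shifted or rc < 1.2:
            rc2 = 1.0 / (rc * rc)
            rc6 = rc2 * rc2 * rc2
            u -= 4.0 * eps * (rc6 * rc6 - rc6)
        e += u
        fmag = 24.0 * eps * (2.0 * sr12 - sr6) * sr2  # F/r
        fabs = abs(fmag) * np.sqrt(r2)
        if fabs > f_cap:
            fmag = fmag / fabs * f_cap
            ncap += 1
        forces[i, 0] += fmag * d0
        forces[i, 1] += fmag * d1
        forces[i, 2] += fmag * d2
        forces[j, 0] -= fmag * d0
        forces[j, 1] -= fmag * d1
        forces[j, 2] -= fmag * d2
    return e, ncap


@njit(cache=True)
def wall_forces(pos, mobile, Rc, k_wall, forces):
    """Harmonic confinement beyond |r| = Rc - 0.5 sigma (bead surface at Rc)."""
    e = 0.0
    edge = Rc - 0.5
    for i in range(pos.shape[0]):
        if not mobile[i]:
            continue
        r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if r > edge and r > 1e-12:
            dr = r - edge
            e += 0.5 * k_wall * dr * dr
            f = -k_wall * dr / r
            forces[i, 0] += f * pos[i, 0]
            forces[i, 1] += f * pos[i, 1]
            forces[i, 2] += f * pos[i, 2]
    return e


@njit(cache=True)
def indenter_forces(pos, mobile, K_indent, R_indent, forces):
    """Spherical indenter: inward force K*(r - R)^2 on beads outside R."""
    e = 0.0
    for i in range(pos.shape[0]):
        if not mobile[i]:
            continue
        r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if r > R_indent and r > 1e-12:
            dr = r - R_indent
            # force saturates beyond 1 sigma penetration (keeps F*dt below a
            # bead diameter during stage shrinks; quadratic law near the wall)
            dr_f = min(dr, 1.0)
            e += K_indent * dr_f * dr_f * (dr - 2.0 * dr_f / 3.0)
            f = -K_indent * dr_f * dr_f / r
            forces[i, 0] += f * pos[i, 0]
            forces[i, 1] += f * pos[i, 1]
            forces[i, 2] += f * pos[i, 2]
    return e


@njit(cache=True)
def compute_forces(
    pos, bonds, triples, pair_i, pair_j, type_idx, chain_id, mobile,
    k_spring, k_bend, eps_mat, cut_mat, lj_shifted,
    pair_mode, eps_intra, cut_intra, eps_inter, cut_inter,
    Rc, k_wall, K_indent, R_indent, f_cap,
):
    """Total forces and the per-term energy breakdown.

    Returns (forces, e_spring, e_bend, e_lj, e_wall, e_indenter, ncap, ok).
    """
    forces = np.zeros_like(pos)
    es, ok1 = spring_forces(pos, bonds, k_spring, forces)
    eb, ok2 = bending_forces(pos, triples, k_bend, forces)
    el, ncap = lj_pair_forces(
        pos, pair_i, pair_j, type_idx, chain_id, eps_mat, cut_mat, lj_shifted,
        pair_mode, eps_intra, cut_intra, eps_inter, cut_inter, f_cap, forces,
    )
    ew = 0.0
    if np.isfinite(Rc):
        ew = wall_forces(pos, mobile, Rc, k_wall, forces)
    ei = 0.0
    if K_indent > 0.0:
        ei = indenter_forces(pos, mobile, K_indent, R_indent, forces)
    return forces, es, eb, el, ew, ei, ncap, ok1 and ok2


# --------------------------------------------------------------------------
# BAOAB Langevin integration loop
# --------------------------------------------------------------------------

@njit(cache=True)
def run_nvt(
    pos, vel, bonds, triples, type_idx, chain_id, mobile,
    k_spring, k_bend, eps_mat, cut_mat, lj_shifted,
    pair_mode, eps_intra, cut_intra, eps_inter, cut_inter,
    Rc, k_wall, K_indent, R_indent, f_cap,
    dt, friction, temperature, thermostat, has_pairs, max_cutoff, skin,
    n_steps, dump_every, seed, step_offset,
    frames, frame_steps, e_log, t_kin_log,
):
    """Integrate n_steps of BAOAB Langevin dynamics in place.

    frames/(frame_steps) receive a snapshot every dump_every steps; e_log
    rows are (spring, bend, lj, wall, indenter, kinetic) at each dump.
    Returns (error_step, ncap_total): error_step is -1 on success, else the
    step at which a non-finite coordinate appeared.
    """
    n = pos.shape[0]
    if thermostat:
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt(max(0.0, (1.0 - c1 * c1) * temperature))
    else:
        c1 = 1.0
        c2 = 0.0
    ncap_total = 0

    # initial neighbor list
    if has_pairs:
        pair_i, pair_j = cell_list_pairs(pos, chain_id, mobile, max_cutoff + skin)
    else:
        pair_i = np.empty(0, np.int64)
        pair_j = np.empty(0, np.int64)
    ref_pos = pos.copy()
    half_skin2 = 0.25 * skin * skin

    forces, es, eb, el, ew, ei, ncap, ok = compute_forces(
        pos, bonds, triples, pair_i, pair_j, type_idx, chain_id, mobile,
        k_spring, k_bend, eps_mat, cut_mat, lj_shifted,
        pair_mode, eps_intra, cut_intra, eps_inter, cut_inter,
        Rc, k_wall, K_indent, R_indent, f_cap,
    )
    if not ok:
        return 0, 0
    ncap_total += ncap

    frame_idx = 0
    for step in range(n_steps):
        gstep = step_offset + step
        # B: half kick
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]
        # A: half drift
        for i in range(n):
            if mobile[i]:
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O: Ornstein-Uhlenbeck (exact)
        if thermostat:
            for i in range(n):
                if mobile[i]:
                    g0, g1, g2 = gauss3_at(seed, gstep, i)
                    vel[i, 0] = c1 * vel[i, 0] + c2 * g0
                    vel[i, 1] = c1 * vel[i, 1] + c2 * g1
                    vel[i, 2] = c1 * vel[i, 2] + c2 * g2
        # A: half drift
        for i in range(n):
            if mobile[i]:
                pos[i, 0] += 0.5 * dt * vel[i, 0]
                pos[i, 1] += 0.5 * dt * vel[i, 1]
                pos[i, 2] += 0.5 * dt * vel[i, 2]
        # neighbor rebuild on half-skin displacement
        if has_pairs:
            maxd2 = 0.0
            for i in range(n):
                d0 = pos[i, 0] - ref_pos[i, 0]
                d1 = pos[i, 1] - ref_pos[i, 1]
                d2 = pos[i, 2] - ref_pos[i, 2]
                dd = d0 * d0 + d1 * d1 + d2 * d2
                if dd > maxd2:
                    maxd2 = dd
            if maxd2 > half_skin2:
                pair_i, pair_j = cell_list_pairs(
                    pos, chain_id, mobile, max_cutoff + skin
                )
                ref_pos[:] = pos
        forces, es, eb, el, ew, ei, ncap, ok = compute_forces(
            pos, bonds, triples, pair_i, pair_j, type_idx, chain_id, mobile,
            k_spring, k_bend, eps_mat, cut_mat, lj_shifted,
            pair_mode, eps_intra, cut_intra, eps_inter, cut_inter,
            Rc, k_wall, K_indent, R_indent, f_cap,
        )
        if not ok or not np.isfinite(es + eb + el + ew + ei):
            return gstep, ncap_total
        ncap_total += ncap
        # B: half kick
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += 0.5 * dt * forces[i, 0]
                vel[i, 1] += 0.5 * dt * forces[i, 1]
                vel[i, 2] += 0.5 * dt * forces[i, 2]

        if (step + 1) % dump_every == 0 and frame_idx < frames.shape[0]:
            bad = False
            ekin = 0.0
            nm = 0
            for i in range(n):
                for a in range(3):
                    frames[frame_idx, i, a] = pos[i, a]
                    if not np.isfinite(pos[i, a]):
                        bad = True
                if mobile[i]:
                    ekin += 0.5 * (
                        vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                    )
                    nm += 1
            if bad:
                return gstep, ncap_total
            frame_steps[frame_idx] = gstep + 1
            e_log[frame_idx, 0] = es
            e_log[frame_idx, 1] = eb
            e_log[frame_idx, 2] = el
            e_log[frame_idx, 3] = ew
            e_log[frame_idx, 4] = ei
            e_log[frame_idx, 5] = ekin
            if nm > 0:
                t_kin_log[frame_idx] = 2.0 * ekin / (3.0 * nm)
            frame_idx += 1
    return -1, ncap_total


@njit(cache=True)
def run_bd(
    pos, bonds, triples, type_idx, chain_id, mobile,
    k_spring, k_bend, eps_mat, cut_mat, lj_shifted,
    pair_mode, eps_intra, cut_intra, eps_inter, cut_inter,
    Rc, k_wall, K_indent, R_indent, f_cap,
    dt, mobility, temperature, has_pairs, max_cutoff, skin,
    n_steps, dump_every, seed, step_offset,
    frames, frame_steps, e_log, t_kin_log,
):
    """Overdamped (Brownian dynamics) Euler-Maruyama integration.

    dx = mobility * F * dt + sqrt(2 * mobility * T * dt) * xi.  Shares the
    counter RNG with the inertial integrator; kinetic-temperature slots of
    the log are filled with the target temperature (velocities are not a
    state variable here).
    """
    n = pos.shape[0]
    amp = np.sqrt(2.0 * mobility * temperature * dt)
    ncap_total = 0
    if has_pairs:
        pair_i, pair_j = cell_list_pairs(pos, chain_id, mobile, max_cutoff + skin)
    else:
        pair_i = np.empty(0, np.int64)
        pair_j = np.empty(0, np.int64)
    ref_pos = pos.copy()
    half_skin2 = 0.25 * skin * skin
    frame_idx = 0
    for step in range(n_steps):
        gstep = step_offset + step
        forces, es, eb, el, ew, ei, ncap, ok = compute_forces(
            pos, bonds, triples, pair_i, pair_j, type_idx, chain_id, mobile,
            k_spring, k_bend, eps_mat, cut_mat, lj_shifted,
            pair_mode, eps_intra, cut_intra, eps_inter, cut_inter,
            Rc, k_wall, K_indent, R_indent, f_cap,
        )
        if not ok or not np.isfinite(es + eb + el + ew + ei):
            return gstep, ncap_total
        ncap_total += ncap
        for i in range(n):
            if mobile[i]:
                g0, g1, g2 = gauss3_at(seed, gstep, i)
                pos[i, 0] += mobility * forces[i, 0] * dt + amp * g0
                pos[i, 1] += mobility * forces[i, 1] * dt + amp * g1
                pos[i, 2] += mobility * forces[i, 2] * dt + amp * g2
        if has_pairs:
            maxd2 = 0.0
            for i in range(n):
                d0 = pos[i, 0] - ref_pos[i, 0]
                d1 = pos[i, 1] - ref_pos[i, 1]
                d2 = pos[i, 2] - ref_pos[i, 2]
                dd = d0 * d0 + d1 * d1 + d2 * d2
                if dd > maxd2:
                    maxd2 = dd
            if maxd2 > half_skin2:
                pair_i, pair_j = cell_list_pairs(pos, chain_id, mobile, max_cutoff + skin)
                ref_pos[:] = pos
        if (step + 1) % dump_every == 0 and frame_idx < frames.shape[0]:
            bad = False
            for i in range(n):
                for a in range(3):
                    frames[frame_idx, i, a] = pos[i, a]
                    if not np.isfinite(pos[i, a]):
                        bad = True
            if bad:
                return gstep, ncap_total
            frame_steps[frame_idx] = gstep + 1
            e_log[frame_idx, 0] = es
            e_log[frame_idx, 1] = eb
            e_log[frame_idx, 2] = el
            e_log[frame_idx, 3] = ew
            e_log[frame_idx, 4] = ei
            e_log[frame_idx, 5] = 0.0
            t_kin_log[frame_idx] = temperature
            frame_idx += 1
    return -1, ncap_total
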