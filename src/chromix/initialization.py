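"""Initial conditions: smooth unknotted chains, packing, compression.

Mitotic chromosomes enter interphase condensed and spatially separated, so
simulations start from separated, compacted, unknotted chains: each chain
is a cubic-spline curve through random control points resampled to unit
bead spacing, copies are placed without overlap in a cubic box, and the
assembly is squeezed into the target confinement sphere by a shrinking
spherical indenter while intra-chain attraction condenses each chain and
inter-chain repulsion keeps them apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .dynamics import SimulationConfig, run_simulation
from .forcefield import ATTRACTIVE_CUTOFF, WCA_CUTOFF, ForceField
from .model_core import GenomeSpec, PolymerSystem

__all__ = [
    "CompressionSchedule",
    "PackingError",
    "generate_smooth_chain",
    "knot_check",
    "assemble_system",
    "compress_to_sphere",
]


class PackingError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# smooth chain generation
# --------------------------------------------------------------------------

def generate_smooth_chain(n_beads, box_size, seed, require_unknotted=False,
                          max_tries=50):
    """Smooth open curve through random control points, unit bead spacing.

    A cubic spline through ~n/20 random control points inside the box is
    scaled to the required contour length and walked with chords of exactly
    one bead diameter.  Returns (positions, knot_report); with
    ``require_unknotted`` the generation retries with derived seeds until
    the knot screen passes.
    """
    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    if box_size <= 2.0:
        raise ValueError("box_size must exceed 2 sigma")
    last_report = None
    for attempt in range(max_tries if require_unknotted else 1):
        pos = _smooth_chain_once(n_beads, box_size, seed + 1000 * attempt)
        report = knot_check(pos)
        last_report = report
        if not require_unknotted or report["status"] == "unknotted":
            return pos, report
    raise PackingError(
        f"no unknotted chain found in {max_tries} tries; last report "
        f"{last_report}"
    )


def _serpentine_controls(n_ctrl, half, rng):
    """Jittered boustrophedon sweep through a grid filling the box.

    A spline through fully random points is almost surely knotted once it
    has more than a few dozen control points; a serpentine sweep visits
    grid cells in a monotone raster order, so the smooth curve through the
    jittered cell centers is unknotted by construction while still filling
    the box with an irregular path.
    """
    g = max(2, int(round(n_ctrl ** (1.0 / 3.0))))
    gz = max(2, -(-n_ctrl // (g * g)))
    centers = []
    for iz in range(gz):
        ys = range(g) if iz % 2 == 0 else range(g - 1, -1, -1)
        for iy in ys:
            fwd = (iz * g + (iy if iz % 2 == 0 else g - 1 - iy)) % 2 == 0
            xs = range(g) if fwd else range(g - 1, -1, -1)
            for ix in xs:
                centers.append((ix, iy, iz))
                if len(centers) == n_ctrl:
                    break
            if len(centers) == n_ctrl:
                break
        if len(centers) == n_ctrl:
            break
    centers = np.asarray(centers, dtype=float)
    dims = np.array([g, g, gz], dtype=float)
    cell = 2.0 * half / dims
    pts = -half + (centers + 0.5) * cell
    pts += rng.uniform(-0.35, 0.35, size=pts.shape) * cell
    # random axis permutation + reflections decorrelate chains that would
    # otherwise all trace the same raster path through the box
    perm = rng.permutation(3)
    signs = rng.choice([-1.0, 1.0], size=3)
    return pts[:, perm] * signs


def _smooth_chain_once(n_beads, box_size, seed):
    rng = np.random.default_rng(seed)
    # enough sweep cells that the serpentine arc (~ box * n_ctrl^(2/3))
    # exceeds the contour length n_beads * sigma
    n_ctrl = max(4, n_beads // 20,
                 math.ceil((1.25 * n_beads / box_size) ** 1.5))
    half = 0.45 * box_size
    ctrl = _serpentine_controls(n_ctrl, half, rng)
    seg = np.linalg.norm(np.diff(ctrl, axis=0), axis=1)
    if np.any(seg <= 1e-6):
        raise PackingError("degenerate control points")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    t /= t[-1]
    spline = CubicSpline(t, ctrl, axis=0)
    dense_t = np.linspace(0.0, 1.0, max(2000, 40 * n_beads))
    dense = spline(dense_t)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    )
    needed = (n_beads - 1) * 1.0
    if arc[-1] < needed:
        raise PackingError(
            f"box of {box_size} sigma too small for a {n_beads}-bead contour"
        )
    # shrink about the centroid so the chord walk has ~4% spare length
    scale = needed * 1.04 / arc[-1]
    centroid = dense.mean(axis=0)
    dense = centroid + (dense - centroid) * scale
    pts = _chord_walk(dense, n_beads, 1.0)
    if pts is None:
        raise PackingError("chord resampling exhausted the curve")
    return pts


def _chord_walk(dense, n_beads, spacing):
    """March along a dense polyline picking points at fixed chord spacing."""
    out = np.empty((n_beads, 3))
    out[0] = dense[0]
    cur = dense[0]
    idx = 0
    m = len(dense)
    for k in range(1, n_beads):
        found = False
        while idx < m - 1:
            # advance to the first dense vertex beyond `spacing` from cur
            nxt = dense[idx + 1]
            if np.linalg.norm(nxt - cur) >= spacing:
                a = dense[idx]
                d = nxt - a
                f = a - cur
                aa = d @ d
                bb = 2.0 * (f @ d)
                cc = f @ f - spacing * spacing
                disc = bb * bb - 4 * aa * cc
                if disc >= 0 and aa > 0:
                    root = (-bb + math.sqrt(disc)) / (2 * aa)
                    if 0.0 <= root <= 1.0:
                        cur = a + root * d
                        out[k] = cur
                        found = True
                        break
            idx += 1
        if not found:
            return None
    return out


# --------------------------------------------------------------------------
# knot screening (KMT reduction + minimal crossing count)
# --------------------------------------------------------------------------

@njit(cache=True)
def _seg_triangle_hit(p, q, a, b, c):
    """Conservative segment/triangle intersection (boundary counts as hit)."""
    eps = 1e-12
    d0 = q[0] - p[0]
    d1 = q[1] - p[1]
    d2 = q[2] - p[2]
    e10 = b[0] - a[0]
    e11 = b[1] - a[1]
    e12 = b[2] - a[2]
    e20 = c[0] - a[0]
    e21 = c[1] - a[1]
    e22 = c[2] - a[2]
    h0 = d1 * e22 - d2 * e21
    h1 = d2 * e20 - d0 * e22
    h2 = d0 * e21 - d1 * e20
    det = e10 * h0 + e11 * h1 + e12 * h2
    if abs(det) < eps:
        return False  # parallel; coplanar overlap has measure zero here
    f = 1.0 / det
    s0 = p[0] - a[0]
    s1 = p[1] - a[1]
    s2 = p[2] - a[2]
    u = f * (s0 * h0 + s1 * h1 + s2 * h2)
    if u < -1e-9 or u > 1.0 + 1e-9:
        return False
    q0 = s1 * e12 - s2 * e11
    q1 = s2 * e10 - s0 * e12
    q2 = s0 * e11 - s1 * e10
    v = f * (d0 * q0 + d1 * q1 + d2 * q2)
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return False
    t = f * (e20 * q0 + e21 * q1 + e22 * q2)
    return -1e-9 <= t <= 1.0 + 1e-9


@njit(cache=True)
def _kmt_reduce(pts):
    """Iteratively delete vertices whose removal triangle is unobstructed."""
    m = pts.shape[0]
    active = np.ones(m, np.bool_)
    n_active = m
    changed = True
    while changed and n_active > 3:
        changed = False
        for i in range(m):
            if not active[i] or n_active <= 3:
                continue
            # previous / next active vertices (cyclic)
            p = i - 1
            while p >= 0 and not active[p]:
                p -= 1
            if p < 0:
                p = m - 1
                while not active[p]:
                    p -= 1
            nx = i + 1
            while nx < m and not active[nx]:
                nx += 1
            if nx >= m:
                nx = 0
                while not active[nx]:
                    nx += 1
            blocked = False
            # does any other active segment pierce triangle (p, i, nx)?
            j = 0
            while j < m and not blocked:
                if active[j]:
                    # find next active vertex after j
                    k = j + 1
                    while k < m and not active[k]:
                        k += 1
                    if k >= m:
                        k = 0
                        while not active[k]:
                            k += 1
                    if not (j == p or j == i or j == nx or
                            k == p or k == i or k == nx):
                        if _seg_triangle_hit(pts[j], pts[k],
                                             pts[p], pts[i], pts[nx]):
                            blocked = True
                j += 1
            if not blocked:
                active[i] = False
                n_active -= 1
                changed = True
    return active


@njit(cache=True)
def _min_crossings(pts, n_proj, seed):
    """Minimal crossing number of a closed polygon over random projections."""
    m = pts.shape[0]
    best = 1 << 30
    for trial in range(n_proj):
        # deterministic pseudo-random direction from the trial index
        z = 1.0 - 2.0 * ((trial * 0.6180339887498949 + 0.1) % 1.0)
        phi = 6.283185307179586 * ((trial * 0.7548776662466927 + seed * 1e-3) % 1.0)
        r = np.sqrt(max(0.0, 1.0 - z * z))
        n0 = r * np.cos(phi)
        n1 = r * np.sin(phi)
        n2 = z
        # orthobasis
        if abs(n2) < 0.9:
            u0, u1, u2 = -n1, n0, 0.0
        else:
            u0, u1, u2 = 0.0, -n2, n1
        nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
        u0, u1, u2 = u0 / nu, u1 / nu, u2 / nu
        v0 = n1 * u2 - n2 * u1
        v1 = n2 * u0 - n0 * u2
        v2 = n0 * u1 - n1 * u0
        xy = np.empty((m, 2))
        for i in range(m):
            xy[i, 0] = pts[i, 0] * u0 + pts[i, 1] * u1 + pts[i, 2] * u2
            xy[i, 1] = pts[i, 0] * v0 + pts[i, 1] * v1 + pts[i, 2] * v2
        crossings = 0
        for i in range(m):
            i2 = (i + 1) % m
            for j in range(i + 2, m):
                j2 = (j + 1) % m
                if j2 == i:
                    continue
                ax, ay = xy[i, 0], xy[i, 1]
                bx, by = xy[i2, 0], xy[i2, 1]
                cx, cy = xy[j, 0], xy[j, 1]
                dx, dy = xy[j2, 0], xy[j2, 1]
                d1 = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
                d2 = (bx - ax) * (dy - ay) - (by - ay) * (dx - ax)
                d3 = (dx - cx) * (ay - cy) - (dy - cy) * (ax - cx)
                d4 = (dx - cx) * (by - cy) - (dy - cy) * (bx - cx)
                if d1 * d2 < 0 and d3 * d4 < 0:
                    crossings += 1
        if crossings < best:
            best = crossings
        if best == 0:
            break
    return best


def knot_check(positions, n_projections=24):
    """KMT-style unknot screen of an open or closed chain.

    The chain is closed through a far external point, simplified by
    repeated triangle-elision (which preserves the knot type), and the
    minimal projected crossing count over random directions is reported.
    Zero crossings imply the unknot; the screen is conservative — a true
    knot always retains crossings, while an awkward unknot may occasionally
    be reported ``possibly_knotted``.
    """
    pos = np.asarray(positions, dtype=np.float64)
    if pos.shape[0] < 3:
        raise ValueError("knot check needs at least 3 beads")
    if np.any(np.linalg.norm(np.diff(pos, axis=0), axis=1) < 1e-12):
        raise ValueError("coincident consecutive beads")
    closed = np.linalg.norm(pos[0] - pos[-1]) < 1e-9
    if closed:
        poly = pos[:-1]
    else:
        centroid = pos.mean(axis=0)
        extent = np.max(np.linalg.norm(pos - centroid, axis=1))
        d1 = pos[0] - centroid
        d2 = pos[-1] - centroid
        d = d1 / max(np.linalg.norm(d1), 1e-12) + d2 / max(
            np.linalg.norm(d2), 1e-12
        )
        if np.linalg.norm(d) < 1e-6:
            d = np.array([0.0, 0.0, 1.0])
        far = centroid + d / np.linalg.norm(d) * 10.0 * (extent + 1.0)
        poly = np.vstack([pos, far])
    active = _kmt_reduce(np.ascontiguousarray(poly))
    reduced = np.ascontiguousarray(poly[active])
    if len(reduced) <= 3:
        crossings = 0
    else:
        crossings = int(_min_crossings(reduced, n_projections, 1))
    status = "unknotted" if crossings == 0 else "possibly_knotted"
    return {
        "status": status,
        "crossings": crossings,
        "reduced_vertices": int(len(reduced)),
    }


# --------------------------------------------------------------------------
# assembly and compression
# --------------------------------------------------------------------------

def assemble_system(genome_spec, n_copies_or_chains=None, box_size=100.0,
                    seed=0, min_separation=0.8, max_tries=40,
                    require_unknotted=True):
    """Place smooth chains in a cubic box without inter-chain overlap.

    A one-chain spec with ``n_copies_or_chains`` = n places n copies of
    that chain; a multi-chain spec places one chain per entry.  Placement
    retries with fresh curves until the minimal inter-chain bead distance
    exceeds ``min_separation``.
    """
    spec = genome_spec
    if spec.n_chains == 1 and n_copies_or_chains and n_copies_or_chains > 1:
        n = int(n_copies_or_chains)
        spec = GenomeSpec(
            [f"{spec.chain_names[0]}_{i + 1}" for i in range(n)],
            [spec.chain_lengths[0]] * n,
            bead_class=np.tile(spec.bead_class, n),
            lad_flag=np.tile(spec.lad_flag, n),
            bp_per_bead=spec.bp_per_bead,
            disconnected=spec.disconnected,
        )
    placed = []
    tree = None
    for c, length in enumerate(spec.chain_lengths):
        ok = False
        for attempt in range(max_tries):
            chain_seed = seed + 7919 * c + 104729 * attempt
            pos, _report = generate_smooth_chain(
                length, box_size, chain_seed,
                require_unknotted=require_unknotted,
            )
            if tree is None or tree.query(pos, k=1)[0].min() >= min_separation:
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place chain {spec.chain_names[c]} without overlap "
                f"after {max_tries} tries"
            )
        placed.append(pos)
        all_pos = np.vstack(placed)
        tree = cKDTree(all_pos)
    positions = np.vstack(placed)
    return PolymerSystem(
        positions=positions,
        chain_id=spec.chain_id(),
        bead_type=spec.bead_class.astype(np.int8),
        lad_flag=spec.lad_flag.copy(),
    )


@dataclass
class CompressionSchedule:
    """Staged indenter shrink protocol.

    The indenter radius decreases geometrically from the enclosing-sphere
    radius to the target over ``n_stages``; the force constant starts at
    ``k_start`` and doubles each stage so late stages can push straggler
    beads through the crowded interior.
    """

    n_stages: int = 20
    steps_per_stage: int = 10000
    k_start: float = 10.0
    k_ramp: float = 1.2
    k_max: float = 20.0        # ramp cap; F*dt must stay well below sigma
    relax_steps: int = 10000
    pair_force_cap: float = 50.0   # soft push-off cap on pair forces


def compress_to_sphere(system, target_Rc, stage_forcefield=None,
                       schedule=None, config=None):
    """Compress an assembled system into a confinement sphere.

    During compression intra-chain pairs attract (eps = 1 k_BT, cutoff
    2.5 sigma) while inter-chain pairs only repel (eps = 1 k_BT, cutoff
    2^(1/6) sigma), which condenses every chain into its own territory.
    Pair forces are soft-capped throughout (push-off): freshly generated
    spline chains self-overlap below sigma, and uncapped Lennard-Jones
    cores there would eject beads.  The returned system has the wall at
    ``target_Rc`` and all beads inside.
    """
    n = system.n_beads
    min_rc = (n / 8.0) ** (1.0 / 3.0)
    if target_Rc < min_rc:
        raise ValueError(
            f"target_Rc {target_Rc} below close packing ({min_rc:.2f} sigma)"
        )
    sched = schedule or CompressionSchedule()
    ff = stage_forcefield or ForceField(k_bend=5.0)
    cfg = config or SimulationConfig(n_steps=sched.steps_per_stage,
                                     dump_every=sched.steps_per_stage)
    dt = min(cfg.dt, 0.005)
    sys_c = system.copy()
    sys_c.positions -= sys_c.positions.mean(axis=0)
    r0 = float(np.max(np.linalg.norm(sys_c.positions, axis=1))) + 1.0
    r0 = max(r0, target_Rc * 1.05)
    pair_override = (1.0, ATTRACTIVE_CUTOFF, 1.0, WCA_CUTOFF)
    # final indenter radius sits at the wall edge (Rc - sigma/2) so the
    # relaxation stage starts with every bead already inside the wall
    radii = np.geomspace(r0, max(target_Rc - 0.5, 1.0), sched.n_stages)
    step_offset = 0
    for stage, r_ind in enumerate(radii):
        k_ind = min(sched.k_start * sched.k_ramp ** stage, sched.k_max)
        stage_cfg = SimulationConfig(
            n_steps=sched.steps_per_stage, dump_every=sched.steps_per_stage,
            dt=dt, damping=cfg.damping, temperature=cfg.temperature,
            seed=cfg.seed, neighbor_skin=cfg.neighbor_skin,
        )
        sys_c.confinement_radius = math.inf
        run_simulation(
            sys_c, ff, stage_cfg, indenter=(k_ind, float(r_ind)),
            pair_override=pair_override, step_offset=step_offset,
            force_cap=sched.pair_force_cap,
        )
        step_offset += sched.steps_per_stage
    # final relaxation under the actual wall
    sys_c.confinement_radius = float(target_Rc)
    relax_cfg = SimulationConfig(
        n_steps=sched.relax_steps, dump_every=sched.relax_steps,
        dt=dt, damping=cfg.damping, temperature=cfg.temperature,
        seed=cfg.seed, neighbor_skin=cfg.neighbor_skin,
    )
    run_simulation(sys_c, ff, relax_cfg, pair_override=pair_override,
                   step_offset=step_offset, force_cap=sched.pair_force_cap)
    return sys_c
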