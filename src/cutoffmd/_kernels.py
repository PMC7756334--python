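"""Numba-compiled inner loops.

Everything here operates on plain contiguous arrays so the kernels stay
cacheable and trivially testable against the pure-numpy oracles in the test
suite. Positions are kept unwrapped; periodicity enters only through the
minimum-image displacement applied per dimension (orthorhombic boxes).
"""

import numpy as np
from numba import njit

F_ELEC = 138.935458  # 1/(4 pi eps0), kJ mol^-1 nm e^-2 (matches constants.F_ELEC)


@njit(cache=True)
def eval_pairs(pos, box, ai, aj, qq, c6, c12, bucket, k1, r_rf, forces):
    """Accumulate reaction-field electrostatics and Lennard-Jones over an
    atom-pair list.

    ``qq`` is f_elec * q_i * q_j per pair and ``k1 = C_rf / R_rf^3``; the
    pair energy is written as (1/r - 1/R_rf) - (k1/2)(r^2 - R_rf^2) so it is
    exactly zero at the reaction-field radius. ``bucket`` indexes the energy
    decomposition (0 solute-solute, 1 solute-solvent, 2 solvent-solvent).

    Adds forces into ``forces`` (kJ mol^-1 nm^-1) and returns
    ``(e_el[3], e_lj[3], w)`` with ``w = sum r_ij . F_ij`` (the virial is
    ``-w/2``).
    """
    e_el = np.zeros(3)
    e_lj = np.zeros(3)
    w = 0.0
    inv_rrf = 1.0 / r_rf
    rrf2 = r_rf * r_rf
    for k in range(ai.shape[0]):
        i = ai[k]
        j = aj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        b = bucket[k]
        # reaction-field electrostatics
        e_el[b] += qq[k] * ((1.0 / r - inv_rrf) - 0.5 * k1 * (r2 - rrf2))
        fscal = qq[k] * (1.0 / (r2 * r) + k1)
        # Lennard-Jones
        if c12[k] != 0.0 or c6[k] != 0.0:
            ir2 = 1.0 / r2
            ir6 = ir2 * ir2 * ir2
            ir12 = ir6 * ir6
            e_lj[b] += c12[k] * ir12 - c6[k] * ir6
            fscal += (12.0 * c12[k] * ir12 - 6.0 * c6[k] * ir6) * ir2
        fx = fscal * dx
        fy = fscal * dy
        fz = fscal * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        w += dx * fx + dy * fy + dz * fz
    return e_el, e_lj, w


@njit(cache=True)
def expand_entity_pairs(ei, ej, ent_ptr, ent_atoms, excl_keys, n_atoms):
    """Expand entity index pairs into atom index pairs, dropping excluded
    atom pairs. ``excl_keys`` is a sorted array of min*N+max encodings."""
    total = 0
    for k in range(ei.shape[0]):
        si = ent_ptr[ei[k] + 1] - ent_ptr[ei[k]]
        sj = ent_ptr[ej[k] + 1] - ent_ptr[ej[k]]
        total += si * sj
    ai = np.empty(total, dtype=np.int64)
    aj = np.empty(total, dtype=np.int64)
    m = 0
    ne = excl_keys.shape[0]
    for k in range(ei.shape[0]):
        for p in range(ent_ptr[ei[k]], ent_ptr[ei[k] + 1]):
            a = ent_atoms[p]
            for q in range(ent_ptr[ej[k]], ent_ptr[ej[k] + 1]):
                b = ent_atoms[q]
                if a == b:
                    continue
                lo = a if a < b else b
                hi = b if a < b else a
                key = lo * n_atoms + hi
                if ne > 0:
                    # binary search in the sorted exclusion keys
                    lo_i = 0
                    hi_i = ne
                    found = False
                    while lo_i < hi_i:
                        mid = (lo_i + hi_i) // 2
                        if excl_keys[mid] < key:
                            lo_i = mid + 1
                        elif excl_keys[mid] > key:
                            hi_i = mid
                        else:
                            found = True
                            break
                    if found:
                        continue
                ai[m] = a
                aj[m] = b
                m += 1
    return ai[:m], aj[:m]


@njit(cache=True)
def shake(pos, ref, ci, cj, d0sq, invmass, tol, max_iter):
    """Iterative bond-length restoration (SHAKE) of ``pos`` toward the target
    lengths, using the reference geometry ``ref`` for the correction
    direction. Returns the number of iterations, or -1 on non-convergence."""
    n = ci.shape[0]
    for it in range(max_iter):
        converged = True
        for k in range(n):
            i = ci[k]
            j = cj[k]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            diff = d2 - d0sq[k]
            if abs(diff) > tol * d0sq[k]:
                converged = False
                rx = ref[i, 0] - ref[j, 0]
                ry = ref[i, 1] - ref[j, 1]
                rz = ref[i, 2] - ref[j, 2]
                dot = rx * dx + ry * dy + rz * dz
                g = diff / (2.0 * (invmass[i] + invmass[j]) * dot)
                pos[i, 0] -= g * invmass[i] * rx
                pos[i, 1] -= g * invmass[i] * ry
                pos[i, 2] -= g * invmass[i] * rz
                pos[j, 0] += g * invmass[j] * rx
                pos[j, 1] += g * invmass[j] * ry
                pos[j, 2] += g * invmass[j] * rz
        if converged:
            return it + 1
    return -1


@njit(cache=True)
def velocity_project(vel, pos, ci, cj, invmass, tol, max_sweeps):
    """Remove relative velocities along constrained bonds by mass-weighted
    impulses, sweeping until the largest residual (nm/ps) is below ``tol``.
    Returns the final maximum residual."""
    n = ci.shape[0]
    res = 0.0
    for _ in range(max_sweeps):
        res = 0.0
        for k in range(n):
            i = ci[k]
            j = cj[k]
            bx = pos[i, 0] - pos[j, 0]
            by = pos[i, 1] - pos[j, 1]
            bz = pos[i, 2] - pos[j, 2]
            bn = np.sqrt(bx * bx + by * by + bz * bz)
            bx /= bn
            by /= bn
            bz /= bn
            vrel = (
                (vel[i, 0] - vel[j, 0]) * bx
                + (vel[i, 1] - vel[j, 1]) * by
                + (vel[i, 2] - vel[j, 2]) * bz
            )
            if abs(vrel) > res:
                res = abs(vrel)
            p = vrel / (invmass[i] + invmass[j])
            vel[i, 0] -= p * invmass[i] * bx
            vel[i, 1] -= p * invmass[i] * by
            vel[i, 2] -= p * invmass[i] * bz
            vel[j, 0] += p * invmass[j] * bx
            vel[j, 1] += p * invmass[j] * by
            vel[j, 2] += p * invmass[j] * bz
        if res < tol:
            break
    return res


@njit(cache=True)
def max_constraint_violation(pos, ci, cj, d0sq):
    """Largest relative constraint violation |d^2 - d0^2| / d0^2."""
    worst = 0.0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        v = abs(d2 - d0sq[k]) / d0sq[k]
        if v > worst:
            worst = v
    return worst


@njit(cache=True)
def max_velocity_residual(vel, pos, ci, cj):
    """Largest relative velocity along any constrained bond (nm/ps)."""
    worst = 0.0
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        bx = pos[i, 0] - pos[j, 0]
        by = pos[i, 1] - pos[j, 1]
        bz = pos[i, 2] - pos[j, 2]
        bn = np.sqrt(bx * bx + by * by + bz * bz)
        vrel = (
            (vel[i, 0] - vel[j, 0]) * bx
            + (vel[i, 1] - vel[j, 1]) * by
            + (vel[i, 2] - vel[j, 2]) * bz
        ) / bn
        if abs(vrel) > worst:
            worst = abs(vrel)
    return worst


@njit(cache=True)
def classify_pairs_brute(centers, box, r_short, r_long):
    """O(N^2) minimum-image classification of entity-center pairs into the
    short [0, r_short) and intermediate [r_short, r_long) shells. Pairs are
    emitted in lexicographic (i, j) order."""
    n = centers.shape[0]
    rs2 = r_short * r_short
    rl2 = r_long * r_long
    ns = 0
    ni = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rs2:
                ns += 1
            elif d2 < rl2:
                ni += 1
    short = np.empty((ns, 2), dtype=np.int64)
    inter = np.empty((ni, 2), dtype=np.int64)
    ks = 0
    ki = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rs2:
                short[ks, 0] = i
                short[ks, 1] = j
                ks += 1
            elif d2 < rl2:
                inter[ki, 0] = i
                inter[ki, 1] = j
                ki += 1
    return short, inter


@njit(cache=True, fastmath={"reassoc", "contract", "nsz"})
def eval_single_range(
    pos, box, centers, ent_ptr, ent_atoms, ent_bucket_base, mol_id,
    qf, ljt, c6t, c12t, excl_keys, n_atoms, r_cut, k1, r_rf, forces,
):
    """Fused single-range evaluation: classify entity pairs by minimum-image
    center distance (strictly < r_cut) and immediately accumulate all
    non-excluded atom-pair interactions, without materializing a pairlist.
    Positions and centers must be pre-wrapped into [0, box) per dimension
    (the caller does this); minimum image is then a single fold.

    ``qf`` holds plain atomic charges (e); ``ent_bucket_base`` the subsystem
    label per entity (so bucket = label_a + label_b indexes the
    decomposition); ``mol_id`` lets the kernel skip exclusion lookups for
    inter-molecular pairs (exclusions never span molecules). Returns
    ``(e_el[3], e_lj[3], w)`` like :func:`eval_pairs`.
    """
    e_el = np.zeros(3)
    e_lj = np.zeros(3)
    w = 0.0
    inv_rrf = 1.0 / r_rf
    rrf2 = r_rf * r_rf
    rc2 = r_cut * r_cut
    ne = excl_keys.shape[0]
    n_ent = ent_ptr.shape[0] - 1
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    for a in range(n_ent):
        pa0 = ent_ptr[a]
        pa1 = ent_ptr[a + 1]
        for b in range(a + 1, n_ent):
            dx = centers[a, 0] - centers[b, 0]
            dy = centers[a, 1] - centers[b, 1]
            dz = centers[a, 2] - centers[b, 2]
            # positions are pre-wrapped into the box, so one fold suffices
            if dx > hx:
                dx -= box[0]
            elif dx < -hx:
                dx += box[0]
            if dy > hy:
                dy -= box[1]
            elif dy < -hy:
                dy += box[1]
            if dz > hz:
                dz -= box[2]
            elif dz < -hz:
                dz += box[2]
            c2 = dx * dx + dy * dy + dz * dz
            if c2 >= rc2:
                continue
            pb0 = ent_ptr[b]
            pb1 = ent_ptr[b + 1]
            bkt = ent_bucket_base[a] + ent_bucket_base[b]
            singletons = (pa1 - pa0 == 1) and (pb1 - pb0 == 1)
            for p in range(pa0, pa1):
                i = ent_atoms[p]
                for q in range(pb0, pb1):
                    j = ent_atoms[q]
                    if i == j:
                        continue
                    if ne > 0 and mol_id[i] == mol_id[j]:
                        lo = i if i < j else j
                        hi = j if i < j else i
                        key = lo * n_atoms + hi
                        lo_i = 0
                        hi_i = ne
                        found = False
                        while lo_i < hi_i:
                            mid = (lo_i + hi_i) // 2
                            if excl_keys[mid] < key:
                                lo_i = mid + 1
                            elif excl_keys[mid] > key:
                                hi_i = mid
                            else:
                                found = True
                                break
                        if found:
                            continue
                    if singletons:
                        # entity centers are the atoms themselves
                        ddx = dx
                        ddy = dy
                        ddz = dz
                        r2 = c2
                    else:
                        ddx = pos[i, 0] - pos[j, 0]
                        ddy = pos[i, 1] - pos[j, 1]
                        ddz = pos[i, 2] - pos[j, 2]
                        if ddx > hx:
                            ddx -= box[0]
                        elif ddx < -hx:
                            ddx += box[0]
                        if ddy > hy:
                            ddy -= box[1]
                        elif ddy < -hy:
                            ddy += box[1]
                        if ddz > hz:
                            ddz -= box[2]
                        elif ddz < -hz:
                            ddz += box[2]
                        r2 = ddx * ddx + ddy * ddy + ddz * ddz
                    r = np.sqrt(r2)
                    qq = F_ELEC * qf[i] * qf[j]
                    e_el[bkt] += qq * ((1.0 / r - inv_rrf) - 0.5 * k1 * (r2 - rrf2))
                    fscal = qq * (1.0 / (r2 * r) + k1)
                    c6 = c6t[ljt[i], ljt[j]]
                    c12 = c12t[ljt[i], ljt[j]]
                    if c6 != 0.0 or c12 != 0.0:
                        ir2 = 1.0 / r2
                        ir6 = ir2 * ir2 * ir2
                        ir12 = ir6 * ir6
                        e_lj[bkt] += c12 * ir12 - c6 * ir6
                        fscal += (12.0 * c12 * ir12 - 6.0 * c6 * ir6) * ir2
                    fx = fscal * ddx
                    fy = fscal * ddy
                    fz = fscal * ddz
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[i, 2] += fz
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    forces[j, 2] -= fz
                    w += ddx * fx + ddy * fy + ddz * fz
    return e_el, e_lj, w
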