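"""Compiled numerical kernels (numba) for the coarse-grained simulator.

Everything here mirrors the closed-form potentials in :mod:`fgpore.cg_model`;
the scalar Python implementations there are the reference the kernels are
tested against.  Units: kJ/mol, nm, Da, ps.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# ------------------------------------------------------------------ splines


@njit(cache=True)
def eval_spline(x, c, t):
    """Evaluate a scipy CubicSpline (breakpoints x, coefficients c) at t.

    Returns (value, derivative); t is clamped to the table range.
    """
    n = x.shape[0]
    if t <= x[0]:
        t = x[0]
    elif t >= x[n - 1]:
        t = x[n - 1]
    lo, hi = 0, n - 2
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if x[mid] <= t:
            lo = mid
        else:
            hi = mid - 1
    dx = t - x[lo]
    u = ((c[0, lo] * dx + c[1, lo]) * dx + c[2, lo]) * dx + c[3, lo]
    du = (3.0 * c[0, lo] * dx + 2.0 * c[1, lo]) * dx + c[2, lo]
    return u, du


# ------------------------------------------------------------- pair terms


@njit(cache=True)
def _pair_energy(r, sigma, lam_pair, qq, ramp,
                 eps0, cut_lj, cut_el, sw_frac, kappa,
                 eps_c, eps_b, eps_mid, eps_w, coul_pref):
    """Nonbonded pair energy and dU/dr (hydrophobic + screened Coulomb)."""
    u = 0.0
    du = 0.0
    rmin = sigma * 1.122462048309373
    lam = lam_pair * ramp
    rs = sw_frac * cut_lj
    if rmin >= rs:
        # oversized repulsive pair (e.g. wall beads): pure WCA
        if r < rmin:
            s2 = sigma * sigma / (r * r)
            s6 = s2 * s2 * s2
            u += 4.0 * eps0 * (s6 * s6 - s6) + eps0
            du += -24.0 * eps0 * (2.0 * s6 * s6 - s6) / r
    elif r < cut_lj:
        s2 = sigma * sigma / (r * r)
        s6 = s2 * s2 * s2
        ulj = 4.0 * eps0 * (s6 * s6 - s6)
        dulj = -24.0 * eps0 * (2.0 * s6 * s6 - s6) / r
        if r < rmin:
            uh = ulj + (1.0 - lam) * eps0
            duh = dulj
        else:
            uh = lam * ulj
            duh = lam * dulj
        if r > rs:
            x = (r - rs) / (cut_lj - rs)
            w = 1.0 - x * x * (3.0 - 2.0 * x)
            dw = -6.0 * x * (1.0 - x) / (cut_lj - rs)
            duh = duh * w + uh * dw
            uh = uh * w
        u += uh
        du += duh
    if qq != 0.0 and r < cut_el:
        ex = np.exp(-(r - eps_mid) / eps_w)
        eps = eps_c + (eps_b - eps_c) / (1.0 + ex)
        deps = (eps_b - eps_c) * ex / (eps_w * (1.0 + ex) ** 2)
        ue = ramp * coul_pref * qq * np.exp(-kappa * r) / (eps * r)
        due = ue * (-kappa - 1.0 / r - deps / eps)
        rs_e = sw_frac * cut_el
        if r > rs_e:
            x = (r - rs_e) / (cut_el - rs_e)
            w = 1.0 - x * x * (3.0 - 2.0 * x)
            dw = -6.0 * x * (1.0 - x) / (cut_el - rs_e)
            due = due * w + ue * dw
            ue = ue * w
        u += ue
        du += due
    return u, du


# --------------------------------------------------------- neighbour list


@njit(cache=True)
def build_pairs(pos, fixed, cutoff, excl_ptr, excl_idx, pairs_out):
    """Cell-list neighbour search; returns the number of pairs written.

    Pairs between two fixed particles are skipped; exclusions are a CSR
    list of bonded (1-2, 1-3) partners.
    """
    n = pos.shape[0]
    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        lo[d] = pos[:, d].min() - 1e-6
        hi[d] = pos[:, d].max() + 1e-6
    cell = cutoff
    # cap the grid so sparse systems in huge boxes stay O(n)
    nc_cap = int((8.0 * n) ** (1.0 / 3.0)) + 1
    nc = np.empty(3, np.int64)
    for d in range(3):
        nc[d] = min(max(1, int((hi[d] - lo[d]) / cell)), nc_cap)
    ncell = nc[0] * nc[1] * nc[2]
    cid = np.empty(n, np.int64)
    for i in range(n):
        cx = min(nc[0] - 1, int((pos[i, 0] - lo[0]) / (hi[0] - lo[0]) * nc[0]))
        cy = min(nc[1] - 1, int((pos[i, 1] - lo[1]) / (hi[1] - lo[1]) * nc[1]))
        cz = min(nc[2] - 1, int((pos[i, 2] - lo[2]) / (hi[2] - lo[2]) * nc[2]))
        cid[i] = (cx * nc[1] + cy) * nc[2] + cz
    count = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        count[cid[i] + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, np.int64)
    fill = count.copy()
    for i in range(n):
        order[fill[cid[i]]] = i
        fill[cid[i]] += 1
    cut2 = cutoff * cutoff
    np_out = pairs_out.shape[0]
    k = 0
    for i in range(n):
        cx = cid[i] // (nc[1] * nc[2])
        cy = (cid[i] // nc[2]) % nc[1]
        cz = cid[i] % nc[2]
        for ox in range(-1, 2):
            x = cx + ox
            if x < 0 or x >= nc[0]:
                continue
            for oy in range(-1, 2):
                y = cy + oy
                if y < 0 or y >= nc[1]:
                    continue
                for oz in range(-1, 2):
                    z = cz + oz
                    if z < 0 or z >= nc[2]:
                        continue
                    c = (x * nc[1] + y) * nc[2] + z
                    for s in range(count[c], count[c + 1]):
                        j = order[s]
                        if j <= i:
                            continue
                        if fixed[i] == 1 and fixed[j] == 1:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz > cut2:
                            continue
                        skip = False
                        for e in range(excl_ptr[i], excl_ptr[i + 1]):
                            if excl_idx[e] == j:
                                skip = True
                                break
                        if skip:
                            continue
                        if k < np_out:
                            pairs_out[k, 0] = i
                            pairs_out[k, 1] = j
                        k += 1
    return k


# --------------------------------------------------------------- forces


@njit(cache=True)
def compute_forces(pos, charge, lam, sigma, pairs, n_pairs, ramp,
                   bonds, bond_k, bond_r0,
                   angles, ang_x, ang_c, angles_on,
                   torsions, tor_x, tor_c, torsions_on,
                   tether_idx, tether_pos, tether_k,
                   box_half, k_container,
                   membrane_on, memb_half_h, memb_r, wall_r_contact,
                   eps0, cut_lj, cut_el, sw_frac, kappa,
                   eps_c, eps_b, eps_mid, eps_w, coul_pref,
                   forces):
    """Total force and potential energy of the bead system."""
    forces[:] = 0.0
    epot = 0.0
    n_beads = pos.shape[0]
    lam_s = np.empty(n_beads)
    for i in range(n_beads):
        lam_s[i] = np.sqrt(lam[i])
    cut_max = max(cut_lj, cut_el)
    smax = 0.0
    for i in range(n_beads):
        if sigma[i] > smax:
            smax = sigma[i]
    cut_max = max(cut_max, smax * 1.122462048309373)
    cut_max2 = cut_max * cut_max
    # nonbonded
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cut_max2 or r2 < 1e-12:
            continue
        r = np.sqrt(r2)
        sig = 0.5 * (sigma[i] + sigma[j])
        lp = lam_s[i] * lam_s[j]
        qq = charge[i] * charge[j]
        u, du = _pair_energy(r, sig, lp, qq, ramp,
                             eps0, cut_lj, cut_el, sw_frac, kappa,
                             eps_c, eps_b, eps_mid, eps_w, coul_pref)
        epot += u
        f = -du / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    # bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        epot += 0.5 * bond_k * (r - bond_r0) ** 2
        f = -bond_k * (r - bond_r0) / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    # bending (tabulated)
    if angles_on:
        for a in range(angles.shape[0]):
            i = angles[a, 0]
            j = angles[a, 1]
            k = angles[a, 2]
            v1x = pos[i, 0] - pos[j, 0]
            v1y = pos[i, 1] - pos[j, 1]
            v1z = pos[i, 2] - pos[j, 2]
            v2x = pos[k, 0] - pos[j, 0]
            v2y = pos[k, 1] - pos[j, 1]
            v2z = pos[k, 2] - pos[j, 2]
            n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
            n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
            ct = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            th = np.arccos(ct)
            u, dudth = eval_spline(ang_x, ang_c, th)
            epot += u
            st = np.sqrt(1.0 - ct * ct)
            if st < 1e-6:
                continue
            coef = dudth / st
            fix = coef * (v2x / (n1 * n2) - ct * v1x / (n1 * n1))
            fiy = coef * (v2y / (n1 * n2) - ct * v1y / (n1 * n1))
            fiz = coef * (v2z / (n1 * n2) - ct * v1z / (n1 * n1))
            fkx = coef * (v1x / (n1 * n2) - ct * v2x / (n2 * n2))
            fky = coef * (v1y / (n1 * n2) - ct * v2y / (n2 * n2))
            fkz = coef * (v1z / (n1 * n2) - ct * v2z / (n2 * n2))
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[i, 2] += fiz
            forces[k, 0] += fkx
            forces[k, 1] += fky
            forces[k, 2] += fkz
            forces[j, 0] -= fix + fkx
            forces[j, 1] -= fiy + fky
            forces[j, 2] -= fiz + fkz
    # torsion (tabulated)
    if torsions_on:
        for t in range(torsions.shape[0]):
            ia = torsions[t, 0]
            ib = torsions[t, 1]
            ic = torsions[t, 2]
            id_ = torsions[t, 3]
            b1 = pos[ib] - pos[ia]
            b2 = pos[ic] - pos[ib]
            b3 = pos[id_] - pos[ic]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
            n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
            b2n = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
            if n1sq < 1e-10 or n2sq < 1e-10:
                continue
            cr = np.cross(n1, n2)
            x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
            y = (cr[0] * b2[0] + cr[1] * b2[1] + cr[2] * b2[2]) / b2n
            phi = np.arctan2(y, x)
            u, dudphi = eval_spline(tor_x, tor_c, phi)
            epot += u
            fa = -dudphi * (-b2n / n1sq) * n1
            fd = -dudphi * (b2n / n2sq) * n2
            A = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (b2n * b2n)
            B = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (b2n * b2n)
            fb = -(1.0 + A) * fa + B * fd
            fc = -(fa + fb + fd)
            forces[ia] += fa
            forces[ib] += fb
            forces[ic] += fc
            forces[id_] += fd
    # tethers
    for t in range(tether_idx.shape[0]):
        i = tether_idx[t]
        dx = pos[i, 0] - tether_pos[t, 0]
        dy = pos[i, 1] - tether_pos[t, 1]
        dz = pos[i, 2] - tether_pos[t, 2]
        epot += 0.5 * tether_k * (dx * dx + dy * dy + dz * dz)
        forces[i, 0] -= tether_k * dx
        forces[i, 1] -= tether_k * dy
        forces[i, 2] -= tether_k * dz
    # container walls (harmonic beyond +-box_half)
    n = pos.shape[0]
    for i in range(n):
        for d in range(3):
            over = abs(pos[i, d]) - box_half[d]
            if over > 0.0:
                s = 1.0 if pos[i, d] > 0 else -1.0
                epot += 0.5 * k_container * over * over
                forces[i, d] -= s * k_container * over
    # pore wall: analytic cylindrical confinement standing in for the
    # inert wall-bead shell, plus membrane faces closing the slab
    # |z| < h/2 outside the pore lumen
    if membrane_on:
        for i in range(n):
            if abs(pos[i, 2]) >= memb_half_h:
                continue
            rxy = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            if wall_r_contact > 0.0 and rxy > wall_r_contact:
                over = rxy - wall_r_contact
                pen_z = memb_half_h - abs(pos[i, 2])
                if over < pen_z or rxy <= memb_r:
                    # push back into the lumen (wall contact)
                    epot += 0.5 * k_container * over * over
                    if rxy > 1e-9:
                        f = k_container * over / rxy
                        forces[i, 0] -= f * pos[i, 0]
                        forces[i, 1] -= f * pos[i, 1]
                else:
                    # shallow face penetration: push out through the face
                    s = 1.0 if pos[i, 2] > 0 else -1.0
                    epot += 0.5 * k_container * pen_z * pen_z
                    forces[i, 2] += s * k_container * pen_z
    return epot


@njit(cache=True)
def cargo_forces(pos, lam, cargo_pos, sites, cargo_radius, cargo_charge,
                 site_eps, site_thresh, charge, ramp,
                 kappa, eps_c, eps_b, eps_mid, eps_w, coul_pref,
                 restraint_z0, restraint_k, eps0, forces, fcargo):
    """Bead-cargo interactions; returns the potential-energy contribution.

    The cargo is a rigid sphere: WCA repulsion from its surface, Gaussian
    attractive wells at its hydrophobic sites (acting on beads whose
    hydrophobicity exceeds the threshold), a centre point charge under the
    same screened-Coulomb law, and an optional axial umbrella restraint.
    """
    epot = 0.0
    n = pos.shape[0]
    sig = cargo_radius + 0.3
    rmin = sig * 1.122462048309373
    for i in range(n):
        dx = pos[i, 0] - cargo_pos[0]
        dy = pos[i, 1] - cargo_pos[1]
        dz = pos[i, 2] - cargo_pos[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < rmin:
            s6 = (sig / r) ** 6
            epot += 4.0 * eps0 * (s6 * s6 - s6) + eps0
            du = -24.0 * eps0 * (2.0 * s6 * s6 - s6) / r
            f = -du / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            fcargo[0] -= f * dx
            fcargo[1] -= f * dy
            fcargo[2] -= f * dz
        qq = cargo_charge * charge[i]
        if qq != 0.0 and r < 4.0:
            ex = np.exp(-(r - eps_mid) / eps_w)
            eps = eps_c + (eps_b - eps_c) / (1.0 + ex)
            deps = (eps_b - eps_c) * ex / (eps_w * (1.0 + ex) ** 2)
            ue = ramp * coul_pref * qq * np.exp(-kappa * r) / (eps * r)
            due = ue * (-kappa - 1.0 / r - deps / eps)
            epot += ue
            f = -due / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            fcargo[0] -= f * dx
            fcargo[1] -= f * dy
            fcargo[2] -= f * dz
        if lam[i] > site_thresh:
            for s in range(sites.shape[0]):
                sx = cargo_pos[0] + sites[s, 0]
                sy = cargo_pos[1] + sites[s, 1]
                sz = cargo_pos[2] + sites[s, 2]
                ddx = pos[i, 0] - sx
                ddy = pos[i, 1] - sy
                ddz = pos[i, 2] - sz
                d = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                if d < 2.0:
                    # Gaussian well centred at contact (0.3 nm)
                    g = np.exp(-((d - 0.3) ** 2) / 0.18)
                    u = -ramp * site_eps * lam[i] * g
                    epot += u
                    du = -u * 2.0 * (d - 0.3) / 0.18
                    if d > 1e-6:
                        f = -du / d
                        forces[i, 0] += f * ddx
                        forces[i, 1] += f * ddy
                        forces[i, 2] += f * ddz
                        fcargo[0] -= f * ddx
                        fcargo[1] -= f * ddy
                        fcargo[2] -= f * ddz
    if restraint_k > 0.0:
        dzr = cargo_pos[2] - restraint_z0
        epot += 0.5 * restraint_k * dzr * dzr
        fcargo[2] -= restraint_k * dzr
    return epot


# ------------------------------------------------------------ integrator


@njit(cache=True)
def run_md(pos, vel, mass, charge, lam, sigma, fixed,
           bonds, bond_k, bond_r0,
           angles, ang_x, ang_c, angles_on,
           torsions, tor_x, tor_c, torsions_on,
           tether_idx, tether_pos, tether_k,
           excl_ptr, excl_idx,
           box_half, k_container, membrane_on, memb_half_h, memb_r,
           wall_r_contact,
           eps0, cut_lj, cut_el, sw_frac, kappa,
           eps_c, eps_b, eps_mid, eps_w, coul_pref,
           cargo_on, cargo_pos, cargo_vel, cargo_mass, cargo_radius,
           cargo_charge, sites, site_eps, site_thresh,
           restraint_z0, restraint_k,
           dt, gamma, kBT, n_steps, ramp_steps, stride,
           skin, check_every, seed, max_pairs,
           frames, cargo_frames, ekin_out, epot_out):
    """BAOAB Langevin dynamics; fills frames/energies at the output stride.

    Returns the number of frames written, or -1 on a NaN blow-up (the
    offending frame index is then in ekin_out[0]).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    fcargo = np.zeros(3)
    pairs = np.zeros((max_pairs, 2), np.int64)
    cutoff = max(cut_el, cut_lj)
    # largest WCA contact can exceed the LJ cutoff (wall beads)
    smax = 0.0
    for i in range(n):
        if sigma[i] > smax:
            smax = sigma[i]
    cutoff = max(cutoff, smax * 1.122462048309373)
    n_pairs = build_pairs(pos, fixed, cutoff + skin, excl_ptr, excl_idx, pairs)
    ref_pos = pos.copy()

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    half_dt = 0.5 * dt
    frame = 0
    ramp = 0.0 if ramp_steps > 0 else 1.0
    epot = compute_forces(pos, charge, lam, sigma, pairs, n_pairs, ramp,
                          bonds, bond_k, bond_r0,
                          angles, ang_x, ang_c, angles_on,
                          torsions, tor_x, tor_c, torsions_on,
                          tether_idx, tether_pos, tether_k,
                          box_half, k_container,
                          membrane_on, memb_half_h, memb_r, wall_r_contact,
                          eps0, cut_lj, cut_el, sw_frac, kappa,
                          eps_c, eps_b, eps_mid, eps_w, coul_pref,
                          forces)
    if cargo_on:
        fcargo[:] = 0.0
        epot += cargo_forces(pos, lam, cargo_pos, sites, cargo_radius,
                             cargo_charge, site_eps, site_thresh, charge,
                             ramp, kappa, eps_c, eps_b, eps_mid, eps_w,
                             coul_pref, restraint_z0, restraint_k,
                             eps0, forces, fcargo)
    for step in range(n_steps):
        ramp = 1.0
        if ramp_steps > 0 and step < ramp_steps:
            ramp = step / ramp_steps
        # B (half kick)
        for i in range(n):
            if fixed[i] == 0:
                for d in range(3):
                    vel[i, d] += half_dt * forces[i, d] / mass[i]
        if cargo_on:
            for d in range(3):
                cargo_vel[d] += half_dt * fcargo[d] / cargo_mass
        # A (half drift)
        for i in range(n):
            if fixed[i] == 0:
                for d in range(3):
                    pos[i, d] += half_dt * vel[i, d]
        if cargo_on:
            for d in range(3):
                cargo_pos[d] += half_dt * cargo_vel[d]
        # O (thermostat)
        for i in range(n):
            if fixed[i] == 0:
                sd = np.sqrt(kBT / mass[i])
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * sd * np.random.standard_normal()
        if cargo_on:
            sd = np.sqrt(kBT / cargo_mass)
            for d in range(3):
                cargo_vel[d] = c1 * cargo_vel[d] + c2 * sd * np.random.standard_normal()
        # A (half drift)
        for i in range(n):
            if fixed[i] == 0:
                for d in range(3):
                    pos[i, d] += half_dt * vel[i, d]
        if cargo_on:
            for d in range(3):
                cargo_pos[d] += half_dt * cargo_vel[d]
        # neighbour-list maintenance (displacement criterion), before the
        # force evaluation at the new positions
        if (step + 1) % check_every == 0:
            dmax = 0.0
            for i in range(n):
                if fixed[i] == 0:
                    dd = ((pos[i, 0] - ref_pos[i, 0]) ** 2
                          + (pos[i, 1] - ref_pos[i, 1]) ** 2
                          + (pos[i, 2] - ref_pos[i, 2]) ** 2)
                    if dd > dmax:
                        dmax = dd
            if np.sqrt(dmax) > 0.5 * skin:
                n_pairs = build_pairs(pos, fixed, cutoff + skin,
                                      excl_ptr, excl_idx, pairs)
                ref_pos[:] = pos
        # B (half kick) with forces at the new positions
        epot = compute_forces(pos, charge, lam, sigma, pairs, n_pairs, ramp,
                              bonds, bond_k, bond_r0,
                              angles, ang_x, ang_c, angles_on,
                              torsions, tor_x, tor_c, torsions_on,
                              tether_idx, tether_pos, tether_k,
                              box_half, k_container,
                              membrane_on, memb_half_h, memb_r, wall_r_contact,
                              eps0, cut_lj, cut_el, sw_frac, kappa,
                              eps_c, eps_b, eps_mid, eps_w, coul_pref,
                              forces)
        if cargo_on:
            fcargo[:] = 0.0
            epot += cargo_forces(pos, lam, cargo_pos, sites, cargo_radius,
                                 cargo_charge, site_eps, site_thresh, charge,
                                 ramp, kappa, eps_c, eps_b, eps_mid, eps_w,
                                 coul_pref, restraint_z0, restraint_k,
                                 eps0, forces, fcargo)
        for i in range(n):
            if fixed[i] == 0:
                for d in range(3):
                    vel[i, d] += half_dt * forces[i, d] / mass[i]
        if cargo_on:
            for d in range(3):
                cargo_vel[d] += half_dt * fcargo[d] / cargo_mass

        if (step + 1) % stride == 0:
            if not np.isfinite(pos).all():
                ekin_out[0] = step
                return -1
            if frame < frames.shape[0]:
                frames[frame] = pos
                if cargo_on:
                    cargo_frames[frame, 0] = cargo_pos[0]
                    cargo_frames[frame, 1] = cargo_pos[1]
                    cargo_frames[frame, 2] = cargo_pos[2]
                ek = 0.0
                nf = 0
                for i in range(n):
                    if fixed[i] == 0:
                        nf += 1
                        ek += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                               + vel[i, 2] ** 2)
                ekin_out[frame] = ek
                epot_out[frame] = epot
                frame += 1
    return frame
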