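"""Numba kernels: pairwise forces and the BAOAB Langevin inner loop.

All kernels work in kcal/mol, Å, ps, amu, e.  The nonbonded potential is
Lennard-Jones (Lorentz–Berthelot mixing) plus Coulomb, both multiplied by
the CHARMM switching polynomial between ``switch_on`` and ``cutoff`` so
that energies and forces go smoothly to zero — forces are exact negative
gradients of the reported energies.
"""

import numpy as np
from numba import njit

from .units import COULOMB_K, KCAL_TO_AKMA

# status codes returned by the propagation kernel
STATUS_OK = 0
STATUS_BLOWUP = 1

_FORCE_BLOWUP = 1.0e5  # kcal/mol/Å per particle component


@njit(cache=True)
def _switch(r2, ron2, roff2):
    """CHARMM switching value and d(S)/d(r²)."""
    if r2 <= ron2:
        return 1.0, 0.0
    denom = (roff2 - ron2) ** 3
    a = roff2 - r2
    s = a * a * (roff2 + 2.0 * r2 - 3.0 * ron2) / denom
    ds_dr2 = -6.0 * a * (r2 - ron2) / denom
    return s, ds_dr2


@njit(cache=True)
def forces_energies(pos, charges, eps, sig, excl, bonds, bond_k, bond_r0,
                    restrained, ref_pos, k_restr, cont_center, cont_radius,
                    cont_k, cutoff, switch_on, forces):
    """Fill ``forces`` (N,3) and return (e_bond, e_lj, e_coulomb, e_restraint).

    ``excl`` is an (N,N) uint8 matrix of nonbonded exclusions (bonded
    pairs).  Container (flat-bottom sphere) energy is folded into the
    restraint term.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0

    e_lj = 0.0
    e_coul = 0.0
    roff2 = cutoff * cutoff
    ron2 = switch_on * switch_on
    for i in range(n):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 1, n):
            if excl[i, j] != 0:
                continue
            dx = xi - pos[j, 0]
            if dx > cutoff or dx < -cutoff:
                continue
            dy = yi - pos[j, 1]
            if dy > cutoff or dy < -cutoff:
                continue
            dz = zi - pos[j, 2]
            if dz > cutoff or dz < -cutoff:
                continue
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= roff2 or r2 == 0.0:
                continue
            r = np.sqrt(r2)
            s, ds_dr2 = _switch(r2, ron2, roff2)

            # Lennard-Jones, Lorentz-Berthelot mixing
            sij = 0.5 * (sig[i] + sig[j])
            eij = np.sqrt(eps[i] * eps[j])
            sr2 = (sij * sij) / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            v_lj = 4.0 * eij * (sr12 - sr6)
            dv_lj_dr = 4.0 * eij * (-12.0 * sr12 + 6.0 * sr6) / r

            # Coulomb
            v_c = COULOMB_K * charges[i] * charges[j] / r
            dv_c_dr = -v_c / r

            e_lj += v_lj * s
            e_coul += v_c * s

            # d(V·S)/dr = V'·S + V·dS/dr,  dS/dr = 2 r dS/dr²
            dvs_dr = (dv_lj_dr + dv_c_dr) * s + (v_lj + v_c) * 2.0 * r * ds_dr2
            fmag = -dvs_dr / r  # force along (ri - rj), per unit displacement
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz

    e_bond = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_bond += bond_k[b] * dr * dr
        if r > 0.0:
            fmag = -2.0 * bond_k[b] * dr / r
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz

    e_restr = 0.0
    for i in range(n):
        if restrained[i]:
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            e_restr += 0.5 * k_restr * (dx * dx + dy * dy + dz * dz)
            forces[i, 0] -= k_restr * dx
            forces[i, 1] -= k_restr * dy
            forces[i, 2] -= k_restr * dz
    if cont_k > 0.0:
        for i in range(n):
            dx = pos[i, 0] - cont_center[0]
            dy = pos[i, 1] - cont_center[1]
            dz = pos[i, 2] - cont_center[2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > cont_radius:
                over = d - cont_radius
                e_restr += 0.5 * cont_k * over * over
                fmag = -cont_k * over / d
                forces[i, 0] += fmag * dx
                forces[i, 1] += fmag * dy
                forces[i, 2] += fmag * dz

    return e_bond, e_lj, e_coul, e_restr


@njit(cache=True)
def _add_spring(pos, forces, masses, pull_idx, k_spring, anchor, f_spring_out):
    """COM spring: force k·(anchor − COM), mass-distributed over pull_idx."""
    m_tot = 0.0
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for a in range(pull_idx.shape[0]):
        i = pull_idx[a]
        m = masses[i]
        m_tot += m
        cx += m * pos[i, 0]
        cy += m * pos[i, 1]
        cz += m * pos[i, 2]
    cx /= m_tot
    cy /= m_tot
    cz /= m_tot
    fx = k_spring * (anchor[0] - cx)
    fy = k_spring * (anchor[1] - cy)
    fz = k_spring * (anchor[2] - cz)
    f_spring_out[0] = fx
    f_spring_out[1] = fy
    f_spring_out[2] = fz
    for a in range(pull_idx.shape[0]):
        i = pull_idx[a]
        w = masses[i] / m_tot
        forces[i, 0] += w * fx
        forces[i, 1] += w * fy
        forces[i, 2] += w * fz
    return cx, cy, cz


@njit(cache=True)
def run_baoab(pos, vel, masses, charges, eps, sig, excl, bonds, bond_k, bond_r0,
              restrained, ref_pos, k_restr, cont_center, cont_radius, cont_k,
              cutoff, switch_on, n_steps, dt, gamma, kT, noise,
              pull_idx, k_spring, anchor0, anchor_vel,
              record_every, rec_t, rec_anchor, rec_com, rec_force,
              traj_every, traj_t, traj_frames):
    """Propagate ``n_steps`` of BAOAB Langevin dynamics in place.

    ``noise`` is (n_steps, N, 3) standard normals drawn by the caller (the
    seeded stream lives outside the kernel).  If ``pull_idx`` is non-empty
    a moving-anchor COM spring is applied, with the anchor at local time
    τ = s·dt placed exactly at ``anchor0 + anchor_vel·τ``.  Samples are
    recorded at local steps 0, record_every, 2·record_every, …; trajectory
    frames likewise at ``traj_every`` (0 disables).  Returns
    (status, n_recorded, n_frames).
    """
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    pulled = pull_idx.shape[0] > 0

    # per-particle O-step noise amplitude and B-step factor
    c2 = np.empty(n)
    inv_m = np.empty(n)
    for i in range(n):
        c2[i] = np.sqrt(kT * KCAL_TO_AKMA / masses[i] * (1.0 - c1 * c1))
        inv_m[i] = KCAL_TO_AKMA / masses[i]

    forces = np.empty((n, 3))
    f_spring = np.zeros(3)
    anchor = np.empty(3)

    e_b, e_l, e_c, e_r = forces_energies(
        pos, charges, eps, sig, excl, bonds, bond_k, bond_r0, restrained,
        ref_pos, k_restr, cont_center, cont_radius, cont_k, cutoff, switch_on,
        forces)
    if pulled:
        anchor[0] = anchor0[0]
        anchor[1] = anchor0[1]
        anchor[2] = anchor0[2]
        com_x, com_y, com_z = _add_spring(pos, forces, masses, pull_idx,
                                          k_spring, anchor, f_spring)

    n_rec = 0
    n_traj = 0
    if record_every > 0:
        rec_t[0] = 0.0
        if pulled:
            for d in range(3):
                rec_anchor[0, d] = anchor[d]
                rec_force[0, d] = f_spring[d]
            rec_com[0, 0] = com_x
            rec_com[0, 1] = com_y
            rec_com[0, 2] = com_z
        n_rec = 1
    if traj_every > 0:
        traj_t[0] = 0.0
        for i in range(n):
            for d in range(3):
                traj_frames[0, i, d] = pos[i, d]
        n_traj = 1

    half_dt = 0.5 * dt
    for s in range(n_steps):
        # B
        for i in range(n):
            f = inv_m[i] * half_dt
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        # A
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # O
        if gamma > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2[i] * noise[s, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2[i] * noise[s, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2[i] * noise[s, i, 2]
        # A
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # force refresh + final B
        e_b, e_l, e_c, e_r = forces_energies(
            pos, charges, eps, sig, excl, bonds, bond_k, bond_r0, restrained,
            ref_pos, k_restr, cont_center, cont_radius, cont_k, cutoff,
            switch_on, forces)
        if pulled:
            tau = (s + 1) * dt
            anchor[0] = anchor0[0] + anchor_vel[0] * tau
            anchor[1] = anchor0[1] + anchor_vel[1] * tau
            anchor[2] = anchor0[2] + anchor_vel[2] * tau
            com_x, com_y, com_z = _add_spring(pos, forces, masses, pull_idx,
                                              k_spring, anchor, f_spring)
        for i in range(n):
            f = inv_m[i] * half_dt
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]

        # blow-up guard
        for i in range(n):
            for d in range(3):
                if (not np.isfinite(pos[i, d]) or abs(pos[i, d]) > 1.0e7
                        or abs(forces[i, d]) > _FORCE_BLOWUP):
                    return STATUS_BLOWUP, n_rec, n_traj

        if record_every > 0 and (s + 1) % record_every == 0:
            rec_t[n_rec] = (s + 1) * dt
            if pulled:
                for d in range(3):
                    rec_anchor[n_rec, d] = anchor[d]
                    rec_force[n_rec, d] = f_spring[d]
                rec_com[n_rec, 0] = com_x
                rec_com[n_rec, 1] = com_y
                rec_com[n_rec, 2] = com_z
            n_rec += 1
        if traj_every > 0 and (s + 1) % traj_every == 0:
            traj_t[n_traj] = (s + 1) * dt
            for i in range(n):
                for d in range(3):
                    traj_frames[n_traj, i, d] = pos[i, d]
            n_traj += 1

    return STATUS_OK, n_rec, n_traj
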