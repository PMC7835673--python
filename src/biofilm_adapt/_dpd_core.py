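"""Numba kernel for the coarse-grained bacteria/polymer/solvent shear model.

Standard dissipative-particle-dynamics forces: soft conservative
repulsion ``a_ij (1 - r/r_c)``, pairwise dissipative friction
``-gamma_d (1 - r/r_c)^2 (rhat . v_ij) rhat`` and matched random kicks
``sigma_r (1 - r/r_c) xi rhat / sqrt(dt)`` — all pairwise antisymmetric,
so momentum is conserved to round-off.  Harmonic bonds hold polymer
chains and bacterial bead clusters together; crosslinks are extra
harmonic springs.

Oscillatory simple shear is imposed by an affine remap of all x
coordinates by the per-step strain increment, with Lees-Edwards
(tilted) periodic images: the minimum image across the y boundary
carries an x offset of ``strain * box``.  The off-diagonal virial
stress (kinetic + all pair forces) is recorded every step.

Neighbor search uses a per-step linked cell list built on the
back-mapped coordinate ``x' = x - strain * y`` (orthorhombic in the
sheared frame); the x search range widens with the instantaneous tilt.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_dpd(
    pos,
    vel,
    types,
    a_mat,
    gamma_d,
    sigma_r,
    r_c,
    box,
    bonds,
    bond_k,
    bond_r0,
    xlinks,
    xlink_k,
    xlink_r0,
    dt,
    strain,
    seed,
):
    """Integrate ``len(strain) - 1`` velocity-Verlet steps under shear.

    ``strain[k]`` is the imposed strain at step k; the increment is
    applied as an affine x displacement before each step.  Returns
    (sigma_xy, temperature) per step, where sigma_xy is the negative
    off-diagonal virial pressure (positive for a network pulled along
    the strain) in reduced units.

    Positions are updated in place; y and z stay wrapped in [0, box),
    x is kept wrapped modulo the tilted image convention.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_steps = strain.shape[0] - 1
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    forces = np.zeros((n, 3))
    sigma_xy = np.empty(n_steps)
    temperature = np.empty(n_steps)
    vol = box * box * box

    # initial forces at strain[0]
    virial = _compute_forces(
        pos, vel, types, a_mat, gamma_d, sigma_r, inv_sqrt_dt, r_c, box,
        strain[0], bonds, bond_k, bond_r0, xlinks, xlink_k, xlink_r0, forces,
    )
    for step in range(n_steps):
        g0 = strain[step]
        g1 = strain[step + 1]
        dg = g1 - g0
        # half-kick + drift
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
            pos[i, 0] += dt * vel[i, 0] + dg * pos[i, 1]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        # wrap with Lees-Edwards images at the new strain
        for i in range(n):
            if pos[i, 1] >= box:
                pos[i, 1] -= box
                pos[i, 0] -= g1 * box
            elif pos[i, 1] < 0.0:
                pos[i, 1] += box
                pos[i, 0] += g1 * box
            if pos[i, 2] >= box:
                pos[i, 2] -= box
            elif pos[i, 2] < 0.0:
                pos[i, 2] += box
            pos[i, 0] -= box * np.floor(pos[i, 0] / box)
        virial = _compute_forces(
            pos, vel, types, a_mat, gamma_d, sigma_r, inv_sqrt_dt, r_c, box,
            g1, bonds, bond_k, bond_r0, xlinks, xlink_k, xlink_r0, forces,
        )
        kin_xy = 0.0
        ke = 0.0
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
            kin_xy += vel[i, 0] * vel[i, 1]
            ke += (
                vel[i, 0] * vel[i, 0]
                + vel[i, 1] * vel[i, 1]
                + vel[i, 2] * vel[i, 2]
            )
        sigma_xy[step] = -(kin_xy + virial) / vol
        temperature[step] = ke / (3.0 * n)
    return sigma_xy, temperature


@njit(cache=True, inline="always")
def _min_image(dxp, dy, dz, box, g):
    """Minimum-image displacement in the lab frame from sheared-frame deltas."""
    dy -= box * np.round(dy / box)
    dz -= box * np.round(dz / box)
    dxp -= box * np.round(dxp / box)
    dx = dxp + g * dy
    return dx, dy, dz


@njit(cache=True)
def _compute_forces(
    pos, vel, types, a_mat, gamma_d, sigma_r, inv_sqrt_dt, r_c, box, g,
    bonds, bond_k, bond_r0, xlinks, xlink_k, xlink_r0, forces,
):
    """Fill ``forces`` and return the pair-virial xy component."""
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    virial = 0.0

    # cell list on back-mapped x' = x - g*y
    ncell = int(box / r_c)
    if ncell < 3:
        ncell = 1
    cell = box / ncell
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    xprime = np.empty(n)
    for i in range(n):
        xp = pos[i, 0] - g * pos[i, 1]
        xp -= box * np.floor(xp / box)
        xprime[i] = xp
        ix = int(xp / cell) % ncell
        iy = int(pos[i, 1] / cell) % ncell
        iz = int(pos[i, 2] / cell) % ncell
        cx[i] = ix
        cy[i] = iy
        cz[i] = iz
        idx = (iz * ncell + iy) * ncell + ix
        nxt[i] = head[idx]
        head[idx] = i

    # tilt widens the x' interaction span: |dx'| <= (1+|g|) r_c
    ox_max = int(np.ceil((1.0 + abs(g)) * r_c / cell - 1e-12))
    if ncell == 1:
        ox_max = 0
    rc2 = r_c * r_c
    for i in range(n):
        ti = types[i]
        for oz in range(-1, 2):
            for oy in range(-1, 2):
                for ox in range(-ox_max, ox_max + 1):
                    if ncell == 1 and (ox != 0 or oy != 0 or oz != 0):
                        continue
                    ccx = (cx[i] + ox) % ncell
                    ccy = (cy[i] + oy) % ncell
                    ccz = (cz[i] + oz) % ncell
                    j = head[(ccz * ncell + ccy) * ncell + ccx]
                    while j >= 0:
                        if j > i:
                            dx, dy, dz = _min_image(
                                xprime[i] - xprime[j],
                                pos[i, 1] - pos[j, 1],
                                pos[i, 2] - pos[j, 2],
                                box,
                                g,
                            )
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2 and r2 > 1e-12:
                                r = np.sqrt(r2)
                                w = 1.0 - r / r_c
                                ex = dx / r
                                ey = dy / r
                                ez = dz / r
                                dvx = vel[i, 0] - vel[j, 0]
                                dvy = vel[i, 1] - vel[j, 1]
                                dvz = vel[i, 2] - vel[j, 2]
                                rdotv = ex * dvx + ey * dvy + ez * dvz
                                fmag = (
                                    a_mat[ti, types[j]] * w
                                    - gamma_d * w * w * rdotv
                                    + sigma_r * w * np.random.normal() * inv_sqrt_dt
                                )
                                fxp = fmag * ex
                                fyp = fmag * ey
                                fzp = fmag * ez
                                forces[i, 0] += fxp
                                forces[i, 1] += fyp
                                forces[i, 2] += fzp
                                forces[j, 0] -= fxp
                                forces[j, 1] -= fyp
                                forces[j, 2] -= fzp
                                virial += fxp * dy
                        j = nxt[j]

    # harmonic bonds (chains / bacterial clusters), then crosslinks
    for arr, kk, r0 in ((bonds, bond_k, bond_r0), (xlinks, xlink_k, xlink_r0)):
        for b in range(arr.shape[0]):
            i = arr[b, 0]
            j = arr[b, 1]
            dx, dy, dz = _min_image(
                xprime[i] - xprime[j],
                pos[i, 1] - pos[j, 1],
                pos[i, 2] - pos[j, 2],
                box,
                g,
            )
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                fmag = -kk * (r - r0) / r
                fxp = fmag * dx
                fyp = fmag * dy
                fzp = fmag * dz
                forces[i, 0] += fxp
                forces[i, 1] += fyp
                forces[i, 2] += fzp
                forces[j, 0] -= fxp
                forces[j, 1] -= fyp
                forces[j, 2] -= fzp
                virial += fxp * dy
    return virial
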