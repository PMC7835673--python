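"""Numba kernels for the 2D run-and-tumble colony simulator.

Rods are spherocylinders: a line segment of half-length ``a = (L - w)/2``
with a circular cap of diameter ``w``.  Pair interactions act on the
minimum distance between the two axis segments through a Lennard-Jones
potential whose attractive branch is scaled by ``lam`` (well depth
``lam * eps``, minimum at ``2**(1/6) * w``).  Dynamics are overdamped;
per-step force displacements are capped at a fraction of the width so a
steep repulsive core cannot destabilise the integration.

Forces are evaluated over a Verlet pair list (pairs within
``r_cut + skin`` of axis-axis distance) rebuilt from a linked cell list
whenever accumulated motion could let an unlisted pair enter range.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi
R_MIN_FACTOR = 2.0 ** (1.0 / 6.0)


@njit(cache=True, fastmath=True, inline="always")
def _pair_force_mag(d, eps, lam, sigma):
    """-dU/dd of the attraction-scaled LJ law (positive = repulsive)."""
    if d < 0.3 * sigma:
        d = 0.3 * sigma  # deep-core guard; displacement cap bounds the move anyway
    sr2 = (sigma / d) * (sigma / d)
    sr6 = sr2 * sr2 * sr2
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / d
    if d > R_MIN_FACTOR * sigma:
        f *= lam
    return f


@njit(cache=True, fastmath=True, inline="always")
def _seg_seg(cx1, cy1, ux1, uy1, a1, cx2, cy2, ux2, uy2, a2):
    """Closest points of two 2D segments; returns (s, t, dx, dy, dist).

    ``s``/``t`` are arc-length parameters in [-a, a]; (dx, dy) points from
    segment 2's closest point to segment 1's.
    """
    dx0 = cx1 - cx2
    dy0 = cy1 - cy2
    B = ux1 * ux2 + uy1 * uy2
    D = ux1 * dx0 + uy1 * dy0
    E = ux2 * dx0 + uy2 * dy0
    denom = 1.0 - B * B
    if denom > 1e-12:
        s = (B * E - D) / denom
    else:
        s = 0.0
    if s > a1:
        s = a1
    elif s < -a1:
        s = -a1
    t = s * B + E
    if t > a2:
        t = a2
    elif t < -a2:
        t = -a2
    s = t * B - D
    if s > a1:
        s = a1
    elif s < -a1:
        s = -a1
    dx = dx0 + s * ux1 - t * ux2
    dy = dy0 + s * uy1 - t * uy2
    dist = np.sqrt(dx * dx + dy * dy)
    return s, t, dx, dy, dist


@njit(cache=True)
def single_pair_force(dist, eps, lam, sigma):
    return _pair_force_mag(dist, eps, lam, sigma)


@njit(cache=True, fastmath=True)
def _build_pairs(x, y, ux, uy, ahalf, length, n, sigma, reach, box, pair_i, pair_j):
    """Fill the Verlet pair list with pairs of axis-axis distance < reach.

    Candidate pairs come from a linked cell list over rod centers (cell
    edge >= the largest possible interaction span).  Returns the number
    of pairs, or -1 if the capacity of ``pair_i`` is exceeded.
    """
    lmax = 0.0
    for i in range(n):
        if length[i] > lmax:
            lmax = length[i]
    span = (lmax - sigma) + reach  # max center distance of an interacting pair
    ncell = int(box / span)
    if ncell < 3:
        ncell = 1
    cell_size = box / ncell
    head = np.full(ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cix = np.empty(n, dtype=np.int64)
    ciy = np.empty(n, dtype=np.int64)
    for i in range(n):
        cxi = int(x[i] / cell_size) % ncell
        cyi = int(y[i] / cell_size) % ncell
        cix[i] = cxi
        ciy[i] = cyi
        idx = cyi * ncell + cxi
        nxt[i] = head[idx]
        head[idx] = i
    cap = pair_i.shape[0]
    n_pairs = 0
    for i in range(n):
        uxi = ux[i]
        uyi = uy[i]
        ai = ahalf[i]
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                if ncell == 1 and (ox != 0 or oy != 0):
                    continue
                ccx = (cix[i] + ox) % ncell
                ccy = (ciy[i] + oy) % ncell
                j = head[ccy * ncell + ccx]
                while j >= 0:
                    if j > i:
                        ddx = x[i] - x[j]
                        ddy = y[i] - y[j]
                        ddx -= box * np.round(ddx / box)
                        ddy -= box * np.round(ddy / box)
                        pair_span = ai + ahalf[j] + reach
                        if ddx * ddx + ddy * ddy < pair_span * pair_span:
                            uxj = ux[j]
                            uyj = uy[j]
                            aj = ahalf[j]
                            s, t, dx, dy, dist = _seg_seg(
                                ddx, ddy, uxi, uyi, ai, 0.0, 0.0, uxj, uyj, aj
                            )
                            if dist < reach:
                                if n_pairs >= cap:
                                    return -1
                                pair_i[n_pairs] = i
                                pair_j[n_pairs] = j
                                n_pairs += 1
                    j = nxt[j]
    return n_pairs


@njit(cache=True, fastmath=True)
def advance_block(
    x,
    y,
    theta,
    target,
    length,
    n,
    n_steps,
    dt,
    v,
    tau_run,
    eps,
    lam,
    sigma,
    r_cut,
    mobility,
    cap_frac,
    omega_tumble,
    box,
    elong_rate,
    seed,
):
    """Advance ``n`` rods by ``n_steps`` overdamped steps.

    Motion = self-propulsion along the orientation + capped pair-force
    displacement + Poisson tumbling.  A tumble redraws the *target*
    heading uniformly; the body then turns toward it at rate
    ``omega_tumble`` (finite-duration tumble), so a rod cannot sweep
    instantaneously through its packed neighbours.  Lengths elongate
    linearly at ``elong_rate`` (length units per second); no division
    happens here.  Returns the maximum axis-axis overlap depth
    (``sigma - d``, > 0 means cores overlap) seen on the final step.
    """
    np.random.seed(seed)
    p_tumble = 1.0 - np.exp(-dt / tau_run)
    cap = cap_frac * sigma
    if cap < 2.0 * v * dt:
        cap = 2.0 * v * dt  # relaxation must outrun propulsion at coarse dt
    skin = 0.5 * sigma
    reach = r_cut + skin
    capacity = 60 * n + 64
    pair_i = np.empty(capacity, dtype=np.int64)
    pair_j = np.empty(capacity, dtype=np.int64)
    fx = np.zeros(n)
    fy = np.zeros(n)
    tq = np.zeros(n)
    ux = np.empty(n)
    uy = np.empty(n)
    ahalf = np.empty(n)
    max_overlap = 0.0
    n_pairs = -1
    acc_motion = skin  # force an initial build
    for step in range(n_steps):
        for i in range(n):
            ux[i] = np.cos(theta[i])
            uy[i] = np.sin(theta[i])
            ai = 0.5 * (length[i] - sigma)
            if ai < 0.0:
                ai = 0.0
            ahalf[i] = ai
        if 2.0 * acc_motion >= skin:
            n_pairs = _build_pairs(
                x, y, ux, uy, ahalf, length, n, sigma, reach, box, pair_i, pair_j
            )
            while n_pairs < 0:  # capacity exceeded: grow and retry
                capacity *= 2
                pair_i = np.empty(capacity, dtype=np.int64)
                pair_j = np.empty(capacity, dtype=np.int64)
                n_pairs = _build_pairs(
                    x, y, ux, uy, ahalf, length, n, sigma, reach, box, pair_i, pair_j
                )
            acc_motion = 0.0
        for i in range(n):
            fx[i] = 0.0
            fy[i] = 0.0
            tq[i] = 0.0
        max_overlap = 0.0
        for k in range(n_pairs):
            i = pair_i[k]
            j = pair_j[k]
            ddx = x[i] - x[j]
            ddy = y[i] - y[j]
            ddx -= box * np.round(ddx / box)
            ddy -= box * np.round(ddy / box)
            uxi = ux[i]
            uyi = uy[i]
            ai = ahalf[i]
            uxj = ux[j]
            uyj = uy[j]
            aj = ahalf[j]
            s, t, dx, dy, dist = _seg_seg(ddx, ddy, uxi, uyi, ai, 0.0, 0.0, uxj, uyj, aj)
            if dist < r_cut and dist > 0.0:
                f = _pair_force_mag(dist, eps, lam, sigma)
                fxp = f * dx / dist
                fyp = f * dy / dist
                fx[i] += fxp
                fy[i] += fyp
                fx[j] -= fxp
                fy[j] -= fyp
                # torque about each center from the contact force
                tq[i] += s * (uxi * fyp - uyi * fxp)
                tq[j] -= t * (uxj * fyp - uyj * fxp)
                ov = sigma - dist
                if ov > max_overlap:
                    max_overlap = ov
        step_motion = 0.0
        for i in range(n):
            dxf = mobility * fx[i] * dt
            dyf = mobility * fy[i] * dt
            mag = np.sqrt(dxf * dxf + dyf * dyf)
            if mag > cap:
                scale = cap / mag
                dxf *= scale
                dyf *= scale
                mag = cap
            x[i] += v * dt * ux[i] + dxf
            y[i] += v * dt * uy[i] + dyf
            x[i] -= box * np.floor(x[i] / box)
            y[i] -= box * np.floor(y[i] / box)
            rot_mob = 12.0 * mobility / (length[i] * length[i])
            dth = rot_mob * tq[i] * dt
            # cap rotation so tip displacement stays within the same bound
            # as the translational force cap
            dth_cap = cap / (0.5 * length[i])
            if dth > dth_cap:
                dth = dth_cap
            elif dth < -dth_cap:
                dth = -dth_cap
            if np.random.random() < p_tumble:
                target[i] = np.random.random() * TWO_PI
            # turn toward the tumble target at a bounded rate, never faster
            # than steric torque can oppose (half the torque cap)
            diff = target[i] - theta[i]
            diff -= TWO_PI * np.round(diff / TWO_PI)
            turn = omega_tumble * dt
            if turn > 0.5 * dth_cap:
                turn = 0.5 * dth_cap
            if diff > turn:
                diff = turn
            elif diff < -turn:
                diff = -turn
            theta[i] += diff + dth
            length[i] += elong_rate * dt
            # worst-case motion of any body point this step
            moved = (
                v * dt
                + mag
                + (abs(diff) + abs(dth)) * 0.5 * length[i]
                + 0.5 * elong_rate * dt
            )
            if moved > step_motion:
                step_motion = moved
        acc_motion += step_motion
    return max_overlap
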