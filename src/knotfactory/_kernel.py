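"""Numba-compiled inner kernels: forces, helix nearest-point solver, integrator.

Everything here operates on plain float64 arrays in reduced units.  The public
modules (`forcefield`, `helix`, `dynamics`) wrap these kernels; tests assert
that the wrapped results agree with independent reference implementations.

Status codes returned by the integrator:
    0  ok
    1  wall violation (bead mid-curve distance d > R_ch)
    2  integration instability (per-step displacement > 0.5 sigma)
    3  helix nearest-point solver failed to converge
    4  neighbor-pair buffer overflow
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi
WCA_CUT2 = 2.0 ** (1.0 / 3.0)       # squared cutoff for sigma = 1
NEWTON_TOL = 1e-10
NEWTON_MAXIT = 50


# ----------------------------------------------------------------------------
# helix geometry
# ----------------------------------------------------------------------------

@njit(cache=True)
def helix_residual(t, x, y, z, kp, RH, omega):
    """Stationarity residual g(t) = k(x - kt) - RH*omega*(y sin wt - z cos wt)."""
    wt = omega * t
    s = np.sin(wt)
    c = np.cos(wt)
    return kp * (x - kp * t) - RH * omega * (y * s - z * c)


@njit(cache=True)
def helix_nearest_t(x, y, z, kp, RH, omega, t0):
    """Parameter of the nearest mid-curve point, by safeguarded Newton iteration.

    Starts from the axial-projection estimate (or a warm start) t0; keeps a
    root bracket and falls back to bisection whenever the Newton step leaves
    it.  Returns (t, ok).
    """
    if RH == 0.0:
        return x / kp, True
    half = TWO_PI
    lo = t0 - half
    hi = t0 + half
    glo = helix_residual(lo, x, y, z, kp, RH, omega)
    ghi = helix_residual(hi, x, y, z, kp, RH, omega)
    tries = 0
    while glo < 0.0 or ghi > 0.0:
        half *= 2.0
        lo = t0 - half
        hi = t0 + half
        glo = helix_residual(lo, x, y, z, kp, RH, omega)
        ghi = helix_residual(hi, x, y, z, kp, RH, omega)
        tries += 1
        if tries > 8:
            return t0, False
    t = t0
    if t <= lo or t >= hi:
        t = 0.5 * (lo + hi)
    g = helix_residual(t, x, y, z, kp, RH, omega)
    for _ in range(NEWTON_MAXIT):
        if np.abs(g) < NEWTON_TOL:
            return t, True
        if g > 0.0:
            lo = t
        else:
            hi = t
        wt = omega * t
        s = np.sin(wt)
        c = np.cos(wt)
        gp = -kp * kp - RH * (y * c + z * s)
        tn = t - g / gp if gp != 0.0 else 0.5 * (lo + hi)
        if tn <= lo or tn >= hi:
            tn = 0.5 * (lo + hi)
        t = tn
        g = helix_residual(t, x, y, z, kp, RH, omega)
    return t, np.abs(g) < 1e-6


@njit(cache=True)
def helix_nearest_t_fast(x, y, z, kp, RH, omega, t0):
    """Warm-started plain Newton; falls back to the safeguarded solver.

    With a warm start from the previous step (beads move ~1e-2 sigma per
    step) this converges in one or two iterations; any sign of trouble
    (vanishing slope, large step) defers to the bracketed solver.
    """
    if RH == 0.0:
        return x / kp, True
    t = t0
    for _ in range(12):
        wt = omega * t
        s = np.sin(wt)
        c = np.cos(wt)
        g = kp * (x - kp * t) - RH * omega * (y * s - z * c)
        if np.abs(g) < NEWTON_TOL:
            return t, True
        gp = -kp * kp - RH * (y * c + z * s)
        if gp >= -1e-12:
            break
        step = g / gp
        if np.abs(step) > 3.0:
            break
        t -= step
    return helix_nearest_t(x, y, z, kp, RH, omega, t0)


@njit(cache=True)
def helix_distance_normal(x, y, z, kp, RH, omega, t0):
    """Nearest mid-curve point for one bead.

    Returns (t*, d, nx, ny, nz, ok): distance d to the mid-curve and the unit
    outward normal (zero vector at d = 0, where no wall force applies).
    """
    t, ok = helix_nearest_t_fast(x, y, z, kp, RH, omega, t0)
    wt = omega * t
    cx = kp * t
    cy = RH * np.cos(wt)
    cz = RH * np.sin(wt)
    dx = x - cx
    dy = y - cy
    dz = z - cz
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    if d > 0.0:
        return t, d, dx / d, dy / d, dz / d, ok
    return t, d, 0.0, 0.0, 0.0, ok


# ----------------------------------------------------------------------------
# pair potentials
# ----------------------------------------------------------------------------

@njit(cache=True)
def wca_energy_scalar(r2, sig):
    """WCA energy at squared distance r2 for length scale sig (eps0 = 1)."""
    s2 = sig * sig / r2
    if s2 < 0.5 ** (1.0 / 3.0):      # r > 2^(1/6) sig
        return 0.0
    s6 = s2 * s2 * s2
    return 4.0 * (s6 * s6 - s6 + 0.25)


@njit(cache=True)
def wca_force_over_r(r2, sig):
    """(-dU/dr)/r for the WCA potential; multiply by the separation vector."""
    s2 = sig * sig / r2
    if s2 < 0.5 ** (1.0 / 3.0):
        return 0.0
    s6 = s2 * s2 * s2
    return 24.0 * (2.0 * s6 * s6 - s6) / r2


# ----------------------------------------------------------------------------
# neighbor list
# ----------------------------------------------------------------------------

@njit(cache=True)
def build_pairs(pos, cutoff2, pairs):
    """All non-bonded pairs within sqrt(cutoff2); returns the pair count.

    Directly bonded neighbors (|i-j| == 1) are excluded from the excluded
    volume, the standard bead-spring convention.  Returns -1 on overflow.
    """
    n = pos.shape[0]
    cap = pairs.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cutoff2:
                if m >= cap:
                    return -1
                pairs[m, 0] = i
                pairs[m, 1] = j
                m += 1
    return m


# ----------------------------------------------------------------------------
# forces
# ----------------------------------------------------------------------------

@njit(cache=True)
def compute_forces(
    pos, forces, pairs, npairs, t_warm,
    k_s, r0, bend_pref, k_tether,
    has_channel, R_ch, RH, kp, omega, wall_sig, bottom_wall,
    has_piston, piston_x, piston_delta,
):
    """Total force on every bead; returns (epot, piston_reaction_x, status).

    Contributions: harmonic bonds U_s = k_s (r - r0)^2, harmonic bending
    U_b = bend_pref (theta - pi)^2, WCA excluded volume over the supplied pair
    list, implicit channel wall (WCA on the surface gap R_ch - d), bottom wall
    (WCA on the gap x), piston sphere (WCA on r - piston_delta) and an optional
    tether of bead 0 to the origin.  ``t_warm`` carries per-bead warm starts
    for the helix solver and is updated in place.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    epot = 0.0
    status = 0
    piston_rx = 0.0

    # bonds: U = k_s (r - r0)^2, f = -2 k_s (r - r0) along the bond
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        epot += k_s * dr * dr
        fmag = -2.0 * k_s * dr / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i + 1, 0] += fx
        forces[i + 1, 1] += fy
        forces[i + 1, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz

    # bending: U = bend_pref (theta - pi)^2 at each interior bead
    for i in range(1, n - 1):
        ax = pos[i - 1, 0] - pos[i, 0]
        ay = pos[i - 1, 1] - pos[i, 1]
        az = pos[i - 1, 2] - pos[i, 2]
        bx = pos[i + 1, 0] - pos[i, 0]
        by = pos[i + 1, 1] - pos[i, 1]
        bz = pos[i + 1, 2] - pos[i, 2]
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        ax /= la; ay /= la; az /= la
        bx /= lb; by /= lb; bz /= lb
        ct = ax * bx + ay * by + az * bz
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dth = theta - np.pi
        epot += bend_pref * dth * dth
        st = np.sqrt(1.0 - ct * ct)
        # dU/dtheta / sin(theta) is smooth at theta = pi: dth/st -> -1
        if st > 1e-8:
            coef = 2.0 * bend_pref * dth / st
        else:
            coef = -2.0 * bend_pref
        # dtheta/d r_{i-1} = (ct*a_hat - b_hat)/(la*st);  F = -dU/dtheta dtheta/dr
        f1x = -coef * (ct * ax - bx) / la
        f1y = -coef * (ct * ay - by) / la
        f1z = -coef * (ct * az - bz) / la
        f3x = -coef * (ct * bx - ax) / lb
        f3y = -coef * (ct * by - ay) / lb
        f3z = -coef * (ct * bz - az) / lb
        forces[i - 1, 0] += f1x
        forces[i - 1, 1] += f1y
        forces[i - 1, 2] += f1z
        forces[i + 1, 0] += f3x
        forces[i + 1, 1] += f3y
        forces[i + 1, 2] += f3z
        forces[i, 0] -= f1x + f3x
        forces[i, 1] -= f1y + f3y
        forces[i, 2] -= f1z + f3z

    # excluded volume (WCA, sigma = 1) over the pair list
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < WCA_CUT2:
            epot += wca_energy_scalar(r2, 1.0)
            fr = wca_force_over_r(r2, 1.0)
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz

    # optional tether of bead 0 to the origin: U = k_tether |r|^2
    if k_tether > 0.0:
        x0 = pos[0, 0]; y0 = pos[0, 1]; z0 = pos[0, 2]
        epot += k_tether * (x0 * x0 + y0 * y0 + z0 * z0)
        forces[0, 0] -= 2.0 * k_tether * x0
        forces[0, 1] -= 2.0 * k_tether * y0
        forces[0, 2] -= 2.0 * k_tether * z0

    # implicit channel wall: WCA on the surface gap g_w = R_ch - d
    if has_channel:
        wcut = 2.0 ** (1.0 / 6.0) * wall_sig
        for i in range(n):
            t, d, nx, ny, nz, ok = helix_distance_normal(
                pos[i, 0], pos[i, 1], pos[i, 2], kp, RH, omega, t_warm[i]
            )
            t_warm[i] = t
            if not ok:
                status = 3
            if d > R_ch:
                status = 1
            gap = R_ch - d
            if 0.0 < gap < wcut and d > 0.0:
                g2 = gap * gap
                epot += wca_energy_scalar(g2, wall_sig)
                # dU/d r = U'(gap) * dgap/dd * n = -U'(gap) n; F = U'(gap) n
                fr = wca_force_over_r(g2, wall_sig) * gap   # = -U'(gap)
                forces[i, 0] -= fr * nx
                forces[i, 1] -= fr * ny
                forces[i, 2] -= fr * nz

    # bottom wall at x = 0: WCA on the gap x
    if bottom_wall:
        wcut = 2.0 ** (1.0 / 6.0) * wall_sig
        for i in range(n):
            gx = pos[i, 0]
            if 0.0 < gx < wcut:
                epot += wca_energy_scalar(gx * gx, wall_sig)
                forces[i, 0] += wca_force_over_r(gx * gx, wall_sig) * gx

    # piston: large sphere on the axis, WCA on r - piston_delta (sigma = 1)
    if has_piston:
        pcut = 2.0 ** (1.0 / 6.0)
        for i in range(n):
            dx = pos[i, 0] - piston_x
            dy = pos[i, 1]
            dz = pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            s = r - piston_delta
            if 0.0 < s < pcut:
                epot += wca_energy_scalar(s * s, 1.0)
                fmag = wca_force_over_r(s * s, 1.0) * s   # = -dU/ds
                fx = fmag * dx / r
                fy = fmag * dy / r
                fz = fmag * dz / r
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                piston_rx -= fx
    return epot, piston_rx, status


# ----------------------------------------------------------------------------
# Langevin integrator (BAOAB splitting)
# ----------------------------------------------------------------------------

@njit(cache=True)
def step_chunk(
    pos, vel, t_warm, noise, pnoise,
    dt, gamma, mass,
    k_s, r0, bend_pref, k_tether, skin,
    has_channel, R_ch, RH, kp, omega, wall_sig, bottom_wall,
    has_piston, piston_x0, piston_delta, piston_force, piston_gamma,
    piston_thermostat,
):
    """Advance the state by noise.shape[0] BAOAB Langevin steps.

    m r'' = -gamma m r' - grad U + R(t) sqrt(2 eps0 m gamma), eps0 = kT = 1.
    ``noise`` holds the pre-drawn unit Gaussians (m, n, 3) for the O-step and
    ``pnoise`` (m,) those of the overdamped axial piston coordinate.  State
    (pos, vel, warm starts) is updated in place; forces are recomputed at
    chunk entry, so chunk boundaries do not alter the dynamics.  Returns
    (status, fail_step, piston_x, epot_last).
    """
    n = pos.shape[0]
    m_steps = noise.shape[0]
    kT = 1.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT / mass)
    halfdt = 0.5 * dt

    cutoff2 = (2.0 ** (1.0 / 6.0) + skin) ** 2
    pairs = np.empty((n * 64, 2), dtype=np.int64)
    npairs = build_pairs(pos, cutoff2, pairs)
    if npairs < 0:
        return 4, 0, piston_x0, 0.0
    ref_pos = pos.copy()

    forces = np.empty((n, 3))
    piston_x = piston_x0
    epot, piston_rx, status = compute_forces(
        pos, forces, pairs, npairs, t_warm,
        k_s, r0, bend_pref, k_tether,
        has_channel, R_ch, RH, kp, omega, wall_sig, bottom_wall,
        has_piston, piston_x, piston_delta,
    )
    if status == 1:
        return status, 0, piston_x, epot

    pc = np.sqrt(2.0 * kT * dt / piston_gamma) if piston_gamma > 0.0 else 0.0
    prev = np.empty((n, 3))
    half_skin2 = (0.5 * skin) ** 2

    for step in range(m_steps):
        for i in range(n):
            prev[i, 0] = pos[i, 0]
            prev[i, 1] = pos[i, 1]
            prev[i, 2] = pos[i, 2]
            # B: half kick + A: half drift
            vel[i, 0] += halfdt * forces[i, 0] / mass
            vel[i, 1] += halfdt * forces[i, 1] / mass
            vel[i, 2] += halfdt * forces[i, 2] / mass
            pos[i, 0] += halfdt * vel[i, 0]
            pos[i, 1] += halfdt * vel[i, 1]
            pos[i, 2] += halfdt * vel[i, 2]
        # O: Ornstein-Uhlenbeck velocity refresh, then A: half drift
        if gamma > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[step, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[step, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[step, i, 2]
        for i in range(n):
            pos[i, 0] += halfdt * vel[i, 0]
            pos[i, 1] += halfdt * vel[i, 1]
            pos[i, 2] += halfdt * vel[i, 2]

        # piston: overdamped axial Langevin using the last reaction force
        if has_piston:
            drift = (-piston_force + piston_rx) * dt / piston_gamma
            if piston_thermostat:
                drift += pc * pnoise[step]
            piston_x += drift
            if piston_x < 100.0:          # surface may not pass the bottom wall
                piston_x = 100.0

        # neighbor-list displacement trigger
        rebuild = False
        for i in range(n):
            ddx = pos[i, 0] - ref_pos[i, 0]
            ddy = pos[i, 1] - ref_pos[i, 1]
            ddz = pos[i, 2] - ref_pos[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > half_skin2:
                rebuild = True
                break
        if rebuild:
            npairs = build_pairs(pos, cutoff2, pairs)
            if npairs < 0:
                return 4, step, piston_x, epot
            for i in range(n):
                ref_pos[i, 0] = pos[i, 0]
                ref_pos[i, 1] = pos[i, 1]
                ref_pos[i, 2] = pos[i, 2]

        epot, piston_rx, status = compute_forces(
            pos, forces, pairs, npairs, t_warm,
            k_s, r0, bend_pref, k_tether,
            has_channel, R_ch, RH, kp, omega, wall_sig, bottom_wall,
            has_piston, piston_x, piston_delta,
        )
        if status == 1 or status == 3:
            return status, step, piston_x, epot

        for i in range(n):
            # B: half kick
            vel[i, 0] += halfdt * forces[i, 0] / mass
            vel[i, 1] += halfdt * forces[i, 1] / mass
            vel[i, 2] += halfdt * forces[i, 2] / mass
            # stability: displacement per step bounded by 0.5 sigma
            ddx = pos[i, 0] - prev[i, 0]
            ddy = pos[i, 1] - prev[i, 1]
            ddz = pos[i, 2] - prev[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > 0.25:
                return 2, step, piston_x, epot

    return 0, m_steps, piston_x, epot
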