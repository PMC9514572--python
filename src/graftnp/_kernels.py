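"""Numba kernels: Langevin (BAOAB) integrators and walk-on-spheres walkers.

All kernels are single-threaded, seeded through numba's np.random, and
deterministic for a given seed and argument set.
"""

import numpy as np
from numba import njit

TWO16 = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# free chains: (n_replicas, L, 3) independent chains, no inter-replica terms
# ---------------------------------------------------------------------------
@njit(cache=True)
def chain_forces(x, f, sigma, eps, kf, r0, klin):
    nr, L, _ = x.shape
    cut2 = (TWO16 * sigma) ** 2
    r02 = r0 * r0
    f[:] = 0.0
    for a in range(nr):
        for i in range(L):
            for j in range(i + 1, L):
                dx = x[a, i, 0] - x[a, j, 0]
                dy = x[a, i, 1] - x[a, j, 1]
                dz = x[a, i, 2] - x[a, j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < cut2:
                    s2 = sigma * sigma / r2
                    s6 = s2 * s2 * s2
                    fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                    f[a, i, 0] += fr * dx
                    f[a, i, 1] += fr * dy
                    f[a, i, 2] += fr * dz
                    f[a, j, 0] -= fr * dx
                    f[a, j, 1] -= fr * dy
                    f[a, j, 2] -= fr * dz
        for i in range(L - 1):
            dx = x[a, i + 1, 0] - x[a, i, 0]
            dy = x[a, i + 1, 1] - x[a, i, 1]
            dz = x[a, i + 1, 2] - x[a, i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= r02:
                return 1  # broken bond
            fr = -kf / (1.0 - r2 / r02)
            f[a, i + 1, 0] += fr * dx
            f[a, i + 1, 1] += fr * dy
            f[a, i + 1, 2] += fr * dz
            f[a, i, 0] -= fr * dx
            f[a, i, 1] -= fr * dy
            f[a, i, 2] -= fr * dz
        for j in range(1, L - 1):
            ax = x[a, j - 1, 0] - x[a, j, 0]
            ay = x[a, j - 1, 1] - x[a, j, 1]
            az = x[a, j - 1, 2] - x[a, j, 2]
            bx = x[a, j + 1, 0] - x[a, j, 0]
            by = x[a, j + 1, 1] - x[a, j, 1]
            bz = x[a, j + 1, 2] - x[a, j, 2]
            na = np.sqrt(ax * ax + ay * ay + az * az)
            nb = np.sqrt(bx * bx + by * by + bz * bz)
            ct = (ax * bx + ay * by + az * bz) / (na * nb)
            gx = (bx / nb - ct * ax / na) / na
            gy = (by / nb - ct * ay / na) / na
            gz = (bz / nb - ct * az / na) / na
            hx = (ax / na - ct * bx / nb) / nb
            hy = (ay / na - ct * by / nb) / nb
            hz = (az / na - ct * bz / nb) / nb
            f[a, j - 1, 0] -= klin * gx
            f[a, j - 1, 1] -= klin * gy
            f[a, j - 1, 2] -= klin * gz
            f[a, j + 1, 0] -= klin * hx
            f[a, j + 1, 1] -= klin * hy
            f[a, j + 1, 2] -= klin * hz
            f[a, j, 0] += klin * (gx + hx)
            f[a, j, 1] += klin * (gy + hy)
            f[a, j, 2] += klin * (gz + hz)
    return 0


@njit(cache=True)
def chain_baoab(x, v, n_steps, dt, gamma, T, seed, sample_every, samples,
                sigma, eps, kf, r0, klin):
    """BAOAB Langevin integration of independent chains.

    Returns (n_samples_taken, error_flag, mean_kinetic_T).  gamma = 0 turns
    the O-step off (plain velocity Verlet, NVE).
    """
    np.random.seed(seed)
    f = np.zeros_like(x)
    err = chain_forces(x, f, sigma, eps, kf, r0, klin)
    if err != 0:
        return 0, err, 0.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(T * (1.0 - c1 * c1))
    nr, L, _ = x.shape
    ns = 0
    tsum = 0.0
    for step in range(n_steps):
        for a in range(nr):
            for i in range(L):
                for k in range(3):
                    v[a, i, k] += 0.5 * dt * f[a, i, k]
                    x[a, i, k] += 0.5 * dt * v[a, i, k]
                    if gamma > 0.0:
                        v[a, i, k] = c1 * v[a, i, k] + c2 * np.random.normal()
                    x[a, i, k] += 0.5 * dt * v[a, i, k]
        err = chain_forces(x, f, sigma, eps, kf, r0, klin)
        if err != 0:
            return ns, err, tsum / max(step, 1)
        vsum = 0.0
        for a in range(nr):
            for i in range(L):
                for k in range(3):
                    v[a, i, k] += 0.5 * dt * f[a, i, k]
                    vsum += v[a, i, k] * v[a, i, k]
        tsum += vsum / (nr * L * 3)
        if (step + 1) % sample_every == 0 and ns < samples.shape[0]:
            samples[ns] = x
            ns += 1
    return ns, 0, tsum / n_steps


# ---------------------------------------------------------------------------
# grafted nanoparticle: one system of N beads + immobile core at the origin
# ---------------------------------------------------------------------------
@njit(cache=True)
def grafted_forces(x, f, chain_start, chain_len, anchors,
                   sigma, eps, kf, r0, klin,
                   rs_core, eps_core, cut_core):
    """Forces for the grafted system.  anchors are absolute points (on the
    core surface) to which the first bead of each chain is FENE-tethered.
    The core term is the shifted LJ with shift rs_core, strength eps_core and
    cutoff cut_core (absolute distance from the core center)."""
    n = x.shape[0]
    cut2 = (TWO16 * sigma) ** 2
    r02 = r0 * r0
    f[:] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cut2:
                s2 = sigma * sigma / r2
                s6 = s2 * s2 * s2
                fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                f[i, 0] += fr * dx
                f[i, 1] += fr * dy
                f[i, 2] += fr * dz
                f[j, 0] -= fr * dx
                f[j, 1] -= fr * dy
                f[j, 2] -= fr * dz
    # core--bead shifted LJ (core at origin)
    for i in range(n):
        r = np.sqrt(x[i, 0] ** 2 + x[i, 1] ** 2 + x[i, 2] ** 2)
        if r <= rs_core:
            return 2  # core penetration
        if r < cut_core:
            u = r - rs_core
            s2 = sigma * sigma / (u * u)
            s6 = s2 * s2 * s2
            fr = 24.0 * eps_core * (2.0 * s6 * s6 - s6) / (u * r)
            f[i, 0] += fr * x[i, 0]
            f[i, 1] += fr * x[i, 1]
            f[i, 2] += fr * x[i, 2]
    nc = chain_start.shape[0]
    for c in range(nc):
        s0 = chain_start[c]
        ln = chain_len[c]
        # tether
        dx = x[s0, 0] - anchors[c, 0]
        dy = x[s0, 1] - anchors[c, 1]
        dz = x[s0, 2] - anchors[c, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return 1
        fr = -kf / (1.0 - r2 / r02)
        f[s0, 0] += fr * dx
        f[s0, 1] += fr * dy
        f[s0, 2] += fr * dz
        for i in range(s0, s0 + ln - 1):
            dx = x[i + 1, 0] - x[i, 0]
            dy = x[i + 1, 1] - x[i, 1]
            dz = x[i + 1, 2] - x[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= r02:
                return 1
            fr = -kf / (1.0 - r2 / r02)
            f[i + 1, 0] += fr * dx
            f[i + 1, 1] += fr * dy
            f[i + 1, 2] += fr * dz
            f[i, 0] -= fr * dx
            f[i, 1] -= fr * dy
            f[i, 2] -= fr * dz
        for j in range(s0 + 1, s0 + ln - 1):
            ax = x[j - 1, 0] - x[j, 0]
            ay = x[j - 1, 1] - x[j, 1]
            az = x[j - 1, 2] - x[j, 2]
            bx = x[j + 1, 0] - x[j, 0]
            by = x[j + 1, 1] - x[j, 1]
            bz = x[j + 1, 2] - x[j, 2]
            na = np.sqrt(ax * ax + ay * ay + az * az)
            nb = np.sqrt(bx * bx + by * by + bz * bz)
            ct = (ax * bx + ay * by + az * bz) / (na * nb)
            gx = (bx / nb - ct * ax / na) / na
            gy = (by / nb - ct * ay / na) / na
            gz = (bz / nb - ct * az / na) / na
            hx = (ax / na - ct * bx / nb) / nb
            hy = (ay / na - ct * by / nb) / nb
            hz = (az / na - ct * bz / nb) / nb
            f[j - 1, 0] -= klin * gx
            f[j - 1, 1] -= klin * gy
            f[j - 1, 2] -= klin * gz
            f[j + 1, 0] -= klin * hx
            f[j + 1, 1] -= klin * hy
            f[j + 1, 2] -= klin * hz
            f[j, 0] += klin * (gx + hx)
            f[j, 1] += klin * (gy + hy)
            f[j, 2] += klin * (gz + hz)
    return 0


@njit(cache=True)
def grafted_baoab(x, v, n_steps, dt, gamma, T, seed, sample_every, samples,
                  chain_start, chain_len, anchors,
                  sigma, eps, kf, r0, klin, rs_core, eps_core, cut_core):
    np.random.seed(seed)
    f = np.zeros_like(x)
    err = grafted_forces(x, f, chain_start, chain_len, anchors, sigma, eps,
                         kf, r0, klin, rs_core, eps_core, cut_core)
    if err != 0:
        return 0, err, 0.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(T * (1.0 - c1 * c1))
    n = x.shape[0]
    ns = 0
    tsum = 0.0
    for step in range(n_steps):
        for i in range(n):
            for k in range(3):
                v[i, k] += 0.5 * dt * f[i, k]
                x[i, k] += 0.5 * dt * v[i, k]
                if gamma > 0.0:
                    v[i, k] = c1 * v[i, k] + c2 * np.random.normal()
                x[i, k] += 0.5 * dt * v[i, k]
        err = grafted_forces(x, f, chain_start, chain_len, anchors, sigma,
                             eps, kf, r0, klin, rs_core, eps_core, cut_core)
        if err != 0:
            return ns, err, tsum / max(step, 1)
        vsum = 0.0
        for i in range(n):
            for k in range(3):
                v[i, k] += 0.5 * dt * f[i, k]
                vsum += v[i, k] * v[i, k]
        tsum += vsum / (n * 3)
        if (step + 1) % sample_every == 0 and ns < samples.shape[0]:
            samples[ns] = x
            ns += 1
    return ns, 0, tsum / n_steps


# ---------------------------------------------------------------------------
# walk-on-spheres
# ---------------------------------------------------------------------------
@njit(cache=True, inline="always")
def _union_distance(px, py, pz, centers, group_start, group_radius):
    """Signed distance from point to the sphere union boundary (negative
    inside).  Spheres are grouped by equal radius so only one sqrt per group
    is needed."""
    best = 1e300
    ng = group_start.shape[0] - 1
    for g in range(ng):
        m2 = 1e300
        for i in range(group_start[g], group_start[g + 1]):
            dx = px - centers[i, 0]
            dy = py - centers[i, 1]
            dz = pz - centers[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < m2:
                m2 = d2
        d = np.sqrt(m2) - group_radius[g]
        if d < best:
            best = d
    return best


@njit(cache=True)
def wos_walk(centers, group_start, group_radius, cx, cy, cz, b,
             n_walks, skin, seed, max_steps, n_batches,
             hits, sum_y, sum_ny):
    """Walk-on-spheres capacity/polarizability walker.

    Walkers launch uniformly from the sphere of radius ``b`` centered at
    (cx, cy, cz).  Walkers stepping outside the launch sphere at distance
    rho return with probability b/rho through the exact first-passage
    re-entry distribution, otherwise escape.  Per batch the kernel records
    the number of absorbed walkers, the sum of hit positions y (relative to
    the launch center) and the sum of n_i y_j over launch direction n and
    hit position y (both needed for the conductor polarizability).

    Returns the number of walks terminated by the step cap (bias warning).
    """
    np.random.seed(seed)
    per_batch = n_walks // n_batches
    capped = 0
    for batch in range(n_batches):
        for w in range(per_batch):
            # uniform direction on the sphere
            zz = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            sz = np.sqrt(max(0.0, 1.0 - zz * zz))
            nx = sz * np.cos(phi)
            ny = sz * np.sin(phi)
            nz = zz
            px = cx + b * nx
            py = cy + b * ny
            pz = cz + b * nz
            alive = True
            absorbed = False
            steps = 0
            while alive:
                steps += 1
                if steps > max_steps:
                    capped += 1
                    alive = False
                    break
                d = _union_distance(px, py, pz, centers, group_start,
                                    group_radius)
                if d < skin:
                    absorbed = True
                    alive = False
                    break
                zz = 2.0 * np.random.random() - 1.0
                phi = 2.0 * np.pi * np.random.random()
                sz = np.sqrt(max(0.0, 1.0 - zz * zz))
                px += d * sz * np.cos(phi)
                py += d * sz * np.sin(phi)
                pz += d * zz
                rx = px - cx
                ry = py - cy
                rz = pz - cz
                rho2 = rx * rx + ry * ry + rz * rz
                if rho2 > b * b:
                    rho = np.sqrt(rho2)
                    if np.random.random() > b / rho:
                        alive = False  # escaped to infinity
                        break
                    # first-passage re-entry onto the launch sphere:
                    # 1/d' uniform between 1/(rho+b) and 1/(rho-b)
                    u = np.random.random()
                    inv = (1.0 - u) / (rho + b) + u / (rho - b)
                    dprime = 1.0 / inv
                    cth = (b * b + rho2 - dprime * dprime) / (2.0 * b * rho)
                    if cth > 1.0:
                        cth = 1.0
                    if cth < -1.0:
                        cth = -1.0
                    sth = np.sqrt(1.0 - cth * cth)
                    # orthonormal frame around w = r/rho
                    wx = rx / rho
                    wy = ry / rho
                    wz = rz / rho
                    if abs(wx) < 0.5:
                        e1x = 0.0 * wx + 1.0
                        e1y = 0.0
                        e1z = 0.0
                    else:
                        e1x = 0.0
                        e1y = 1.0
                        e1z = 0.0
                    # e1 = normalize(e1 - (e1.w) w)
                    dot = e1x * wx + e1y * wy + e1z * wz
                    e1x -= dot * wx
                    e1y -= dot * wy
                    e1z -= dot * wz
                    nrm = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                    e1x /= nrm
                    e1y /= nrm
                    e1z /= nrm
                    e2x = wy * e1z - wz * e1y
                    e2y = wz * e1x - wx * e1z
                    e2z = wx * e1y - wy * e1x
                    phi2 = 2.0 * np.pi * np.random.random()
                    cp = np.cos(phi2)
                    sp = np.sin(phi2)
                    px = cx + b * (cth * wx + sth * (cp * e1x + sp * e2x))
                    py = cy + b * (cth * wy + sth * (cp * e1y + sp * e2y))
                    pz = cz + b * (cth * wz + sth * (cp * e1z + sp * e2z))
            if absorbed:
                hits[batch] += 1
                yx = px - cx
                yy = py - cy
                yz = pz - cz
                sum_y[batch, 0] += yx
                sum_y[batch, 1] += yy
                sum_y[batch, 2] += yz
                sum_ny[batch, 0, 0] += nx * yx
                sum_ny[batch, 0, 1] += nx * yy
                sum_ny[batch, 0, 2] += nx * yz
                sum_ny[batch, 1, 0] += ny * yx
                sum_ny[batch, 1, 1] += ny * yy
                sum_ny[batch, 1, 2] += ny * yz
                sum_ny[batch, 2, 0] += nz * yx
                sum_ny[batch, 2, 1] += nz * yy
                sum_ny[batch, 2, 2] += nz * yz
    return capped


@njit(cache=True)
def union_volume_hits(centers, group_start, group_radius, cx, cy, cz, b,
                      n_samples, seed, n_batches, hits):
    """Uniform sampling in the launch ball; counts points inside the union."""
    np.random.seed(seed)
    per_batch = n_samples // n_batches
    for batch in range(n_batches):
        for w in range(per_batch):
            while True:
                px = 2.0 * np.random.random() - 1.0
                py = 2.0 * np.random.random() - 1.0
                pz = 2.0 * np.random.random() - 1.0
                if px * px + py * py + pz * pz <= 1.0:
                    break
            px = cx + b * px
            py = cy + b * py
            pz = cz + b * pz
            if _union_distance(px, py, pz, centers, group_start,
                               group_radius) < 0.0:
                hits[batch] += 1
    return 0
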