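"""Numba photon-transport kernels.

Random-walk Monte Carlo with survival weighting: step lengths are sampled
from the extinction coefficient, absorption reduces the photon weight by the
single-scattering albedo at each interaction, deflection angles follow the
Henyey-Greenstein distribution, and refractive-index mismatches are handled
with unpolarized Fresnel coefficients plus Snell refraction.  Fluence is
accumulated with the path-length estimator (deposited path per unit volume),
which remains unbiased in non-absorbing media; time of flight accumulates
n * s / c per sub-step.

All kernels are deterministic for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: vacuum speed of light, mm / ns
C0 = 299.792458

#: Russian-roulette weight threshold and survival probability
W_MIN = 1e-4
P_SURVIVE = 0.1

_MAX_STEPS = 1_000_000


@njit(cache=True, inline="always")
def _fresnel(n1, n2, ci):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    Returns (R, cos_t); R = 1 and cos_t = 0 on total internal reflection.
    """
    if n1 == n2:
        return 0.0, ci
    if ci > 1.0:
        ci = 1.0
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 / n2 * si
    if st >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st * st)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True, inline="always")
def _sample_hg(g):
    """Cosine of the Henyey-Greenstein deflection angle (isotropic for g=0)."""
    if g == 0.0:
        return 2.0 * np.random.random() - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _scatter(ux, uy, uz, g):
    """Rotate the direction by an HG polar angle and uniform azimuth."""
    ct = _sample_hg(g)
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * np.random.random()
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -den * st * cp + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def sample_hg_cosines(g, n, seed):
    """Array of HG cosines; used to validate the sampler's mean against g."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _sample_hg(g)
    return out


@njit(cache=True, inline="always")
def _deposit_z(fl, t, dt, nt, z0, z1, w, s, nz, dz, n_over_c):
    """Add w * path to time/depth fluence bins for a segment z0 -> z1.

    ``z0`` is the segment start; time advances along the segment at the
    medium's light speed so each depth bin lands in its own time bin.
    """
    zs = z0
    if z1 < z0:
        tmp = z0
        z0 = z1
        z1 = tmp
    if z1 - z0 < 1e-12:
        it = int(t / dt)
        if it >= nt:
            it = nt - 1
        ib = int(zs / dz)
        if ib < 0:
            ib = 0
        elif ib >= nz:
            ib = nz - 1
        fl[it, ib] += w * s
        return
    factor = s / (z1 - z0)  # path length per unit depth
    i0 = int(z0 / dz)
    i1 = int(z1 / dz)
    if i0 < 0:
        i0 = 0
    if i1 >= nz:
        i1 = nz - 1
    for i in range(i0, i1 + 1):
        blo = i * dz
        if z0 > blo:
            blo = z0
        bhi = (i + 1) * dz
        if z1 < bhi:
            bhi = z1
        if bhi > blo:
            zmid = 0.5 * (blo + bhi)
            tb = t + abs(zmid - zs) * factor * n_over_c
            it = int(tb / dt)
            if it >= nt:
                it = nt - 1
            fl[it, i] += w * (bhi - blo) * factor


@njit(cache=True)
def run_layered(
    mu_a,
    mu_s,
    g,
    n,
    zb,
    n_above,
    n_below,
    n_photons,
    seed,
    fluence_tz,
    dt,
    dz,
    trans_hist,
    refl_hist,
):
    """Trace photons through a layered slab.

    Returns (T, R, A, lost, n_transmitted).  ``fluence_tz`` has shape
    (nt, nz) and receives deposited path length (mm) per photon batch; the
    angular histograms receive exit weight per 1-degree bin of the exit
    polar angle in the ambient medium.
    """
    np.random.seed(seed)
    nl = mu_a.shape[0]
    nt, nz = fluence_tz.shape
    T = 0.0
    R = 0.0
    A = 0.0
    lost = 0.0
    n_trans = 0

    for _ in range(n_photons):
        # deterministic specular split at the entry interface
        r_sp, _ct = _fresnel(n_above, n[0], 1.0)
        R += r_sp
        w = 1.0 - r_sp
        lay = 0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        t = 0.0
        tau = -math.log(np.random.random())
        steps = 0
        while True:
            steps += 1
            if steps > _MAX_STEPS:
                lost += w
                break
            mt = mu_a[lay] + mu_s[lay]
            s = tau / mt if mt > 0.0 else 1e30
            if uz > 0.0:
                db = (zb[lay + 1] - z) / uz
            elif uz < 0.0:
                db = (zb[lay] - z) / uz
            else:
                db = 1e30
            if db < 0.0:
                db = 0.0
            if s < db:
                # interaction inside the layer
                _deposit_z(
                    fluence_tz, t, dt, nt, z, z + uz * s, w, s, nz, dz, n[lay] / C0
                )
                z += uz * s
                t += s * n[lay] / C0
                da = w * (mu_a[lay] / mt)
                A += da
                w -= da
                ux, uy, uz = _scatter(ux, uy, uz, g[lay])
                tau = -math.log(np.random.random())
                if w < W_MIN:
                    if np.random.random() < P_SURVIVE:
                        w /= P_SURVIVE
                    else:
                        break
            else:
                # transport to the layer boundary
                _deposit_z(
                    fluence_tz, t, dt, nt, z, z + uz * db, w, db, nz, dz, n[lay] / C0
                )
                t += db * n[lay] / C0
                if mt > 0.0:
                    tau -= db * mt
                    if tau < 0.0:
                        tau = 0.0
                going_down = uz > 0.0
                z = zb[lay + 1] if going_down else zb[lay]
                n1 = n[lay]
                if going_down:
                    n2 = n_below if lay == nl - 1 else n[lay + 1]
                else:
                    n2 = n_above if lay == 0 else n[lay - 1]
                ci = abs(uz)
                refl, ct = _fresnel(n1, n2, ci)
                if np.random.random() < refl:
                    uz = -uz
                else:
                    if n1 != n2:
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz = ct if going_down else -ct
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                    if going_down and lay == nl - 1:
                        T += w
                        n_trans += 1
                        ang = math.degrees(math.acos(min(abs(uz), 1.0)))
                        ib = int(ang)
                        if ib > 89:
                            ib = 89
                        trans_hist[ib] += w
                        break
                    elif (not going_down) and lay == 0:
                        R += w
                        ang = math.degrees(math.acos(min(abs(uz), 1.0)))
                        ib = int(ang)
                        if ib > 89:
                            ib = 89
                        refl_hist[ib] += w
                        break
                    else:
                        lay += 1 if going_down else -1
    return T, R, A, lost, n_trans


@njit(cache=True)
def run_voxel(
    labels,
    mu_a,
    mu_s,
    g,
    n,
    dz,
    dy,
    dx,
    n_above,
    n_below,
    n_photons,
    seed,
    plane_source,
    x0,
    y0,
    fluence_vox,
    fluence_tz,
    dt,
    trans_hist,
    refl_hist,
):
    """Trace photons through a laterally periodic voxel grid.

    Index mismatches are resolved with Fresnel/Snell on the axis-aligned
    voxel face being crossed.  Returns (T, R, A, lost, n_transmitted);
    ``fluence_vox`` (nz, ny, nx) and ``fluence_tz`` (nt, nz) accumulate
    deposited path length in mm.
    """
    np.random.seed(seed)
    nz, ny, nx = labels.shape
    nt = fluence_tz.shape[0]
    Lx = nx * dx
    Ly = ny * dy
    T = 0.0
    R = 0.0
    A = 0.0
    lost = 0.0
    n_trans = 0

    for _ in range(n_photons):
        if plane_source:
            x = np.random.random() * Lx
            y = np.random.random() * Ly
        else:
            x = x0 % Lx
            y = y0 % Ly
        z = 0.0
        ix = int(x / dx)
        iy = int(y / dy)
        iz = 0
        if ix >= nx:
            ix = nx - 1
        if iy >= ny:
            iy = ny - 1
        lab = labels[iz, iy, ix]
        r_sp, _ct = _fresnel(n_above, n[lab], 1.0)
        R += r_sp
        w = 1.0 - r_sp
        ux = 0.0
        uy = 0.0
        uz = 1.0
        t = 0.0
        tau = -math.log(np.random.random())
        steps = 0
        alive = True
        while alive:
            steps += 1
            if steps > _MAX_STEPS:
                lost += w
                break
            lab = labels[iz, iy, ix]
            mt = mu_a[lab] + mu_s[lab]
            s_int = tau / mt if mt > 0.0 else 1e30
            # distances to the three candidate voxel faces
            if ux > 0.0:
                tx = ((ix + 1) * dx - x) / ux
            elif ux < 0.0:
                tx = (ix * dx - x) / ux
            else:
                tx = 1e30
            if uy > 0.0:
                ty = ((iy + 1) * dy - y) / uy
            elif uy < 0.0:
                ty = (iy * dy - y) / uy
            else:
                ty = 1e30
            if uz > 0.0:
                tz = ((iz + 1) * dz - z) / uz
            elif uz < 0.0:
                tz = (iz * dz - z) / uz
            else:
                tz = 1e30
            if tx < 0.0:
                tx = 0.0
            if ty < 0.0:
                ty = 0.0
            if tz < 0.0:
                tz = 0.0
            db = min(tx, min(ty, tz))
            if s_int < db:
                # interaction inside this voxel
                fluence_vox[iz, iy, ix] += w * s_int
                it = int(t / dt)
                if it >= nt:
                    it = nt - 1
                fluence_tz[it, iz] += w * s_int
                x += ux * s_int
                y += uy * s_int
                z += uz * s_int
                t += s_int * n[lab] / C0
                da = w * (mu_a[lab] / mt)
                A += da
                w -= da
                ux, uy, uz = _scatter(ux, uy, uz, g[lab])
                tau = -math.log(np.random.random())
                if w < W_MIN:
                    if np.random.random() < P_SURVIVE:
                        w /= P_SURVIVE
                    else:
                        break
            else:
                # advance to the voxel face
                fluence_vox[iz, iy, ix] += w * db
                it = int(t / dt)
                if it >= nt:
                    it = nt - 1
                fluence_tz[it, iz] += w * db
                x += ux * db
                y += uy * db
                z += uz * db
                t += db * n[lab] / C0
                if mt > 0.0:
                    tau -= db * mt
                    if tau < 0.0:
                        tau = 0.0
                # which axis was crossed?
                axis = 0 if db == tx else (1 if db == ty else 2)
                if axis == 0:
                    step_dir = 1 if ux > 0.0 else -1
                    jx = ix + step_dir
                    jy = iy
                    jz = iz
                elif axis == 1:
                    step_dir = 1 if uy > 0.0 else -1
                    jx = ix
                    jy = iy + step_dir
                    jz = iz
                else:
                    step_dir = 1 if uz > 0.0 else -1
                    jx = ix
                    jy = iy
                    jz = iz + step_dir
                # lateral periodicity
                if jx < 0:
                    jx = nx - 1
                    x = Lx
                elif jx >= nx:
                    jx = 0
                    x = 0.0
                if jy < 0:
                    jy = ny - 1
                    y = Ly
                elif jy >= ny:
                    jy = 0
                    y = 0.0
                # target index n2 across the face
                if jz < 0:
                    n2 = n_above
                elif jz >= nz:
                    n2 = n_below
                else:
                    n2 = n[labels[jz, jy, jx]]
                n1 = n[lab]
                if axis == 0:
                    ci = abs(ux)
                elif axis == 1:
                    ci = abs(uy)
                else:
                    ci = abs(uz)
                refl, ct = _fresnel(n1, n2, ci)
                if np.random.random() < refl:
                    if axis == 0:
                        ux = -ux
                    elif axis == 1:
                        uy = -uy
                    else:
                        uz = -uz
                    # stay in the current voxel
                else:
                    if n1 != n2:
                        ratio = n1 / n2
                        if axis == 0:
                            sgn = 1.0 if ux > 0.0 else -1.0
                            uy *= ratio
                            uz *= ratio
                            ux = sgn * ct
                        elif axis == 1:
                            sgn = 1.0 if uy > 0.0 else -1.0
                            ux *= ratio
                            uz *= ratio
                            uy = sgn * ct
                        else:
                            sgn = 1.0 if uz > 0.0 else -1.0
                            ux *= ratio
                            uy *= ratio
                            uz = sgn * ct
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                    if jz < 0:
                        R += w
                        ang = math.degrees(math.acos(min(abs(uz), 1.0)))
                        ib = int(ang)
                        if ib > 89:
                            ib = 89
                        refl_hist[ib] += w
                        alive = False
                    elif jz >= nz:
                        T += w
                        n_trans += 1
                        ang = math.degrees(math.acos(min(abs(uz), 1.0)))
                        ib = int(ang)
                        if ib > 89:
                            ib = 89
                        trans_hist[ib] += w
                        alive = False
                    else:
                        ix = jx
                        iy = jy
                        iz = jz
    return T, R, A, lost, n_trans
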