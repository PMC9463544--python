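"""Numba kernels for photon-packet transport.

Weighted (implicit-capture) Monte Carlo: packets hop with free paths drawn
from the local interaction coefficient, deposit ``w * mu_a / mu_t`` at
each interaction, and spin through Henyey-Greenstein deflections.
Boundaries use unpolarized Fresnel coefficients with a single stochastic
reflect/transmit decision.  Low-weight packets face Russian roulette; in
nearly conservative media an additional unbiased age roulette thins
packets that have scattered for a very long time, with all killed and
gained weight booked to the roulette ledger so the weight budget closes
exactly.

In a strictly non-absorbing medium with no transmission path (semi-
infinite stack, or a laterally clamped voxel volume) every packet escapes
through the top surface with probability one, so packets that exceed the
event cap are booked directly to diffuse reflectance (``cap_to_diffuse``):
total reflectance is then exact while the unrecorded exit radius lies far
outside the probe.  Roulette is disabled in that regime because killing a
packet whose true escape probability is one only adds variance.

Randomness is a counter-based splitmix64 stream: every (seed, wavelength,
photon) triple owns an independent substream, which makes results a pure
function of the configuration and bit-reproducible regardless of
execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

# ledger slot layout in the result vector
NDET = 6
R_DET0 = 0          # 6 detected-weight slots
R_DETSQ0 = 6        # 6 detected weight-squared slots (for MC standard errors)
R_SPEC = 12
R_DIFFUSE = 13
R_TRANS = 14
R_ABSORBED = 15
R_ROULETTE = 16
R_LOST = 17
R_NSLOTS = 18

_GAMMA = uint64(0x9E3779B97F4A7C15)
_MIX1 = uint64(0xBF58476D1CE4E5B9)
_MIX2 = uint64(0x94D049BB133111EB)


@njit(cache=True, fastmath=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> uint64(30))) * _MIX1
    z = (z ^ (z >> uint64(27))) * _MIX2
    return z ^ (z >> uint64(31))


@njit(cache=True, fastmath=True, inline="always")
def _stream_init(stream_key, photon):
    return _mix64((stream_key + _GAMMA * (uint64(photon) + uint64(1))))


@njit(cache=True, fastmath=True, inline="always")
def _next_u64(state):
    state = state + _GAMMA
    return state, _mix64(state)


@njit(cache=True, fastmath=True, inline="always")
def _next_open01(state):
    """Uniform double in the open interval (0, 1)."""
    state, z = _next_u64(state)
    return state, ((z >> uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


def make_stream_key(seed: int, wl_index: int) -> int:
    """Python-side derivation of the kernel stream key."""
    mask = (1 << 64) - 1
    z = (int(seed) & mask) ^ ((int(wl_index) + 1) * 0xD1B54A32D192ED03 & mask)
    # same finalizer as _mix64
    z ^= z >> 30
    z = z * 0xBF58476D1CE4E5B9 & mask
    z ^= z >> 27
    z = z * 0x94D049BB133111EB & mask
    z ^= z >> 31
    return z


@njit(cache=True, fastmath=True, inline="always")
def _fresnel(ni, nt, ci):
    """Unpolarized Fresnel reflectance for incidence cosine ``ci``."""
    if ci > 1.0:
        ci = 1.0
    si = np.sqrt(max(0.0, 1.0 - ci * ci))
    st = ni / nt * si
    if st >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - st * st)
    rs = (ni * ci - nt * ct) / (ni * ci + nt * ct)
    rp = (ni * ct - nt * ci) / (ni * ct + nt * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, inline="always")
def _hg_cos(g, u):
    """Inverse-CDF sample of the HG deflection cosine."""
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, fastmath=True, inline="always")
def _spin(ux, uy, uz, ct, phi):
    """Rotate the direction by deflection cosine ``ct`` and azimuth ``phi``."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -den * st * cp + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def run_layered(
    bounds,
    mua,
    mus,
    gg,
    nn,
    n_top,
    n_bottom,
    src_r,
    cos_amax,
    det_x,
    det_y,
    det_r,
    n_photons,
    stream_key,
    rr_wthresh,
    rr_p,
    age_limit,
    age_p,
    max_events,
    cap_to_diffuse,
    radial_dr,
    res,
    radial,
):
    """Transport ``n_photons`` packets through a layered half-space stack.

    ``bounds`` holds interface depths [0, d1, ..., dL] (dL may be huge for
    a semi-infinite terminal layer).  Results accumulate into ``res``
    (slots ``R_*``) and the escaped-weight radial histogram ``radial``.
    """
    nlay = mua.shape[0]
    det_r2 = det_r * det_r
    nbins = radial.shape[0]
    one_minus_ca = 1.0 - cos_amax
    for ip in range(n_photons):
        st = _stream_init(stream_key, ip)
        # --- launch: uniform over the source core, uniform solid angle in
        # the NA cone (air side), refracted into the top layer
        st, u = _next_open01(st)
        r0 = src_r * np.sqrt(u)
        st, u = _next_open01(st)
        phi0 = 2.0 * np.pi * u
        x = r0 * np.cos(phi0)
        y = r0 * np.sin(phi0)
        z = 0.0
        st, u = _next_open01(st)
        ca = 1.0 - u * one_minus_ca  # cos(theta) in air
        st, u = _next_open01(st)
        phid = 2.0 * np.pi * u
        rsp = _fresnel(n_top, nn[0], ca)
        res[R_SPEC] += rsp
        w = 1.0 - rsp
        sa = np.sqrt(max(0.0, 1.0 - ca * ca))
        stt = sa * n_top / nn[0]
        ctt = np.sqrt(max(0.0, 1.0 - stt * stt))
        ux = stt * np.cos(phid)
        uy = stt * np.sin(phid)
        uz = ctt
        lay = 0
        s_left = 0.0
        events = 0
        n_scat = 0
        alive = True
        while alive:
            events += 1
            if events >= max_events:
                if cap_to_diffuse:
                    res[R_DIFFUSE] += w
                else:
                    res[R_LOST] += w
                break
            mt = mua[lay] + mus[lay]
            if s_left <= 0.0:
                st, u = _next_open01(st)
                s_left = -np.log(u)
            step = s_left / mt
            # distance to the layer boundary along the flight direction
            if uz > 0.0:
                db = (bounds[lay + 1] - z) / uz
            elif uz < 0.0:
                db = (bounds[lay] - z) / uz
            else:
                db = 1.0e30
            if db < step:
                # move to the boundary; bank the unused optical depth
                x += ux * db
                y += uy * db
                z += uz * db
                s_left -= db * mt
                going_up = uz < 0.0
                if going_up and lay == 0:
                    n2 = n_top
                elif (not going_up) and lay == nlay - 1:
                    n2 = n_bottom
                else:
                    n2 = nn[lay + 1] if not going_up else nn[lay - 1]
                n1 = nn[lay]
                ci = abs(uz)
                refl = _fresnel(n1, n2, ci)
                if refl > 0.0:
                    st, u = _next_open01(st)
                else:
                    u = 1.0  # matched indices: deterministic transmission
                if u < refl:
                    uz = -uz  # internal reflection
                    # nudge off the interface
                    z += uz * 1.0e-12
                else:
                    sin_i = np.sqrt(max(0.0, 1.0 - ci * ci))
                    sin_t = sin_i * n1 / n2
                    cos_t = np.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                    if going_up and lay == 0:
                        # escaped through the top surface
                        res[R_DIFFUSE] += w
                        rr = np.sqrt(x * x + y * y)
                        ib = int(rr / radial_dr)
                        if ib < nbins:
                            radial[ib] += w
                        if cos_t >= cos_amax:
                            for k in range(NDET):
                                dx = x - det_x[k]
                                dy = y - det_y[k]
                                if dx * dx + dy * dy <= det_r2:
                                    res[R_DET0 + k] += w
                                    res[R_DETSQ0 + k] += w * w
                                    break
                        alive = False
                    elif (not going_up) and lay == nlay - 1:
                        res[R_TRANS] += w
                        alive = False
                    else:
                        # refract into the neighbouring layer
                        scale = n1 / n2
                        ux *= scale
                        uy *= scale
                        uz = cos_t if uz > 0.0 else -cos_t
                        norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                        lay = lay + 1 if not going_up else lay - 1
                        z += uz * 1.0e-12
                continue
            # interaction site
            x += ux * step
            y += uy * step
            z += uz * step
            s_left = 0.0
            dw = w * mua[lay] / mt
            res[R_ABSORBED] += dw
            w -= dw
            n_scat += 1
            # low-weight Russian roulette
            if w < rr_wthresh:
                st, u = _next_open01(st)
                if u < rr_p:
                    res[R_ROULETTE] -= w * (1.0 / rr_p - 1.0)
                    w /= rr_p
                else:
                    res[R_ROULETTE] += w
                    alive = False
                    continue
            # age roulette for near-conservative media (unbiased)
            if n_scat > age_limit:
                st, u = _next_open01(st)
                if u < age_p:
                    res[R_ROULETTE] -= w * (1.0 / age_p - 1.0)
                    w /= age_p
                else:
                    res[R_ROULETTE] += w
                    alive = False
                    continue
            st, u = _next_open01(st)
            ct = _hg_cos(gg[lay], u)
            st, u = _next_open01(st)
            ux, uy, uz = _spin(ux, uy, uz, ct, 2.0 * np.pi * u)


@njit(cache=True, fastmath=True)
def run_voxel(
    grid,
    mua,
    mus,
    gg,
    n_tissue,
    n_top,
    voxel,
    src_r,
    cos_amax,
    det_x,
    det_y,
    det_r,
    n_photons,
    stream_key,
    rr_wthresh,
    rr_p,
    age_limit,
    age_p,
    max_events,
    cap_to_diffuse,
    radial_dr,
    res,
    radial,
):
    """Transport through a voxelized volume with a uniform tissue index.

    Material changes occur at voxel faces with no internal Fresnel step
    (all voxel materials share ``n_tissue``); the only index mismatch is
    the top surface against ``n_top``.  Lateral and bottom lookups clamp
    to the edge voxel, extending the boundary material outward.
    """
    nz, ny, nx = grid.shape
    hx = voxel
    x_org = nx * hx / 2.0
    y_org = ny * hx / 2.0
    det_r2 = det_r * det_r
    nbins = radial.shape[0]
    one_minus_ca = 1.0 - cos_amax
    eps = 1.0e-9
    for ip in range(n_photons):
        st = _stream_init(stream_key, ip)
        st, u = _next_open01(st)
        r0 = src_r * np.sqrt(u)
        st, u = _next_open01(st)
        phi0 = 2.0 * np.pi * u
        x = r0 * np.cos(phi0)
        y = r0 * np.sin(phi0)
        z = 0.0
        st, u = _next_open01(st)
        ca = 1.0 - u * one_minus_ca
        st, u = _next_open01(st)
        phid = 2.0 * np.pi * u
        rsp = _fresnel(n_top, n_tissue, ca)
        res[R_SPEC] += rsp
        w = 1.0 - rsp
        sa = np.sqrt(max(0.0, 1.0 - ca * ca))
        stt = sa * n_top / n_tissue
        ctt = np.sqrt(max(0.0, 1.0 - stt * stt))
        ux = stt * np.cos(phid)
        uy = stt * np.sin(phid)
        uz = ctt
        z = eps  # start just below the surface
        s_left = 0.0
        events = 0
        n_scat = 0
        alive = True
        while alive:
            events += 1
            if events >= max_events:
                if cap_to_diffuse:
                    res[R_DIFFUSE] += w
                else:
                    res[R_LOST] += w
                break
            # clamped voxel index
            ix = int(np.floor((x + x_org) / hx))
            if ix < 0:
                ix = 0
            elif ix >= nx:
                ix = nx - 1
            iy = int(np.floor((y + y_org) / hx))
            if iy < 0:
                iy = 0
            elif iy >= ny:
                iy = ny - 1
            iz = int(np.floor(z / hx))
            if iz < 0:
                iz = 0
            elif iz >= nz:
                iz = nz - 1
            m = grid[iz, iy, ix]
            mt = mua[m] + mus[m]
            if s_left <= 0.0:
                st, u = _next_open01(st)
                s_left = -np.log(u)
            step = s_left / mt
            # distance to the next voxel face on the infinite lattice
            if ux > 0.0:
                tx = ((np.floor((x + x_org) / hx) + 1.0) * hx - (x + x_org)) / ux
            elif ux < 0.0:
                tx = (np.floor((x + x_org) / hx) * hx - (x + x_org)) / ux
            else:
                tx = 1.0e30
            if uy > 0.0:
                ty = ((np.floor((y + y_org) / hx) + 1.0) * hx - (y + y_org)) / uy
            elif uy < 0.0:
                ty = (np.floor((y + y_org) / hx) * hx - (y + y_org)) / uy
            else:
                ty = 1.0e30
            if uz > 0.0:
                tz = ((np.floor(z / hx) + 1.0) * hx - z) / uz
            elif uz < 0.0:
                tz = (np.floor(z / hx) * hx - z) / uz
            else:
                tz = 1.0e30
            db = min(tx, min(ty, tz))
            if db < 0.0:
                db = 0.0
            # distance to the physical top surface
            if uz < 0.0:
                dsurf = z / (-uz)
            else:
                dsurf = 1.0e30
            if dsurf <= db and dsurf < step:
                # hit the top surface
                x += ux * dsurf
                y += uy * dsurf
                z = 0.0
                s_left -= dsurf * mt
                ci = abs(uz)
                refl = _fresnel(n_tissue, n_top, ci)
                if refl > 0.0:
                    st, u = _next_open01(st)
                else:
                    u = 1.0  # matched indices: deterministic transmission
                if u < refl:
                    uz = -uz
                    z = eps
                else:
                    sin_i = np.sqrt(max(0.0, 1.0 - ci * ci))
                    sin_t = sin_i * n_tissue / n_top
                    cos_t = np.sqrt(max(0.0, 1.0 - sin_t * sin_t))
                    res[R_DIFFUSE] += w
                    rr = np.sqrt(x * x + y * y)
                    ib = int(rr / radial_dr)
                    if ib < nbins:
                        radial[ib] += w
                    if cos_t >= cos_amax:
                        for k in range(NDET):
                            dx = x - det_x[k]
                            dy = y - det_y[k]
                            if dx * dx + dy * dy <= det_r2:
                                res[R_DET0 + k] += w
                                res[R_DETSQ0 + k] += w * w
                                break
                    alive = False
                continue
            if db < step:
                # cross into the neighbouring voxel; bank optical depth
                adv = db + eps
                x += ux * adv
                y += uy * adv
                z += uz * adv
                s_left -= db * mt
                if z < 0.0:
                    z = eps
                continue
            x += ux * step
            y += uy * step
            z += uz * step
            s_left = 0.0
            dw = w * mua[m] / mt
            res[R_ABSORBED] += dw
            w -= dw
            n_scat += 1
            if w < rr_wthresh:
                st, u = _next_open01(st)
                if u < rr_p:
                    res[R_ROULETTE] -= w * (1.0 / rr_p - 1.0)
                    w /= rr_p
                else:
                    res[R_ROULETTE] += w
                    alive = False
                    continue
            if n_scat > age_limit:
                st, u = _next_open01(st)
                if u < age_p:
                    res[R_ROULETTE] -= w * (1.0 / age_p - 1.0)
                    w /= age_p
                else:
                    res[R_ROULETTE] += w
                    alive = False
                    continue
            st, u = _next_open01(st)
            ct = _hg_cos(gg[m], u)
            st, u = _next_open01(st)
            ux, uy, uz = _spin(ux, uy, uz, ct, 2.0 * np.pi * u)
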