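"""Numba kernel for multilayer photon-weight Monte Carlo transport.

Implements the standard hop-drop-spin random walk for a pencil beam
normally incident on a stack of plane-parallel turbid layers: step
lengths sampled from the free-path distribution with carry-over of the
dimensionless remainder across boundaries, weight deposition
``w * mua/mut`` per interaction, Henyey-Greenstein (or isotropic)
scattering, Fresnel reflection/refraction at refractive-index
mismatches, and Russian-roulette termination of low-weight photons.

Only the depth coordinate is tracked; all tallies (diffuse reflectance,
absorbed and transmitted fractions) are spatially integrated.  The
kernel additionally books the weight destroyed and created by roulette
so that callers can audit energy conservation as an exact floating-point
identity rather than a statistical statement.
"""

import numpy as np
from numba import njit

BIG = 1.0e30


@njit(cache=True)
def _fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_i``.

    Returns (reflectance, cos_t). cos_t is 0 under total internal
    reflection.
    """
    if n1 == n2:
        return 0.0, cos_i
    if cos_i > 0.999999:
        r = (n2 - n1) / (n2 + n1)
        return r * r, 1.0
    if cos_i < 1.0e-6:
        return 1.0, 0.0
    sin_i = np.sqrt(1.0 - cos_i * cos_i)
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    # averaged s/p polarization via angle sums and differences
    sam = sin_i * cos_t - cos_i * sin_t
    sap = sin_i * cos_t + cos_i * sin_t
    cam = cos_i * cos_t + sin_i * sin_t
    cap = cos_i * cos_t - sin_i * sin_t
    r = 0.5 * sam * sam * (cam * cam + cap * cap) / (sap * sap * cam * cam)
    return r, cos_t


@njit(cache=True, fastmath=True)
def transport(n_photons, seed, z_bounds, mua, mus, g, n_refr,
              n_ambient, n_backing, w_threshold, p_survive):
    """Trace ``n_photons`` through the layer stack at one wavelength.

    Parameters
    ----------
    z_bounds : float64[n_layers + 1]
        Cumulative layer interfaces in cm, starting at 0.
    mua, mus, g, n_refr : float64[n_layers]
        Per-layer optical properties.
    n_ambient, n_backing : float
        Refractive indices above the first and below the last layer.
    w_threshold, p_survive : float
        Russian-roulette trigger weight and survival probability.

    Returns
    -------
    (rsp, rd_sum, rd_sumsq, absorbed, transmitted, roulette_killed,
    roulette_boost) -- weight sums over all photons; each launched
    photon carries unit weight.
    """
    np.random.seed(seed)
    n_layers = mua.size

    # With isotropic scattering in every layer, only the depth cosine of
    # the direction is ever used (transport is 1-D in z and the Fresnel
    # angle depends on uz alone), so the transverse components need not
    # be sampled.  Any anisotropic layer requires the full unit vector.
    all_isotropic = True
    for k in range(n_layers):
        if g[k] != 0.0:
            all_isotropic = False

    # specular reflection of the normally incident beam at the top surface
    rsp_one = ((n_ambient - n_refr[0]) / (n_ambient + n_refr[0])) ** 2
    rsp = rsp_one * n_photons

    rd_sum = 0.0
    rd_sumsq = 0.0
    absorbed = 0.0
    transmitted = 0.0
    roulette_killed = 0.0
    roulette_boost = 0.0

    for _ in range(n_photons):
        w = 1.0 - rsp_one
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        sleft = 0.0
        escaped = 0.0
        alive = True

        while alive:
            mut = mua[layer] + mus[layer]
            if sleft <= 0.0:
                rnd = np.random.random()
                while rnd <= 0.0:
                    rnd = np.random.random()
                sleft = -np.log(rnd)
            if mut > 0.0:
                s = sleft / mut
            else:
                s = BIG  # transparent layer: ballistic to the boundary

            # distance to the layer interface along the flight direction
            if uz > 0.0:
                db = (z_bounds[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z_bounds[layer] - z) / uz
            else:
                db = BIG

            if db < s:
                # hit the interface before completing the step
                if mut > 0.0:
                    sleft -= db * mut
                going_down = uz > 0.0
                if going_down:
                    z = z_bounds[layer + 1]
                    n2 = n_backing if layer == n_layers - 1 else n_refr[layer + 1]
                else:
                    z = z_bounds[layer]
                    n2 = n_ambient if layer == 0 else n_refr[layer - 1]
                n1 = n_refr[layer]
                refl, cos_t = _fresnel(n1, n2, abs(uz))
                if refl > 0.0 and np.random.random() <= refl:
                    uz = -uz  # internally reflected
                else:
                    if going_down:
                        if layer == n_layers - 1:
                            transmitted += w
                            alive = False
                        else:
                            layer += 1
                            if n1 != n2:
                                scale = n1 / n2
                                ux *= scale
                                uy *= scale
                                uz = cos_t
                    else:
                        if layer == 0:
                            escaped = w
                            alive = False
                        else:
                            layer -= 1
                            if n1 != n2:
                                scale = n1 / n2
                                ux *= scale
                                uy *= scale
                                uz = -cos_t
                continue

            # complete the step inside the layer
            z += uz * s
            sleft = 0.0
            dw = w * mua[layer] / mut
            absorbed += dw
            w -= dw
            if w <= 0.0:
                alive = False
                continue

            # spin: sample the deflection from Henyey-Greenstein
            if all_isotropic:
                # new direction independent of the old; only uz matters
                uz = 2.0 * np.random.random() - 1.0
            else:
                gg = g[layer]
                if gg == 0.0:
                    cost = 2.0 * np.random.random() - 1.0
                else:
                    temp = (1.0 - gg * gg) / (
                        1.0 - gg + 2.0 * gg * np.random.random())
                    cost = (1.0 + gg * gg - temp * temp) / (2.0 * gg)
                    if cost > 1.0:
                        cost = 1.0
                    elif cost < -1.0:
                        cost = -1.0
                sint = np.sqrt(max(0.0, 1.0 - cost * cost))
                phi = 2.0 * np.pi * np.random.random()
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    temp = np.sqrt(1.0 - uz * uz)
                    ux_new = sint * (ux * uz * cosp - uy * sinp) / temp + ux * cost
                    uy_new = sint * (uy * uz * cosp + ux * sinp) / temp + uy * cost
                    uz_new = -sint * cosp * temp + uz * cost
                    ux = ux_new
                    uy = uy_new
                    uz = uz_new

            # roulette
            if w < w_threshold:
                if np.random.random() < p_survive:
                    roulette_boost += w * (1.0 / p_survive - 1.0)
                    w /= p_survive
                else:
                    roulette_killed += w
                    alive = False

        rd_sum += escaped
        rd_sumsq += escaped * escaped

    return (rsp, rd_sum, rd_sumsq, absorbed, transmitted,
            roulette_killed, roulette_boost)


@njit(cache=True, fastmath=True)
def two_layer_paths(n_photons, seed, d_top, d_bottom, mus_top, mus_bottom,
                    n_skin, n_ambient, n_backing):
    """Zero-absorption path ensemble for a matched-index two-layer slab.

    Photons scatter isotropically with no absorption; each photon is
    traced until it escapes the top surface or transmits through the
    bottom.  Because the scattering coefficients and boundaries do not
    depend on the absorbers, the recorded per-layer path lengths let the
    diffuse reflectance of *any* absorption pair be evaluated afterwards
    as ``(1 - Rsp) * mean(escaped * exp(-mua_top*L_top - mua_bot*L_bot))``
    -- the standard path-length-reweighting ("white Monte Carlo")
    estimator, exact in expectation.

    The two layers must share a refractive index (``n_skin``); the top
    and bottom ambient media may differ.  Returns float32 arrays
    ``(L_top, L_bottom)`` in cm and a uint8 flag set to 1 for photons
    that escaped through the top surface.
    """
    np.random.seed(seed)
    l_top = np.empty(n_photons, dtype=np.float32)
    l_bottom = np.empty(n_photons, dtype=np.float32)
    escaped = np.zeros(n_photons, dtype=np.uint8)
    z1 = d_top
    z2 = d_top + d_bottom
    # quick total-internal-reflection rejection at the top surface
    if n_skin > n_ambient:
        cos_crit_top = np.sqrt(1.0 - (n_ambient / n_skin) ** 2)
    else:
        cos_crit_top = 0.0
    if n_skin > n_backing:
        cos_crit_bot = np.sqrt(1.0 - (n_backing / n_skin) ** 2)
    else:
        cos_crit_bot = 0.0

    for i in range(n_photons):
        z = 0.0
        uz = 1.0
        layer = 0  # 0 = top, 1 = bottom
        le = 0.0
        ld = 0.0
        sleft = 0.0
        alive = True
        while alive:
            mus = mus_top if layer == 0 else mus_bottom
            if sleft <= 0.0:
                rnd = np.random.random()
                while rnd <= 0.0:
                    rnd = np.random.random()
                sleft = -np.log(rnd)
            s = sleft / mus if mus > 0.0 else BIG
            if uz > 0.0:
                zb = z1 if layer == 0 else z2
                db = (zb - z) / uz
            elif uz < 0.0:
                zb = 0.0 if layer == 0 else z1
                db = (zb - z) / uz
            else:
                db = BIG
            if db < s:
                if layer == 0:
                    le += db
                else:
                    ld += db
                if mus > 0.0:
                    sleft -= db * mus
                z = zb
                if uz > 0.0:
                    if layer == 0:
                        layer = 1  # matched internal boundary
                    else:
                        # bottom surface
                        if uz <= cos_crit_bot:
                            uz = -uz
                        else:
                            refl, _ = _fresnel(n_skin, n_backing, uz)
                            if np.random.random() <= refl:
                                uz = -uz
                            else:
                                alive = False  # transmitted
                else:
                    if layer == 1:
                        layer = 0
                    else:
                        # top surface
                        ci = -uz
                        if ci <= cos_crit_top:
                            uz = -uz
                        else:
                            refl, _ = _fresnel(n_skin, n_ambient, ci)
                            if np.random.random() <= refl:
                                uz = -uz
                            else:
                                escaped[i] = 1
                                alive = False
            else:
                if layer == 0:
                    le += s
                else:
                    ld += s
                z += uz * s
                sleft = 0.0
                uz = 2.0 * np.random.random() - 1.0
        l_top[i] = le
        l_bottom[i] = ld
    return l_top, l_bottom, escaped
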