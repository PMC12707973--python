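"""Numba photon-packet transport kernel for layered slabs.

Implicit-capture weights, Henyey-Greenstein scattering, Fresnel
reflection/refraction at every index-mismatched interface, Russian
roulette. Roulette bookkeeping is weight-exact: a kill credits the packet
weight to the absorbed tally and a survival debits w*(1-p)/p, so
specular + reflected + transmitted + escaped + absorbed equals the
launched weight to float rounding on every run, not just in expectation.

z increases downward; z = 0 is the illuminated surface.
"""

import numpy as np
from numba import njit

_CHANCE_INV = 10.0  # 1 / roulette survival probability


@njit(cache=True, fastmath=True)
def _fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance; returns (R, cos_t)."""
    if n1 == n2:
        return 0.0, cos_i
    if cos_i > 0.99999:
        r = (n1 - n2) / (n1 + n2)
        return r * r, 1.0
    sin_i = np.sqrt(1.0 - cos_i * cos_i)
    sin_t = n1 / n2 * sin_i
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, fastmath=True)
def transport(n_photons, seed, thick, mua, mus, g_arr, n_arr,
              n_ambient, beam_radius, det_radius, w_threshold,
              n_bins, bin_width):
    """Run the packet loop; returns tallies and radial exit profiles.

    det_radius < 0 tallies every exiting packet as detected (unbounded
    aperture); otherwise exits at r > det_radius go to the escaped tally.
    Radial profiles always bin all exits (overflow collects in the last bin).
    """
    np.random.seed(seed)
    n_layers = thick.shape[0]
    z_edge = np.empty(n_layers + 1)
    z_edge[0] = 0.0
    for i in range(n_layers):
        z_edge[i + 1] = z_edge[i] + thick[i]

    refl = 0.0
    trans = 0.0
    absorbed = 0.0
    escaped = 0.0
    refl_prof = np.zeros(n_bins)
    trans_prof = np.zeros(n_bins)

    r0 = (n_ambient - n_arr[0]) / (n_ambient + n_arr[0])
    rsp = r0 * r0
    specular = rsp * n_photons

    for _ in range(n_photons):
        # flat (top-hat) beam, normal incidence
        rr = beam_radius * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        x = rr * np.cos(phi)
        y = rr * np.sin(phi)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0 - rsp
        layer = 0
        alive = True

        while alive:
            s_left = -np.log(np.random.random() + 1e-300)
            while s_left > 0.0 and alive:
                mut = mua[layer] + mus[layer]
                if uz > 0.0:
                    db = (z_edge[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_edge[layer] - z) / uz
                else:
                    db = 1e30
                if mut <= 0.0:
                    ds = db
                    hit = True
                else:
                    ds = s_left / mut
                    hit = db <= ds
                    if hit:
                        ds = db
                if hit:
                    x += ux * ds
                    y += uy * ds
                    z += uz * ds
                    if mut > 0.0:
                        s_left -= ds * mut
                    going_down = uz > 0.0
                    nxt = layer + 1 if going_down else layer - 1
                    n1 = n_arr[layer]
                    n2 = n_ambient if (nxt < 0 or nxt >= n_layers) else n_arr[nxt]
                    cos_i = abs(uz)
                    R, cos_t = _fresnel(n1, n2, cos_i)
                    if np.random.random() < R:
                        uz = -uz  # internal reflection
                        # clamp to edge to avoid drifting out by rounding
                        z = z_edge[layer + 1] if going_down else z_edge[layer]
                    else:
                        if nxt < 0 or nxt >= n_layers:
                            r_exit = np.sqrt(x * x + y * y)
                            b = int(r_exit / bin_width)
                            if b >= n_bins:
                                b = n_bins - 1
                            detected = det_radius < 0.0 or r_exit <= det_radius
                            if nxt < 0:
                                if detected:
                                    refl += w
                                else:
                                    escaped += w
                                refl_prof[b] += w
                            else:
                                if detected:
                                    trans += w
                                else:
                                    escaped += w
                                trans_prof[b] += w
                            alive = False
                        else:
                            ratio = n1 / n2
                            ux *= ratio
                            uy *= ratio
                            uz = cos_t if going_down else -cos_t
                            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                            ux /= norm
                            uy /= norm
                            uz /= norm
                            layer = nxt
                            z = z_edge[layer] if going_down else z_edge[layer + 1]
                else:
                    x += ux * ds
                    y += uy * ds
                    z += uz * ds
                    s_left = 0.0
                    # implicit capture
                    absorbed += w * mua[layer] / mut
                    w *= mus[layer] / mut
                    if w <= 0.0:
                        alive = False
                        break
                    # Henyey-Greenstein deflection
                    g = g_arr[layer]
                    if g == 0.0:
                        cost = 2.0 * np.random.random() - 1.0
                    else:
                        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                        cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                        if cost > 1.0:
                            cost = 1.0
                        elif cost < -1.0:
                            cost = -1.0
                    sint = np.sqrt(1.0 - cost * cost)
                    phi = 2.0 * np.pi * np.random.random()
                    cosp = np.cos(phi)
                    sinp = np.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = sint * cosp
                        uy = sint * sinp
                        uz = cost if uz > 0.0 else -cost
                    else:
                        den = np.sqrt(1.0 - uz * uz)
                        ux_n = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                        uy_n = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                        uz_n = -sint * cosp * den + uz * cost
                        ux, uy, uz = ux_n, uy_n, uz_n
                    if w < w_threshold and alive:
                        if np.random.random() * _CHANCE_INV < 1.0:
                            absorbed -= w * (_CHANCE_INV - 1.0)
                            w *= _CHANCE_INV
                        else:
                            absorbed += w
                            alive = False

    inv = 1.0 / n_photons
    return (refl * inv, trans * inv, absorbed * inv, specular * inv,
            escaped * inv, refl_prof * inv, trans_prof * inv)
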