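"""Independent single-purpose reference transport loop for cross-checking
the packaged Monte Carlo kernel.

Deliberately a different estimator scheme: analog sampling (no packet
weights) — at each collision the photon is absorbed outright with
probability mu_a/mu_t, otherwise scattered; reflection/transmission are
plain photon counts. Coded from scratch against the same physics
(exponential free paths, Henyey-Greenstein, Fresnel/Snell at interfaces);
njit only for speed. Counts are binomial, so standard errors are exact.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def analog_rt(n_photons, seed, thickness, mu_a, mu_s, g, n_med, n_out):
    """Reflected/transmitted photon counts for a layered slab.

    Photons launched at the origin straight down (a pencil beam: for a
    laterally infinite slab the integrated R/T equal those of any wider
    uniform beam). Specular reflection at entry is sampled, not split.
    Returns (n_reflected, n_transmitted).
    """
    np.random.seed(seed)
    nl = thickness.shape[0]
    edges = np.empty(nl + 1)
    edges[0] = 0.0
    for i in range(nl):
        edges[i + 1] = edges[i] + thickness[i]

    n_r = 0
    n_t = 0
    for _ in range(n_photons):
        z = 0.0
        uz = 1.0
        ux = 0.0
        uy = 0.0
        lay = 0
        # entry Fresnel, normal incidence, sampled
        r0 = (n_out - n_med[0]) / (n_out + n_med[0])
        if np.random.random() < r0 * r0:
            n_r += 1
            continue
        alive = True
        while alive:
            mt = mu_a[lay] + mu_s[lay]
            s = -math.log(np.random.random() + 1e-300) / mt
            # distance to the layer boundary along the flight direction
            if uz > 0.0:
                d_b = (edges[lay + 1] - z) / uz
            elif uz < 0.0:
                d_b = (edges[lay] - z) / uz
            else:
                d_b = 1e30
            if s < d_b:
                z += uz * s
                if np.random.random() < mu_a[lay] / mt:
                    alive = False  # absorbed (analog)
                else:
                    gg = g[lay]
                    u = np.random.random()
                    if gg == 0.0:
                        ct = 2.0 * u - 1.0
                    else:
                        f = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u)
                        ct = (1.0 + gg * gg - f * f) / (2.0 * gg)
                        ct = min(1.0, max(-1.0, ct))
                    st = math.sqrt(1.0 - ct * ct)
                    ph = 2.0 * math.pi * np.random.random()
                    if abs(uz) > 0.99999:
                        ux = st * math.cos(ph)
                        uy = st * math.sin(ph)
                        uz = ct * (1.0 if uz > 0 else -1.0)
                    else:
                        sq = math.sqrt(1.0 - uz * uz)
                        nx = st * (ux * uz * math.cos(ph) - uy * math.sin(ph)) / sq \
                            + ux * ct
                        ny = st * (uy * uz * math.cos(ph) + ux * math.sin(ph)) / sq \
                            + uy * ct
                        nz = -st * math.cos(ph) * sq + uz * ct
                        ux, uy, uz = nx, ny, nz
            else:
                z += uz * d_b
                down = uz > 0.0
                nxt = lay + 1 if down else lay - 1
                n1 = n_med[lay]
                n2 = n_out if (nxt < 0 or nxt >= nl) else n_med[nxt]
                ci = abs(uz)
                if n1 == n2:
                    refl = 0.0
                    ct_t = ci
                else:
                    si = math.sqrt(max(0.0, 1.0 - ci * ci))
                    stt = n1 / n2 * si
                    if stt >= 1.0:
                        refl = 1.0
                        ct_t = 0.0
                    else:
                        ct_t = math.sqrt(1.0 - stt * stt)
                        rs = (n1 * ci - n2 * ct_t) / (n1 * ci + n2 * ct_t)
                        rp = (n1 * ct_t - n2 * ci) / (n1 * ct_t + n2 * ci)
                        refl = 0.5 * (rs * rs + rp * rp)
                if np.random.random() < refl:
                    uz = -uz
                    z = edges[lay + 1] if down else edges[lay]
                else:
                    if nxt < 0:
                        n_r += 1
                        alive = False
                    elif nxt >= nl:
                        n_t += 1
                        alive = False
                    else:
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz = ct_t if down else -ct_t
                        nrm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= nrm
                        uy /= nrm
                        uz /= nrm
                        lay = nxt
                        z = edges[lay] if down else edges[lay + 1]
    return n_r, n_t
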