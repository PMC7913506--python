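"""Independent single-purpose Monte Carlo oracle for diffuse reflectance.

A deliberately separate implementation from the package kernel: vectorized
NumPy over a photon population, single homogeneous semi-infinite medium,
pencil beam at normal incidence, Henyey-Greenstein scattering, unpolarized
Fresnel boundary at the top surface (handled by mirroring the position of
internally reflected photons), and Russian roulette with the classic 1/p
weight boost. Used only as a cross-check of the package kernel.
"""

from __future__ import annotations

import numpy as np


def _fresnel_up(n_rel: float, mu: np.ndarray) -> np.ndarray:
    """Unpolarized reflectance for upward cosine ``mu`` (>0), inside->outside.

    ``n_rel`` = n_inside / n_outside (outside is air, n = 1).
    """
    mu = np.clip(mu, 0.0, 1.0)
    sin_i = np.sqrt(1.0 - mu**2)
    sin_t = n_rel * sin_i
    refl = np.ones_like(mu)
    ok = sin_t < 1.0
    cos_t = np.sqrt(1.0 - np.minimum(sin_t, 1.0) ** 2)
    ni, nt = n_rel, 1.0
    rs = (ni * mu - nt * cos_t) / (ni * mu + nt * cos_t)
    rp = (ni * cos_t - nt * mu) / (ni * cos_t + nt * mu)
    r_ok = 0.5 * (rs**2 + rp**2)
    refl[ok] = r_ok[ok]
    normal = mu > 0.9999999
    refl[normal] = ((ni - nt) / (ni + nt)) ** 2
    return refl


def semi_infinite_rd(
    mu_a: float,
    mu_s: float,
    g: float,
    n_medium: float,
    n_photons: int = 100_000,
    seed: int = 0,
    weight_min: float = 1.0e-4,
    survive_p: float = 0.1,
) -> float:
    """Total diffuse reflectance of a semi-infinite homogeneous medium."""
    rng = np.random.default_rng(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    n_rel = n_medium / 1.0

    r_spec = ((1.0 - n_medium) / (1.0 + n_medium)) ** 2
    w = np.full(n_photons, 1.0 - r_spec)
    z = np.zeros(n_photons)
    ux = np.zeros(n_photons)
    uy = np.zeros(n_photons)
    uz = np.ones(n_photons)

    escaped_weight = 0.0
    alive = np.ones(n_photons, bool)
    while alive.any():
        idx = np.flatnonzero(alive)
        step = -np.log(rng.random(idx.size)) / mu_t
        z_new = z[idx] + uz[idx] * step

        esc = np.zeros(idx.size, bool)
        cross = z_new < 0.0
        if cross.any():
            pos = np.flatnonzero(cross)
            mu_up = -uz[idx[pos]]
            refl = _fresnel_up(n_rel, mu_up)
            out = rng.random(pos.size) >= refl
            esc[pos[out]] = True
            escaped_weight += float(w[idx[pos[out]]].sum())
            alive[idx[pos[out]]] = False
            # internally reflected photons finish their step mirrored below the surface
            bounce = idx[pos[~out]]
            z[bounce] = -z_new[pos[~out]]
            uz[bounce] = -uz[bounce]
        z[idx[~cross]] = z_new[~cross]

        surv = idx[~esc]
        if surv.size == 0:
            continue

        # interaction: implicit-capture absorption, then HG deflection
        w[surv] *= albedo
        m = surv.size
        u1 = rng.random(m)
        if abs(g) < 1e-6:
            cost = 2.0 * u1 - 1.0
        else:
            tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
            cost = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
        sint = np.sqrt(1.0 - cost**2)
        phi = 2.0 * np.pi * rng.random(m)
        cosp, sinp = np.cos(phi), np.sin(phi)
        uxs, uys, uzs = ux[surv], uy[surv], uz[surv]
        near_vert = np.abs(uzs) > 0.99999
        den = np.sqrt(np.maximum(1.0 - uzs**2, 1e-30))
        nux = sint * (uxs * uzs * cosp - uys * sinp) / den + uxs * cost
        nuy = sint * (uys * uzs * cosp + uxs * sinp) / den + uys * cost
        nuz = -sint * cosp * den + uzs * cost
        nux[near_vert] = (sint * cosp)[near_vert]
        nuy[near_vert] = (sint * sinp)[near_vert]
        nuz[near_vert] = (cost * np.sign(uzs))[near_vert]
        norm = np.sqrt(nux**2 + nuy**2 + nuz**2)
        ux[surv] = nux / norm
        uy[surv] = nuy / norm
        uz[surv] = nuz / norm

        small = surv[w[surv] < weight_min]
        if small.size:
            u = rng.random(small.size)
            die = small[u >= survive_p]
            boost = small[u < survive_p]
            alive[die] = False
            w[boost] /= survive_p

    return escaped_weight / n_photons
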