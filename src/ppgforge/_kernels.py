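"""Numba-compiled photon-transport kernels.

Two kernels over the same laterally infinite layered-slab geometry
(z = 0 at the illuminated top surface, z increasing into the tissue,
lengths in cm):

``mcml_kernel``
    The reference sampler: dimensionless step ``-ln(xi)`` converted by the
    local ``mu_t``, absorption weighting ``mu_a/mu_t`` at each collision,
    Henyey-Greenstein scattering, Fresnel reflection at the top interface,
    Russian roulette below a weight threshold.

``paths_kernel``
    A common-random-number / "white Monte Carlo" estimator: the trajectory
    is sampled from the scattering coefficients only (step ``-ln(xi)/mu_s``)
    and K absorption vectors are scored simultaneously along the shared
    path via the track-length factor ``exp(-sum mu_a * l)``.  Because rest
    and pulse tissue differ only in dermal ``mu_a``, both states (or a whole
    VFM ladder) ride the same paths, so their difference — the pulsatile AC
    — has per-photon, not per-run, variance.

Both kernels seed numba's internal Mersenne-Twister with ``np.random.seed``
so that a fixed seed gives a bit-reproducible stream identical to NumPy's
legacy ``RandomState``.  The draw order per photon is part of the kernel
contract (tests mirror it with an independent pure-Python loop):

1. launch x, then y (square top-hat source);
2. direction: one uniform for ``cos(theta)`` (Lambertian clamped to the
   half-angle), one for the azimuth;
3. per flight: one uniform for the step; at a collision two uniforms for
   the new direction (HG deflection, then azimuth);
4. one uniform per partially reflecting boundary hit (drawn iff R < 1);
5. one uniform per Russian-roulette trial.

Weight bookkeeping is exact: roulette kills deposit the dead weight in the
absorbed bin and survivals deposit the (negative) amplification
``w - w/p_survive`` there, so detected + absorbed + escaped equals the
launched weight to floating-point round-off on every run.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: roulette parameters (overridable through the transport-level API)
WEIGHT_MIN = 1e-4
P_SURVIVE = 0.1

DET_TOP = 0
DET_BOTTOM = 1


@njit(cache=True)
def _fresnel_unpolarized(n_rel: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for internal incidence, n_rel = n_in/n_out."""
    if n_rel == 1.0:
        return 0.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _spin(ux: float, uy: float, uz: float, cos_t: float, phi: float):
    """Rotate a unit direction by deflection cos_t and azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t if uz >= 0.0 else -cos_t
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nz = -sin_t * cos_p * den + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _hg_cos(g: float, u: float) -> float:
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def mcml_kernel(
    seed: int,
    n_photons: int,
    z_bounds: np.ndarray,  # (n_layers + 1,) cm, z_bounds[0] = 0
    mua: np.ndarray,
    mus: np.ndarray,
    g: np.ndarray,
    n_rel: float,  # n_tissue / n_ambient
    src_side: float,  # cm
    sin2_half: float,  # sin^2 of the (clamped) source half angle
    det_surface: int,  # DET_TOP or DET_BOTTOM
    det_inner: float,  # cm
    det_outer: float,
    det_cx: float,
    det_cy: float,
    w_min: float,
    p_survive: float,
):
    """Reference absorption-weighting transport. Returns (detected, absorbed, escaped)."""
    np.random.seed(seed)
    n_layers = z_bounds.shape[0] - 1
    detected = 0.0
    absorbed = 0.0
    escaped = 0.0

    for _ in range(n_photons):
        x = (np.random.random() - 0.5) * src_side
        y = (np.random.random() - 0.5) * src_side
        z = 0.0
        cos_t = math.sqrt(1.0 - np.random.random() * sin2_half)
        phi = 2.0 * math.pi * np.random.random()
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
        ux = sin_t * math.cos(phi)
        uy = sin_t * math.sin(phi)
        uz = cos_t
        w = 1.0
        layer = 0
        alive = True

        while alive:
            s = -math.log(np.random.random())  # dimensionless step
            while s > 0.0 and alive:
                mut = mua[layer] + mus[layer]
                if uz > 0.0:
                    db = (z_bounds[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[layer] - z) / uz
                else:
                    db = np.inf
                d = np.inf if mut <= 0.0 else s / mut
                if d == np.inf and db == np.inf:
                    # non-interacting layer and horizontal flight: unreachable exit
                    absorbed += w
                    alive = False
                    break
                if d < db:
                    # collision inside the layer
                    x += ux * d
                    y += uy * d
                    z += uz * d
                    s = 0.0
                    dw = w * mua[layer] / mut
                    absorbed += dw
                    w -= dw
                    if w <= 0.0:
                        alive = False
                        break
                    cs = _hg_cos(g[layer], np.random.random())
                    ph = 2.0 * math.pi * np.random.random()
                    ux, uy, uz = _spin(ux, uy, uz, cs, ph)
                    if w < w_min:
                        if np.random.random() < p_survive:
                            absorbed += w - w / p_survive
                            w /= p_survive
                        else:
                            absorbed += w
                            alive = False
                else:
                    # move to the boundary
                    x += ux * db
                    y += uy * db
                    z += uz * db
                    s -= db * mut
                    if uz < 0.0 and layer == 0:
                        # top surface
                        r_f = _fresnel_unpolarized(n_rel, -uz)
                        if r_f >= 1.0:
                            uz = -uz
                            z = z_bounds[0]
                        elif np.random.random() >= r_f:
                            rr = math.sqrt((x - det_cx) ** 2 + (y - det_cy) ** 2)
                            if det_surface == DET_TOP and det_inner <= rr <= det_outer:
                                detected += w
                            else:
                                escaped += w
                            alive = False
                        else:
                            uz = -uz
                            z = z_bounds[0]
                    elif uz > 0.0 and layer == n_layers - 1:
                        # bottom surface: absorbing unless it is the detection plane
                        if det_surface == DET_BOTTOM:
                            r_f = _fresnel_unpolarized(n_rel, uz)
                            if r_f >= 1.0:
                                uz = -uz
                                z = z_bounds[n_layers]
                            elif np.random.random() >= r_f:
                                rr = math.sqrt((x - det_cx) ** 2 + (y - det_cy) ** 2)
                                if det_inner <= rr <= det_outer:
                                    detected += w
                                else:
                                    escaped += w
                                alive = False
                            else:
                                uz = -uz
                                z = z_bounds[n_layers]
                        else:
                            absorbed += w
                            alive = False
                    elif uz < 0.0:
                        layer -= 1
                        z = z_bounds[layer + 1]
                    else:
                        layer += 1
                        z = z_bounds[layer]

    inv = 1.0 / n_photons
    return detected * inv, absorbed * inv, escaped * inv


@njit(cache=True)
def paths_kernel(
    seed: int,
    n_photons: int,
    z_bounds: np.ndarray,
    mua_sets: np.ndarray,  # (K, n_layers); row 0 must have the smallest mua (drives roulette)
    mus: np.ndarray,
    g: np.ndarray,
    n_rel: float,
    src_side: float,
    sin2_half: float,
    det_inner: float,
    det_outer: float,
    det_cx: float,
    det_cy: float,
    w_min: float,
    p_survive: float,
):
    """Shared-path multi-absorption estimator (top-surface detection only).

    Returns (detected[K], absorbed[K], escaped[K]).  All K absorption
    vectors see identical trajectories; differences between rows are
    per-photon paired differences.
    """
    np.random.seed(seed)
    n_layers = z_bounds.shape[0] - 1
    n_sets = mua_sets.shape[0]
    detected = np.zeros(n_sets)
    absorbed = np.zeros(n_sets)
    escaped = np.zeros(n_sets)
    w = np.empty(n_sets)

    for _ in range(n_photons):
        x = (np.random.random() - 0.5) * src_side
        y = (np.random.random() - 0.5) * src_side
        z = 0.0
        cos_t = math.sqrt(1.0 - np.random.random() * sin2_half)
        phi = 2.0 * math.pi * np.random.random()
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
        ux = sin_t * math.cos(phi)
        uy = sin_t * math.sin(phi)
        uz = cos_t
        for k in range(n_sets):
            w[k] = 1.0
        layer = 0
        alive = True

        while alive:
            if mus[layer] > 0.0:
                d = -math.log(np.random.random()) / mus[layer]
            else:
                d = np.inf
            if uz > 0.0:
                db = (z_bounds[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z_bounds[layer] - z) / uz
            else:
                db = np.inf
            seg = d if d < db else db
            if seg == np.inf:
                for k in range(n_sets):
                    absorbed[k] += w[k]
                break
            # attenuate every absorption channel along the shared segment
            for k in range(n_sets):
                f = math.exp(-mua_sets[k, layer] * seg)
                absorbed[k] += w[k] * (1.0 - f)
                w[k] *= f
            x += ux * seg
            y += uy * seg
            z += uz * seg
            if d < db:
                cs = _hg_cos(g[layer], np.random.random())
                ph = 2.0 * math.pi * np.random.random()
                ux, uy, uz = _spin(ux, uy, uz, cs, ph)
                if w[0] < w_min:
                    if np.random.random() < p_survive:
                        for k in range(n_sets):
                            absorbed[k] += w[k] - w[k] / p_survive
                            w[k] /= p_survive
                    else:
                        for k in range(n_sets):
                            absorbed[k] += w[k]
                        alive = False
            else:
                if uz < 0.0 and layer == 0:
                    r_f = _fresnel_unpolarized(n_rel, -uz)
                    if r_f >= 1.0:
                        uz = -uz
                        z = z_bounds[0]
                    elif np.random.random() >= r_f:
                        rr = math.sqrt((x - det_cx) ** 2 + (y - det_cy) ** 2)
                        if det_inner <= rr <= det_outer:
                            for k in range(n_sets):
                                detected[k] += w[k]
                        else:
                            for k in range(n_sets):
                                escaped[k] += w[k]
                        alive = False
                    else:
                        uz = -uz
                        z = z_bounds[0]
                elif uz > 0.0 and layer == n_layers - 1:
                    for k in range(n_sets):
                        absorbed[k] += w[k]
                    alive = False
                elif uz < 0.0:
                    layer -= 1
                    z = z_bounds[layer + 1]
                else:
                    layer += 1
                    z = z_bounds[layer]

    inv = 1.0 / n_photons
    return detected * inv, absorbed * inv, escaped * inv
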