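"""Numba kernels: batched adding-doubling inner loop and photon Monte Carlo.

The doubling recursion works on small dense matrices (n_quad x n_quad, one
pair per (spectrum, wavelength) channel); a hand-rolled LU with partial
pivoting avoids per-call LAPACK overhead at these sizes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _lu_factor(a, piv):
    n = a.shape[0]
    for k in range(n):
        p = k
        amax = abs(a[k, k])
        for i in range(k + 1, n):
            v = abs(a[i, k])
            if v > amax:
                amax = v
                p = i
        piv[k] = p
        if p != k:
            for j in range(n):
                tmp = a[k, j]
                a[k, j] = a[p, j]
                a[p, j] = tmp
        akk = a[k, k]
        for i in range(k + 1, n):
            lik = a[i, k] / akk
            a[i, k] = lik
            for j in range(k + 1, n):
                a[i, j] -= lik * a[k, j]


@njit(cache=True, fastmath=True)
def _lu_solve_inplace(a, piv, b):
    """Solve A X = B for all columns of B, using the factored A."""
    n = a.shape[0]
    m = b.shape[1]
    for k in range(n):
        p = piv[k]
        if p != k:
            for j in range(m):
                tmp = b[k, j]
                b[k, j] = b[p, j]
                b[p, j] = tmp
        for i in range(k + 1, n):
            lik = a[i, k]
            for j in range(m):
                b[i, j] -= lik * b[k, j]
    for k in range(n - 1, -1, -1):
        akk = a[k, k]
        for j in range(m):
            b[k, j] /= akk
        for i in range(k):
            aik = a[i, k]
            for j in range(m):
                b[i, j] -= aik * b[k, j]


@njit(cache=True, fastmath=True)
def _matmul(a, b, out):
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(n):
                s += a[i, k] * b[k, j]
            out[i, j] = s


@njit(cache=True, fastmath=True)
def rt_homogeneous_batch(albedo, tau, h_plus, h_minus, mu, w, tau0_factor):
    """R, T flux operators of homogeneous layers, one per channel.

    albedo, tau: (C,); h_plus/h_minus: (C, N, N); mu, w: (C, N).
    Diamond initialisation at tau / 2**k (k chosen so the starting thickness
    is below tau0_factor * min(mu)), then k doublings.
    """
    C, N = mu.shape
    R = np.zeros((C, N, N))
    T = np.zeros((C, N, N))
    a = np.empty((N, N))
    b = np.empty((N, N))
    tmp1 = np.empty((N, N))
    tmp2 = np.empty((N, N))
    rhs = np.empty((N, 2 * N))
    piv = np.empty(N, dtype=np.int64)
    for c in range(C):
        t_c = tau[c]
        if t_c <= 0.0:
            for i in range(N):
                T[c, i, i] = 1.0
            continue
        mu_min = mu[c, 0]
        for i in range(1, N):
            if mu[c, i] < mu_min:
                mu_min = mu[c, i]
        tau0 = mu_min * tau0_factor
        k = 0
        while t_c / (2.0 ** k) > tau0:
            k += 1
        dt = t_c / (2.0 ** k)
        # flux-space generators scaled by dt/2
        half = dt / 2.0
        om = albedo[c]
        for i in range(N):
            si = 2.0 * mu[c, i] * w[c, i]
            for j in range(N):
                sj = 2.0 * mu[c, j] * w[c, j]
                fac = half * si / (mu[c, i] * sj)
                a[i, j] = -fac * 0.5 * om * h_plus[c, i, j] * w[c, j]
                if i == j:
                    a[i, j] += half / mu[c, i]
                b[i, j] = fac * 0.5 * om * h_minus[c, i, j] * w[c, j]
        # diamond init: q_db = (I + a)^{-1} b
        for i in range(N):
            for j in range(N):
                tmp1[i, j] = a[i, j]
                tmp2[i, j] = b[i, j]
            tmp1[i, i] += 1.0
        _lu_factor(tmp1, piv)
        _lu_solve_inplace(tmp1, piv, tmp2)          # tmp2 = q_db
        _matmul(b, tmp2, tmp1)                      # tmp1 = b @ q_db
        # T = (I + a - b q_db)^{-1} (I - a + b q_db); R = q_db (I + T)
        for i in range(N):
            for j in range(N):
                rhs[i, j] = a[i, j] - tmp1[i, j]
                rhs[i, N + j] = -a[i, j] + tmp1[i, j]
                tmp1[i, j] = rhs[i, j]
            tmp1[i, i] += 1.0
            rhs[i, N + i] += 1.0
        _lu_factor(tmp1, piv)
        rview = rhs[:, N:]
        _lu_solve_inplace(tmp1, piv, rview)
        for i in range(N):
            for j in range(N):
                T[c, i, j] = rhs[i, N + j]
        for i in range(N):
            for j in range(N):
                s = tmp2[i, j]
                for m in range(N):
                    s += tmp2[i, m] * T[c, m, j]
                R[c, i, j] = s
        # doubling
        for _ in range(k):
            _matmul(R[c], R[c], tmp1)               # R R
            for i in range(N):
                for j in range(N):
                    tmp1[i, j] = -tmp1[i, j]
                tmp1[i, i] += 1.0                   # I - RR
            _matmul(R[c], T[c], tmp2)               # R T
            for i in range(N):
                for j in range(N):
                    rhs[i, j] = T[c, i, j]
                    rhs[i, N + j] = tmp2[i, j]
            _lu_factor(tmp1, piv)
            _lu_solve_inplace(tmp1, piv, rhs)
            # T2 = T X1 ; R2 = R + T X2
            for i in range(N):
                for j in range(N):
                    s1 = 0.0
                    s2 = 0.0
                    for m in range(N):
                        s1 += T[c, i, m] * rhs[m, j]
                        s2 += T[c, i, m] * rhs[m, N + j]
                    tmp2[i, j] = s1
                    b[i, j] = R[c, i, j] + s2
            for i in range(N):
                for j in range(N):
                    T[c, i, j] = tmp2[i, j]
                    R[c, i, j] = b[i, j]
    return R, T


# ---------------------------------------------------------------------------
# photon Monte Carlo oracle
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _fresnel(n_i, n_t, mu_i):
    sin_t2 = (n_i / n_t) * (n_i / n_t) * (1.0 - mu_i * mu_i)
    if sin_t2 >= 1.0:
        return 1.0
    mu_t = np.sqrt(1.0 - sin_t2)
    rs = (n_i * mu_i - n_t * mu_t) / (n_i * mu_i + n_t * mu_t)
    rp = (n_t * mu_i - n_i * mu_t) / (n_t * mu_i + n_i * mu_t)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def mc_reflectance(mu_a_epi, mu_s_epi, g_epi, mu_a_der, mu_s_der, g_der,
                   n_slab, d_epi, d_der, n_photons, seed):
    """Total reflectance of the two-layer slab in air by photon transport.

    Collimated normal incidence; specular entry reflection added analytically;
    Henyey-Greenstein scattering; Fresnel top/bottom interfaces (matched
    epidermis/dermis interface); absorption by weight attenuation with
    Russian-roulette termination. Returns (R_total, sum of squared weights)
    for a standard-error estimate.
    """
    np.random.seed(seed)
    r_spec = _fresnel(1.0, n_slab, 1.0)
    total = 0.0
    total_sq = 0.0
    z_bottom = d_epi + d_der
    for _ in range(n_photons):
        w = 1.0 - r_spec
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        escaped = 0.0
        alive = True
        while alive:
            in_epi = z < d_epi
            mu_a = mu_a_epi if in_epi else mu_a_der
            mu_s = mu_s_epi if in_epi else mu_s_der
            g = g_epi if in_epi else g_der
            mu_t = mu_a + mu_s
            step = -np.log(np.random.random() + 1e-300) / mu_t
            z_new = z + uz * step
            # boundary crossings within the current layer
            if uz > 0.0:
                zb = d_epi if in_epi else z_bottom
                if z_new > zb:
                    if zb == z_bottom:
                        # bottom interface
                        r = _fresnel(n_slab, 1.0, uz)
                        if np.random.random() < r:
                            z = z_bottom
                            uz = -uz
                        else:
                            alive = False  # transmitted out the bottom
                        continue
                    z = zb + 1e-12
                    continue  # crossed into dermis, redraw step
            elif uz < 0.0:
                zb = d_epi if not in_epi else 0.0
                if z_new < zb:
                    if zb == 0.0:
                        r = _fresnel(n_slab, 1.0, -uz)
                        if np.random.random() < r:
                            z = 0.0
                            uz = -uz
                        else:
                            escaped = w
                            alive = False
                        continue
                    z = zb - 1e-12
                    continue
            z = z_new
            # absorb
            w *= mu_s / mu_t
            if w < 1e-4:
                if np.random.random() < 0.1:
                    w *= 10.0
                else:
                    alive = False
                    continue
            # HG scatter
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                ct = 2.0 * np.random.random() - 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            cp, sp = np.cos(phi), np.sin(phi)
            if abs(uz) > 0.99999:
                ux_n = st * cp
                uy_n = st * sp
                uz_n = ct * (1.0 if uz >= 0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz_n = -den * st * cp + uz * ct
            norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
            ux, uy, uz = ux_n / norm, uy_n / norm, uz_n / norm
        total += escaped
        total_sq += escaped * escaped
    mean = total / n_photons
    var = total_sq / n_photons - mean * mean
    return r_spec + mean, var
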