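"""Adding-doubling radiative transfer for the two-layer skin slab.

Computes total diffuse reflectance of an epidermis-over-dermis slab in air for
collimated, normally incident light. Radiances are discretised on a
Gauss-Radau quadrature of direction cosines (the node at mu=1 carries the
collimated beam); per-layer reflection/transmission operators are built by
diamond (Crank-Nicolson) initialisation of a thin layer followed by repeated
doubling, layers and Fresnel boundaries are composed with the standard adding
equations, and the result is read off as the reflected flux for unit flux
injected in the mu=1 channel.

All matrix operators act on per-channel *fluxes* (so conservation is a column
sum) and are vectorised over a leading "channel" axis, one channel per
(spectrum, wavelength) pair; the scalar entry points are batch-of-one calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

from .optics import (
    FixedParams,
    TissueParams,
    WavelengthGrid,
    ChromophoreLibrary,
    assemble_optical_properties,
)

DEFAULT_N_QUAD = 16
#: starting optical thickness for doubling, as a fraction of the smallest node
TAU0_FACTOR = 1e-4


class QuadratureError(ValueError):
    pass


@dataclass(frozen=True)
class QuadratureScheme:
    """Direction-cosine nodes/weights on (0, 1]; integrates f(mu) d(mu)."""

    mu: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        if not np.all(np.diff(self.mu) > 0):
            raise QuadratureError("nodes must be strictly increasing")
        if np.any(self.mu <= 0) or np.any(self.mu > 1 + 1e-12):
            raise QuadratureError("nodes must lie in (0, 1]")
        if np.any(self.w <= 0):
            raise QuadratureError("weights must be positive")

    @property
    def n(self) -> int:
        return self.mu.size

    @property
    def beam_index(self) -> int:
        """Index of the node carrying the collimated normal beam (mu=1)."""
        return int(np.argmax(self.mu))


def _radau_right(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Radau nodes/weights on [-1, 1] with a fixed node at +1."""
    # left-Radau (fixed at -1): interior nodes are the roots of
    # (P_{n-1} + P_n)/(1+x); mirror to get the right-Radau rule.
    c = np.zeros(n + 1)
    c[n - 1] = 1.0
    c[n] = 1.0
    roots = npleg.legroots(c)
    roots = np.real(roots[np.abs(np.imag(roots)) < 1e-12]) if np.iscomplexobj(roots) else roots
    interior = np.sort(roots[roots > -1 + 1e-10])
    x = np.concatenate(([-1.0], interior))
    pn1 = npleg.legval(x, np.eye(n)[n - 1])
    w = np.empty(n)
    w[0] = 2.0 / n ** 2
    w[1:] = (1.0 - x[1:]) / (n ** 2 * pn1[1:] ** 2)
    # mirror x -> -x for the right rule
    return np.sort(-x), w[np.argsort(-x)]


def make_quadrature(n_quad: int = DEFAULT_N_QUAD,
                    critical_mu: float | None = None) -> QuadratureScheme:
    """Quadrature on cosine in (0, 1] with an endpoint node at mu = 1.

    Without ``critical_mu``: a single right-Radau rule on (0, 1]. With it
    (cosine of the total-internal-reflection angle of the slab): the range is
    split there, Gauss-Legendre below and right-Radau above, so the Fresnel
    transmission step at the critical angle is resolved.
    """
    if n_quad < 4 or n_quad % 2:
        raise QuadratureError("n_quad must be even and >= 4")
    if critical_mu is None:
        x, w = _radau_right(n_quad)
        return QuadratureScheme((x + 1.0) / 2.0, w / 2.0)
    mc = float(critical_mu)
    if not 0.0 < mc < 1.0:
        raise QuadratureError("critical_mu must lie in (0, 1)")
    n_lo = n_quad // 2
    xg, wg = npleg.leggauss(n_lo)
    mu_lo = mc * (xg + 1.0) / 2.0
    w_lo = mc * wg / 2.0
    xr, wr = _radau_right(n_quad - n_lo)
    half = (1.0 - mc) / 2.0
    mu_hi = mc + half * (xr + 1.0)
    w_hi = half * wr
    return QuadratureScheme(np.concatenate([mu_lo, mu_hi]),
                            np.concatenate([w_lo, w_hi]))


# ---------------------------------------------------------------------------
# Henyey-Greenstein redistribution
# ---------------------------------------------------------------------------

def _hg_phase(cos_theta: np.ndarray, g: float) -> np.ndarray:
    """HG phase function normalised so (1/2) int p d(cos) = 1."""
    return (1.0 - g * g) / (1.0 + g * g - 2.0 * g * cos_theta) ** 1.5


def _azimuthal_average(phase_fn, quad: QuadratureScheme,
                       normalize: bool = True,
                       n_phi: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged redistribution matrices for a phase function."""
    mu, w = quad.mu, quad.w
    s = np.sqrt(np.maximum(0.0, 1.0 - mu ** 2))
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    cphi = np.cos(phi)
    mm = mu[:, None] * mu[None, :]
    ss = s[:, None] * s[None, :]
    # midpoint rule in phi (periodic integrand: spectrally accurate)
    h_plus = phase_fn(mm[..., None] + ss[..., None] * cphi).mean(axis=-1)
    h_minus = phase_fn(-mm[..., None] + ss[..., None] * cphi).mean(axis=-1)
    if normalize:
        d = np.ones(mu.size)
        for _ in range(200):
            # col[j] = (1/2) sum_i w_i d_i (h+ + h-)_ij d_j
            col = 0.5 * ((w * d) @ (h_plus + h_minus)) * d
            if np.max(np.abs(col - 1.0)) < 1e-14:
                break
            d = d / np.sqrt(col)
        h_plus = h_plus * d[:, None] * d[None, :]
        h_minus = h_minus * d[:, None] * d[None, :]
    return h_plus, h_minus


def hg_redistribution(g: float, quad: QuadratureScheme,
                      normalize: bool = True,
                      n_phi: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged HG redistribution matrices (h_plus, h_minus).

    ``h_plus[i, j]`` couples directions in the same hemisphere, ``h_minus``
    opposite hemispheres. With ``normalize`` the pair is Sinkhorn-balanced
    (symmetric diagonal scaling) so the discrete scattering operator conserves
    energy exactly: (1/2) sum_i w_i (h_plus + h_minus)[i, j] = 1 for every j.
    """
    if abs(g) >= 1:
        raise ValueError(f"|g| must be < 1, got {g}")
    return _azimuthal_average(lambda ct: _hg_phase(ct, g), quad,
                              normalize=normalize, n_phi=n_phi)


def delta_m_redistribution(g: float, quad: QuadratureScheme,
                           n_phi: int = 256) -> tuple[np.ndarray, np.ndarray, float]:
    """Delta-M-truncated HG redistribution: (h_plus, h_minus, peak fraction f).

    The forward delta peak carrying the fraction f = g**(2 n_quad) of the
    scattering is removed (treated as unscattered transmission, so the caller
    scales mu_s by 1 - f) and the remainder keeps the first 2 n_quad Legendre
    moments of the HG phase function exactly. This is the standard truncation
    that makes low-order quadratures accurate for forward-peaked scattering.
    """
    if abs(g) >= 1:
        raise ValueError(f"|g| must be < 1, got {g}")
    if g == 0.0:
        hp, hm = hg_redistribution(0.0, quad, n_phi=n_phi)
        return hp, hm, 0.0
    m = 2 * quad.n
    f = g ** m
    ell = np.arange(m)
    coeffs = (2 * ell + 1) * (g ** ell - f) / (1.0 - f)
    hp, hm = _azimuthal_average(lambda ct: npleg.legval(ct, coeffs), quad,
                                n_phi=n_phi)
    return hp, hm, f


# ---------------------------------------------------------------------------
# layer operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabLayer:
    """Single-wavelength homogeneous layer."""

    mu_a: float
    mu_s: float
    g: float
    n: float
    d: float

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be >= 0")
        if abs(self.g) >= 1:
            raise ValueError("|g| must be < 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.d <= 0:
            raise ValueError("thickness must be > 0")


@dataclass(frozen=True)
class LayerRT:
    """Reflection/transmission flux operators of a layer or stack.

    ``rt[..., i, j]``: upward flux in channel i per unit downward flux in
    channel j incident from above; ``rb``: reflection for light from below;
    ``td``/``tu``: downward/upward transmission. Leading axes are batch.
    """

    rt: np.ndarray
    rb: np.ndarray
    td: np.ndarray
    tu: np.ndarray

    @classmethod
    def symmetric(cls, r: np.ndarray, t: np.ndarray) -> "LayerRT":
        return cls(rt=r, rb=r, td=t, tu=t)

    @classmethod
    def diagonal(cls, r: np.ndarray) -> "LayerRT":
        """Specular interface: diagonal reflection r, transmission 1 - r."""
        rd = r[..., None] * np.eye(r.shape[-1])
        td = (1.0 - r)[..., None] * np.eye(r.shape[-1])
        return cls(rt=rd, rb=rd, td=td, tu=td)


def _generators(albedo, h_plus, h_minus, quad_mu, quad_w):
    """Flux-space transport generators (A, B): dLdown/dtau = -A Ldown + B Lup."""
    albedo = np.asarray(albedo, dtype=float)[..., None, None]
    n = quad_mu.shape[-1]
    eye = np.eye(n)
    w_row = quad_w[..., None, :]
    a_rad = (eye - 0.5 * albedo * h_plus * w_row) / quad_mu[..., :, None]
    b_rad = (0.5 * albedo * h_minus * w_row) / quad_mu[..., :, None]
    scale = 2.0 * quad_mu * quad_w
    a_flux = scale[..., :, None] * a_rad / scale[..., None, :]
    b_flux = scale[..., :, None] * b_rad / scale[..., None, :]
    return a_flux, b_flux


def _diamond_init(a_gen, b_gen, dtau):
    """Thin-layer R, T by the diamond (trapezoid) discretisation."""
    d = np.asarray(dtau, dtype=float)[..., None, None] / 2.0
    n = a_gen.shape[-1]
    eye = np.eye(n)
    da, db = d * a_gen, d * b_gen
    q_db = np.linalg.solve(eye + da, db)
    db_q_db = db @ q_db
    t = np.linalg.solve(eye + da - db_q_db, eye - da + db_q_db)
    r = q_db @ (eye + t)
    return r, t


def _double_once(r, t):
    n = r.shape[-1]
    rr = r @ r
    rhs = np.concatenate([t, r @ t], axis=-1)
    x = np.linalg.solve(np.eye(n) - rr, rhs)
    t2 = t @ x[..., :n]
    r2 = r + t @ x[..., n:]
    return r2, t2


def init_thin_layer(layer: SlabLayer, quad: QuadratureScheme,
                    tau0: float | None = None) -> LayerRT:
    """Starting-layer operators at optical thickness tau0 (diamond init)."""
    if tau0 is None:
        tau0 = float(np.min(quad.mu)) * TAU0_FACTOR
    mu_t = layer.mu_a + layer.mu_s
    albedo = layer.mu_s / mu_t if mu_t > 0 else 0.0
    hp, hm = hg_redistribution(layer.g, quad)
    a_gen, b_gen = _generators(np.array([albedo]), hp[None], hm[None],
                               quad.mu[None], quad.w[None])
    r, t = _diamond_init(a_gen, b_gen, np.array([tau0]))
    return LayerRT.symmetric(r[0], t[0])


def double(rt: LayerRT) -> LayerRT:
    """Operators of a layer twice as thick (homogeneous layers only)."""
    r2, t2 = _double_once(rt.rt, rt.td)
    return LayerRT.symmetric(r2, t2)


def add(top: LayerRT, bottom: LayerRT) -> LayerRT:
    """Adding equations for a stack: ``top`` above ``bottom``."""
    n = top.rt.shape[-1]
    eye = np.eye(n)
    # downward field at the interface: D = td_a + rb_a rt_b D
    down = np.linalg.solve(eye - top.rb @ bottom.rt, top.td)
    # upward field at the interface for incidence from below: U = tu_b + rt_b rb_a U
    up = np.linalg.solve(eye - bottom.rt @ top.rb, bottom.tu)
    return LayerRT(
        rt=top.rt + top.tu @ bottom.rt @ down,
        td=bottom.td @ down,
        rb=bottom.rb + bottom.td @ top.rb @ up,
        tu=top.tu @ up,
    )


def _fresnel_unpolarized(n_i, n_t, mu_i):
    """Unpolarised Fresnel flux reflectance; 1 beyond the critical angle."""
    mu_i = np.asarray(mu_i, dtype=float)
    sin_t2 = (n_i / n_t) ** 2 * (1.0 - mu_i ** 2)
    tir = sin_t2 >= 1.0
    mu_t = np.sqrt(np.maximum(0.0, 1.0 - sin_t2))
    rs = ((n_i * mu_i - n_t * mu_t) / (n_i * mu_i + n_t * mu_t)) ** 2
    rp = ((n_t * mu_i - n_i * mu_t) / (n_t * mu_i + n_i * mu_t)) ** 2
    return np.where(tir, 1.0, 0.5 * (rs + rp))


def add_boundaries(rt: LayerRT, quad_mu, n_above: float, n_slab_top: float,
                   n_slab_bottom: float, n_below: float) -> LayerRT:
    """Compose Fresnel interfaces above and below a slab stack.

    Channels remain the slab-internal direction cosines; an interface is a
    diagonal layer with Fresnel reflectance at the internal angle (equal from
    either side by reciprocity). Matched indices give identity interfaces.
    """
    r_top = _fresnel_unpolarized(n_slab_top, n_above, quad_mu)
    r_bot = _fresnel_unpolarized(n_slab_bottom, n_below, quad_mu)
    stack = add(rt, LayerRT.diagonal(np.broadcast_to(r_bot, rt.rt.shape[:-1])))
    return add(LayerRT.diagonal(np.broadcast_to(r_top, rt.rt.shape[:-1])), stack)


def _homogeneous_rt_batched(mu_a, mu_s, h_plus, h_minus, mu, w, d):
    """R, T of homogeneous layers, batched over the leading channel axis."""
    from ._kernels import rt_homogeneous_batch

    mu_t = np.asarray(mu_a + mu_s, dtype=float)
    tau = np.ascontiguousarray(mu_t * d)
    albedo = np.ascontiguousarray(
        np.where(mu_t > 0, mu_s / np.maximum(mu_t, 1e-300), 0.0))
    return rt_homogeneous_batch(
        albedo, tau,
        np.ascontiguousarray(h_plus), np.ascontiguousarray(h_minus),
        np.ascontiguousarray(mu), np.ascontiguousarray(w), TAU0_FACTOR)


def total_reflectance(epidermis: SlabLayer, dermis: SlabLayer,
                      quad: QuadratureScheme | None = None,
                      n_quad: int = DEFAULT_N_QUAD,
                      include_specular: bool = True) -> float:
    """Total reflectance of the two-layer slab in air, collimated normal beam."""
    n_slab = epidermis.n
    if quad is None:
        crit = np.sqrt(1.0 - 1.0 / n_slab ** 2) if n_slab > 1 else None
        quad = make_quadrature(n_quad, critical_mu=crit)
    rt_epi = _layer_rt(epidermis, quad)
    rt_der = _layer_rt(dermis, quad)
    stack = add(rt_epi, rt_der)
    full = add_boundaries(stack, quad.mu, 1.0, epidermis.n, dermis.n, 1.0)
    j = quad.beam_index
    refl = float(np.sum(full.rt[..., :, j]))
    if not include_specular:
        refl -= float(_fresnel_unpolarized(1.0, n_slab, 1.0))
    return refl


def _layer_rt(layer: SlabLayer, quad: QuadratureScheme) -> LayerRT:
    hp, hm, f = delta_m_redistribution(layer.g, quad)
    r, t = _homogeneous_rt_batched(
        np.array([layer.mu_a]), np.array([layer.mu_s * (1.0 - f)]), hp[None],
        hm[None], quad.mu[None], quad.w[None], np.array([layer.d]))
    return LayerRT.symmetric(r[0], t[0])


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """Diffuse reflectance on a wavelength grid."""

    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (len(self.grid),):
            raise ValueError("reflectance length must match the grid")
        if np.any(r < 0) or np.any(r > 1.05):
            raise ValueError("reflectance must lie in [0, 1.05]")
        object.__setattr__(self, "reflectance", r)

    def save_text(self, path):
        np.savetxt(path, np.column_stack([self.grid.wavelengths, self.reflectance]),
                   header="wavelength_nm reflectance")

    @classmethod
    def load_text(cls, path) -> "Spectrum":
        arr = np.loadtxt(path)
        return cls(WavelengthGrid(arr[:, 0]), arr[:, 1])


class ADSolver:
    """Vectorised forward solver for one wavelength grid.

    Precomputes, per wavelength: the split quadrature (at that wavelength's
    critical angle), the normalised HG redistribution matrices at g(lambda),
    the Fresnel boundary reflectances and the normal-incidence specular term.
    Spectra are then simulated in channel batches of (spectrum, wavelength).
    """

    def __init__(self, grid: WavelengthGrid | None = None,
                 lib: ChromophoreLibrary | None = None,
                 fixed: FixedParams = FixedParams(),
                 n_quad: int = DEFAULT_N_QUAD,
                 include_specular: bool = True):
        from .optics import synthetic_chromophore_library, anisotropy, refractive_index

        self.grid = grid or WavelengthGrid.default()
        self.lib = (lib or synthetic_chromophore_library(self.grid)).on_grid(self.grid)
        self.fixed = fixed
        self.n_quad = n_quad
        self.include_specular = include_specular
        self.g = anisotropy(self.grid)
        self.n = refractive_index(self.grid)
        nb = len(self.grid)
        self.mu = np.empty((nb, n_quad))
        self.w = np.empty((nb, n_quad))
        self.h_plus = np.empty((nb, n_quad, n_quad))
        self.h_minus = np.empty((nb, n_quad, n_quad))
        self.delta_f = np.empty(nb)
        for i in range(nb):
            q = make_quadrature(n_quad, critical_mu=np.sqrt(1.0 - 1.0 / self.n[i] ** 2))
            self.mu[i], self.w[i] = q.mu, q.w
            self.h_plus[i], self.h_minus[i], self.delta_f[i] = \
                delta_m_redistribution(self.g[i], q)
        self.beam = n_quad - 1  # mu = 1 is the last node of the upper panel
        self.r_top = _fresnel_unpolarized(self.n[:, None], 1.0, self.mu)
        self.r_bot = self.r_top  # same n both layers, air below
        self.r0 = _fresnel_unpolarized(1.0, self.n, 1.0)

    def reflectance_for_optical(self, mu_a_epi, mu_a_der, mu_s) -> np.ndarray:
        """Reflectance per wavelength for (n_spec, n_bands) optical properties."""
        mu_a_epi = np.atleast_2d(mu_a_epi)
        mu_a_der = np.atleast_2d(mu_a_der)
        mu_s = np.atleast_2d(mu_s) * (1.0 - self.delta_f)[None, :]
        n_spec, nb = mu_a_epi.shape
        hp = np.broadcast_to(self.h_plus, (n_spec,) + self.h_plus.shape).reshape(-1, self.n_quad, self.n_quad)
        hm = np.broadcast_to(self.h_minus, (n_spec,) + self.h_minus.shape).reshape(-1, self.n_quad, self.n_quad)
        mu = np.broadcast_to(self.mu, (n_spec,) + self.mu.shape).reshape(-1, self.n_quad)
        w = np.broadcast_to(self.w, (n_spec,) + self.w.shape).reshape(-1, self.n_quad)
        r_epi, t_epi = _homogeneous_rt_batched(
            mu_a_epi.ravel(), mu_s.ravel(), hp, hm, mu, w, self.fixed.d_epi)
        r_der, t_der = _homogeneous_rt_batched(
            mu_a_der.ravel(), mu_s.ravel(), hp, hm, mu, w, self.fixed.d_der)
        stack = add(LayerRT.symmetric(r_epi, t_epi), LayerRT.symmetric(r_der, t_der))
        r_bot = np.broadcast_to(self.r_bot, (n_spec,) + self.r_bot.shape).reshape(-1, self.n_quad)
        r_top = np.broadcast_to(self.r_top, (n_spec,) + self.r_top.shape).reshape(-1, self.n_quad)
        with_bot = add(stack, LayerRT.diagonal(r_bot))
        full = add(LayerRT.diagonal(r_top), with_bot)
        refl = np.sum(full.rt[:, :, self.beam], axis=-1).reshape(n_spec, nb)
        if not self.include_specular:
            refl = refl - self.r0[None, :]
        return refl

    def simulate(self, params: TissueParams) -> Spectrum:
        """Forward-simulate one spectrum (deterministic)."""
        return Spectrum(self.grid, self.simulate_matrix(params.as_array()[None])[0])

    def simulate_matrix(self, param_matrix: np.ndarray,
                        batch_size: int = 64) -> np.ndarray:
        """Forward-simulate rows of a (n, 7) physical-parameter matrix."""
        param_matrix = np.atleast_2d(np.asarray(param_matrix, dtype=float))
        from .optics import (melanin_baseline_absorption, dermis_absorption,
                             reduced_scattering)
        out = np.empty((param_matrix.shape[0], len(self.grid)))
        one_minus_g = 1.0 - self.g
        for start in range(0, param_matrix.shape[0], batch_size):
            rows = param_matrix[start:start + batch_size]
            mu_a_epi = np.stack([melanin_baseline_absorption(self.grid, p[0]) for p in rows])
            mu_a_der = np.stack([
                dermis_absorption(self.grid, TissueParams.from_array(p), self.lib)
                for p in rows])
            mu_s = np.stack([reduced_scattering(self.grid, p[6], self.fixed)
                             for p in rows]) / one_minus_g
            out[start:start + len(rows)] = self.reflectance_for_optical(
                mu_a_epi, mu_a_der, mu_s)
        return out


def simulate_spectrum(params: TissueParams,
                      fixed: FixedParams = FixedParams(),
                      grid: WavelengthGrid | None = None,
                      lib: ChromophoreLibrary | None = None,
                      n_quad: int = DEFAULT_N_QUAD) -> Spectrum:
    """One-shot forward simulation (builds a solver; prefer ADSolver in loops)."""
    if not params.in_range():
        raise ValueError("simulation inputs must lie within the sampling bounds")
    return ADSolver(grid, lib, fixed, n_quad).simulate(params)
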