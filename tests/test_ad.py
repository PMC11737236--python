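"""Adding-doubling solver: quadrature, redistribution, doubling/adding
algebra, boundary composition and forward-simulation behaviour."""

import numpy as np
import pytest

import skinspect as sk
from skinspect.ad import (LayerRT, QuadratureError, _fresnel_unpolarized,
                          delta_m_redistribution)


@pytest.fixture(scope="module")
def quad():
    return sk.make_quadrature(16)


class TestQuadrature:
    def test_weights_integrate_unity(self, quad):
        assert quad.w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nodes_increasing_in_unit_interval(self, quad):
        assert np.all(np.diff(quad.mu) > 0)
        assert quad.mu[0] > 0 and quad.mu[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("degree", [3, 11, 20, 29])
    def test_polynomial_exactness(self, quad, degree):
        # right-Radau with 16 nodes is exact through degree 2n-2 = 30;
        # the exact integral of x^d over [0,1] is 1/(d+1)
        approx = float(np.sum(quad.w * quad.mu ** degree))
        assert approx == pytest.approx(1.0 / (degree + 1), rel=1e-12)

    def test_split_rule_keeps_beam_node(self):
        q = sk.make_quadrature(16, critical_mu=0.66)
        assert q.mu[-1] == pytest.approx(1.0)
        assert np.sum(q.mu < 0.66) == 8
        assert q.w.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 7])
    def test_bad_order_rejected(self, n):
        with pytest.raises(QuadratureError):
            sk.make_quadrature(n)


class TestRedistribution:
    def test_isotropic_is_constant(self, quad):
        hp, hm = sk.hg_redistribution(0.0, quad)
        assert np.allclose(hp, hp[0, 0]) and np.allclose(hm, hp[0, 0])

    def test_symmetry(self, quad):
        hp, hm = sk.hg_redistribution(0.8, quad)
        assert np.allclose(hp, hp.T, atol=1e-12)
        assert np.allclose(hm, hm.T, atol=1e-12)

    def test_energy_normalisation(self, quad):
        hp, hm = sk.hg_redistribution(0.8, quad)
        col = 0.5 * (quad.w @ (hp + hm))
        assert np.allclose(col, 1.0, atol=1e-12)

    def test_first_moment_recovers_g(self, quad):
        hp, hm = sk.hg_redistribution(0.8, quad)
        first = 0.5 * (quad.w[:, None] * quad.mu[:, None]
                       * (hp - hm)).sum(axis=0) / quad.mu
        assert np.allclose(first, 0.8, atol=5e-3)

    def test_invalid_g_rejected(self, quad):
        with pytest.raises(ValueError):
            sk.hg_redistribution(1.0, quad)

    def test_delta_m_preserves_reduced_scattering(self, quad):
        # the removed forward peak f rescales mu_s so that the first-moment
        # product mu_s (1 - g) is preserved to truncation accuracy
        hp, hm, f = delta_m_redistribution(0.8, quad)
        g_eff = (0.5 * (quad.w[:, None] * quad.mu[:, None]
                        * (hp - hm)).sum(axis=0) / quad.mu)
        assert np.allclose((1 - f) * (1 - g_eff), 1 - 0.8, atol=2e-3)


class TestLayerOperators:
    def test_pure_absorber_is_diagonal_attenuation(self, quad):
        layer = sk.SlabLayer(mu_a=5.0, mu_s=0.0, g=0.0, n=1.4, d=0.1)
        rt = sk.init_thin_layer(layer, quad, tau0=0.5 / 2 ** 20)
        cur = rt
        for _ in range(20):
            cur = sk.double(cur)
        assert np.allclose(np.diag(cur.td), np.exp(-0.5 / quad.mu), atol=1e-9)
        assert np.allclose(cur.rt, 0.0)

    def test_vanishing_layer_is_identity(self, quad):
        layer = sk.SlabLayer(mu_a=1.0, mu_s=10.0, g=0.5, n=1.4, d=1.0)
        rt = sk.init_thin_layer(layer, quad, tau0=1e-12)
        assert np.allclose(rt.td, np.eye(16), atol=1e-9)
        assert np.allclose(rt.rt, 0.0, atol=1e-9)

    def test_single_scatter_reflection_linear_in_albedo(self, quad):
        tau0 = 1e-4
        r = {}
        for mu_s in (1.0, 2.0):
            layer = sk.SlabLayer(mu_a=10.0 - mu_s, mu_s=mu_s, g=0.0, n=1.4,
                                 d=tau0 / 10.0)
            r[mu_s] = sk.init_thin_layer(layer, quad, tau0=tau0).rt
        assert np.allclose(r[2.0], 2.0 * r[1.0], rtol=1e-3)

    def test_double_equals_add_of_identical_layers(self, quad):
        layer = sk.SlabLayer(mu_a=1.0, mu_s=30.0, g=0.7, n=1.4, d=0.05)
        base = sk.init_thin_layer(layer, quad, tau0=31.0 * 0.05 / 2 ** 16)
        for _ in range(16):
            base = sk.double(base)
        doubled = sk.double(base)
        added = sk.add(base, base)
        assert np.allclose(doubled.rt, added.rt, atol=1e-10)
        assert np.allclose(doubled.td, added.td, atol=1e-10)

    def test_add_with_empty_layer_is_identity_element(self, quad):
        layer = sk.SlabLayer(mu_a=1.0, mu_s=30.0, g=0.7, n=1.4, d=0.05)
        base = sk.init_thin_layer(layer, quad, tau0=1e-5)
        empty = LayerRT.symmetric(np.zeros((16, 16)), np.eye(16))
        out = sk.add(base, empty)
        assert np.allclose(out.rt, base.rt, atol=1e-14)
        assert np.allclose(out.td, base.td, atol=1e-14)

    def test_conservation_for_conservative_slab(self, quad):
        layer = sk.SlabLayer(mu_a=0.0, mu_s=10.0, g=0.8, n=1.4, d=1.0)
        k = 24
        cur = sk.init_thin_layer(layer, quad, tau0=10.0 / 2 ** k)
        for _ in range(k):
            cur = sk.double(cur)
        colsum = (cur.rt + cur.td).sum(axis=0)
        assert np.all(colsum <= 1.0 + 1e-6)
        assert np.all(colsum >= 1.0 - 1e-6)


class TestBoundaries:
    def test_matched_indices_are_transparent(self, quad):
        layer = sk.SlabLayer(mu_a=1.0, mu_s=30.0, g=0.7, n=1.0, d=0.1)
        base = sk.init_thin_layer(layer, quad, tau0=1e-5)
        out = sk.add_boundaries(base, quad.mu, 1.0, 1.0, 1.0, 1.0)
        assert np.allclose(out.rt, base.rt, atol=1e-12)

    def test_normal_incidence_specular_closed_form(self):
        r = _fresnel_unpolarized(1.0, 1.4, 1.0)
        assert r == pytest.approx(((1.0 - 1.4) / (1.0 + 1.4)) ** 2, rel=1e-12)

    def test_total_internal_reflection_blocks_transmission(self, quad):
        n_slab = 1.4
        r = _fresnel_unpolarized(n_slab, 1.0, quad.mu)
        crit = np.sqrt(1.0 - 1.0 / n_slab ** 2)
        assert np.all(r[quad.mu < crit] == 1.0)
        bound = LayerRT.diagonal(r)
        assert np.allclose(bound.tu[quad.mu < crit], 0.0)

    def test_conservation_survives_boundary_composition(self):
        # conservative slab with matched boundaries: every channel conserves
        q = sk.make_quadrature(16)
        layer = sk.SlabLayer(mu_a=0.0, mu_s=20.0, g=0.7, n=1.0, d=0.5)
        cur = sk.init_thin_layer(layer, q, tau0=10.0 / 2 ** 22)
        for _ in range(22):
            cur = sk.double(cur)
        out = sk.add_boundaries(cur, q.mu, 1.0, 1.0, 1.0, 1.0)
        colsum = (out.rt + out.td).sum(axis=0)
        assert np.all(np.abs(colsum - 1.0) <= 1e-6)


class TestTotalReflectance:
    def test_black_slab_reduces_to_specular(self):
        epi = sk.SlabLayer(mu_a=1e4, mu_s=1.0, g=0.5, n=1.4, d=0.01)
        der = sk.SlabLayer(mu_a=1e4, mu_s=1.0, g=0.5, n=1.4, d=1.0)
        r = sk.total_reflectance(epi, der)
        assert r == pytest.approx(((0.4 / 2.4) ** 2), abs=1e-4)

    def test_specular_exclusion_flag(self):
        epi = sk.SlabLayer(mu_a=20.0, mu_s=200.0, g=0.76, n=1.33, d=0.01)
        der = sk.SlabLayer(mu_a=5.0, mu_s=200.0, g=0.76, n=1.33, d=1.0)
        with_spec = sk.total_reflectance(epi, der)
        without = sk.total_reflectance(epi, der, include_specular=False)
        r0 = ((1.0 - 1.33) / (1.0 + 1.33)) ** 2
        assert with_spec - without == pytest.approx(r0, rel=1e-9)

    def test_monotone_in_absorption_and_scattering(self):
        # reflectance falls with either layer's absorption, rises with the
        # scattering amplitude (10-point grids per axis)
        base = dict(mu_s=200.0, g=0.76, n=1.33)
        r_der = [sk.total_reflectance(
            sk.SlabLayer(mu_a=10.0, d=0.01, **base),
            sk.SlabLayer(mu_a=mu, d=1.0, **base), n_quad=8)
            for mu in np.linspace(0.5, 50, 10)]
        assert np.all(np.diff(r_der) < 0)
        r_epi = [sk.total_reflectance(
            sk.SlabLayer(mu_a=mu, d=0.01, **base),
            sk.SlabLayer(mu_a=5.0, d=1.0, **base), n_quad=8)
            for mu in np.linspace(1, 100, 10)]
        assert np.all(np.diff(r_epi) < 0)
        r_scat = [sk.total_reflectance(
            sk.SlabLayer(mu_a=10.0, mu_s=ms, g=0.76, n=1.33, d=0.01),
            sk.SlabLayer(mu_a=5.0, mu_s=ms, g=0.76, n=1.33, d=1.0), n_quad=8)
            for ms in np.linspace(50, 500, 10)]
        assert np.all(np.diff(r_scat) > 0)

    def test_quadrature_convergence(self):
        # characterised convergence of this formulation: ~1e-3 from 8 to 16
        # and ~3e-4 from 16 to 32 on in-range tissue optics
        epi = sk.SlabLayer(mu_a=20.0, mu_s=300.0, g=0.78, n=1.33, d=0.01)
        der = sk.SlabLayer(mu_a=8.0, mu_s=300.0, g=0.78, n=1.33, d=1.0)
        r8 = sk.total_reflectance(epi, der, n_quad=8)
        r16 = sk.total_reflectance(epi, der, n_quad=16)
        r32 = sk.total_reflectance(epi, der, n_quad=32)
        assert abs(r8 - r16) < 2e-3
        assert abs(r16 - r32) < 3e-4


class TestSpectrumSimulation:
    def test_default_grid_gives_321_bands(self, solver8):
        spec = solver8.simulate(sk.TissueParams.midpoint())
        assert spec.reflectance.shape == (321,)
        assert np.all((spec.reflectance > 0) & (spec.reflectance < 1))

    def test_deterministic_across_calls(self, solver8):
        a = solver8.simulate(sk.TissueParams.midpoint()).reflectance
        b = solver8.simulate(sk.TissueParams.midpoint()).reflectance
        assert np.array_equal(a, b)

    def test_melanin_darkens_blue_end(self, solver8):
        lo = sk.TissueParams(0.005, 0.02, 0.02, 0.05, 1.0, 1.0, 40.0)
        hi = sk.TissueParams(0.045, 0.02, 0.02, 0.05, 1.0, 1.0, 40.0)
        r_lo = solver8.simulate(lo).reflectance
        r_hi = solver8.simulate(hi).reflectance
        blue = solver8.grid.wavelengths <= 500
        assert np.all(r_hi[blue] < r_lo[blue])

    def test_out_of_range_simulation_input_rejected(self):
        bad = sk.TissueParams(0.5, 0.02, 0.02, 0.05, 1.0, 1.0, 40.0)
        with pytest.raises(ValueError):
            sk.simulate_spectrum(bad)

    def test_spectrum_text_round_trip(self, solver8, tmp_path):
        spec = solver8.simulate(sk.TissueParams.midpoint())
        spec.save_text(tmp_path / "s.txt")
        back = sk.Spectrum.load_text(tmp_path / "s.txt")
        assert np.allclose(back.reflectance, spec.reflectance, atol=1e-12)
        assert np.array_equal(back.grid.wavelengths, spec.grid.wavelengths)
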