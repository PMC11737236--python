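"""Skin optical model: closed-form component formulas and the chromophore
library. High-precision reference values were computed independently with
40-digit arithmetic and frozen here."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skinspect as sk
from skinspect.optics import CoverageError, baseline_absorption

GRID = sk.WavelengthGrid.default()


def grid_of(*wl):
    return sk.WavelengthGrid(np.array(wl, dtype=float))


class TestEpidermisAbsorption:
    def test_zero_melanin_reduces_to_baseline(self):
        out = sk.melanin_baseline_absorption(GRID, 0.0)
        assert np.allclose(out, baseline_absorption(GRID))

    def test_exponent_zero_at_154nm(self):
        # at 154 nm the baseline exponential is exactly e^0
        out = sk.melanin_baseline_absorption(grid_of(154.0, 200.0), 0.0)
        assert out[0] == pytest.approx(0.244 + 85.3, abs=1e-12)

    def test_frozen_value_at_500nm(self):
        out = sk.melanin_baseline_absorption(grid_of(500.0, 501.0), 0.05)
        assert out[0] == pytest.approx(34.660351950196255, rel=1e-12)

    def test_negative_melanin_rejected(self):
        with pytest.raises(ValueError):
            sk.melanin_baseline_absorption(GRID, -0.01)

    @given(fm=st.floats(0.0, 0.2), scale=st.floats(0.1, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_melanin_fraction(self, fm, scale):
        base = sk.melanin_baseline_absorption(GRID, 0.0)
        one = sk.melanin_baseline_absorption(GRID, fm) - base
        other = sk.melanin_baseline_absorption(GRID, fm * scale) - base
        assert np.allclose(other, one * scale, rtol=1e-9, atol=1e-12)


@pytest.fixture(scope="module")
def lib():
    return sk.synthetic_chromophore_library(GRID, seed=0)


class TestDermisAbsorption:
    def test_zero_fractions_reduce_to_baseline(self, lib):
        p = sk.TissueParams(0.01, 0, 0, 0, 0, 0, 30.0)
        assert np.allclose(sk.dermis_absorption(GRID, p, lib),
                           baseline_absorption(GRID))

    def test_weighted_sum_matches_elementwise_oracle(self, lib):
        p = sk.TissueParams(0.01, 0.05, 0.02, 0.03, 0.7, 1.1, 30.0)
        out = sk.dermis_absorption(GRID, p, lib)
        expect = baseline_absorption(GRID).copy()
        for name, w in zip(("Hb", "HbO2", "brub", "CO", "COO2"),
                           (0.05, 0.02, 0.03, 0.7, 1.1)):
            expect = expect + w * lib.spectra[name]
        assert np.allclose(out, expect, rtol=1e-12)
        assert np.all(out >= baseline_absorption(GRID) - 1e-12)

    def test_doubling_fractions_doubles_excess(self, lib):
        p1 = sk.TissueParams(0.0, 0.02, 0.01, 0.05, 0.5, 0.25, 30.0)
        p2 = sk.TissueParams(0.0, 0.04, 0.02, 0.10, 1.0, 0.50, 30.0)
        base = baseline_absorption(GRID)
        e1 = sk.dermis_absorption(GRID, p1, lib) - base
        e2 = sk.dermis_absorption(GRID, p2, lib) - base
        assert np.allclose(e2, 2 * e1, rtol=1e-10)

    def test_uncovered_grid_rejected(self, lib):
        with pytest.raises(CoverageError):
            sk.dermis_absorption(grid_of(300.0, 500.0),
                                 sk.TissueParams.midpoint(), lib)


class TestScattering:
    def test_amplitude_recovered_at_500nm(self):
        out = sk.reduced_scattering(grid_of(499.0, 500.0), 37.5)
        assert out[1] == pytest.approx(37.5, rel=1e-9)

    def test_pure_mie_power_one_closed_form(self):
        fixed = sk.FixedParams(mie_b=1.0, f_ray=0.0)
        out = sk.reduced_scattering(GRID, 10.0, fixed)
        assert np.allclose(out, 10.0 * 500.0 / GRID.wavelengths, rtol=1e-12)

    def test_frozen_value_at_750nm(self):
        out = sk.reduced_scattering(grid_of(500.0, 750.0), 20.0)
        assert out[1] == pytest.approx(12.294771318674217, rel=1e-12)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sk.reduced_scattering(GRID, 0.0)


class TestRefractiveIndexAndAnisotropy:
    def test_frozen_value_at_430nm(self):
        assert sk.refractive_index(grid_of(430.0, 431.0))[0] == pytest.approx(
            1.3333734997752381, rel=1e-12)

    def test_long_wavelength_limit(self):
        assert sk.refractive_index(grid_of(1e7, 1e8))[1] == pytest.approx(
            1.309, abs=1e-9)

    def test_bounds_and_monotonicity_on_grid(self):
        n = sk.refractive_index(GRID)
        assert np.all((n > 1.0) & (n < 1.5))
        assert np.all(np.diff(n) < 0)

    def test_anisotropy_values_and_linearity(self):
        g = sk.anisotropy(GRID)
        assert g[GRID.wavelengths == 500.0][0] == pytest.approx(0.765)
        assert g[0] == pytest.approx(0.7447)
        assert g[-1] - g[0] == pytest.approx(29e-5 * 320, rel=1e-9)
        assert np.all(np.diff(g) > 0)


class TestAssembly:
    def test_matches_component_calls(self):
        lib = sk.synthetic_chromophore_library(GRID)
        p = sk.TissueParams.midpoint()
        fixed = sk.FixedParams()
        rec = sk.assemble_optical_properties(p, fixed, GRID, lib)
        assert np.array_equal(rec.mu_a_epi,
                              sk.melanin_baseline_absorption(GRID, p.fm))
        assert np.array_equal(rec.mu_a_der,
                              sk.dermis_absorption(GRID, p, lib))
        assert np.array_equal(rec.mu_s_reduced,
                              sk.reduced_scattering(GRID, p.a, fixed))
        assert np.array_equal(rec.g, sk.anisotropy(GRID))
        assert np.array_equal(rec.n, sk.refractive_index(GRID))
        assert np.all(rec.mu_a_epi >= 0) and np.all(rec.mu_s_reduced > 0)
        assert np.all((rec.g > 0) & (rec.g < 1)) and np.all(rec.n > 1)


class TestNormalization:
    def test_bounds_map_to_unit_corners(self):
        assert np.allclose(sk.normalize_params(sk.PARAM_MIN), 0.0)
        assert np.allclose(sk.normalize_params(sk.PARAM_MAX), 1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(sk.PARAM_MIN, sk.PARAM_MAX)
        back = sk.denormalize_params(sk.normalize_params(p))
        assert np.allclose(back, p, rtol=1e-12, atol=1e-12)

    def test_denormalize_clips_unless_disabled(self):
        v = np.full(7, 1.5)
        assert np.allclose(sk.denormalize_params(v), sk.PARAM_MAX)
        free = sk.denormalize_params(v, clip=False)
        assert np.all(free > sk.PARAM_MAX)


class TestSyntheticLibrary:
    def test_deterministic_for_seed(self):
        a = sk.synthetic_chromophore_library(GRID, seed=4)
        b = sk.synthetic_chromophore_library(GRID, seed=4)
        for name in a.spectra:
            assert np.array_equal(a.spectra[name], b.spectra[name])

    def test_strictly_positive(self):
        lib = sk.synthetic_chromophore_library(GRID, seed=0)
        for s in lib.spectra.values():
            assert np.all(s > 0)

    def test_hb_hbo2_cross_in_q_band_window(self):
        lib = sk.synthetic_chromophore_library(GRID, seed=0)
        wl = GRID.wavelengths
        window = (wl >= 500) & (wl <= 600)
        diff = (lib.spectra["Hb"] - lib.spectra["HbO2"])[window]
        assert np.sum(np.abs(np.diff(np.sign(diff))) > 0) >= 2


class TestChromophoreTables:
    def test_load_table_with_comments(self, tmp_path):
        f = tmp_path / "hb.txt"
        f.write_text("# wavelength mu_a\n400 10.0\n500, 20.0\n600 5.0\n")
        wl, mu = sk.load_chromophore_table(f)
        assert np.array_equal(wl, [400, 500, 600])
        assert np.array_equal(mu, [10, 20, 5])

    def test_non_monotone_rejected(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("500 1.0\n400 2.0\n")
        with pytest.raises(ValueError):
            sk.load_chromophore_table(f)

    def test_library_interpolation_and_coverage(self, tmp_path):
        for name in ("Hb", "HbO2", "brub", "CO", "COO2"):
            (tmp_path / f"{name}.txt").write_text("400 1.0\n800 5.0\n")
        paths = {n: tmp_path / f"{n}.txt"
                 for n in ("Hb", "HbO2", "brub", "CO", "COO2")}
        lib = sk.library_from_tables(paths, GRID)
        assert lib.provenance == "measured-table"
        # linear interpolation between the two table points
        expect = 1.0 + 4.0 * (GRID.wavelengths - 400.0) / 400.0
        assert np.allclose(lib.spectra["Hb"], expect)
        with pytest.raises(CoverageError):
            sk.library_from_tables(paths, sk.WavelengthGrid(
                np.array([300.0, 500.0])))
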