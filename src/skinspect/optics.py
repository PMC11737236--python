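"""Two-layer skin optical model.

Maps the seven free physiological parameters (melanin volume fraction,
deoxy-/oxyhemoglobin volume fractions, bilirubin and cytochrome-c-oxidase
concentrations, scattering amplitude) and the fixed structural constants
(Mie power, Rayleigh fraction, layer thicknesses) to per-wavelength optical
properties of an epidermis-over-dermis slab:

* epidermal absorption    mu_a_epi = fm * mu_a_melanin + mu_a_baseline
* dermal absorption       mu_a_der = sum_c f_c * mu_a_c + mu_a_baseline
* reduced scattering      mu_s' = a * [fRay (l/500)^-4 + (1-fRay)(l/500)^-b]
* refractive index        n(l)  = 1.309 - 4.346e2 l^-2 + 1.6065e9 l^-4 - 1.2811e14 l^-6
* anisotropy              g(l)  = 0.62 + 29e-5 l

Wavelengths are in nanometres throughout; absorption/scattering in 1/cm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: names of the seven free parameters, in canonical column order
PARAM_NAMES = ("fm", "fHb", "fHbO2", "fbrub", "fCO", "fCOO2", "a")

#: simulator bounds for the free parameters (volume fractions are unitless,
#: bilirubin/cytochrome concentrations in mM, `a` in 1/cm at 500 nm)
PARAM_MIN = np.array([0.001, 0.001, 0.001, 1e-7, 1e-7, 1e-7, 20.0])
PARAM_MAX = np.array([0.05, 0.05, 0.05, 0.1, 2.0, 2.0, 80.0])

CHROMOPHORES = ("Hb", "HbO2", "brub", "CO", "COO2")


class CoverageError(ValueError):
    """A chromophore table does not span the requested wavelength grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength grid in nm."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid must be a 1-D array with >= 2 wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """430..750 nm inclusive at 1 nm: 321 bands."""
        return cls(np.arange(430.0, 751.0, 1.0))


@dataclass(frozen=True)
class FixedParams:
    """Structural constants held fixed during inversion."""

    mie_b: float = 1.2        # Mie scattering power (dimensionless)
    f_ray: float = 1e-7       # fraction of Rayleigh scattering
    d_epi: float = 0.01       # epidermis thickness, cm
    d_der: float = 1.0        # dermis thickness, cm


@dataclass(frozen=True)
class TissueParams:
    """The seven free physiological parameters."""

    fm: float
    fHb: float
    fHbO2: float
    fbrub: float
    fCO: float
    fCOO2: float
    a: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, v) -> "TissueParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (7,):
            raise ValueError(f"expected 7 parameters, got shape {v.shape}")
        return cls(*v.tolist())

    def in_range(self) -> bool:
        v = self.as_array()
        return bool(np.all(v >= PARAM_MIN) and np.all(v <= PARAM_MAX))

    @classmethod
    def midpoint(cls) -> "TissueParams":
        return cls.from_array(0.5 * (PARAM_MIN + PARAM_MAX))


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Per-chromophore absorption spectra on a wavelength grid.

    ``spectra[name]`` is mu_a in 1/cm per unit of the parameter that scales it
    (per unit volume fraction for Hb/HbO2, per mM for bilirubin and the
    cytochrome-c-oxidase forms), tabulated on ``grid``.
    """

    grid: WavelengthGrid
    spectra: dict
    provenance: str = "synthetic-fixture"   # or "measured-table"

    def __post_init__(self):
        for name in CHROMOPHORES:
            if name not in self.spectra:
                raise ValueError(f"library is missing chromophore {name!r}")
            s = np.asarray(self.spectra[name], dtype=float)
            if s.shape != (len(self.grid),):
                raise ValueError(f"{name}: spectrum length != grid length")
            if np.any(s < 0):
                raise ValueError(f"{name}: absorption must be >= 0")
            self.spectra[name] = s

    def on_grid(self, grid: WavelengthGrid) -> "ChromophoreLibrary":
        """Linearly interpolate onto ``grid``; extrapolation is forbidden."""
        src = self.grid.wavelengths
        dst = grid.wavelengths
        if dst[0] < src[0] or dst[-1] > src[-1]:
            raise CoverageError(
                f"library covers {src[0]:.1f}-{src[-1]:.1f} nm, "
                f"requested {dst[0]:.1f}-{dst[-1]:.1f} nm"
            )
        out = {k: np.interp(dst, src, v) for k, v in self.spectra.items()}
        return ChromophoreLibrary(grid, out, self.provenance)


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength optical properties of the two-layer slab."""

    grid: WavelengthGrid
    mu_a_epi: np.ndarray    # 1/cm
    mu_a_der: np.ndarray    # 1/cm
    mu_s_reduced: np.ndarray  # 1/cm, shared by both layers
    g: np.ndarray           # anisotropy, dimensionless
    n: np.ndarray           # refractive index, shared by both layers


# ---------------------------------------------------------------------------
# component formulas
# ---------------------------------------------------------------------------

def baseline_absorption(grid: WavelengthGrid) -> np.ndarray:
    """Baseline absorption of bloodless skin, 1/cm."""
    lam = grid.wavelengths
    return 0.244 + 85.3 * np.exp(-(lam - 154.0) / 66.2)


def melanin_baseline_absorption(grid: WavelengthGrid, fm: float) -> np.ndarray:
    """Epidermal absorption fm * mu_a_melanin + mu_a_baseline, 1/cm."""
    if fm < 0:
        raise ValueError(f"melanin fraction must be >= 0, got {fm}")
    lam = grid.wavelengths
    mu_a_m = 6.6e11 * lam ** (-3.33)
    return fm * mu_a_m + baseline_absorption(grid)


def dermis_absorption(grid: WavelengthGrid, params: TissueParams,
                      lib: ChromophoreLibrary) -> np.ndarray:
    """Dermal absorption: weighted chromophore sum plus baseline, 1/cm."""
    weights = {
        "Hb": params.fHb, "HbO2": params.fHbO2, "brub": params.fbrub,
        "CO": params.fCO, "COO2": params.fCOO2,
    }
    for k, w in weights.items():
        if w < 0:
            raise ValueError(f"{k} weight must be >= 0, got {w}")
    lib = lib.on_grid(grid)
    out = baseline_absorption(grid).copy()
    for k, w in weights.items():
        out += w * lib.spectra[k]
    return out


def reduced_scattering(grid: WavelengthGrid, a: float,
                       fixed: FixedParams = FixedParams()) -> np.ndarray:
    """Reduced scattering coefficient mu_s', 1/cm; a is mu_s'(500 nm)."""
    if a <= 0:
        raise ValueError(f"scattering amplitude must be > 0, got {a}")
    x = grid.wavelengths / 500.0
    return a * (fixed.f_ray * x ** (-4.0) + (1.0 - fixed.f_ray) * x ** (-fixed.mie_b))


def refractive_index(grid: WavelengthGrid) -> np.ndarray:
    """Tissue refractive index (Cauchy-type dispersion in nm)."""
    lam = grid.wavelengths
    return (1.309 - 4.346e2 * lam ** -2.0 + 1.6065e9 * lam ** -4.0
            - 1.2811e14 * lam ** -6.0)


def anisotropy(grid: WavelengthGrid) -> np.ndarray:
    """Scattering anisotropy factor g, linear in wavelength."""
    return 0.62 + 29e-5 * grid.wavelengths


def assemble_optical_properties(params: TissueParams,
                                fixed: FixedParams,
                                grid: WavelengthGrid,
                                lib: ChromophoreLibrary) -> OpticalProperties:
    """Compose the component formulas into one per-wavelength record."""
    return OpticalProperties(
        grid=grid,
        mu_a_epi=melanin_baseline_absorption(grid, params.fm),
        mu_a_der=dermis_absorption(grid, params, lib),
        mu_s_reduced=reduced_scattering(grid, params.a, fixed),
        g=anisotropy(grid),
        n=refractive_index(grid),
    )


# ---------------------------------------------------------------------------
# parameter normalization
# ---------------------------------------------------------------------------

def normalize_params(values) -> np.ndarray:
    """Min-max scale physical parameters to [0,1] (rows or a single vector)."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    out = (v - PARAM_MIN) / (PARAM_MAX - PARAM_MIN)
    return out.reshape(np.shape(values))


def denormalize_params(values, clip: bool = True) -> np.ndarray:
    """Inverse of :func:`normalize_params`.

    With ``clip`` (the default, for simulation inputs) values outside [0,1]
    are clipped and logged; with ``clip=False`` (model predictions) the linear
    map is applied as-is, so out-of-range predictions keep their physical
    magnitude.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if clip and (np.any(v < 0) or np.any(v > 1)):
        log.warning("denormalize_params: clipping %d values outside [0,1]",
                    int(np.sum((v < 0) | (v > 1))))
        v = np.clip(v, 0.0, 1.0)
    out = PARAM_MIN + v * (PARAM_MAX - PARAM_MIN)
    return out.reshape(np.shape(values))


# ---------------------------------------------------------------------------
# chromophore tables
# ---------------------------------------------------------------------------

def load_chromophore_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 2-column delimited text table (wavelength_nm, mu_a).

    ``#`` starts a comment; whitespace or comma delimited. Wavelengths must be
    strictly increasing and absorption non-negative.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"expected 2 columns, got {len(parts)}: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"empty chromophore table: {path}")
    arr = np.array(rows)
    wl, mu = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(wl) > 0):
        raise ValueError("table wavelengths must be strictly increasing")
    if np.any(mu < 0):
        raise ValueError("table absorption must be >= 0")
    return wl, mu


def library_from_tables(paths: dict, grid: WavelengthGrid) -> ChromophoreLibrary:
    """Build a measured-table library from per-chromophore text files."""
    spectra = {}
    for name in CHROMOPHORES:
        wl, mu = load_chromophore_table(paths[name])
        if grid.wavelengths[0] < wl[0] or grid.wavelengths[-1] > wl[-1]:
            raise CoverageError(
                f"{name}: table covers {wl[0]:.1f}-{wl[-1]:.1f} nm, "
                f"grid needs {grid.wavelengths[0]:.1f}-{grid.wavelengths[-1]:.1f} nm")
        spectra[name] = np.interp(grid.wavelengths, wl, mu)
    return ChromophoreLibrary(grid, spectra, provenance="measured-table")


# ---------------------------------------------------------------------------
# synthetic chromophore fixture
# ---------------------------------------------------------------------------

def _gauss(lam, center, width, amp):
    return amp * np.exp(-0.5 * ((lam - center) / width) ** 2)

#: canonical band structure (center nm, width nm, amplitude 1/cm per unit):
#: hemoglobin amplitudes are per unit volume fraction of whole blood, the
#: others per mM. Shapes mimic the gross structure of the measured spectra:
#: Soret-type peaks near 420-450 nm, a single Q band for Hb near 556 nm and a
#: Q doublet (542/577 nm) for HbO2, a blue bilirubin band, and weak red
#: cytochrome bands.
_BANDS = {
    "Hb":   [(433.0, 16.0, 2200.0), (556.0, 22.0, 300.0), (760.0, 40.0, 30.0)],
    "HbO2": [(418.0, 14.0, 2600.0), (542.0, 11.0, 320.0), (577.0, 10.0, 330.0),
             (640.0, 120.0, 6.0)],
    "brub": [(460.0, 32.0, 12.0)],
    "CO":   [(445.0, 18.0, 28.0), (605.0, 16.0, 5.0)],
    "COO2": [(428.0, 28.0, 20.0), (650.0, 90.0, 2.0)],
}
_FLOOR = {"Hb": 1.0, "HbO2": 0.5, "brub": 0.02, "CO": 0.05, "COO2": 0.05}


def synthetic_chromophore_library(grid: WavelengthGrid | None = None,
                                  seed: int = 0) -> ChromophoreLibrary:
    """Deterministic synthetic chromophore library (fixture).

    A stand-in for the measured extinction tables, built from sums of Gaussian
    bands whose centres/widths/amplitudes are jittered deterministically by
    ``seed`` (seed 0 gives the canonical shapes). The Hb and HbO2 spectra
    cross at least twice between 500 and 600 nm so oxygen saturation remains
    identifiable.
    """
    if grid is None:
        grid = WavelengthGrid.default()
    rng = np.random.default_rng(seed)
    lam = grid.wavelengths
    spectra = {}
    for name, bands in _BANDS.items():
        s = np.full(lam.shape, _FLOOR[name])
        for center, width, amp in bands:
            if seed != 0:
                center = center * (1.0 + 0.01 * rng.standard_normal())
                width = width * (1.0 + 0.05 * rng.standard_normal())
                amp = amp * (1.0 + 0.05 * rng.standard_normal())
            s = s + _gauss(lam, center, abs(width), abs(amp))
        spectra[name] = s
    return ChromophoreLibrary(grid, spectra, provenance="synthetic-fixture")
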