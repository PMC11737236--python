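"""Simulated spectra corpora: uniform sampling, halving, folds, augmentation.

The training conditions are uniform i.i.d. draws of the seven tissue
parameters inside the simulator bounds, forward-simulated with the
adding-doubling solver on the default 321-band grid. One half of a dataset
feeds Bayesian inference, the other half trains the forward emulator.
Robustness evaluation perturbs spectra with "use errors": a random
multiplicative tilt of up to 5% at the tails, a random wavelength shift of up
to +-10 nm, and band-limited Gaussian noise (sigma 0.002 below 631 nm, 0.008
above), mimicking miscalibration and detector noise of a real instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold

from .ad import ADSolver
from .optics import PARAM_MIN, PARAM_MAX, WavelengthGrid, normalize_params

#: augmentation noise: sigma below/above the 630/631 nm boundary
NOISE_SIGMA_BLUE = 0.002
NOISE_SIGMA_RED = 0.008
NOISE_SPLIT_NM = 630.0
TAIL_ROTATION = 0.05
MAX_SHIFT_BANDS = 10


@dataclass(frozen=True)
class SpectraDataset:
    """Parameter matrix (physical and normalized) with simulated spectra."""

    params: np.ndarray        # (n, 7) physical units
    params_norm: np.ndarray   # (n, 7) in [0, 1]
    spectra: np.ndarray       # (n, n_bands)
    grid: WavelengthGrid
    seed: int
    provenance: str = "clean"  # or "augmented"

    def __post_init__(self):
        if not (self.params.shape[0] == self.params_norm.shape[0]
                == self.spectra.shape[0]):
            raise ValueError("row counts disagree")
        if self.spectra.shape[1] != len(self.grid):
            raise ValueError("spectra width must match the grid")

    def __len__(self) -> int:
        return self.params.shape[0]

    def save(self, path):
        """Write the dataset as a binary container plus a JSON manifest."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), params=self.params,
                            spectra=self.spectra,
                            wavelengths=self.grid.wavelengths)
        manifest = {"n": len(self), "seed": self.seed,
                    "provenance": self.provenance,
                    "grid": [float(self.grid.wavelengths[0]),
                             float(self.grid.wavelengths[-1]),
                             len(self.grid)]}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "SpectraDataset":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            params, spectra = z["params"], z["spectra"]
            grid = WavelengthGrid(z["wavelengths"])
        manifest = json.loads(path.with_suffix(".json").read_text())
        return cls(params, normalize_params(params), spectra, grid,
                   int(manifest["seed"]), manifest["provenance"])


def sample_uniform(n: int, seed: int) -> np.ndarray:
    """(n, 7) i.i.d. uniform draws inside the simulator bounds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(PARAM_MIN, PARAM_MAX, size=(n, 7))


def build_dataset(n: int, seed: int, solver: ADSolver | None = None,
                  n_quad: int | None = None) -> SpectraDataset:
    """Sample parameters uniformly and forward-simulate their spectra."""
    if solver is None:
        solver = ADSolver(**({"n_quad": n_quad} if n_quad else {}))
    params = sample_uniform(n, seed)
    spectra = solver.simulate_matrix(params)
    return SpectraDataset(params, normalize_params(params), spectra,
                          solver.grid, seed)


def split_halves(ds: SpectraDataset) -> tuple[SpectraDataset, SpectraDataset]:
    """Disjoint equal halves: one for Bayesian inference, one for the F-NN."""
    n = len(ds)
    if n % 2:
        raise ValueError("dataset size must be even to split into halves")
    h = n // 2

    def _sub(sl):
        return SpectraDataset(ds.params[sl], ds.params_norm[sl],
                              ds.spectra[sl], ds.grid, ds.seed, ds.provenance)

    return _sub(slice(0, h)), _sub(slice(h, n))


def augment_spectrum(spectrum: np.ndarray, seed=None,
                     grid: WavelengthGrid | None = None,
                     rng: np.random.Generator | None = None,
                     **overrides) -> np.ndarray:
    """Apply use-error perturbations to one spectrum (default grid only).

    In order: (1) tail rotation -- multiply by a linear ramp between
    1 + dL and 1 + dR with dL, dR ~ U(-0.05, 0.05); (2) wavelength shift by an
    integer number of bands k ~ U{-10..10} with edge replication; (3) Gaussian
    noise, sigma 0.002 on 430-630 nm and 0.008 on 631-750 nm; clip at >= 0.

    ``tilt=(dL, dR)``, ``shift=k`` and ``noise=False`` pin individual
    components (for diagnostics and tests).
    """
    grid = grid or WavelengthGrid.default()
    return augment_spectra(np.asarray(spectrum)[None, :], seed=seed, grid=grid,
                           rng=rng, **overrides)[0]


def augment_spectra(spectra: np.ndarray, seed=None,
                    grid: WavelengthGrid | None = None,
                    rng: np.random.Generator | None = None,
                    tilt=None, shift=None, noise: bool = True) -> np.ndarray:
    """Vectorised :func:`augment_spectrum` over rows."""
    grid = grid or WavelengthGrid.default()
    default = WavelengthGrid.default()
    if len(grid) != len(default) or not np.allclose(
            grid.wavelengths, default.wavelengths):
        raise ValueError("augmentation supports only the default 430-750@1nm grid")
    if rng is None:
        rng = np.random.default_rng(seed)
    spectra = np.asarray(spectra, dtype=float)
    n, nb = spectra.shape
    # (1) multiplicative tilt
    if tilt is None:
        delta = rng.uniform(-TAIL_ROTATION, TAIL_ROTATION, size=(n, 2))
    else:
        delta = np.broadcast_to(np.asarray(tilt, dtype=float), (n, 2)).copy()
    ramp = np.linspace(0.0, 1.0, nb)
    factor = (1.0 + delta[:, :1]) * (1.0 - ramp) + (1.0 + delta[:, 1:]) * ramp
    out = spectra * factor
    # (2) integer band shift with edge replication; k > 0 moves features redward
    if shift is None:
        shifts = rng.integers(-MAX_SHIFT_BANDS, MAX_SHIFT_BANDS + 1, size=n)
    else:
        shifts = np.broadcast_to(np.asarray(shift, dtype=int), (n,))
    idx = np.arange(nb)
    src = np.clip(idx[None, :] - shifts[:, None], 0, nb - 1)
    out = np.take_along_axis(out, src, axis=1)
    # (3) band-limited noise
    if noise:
        sigma = np.where(grid.wavelengths <= NOISE_SPLIT_NM,
                         NOISE_SIGMA_BLUE, NOISE_SIGMA_RED)
        out = out + rng.standard_normal(out.shape) * sigma
    return np.clip(out, 0.0, None)


def augment_dataset(ds: SpectraDataset, seed: int) -> SpectraDataset:
    return SpectraDataset(ds.params, ds.params_norm,
                          augment_spectra(ds.spectra, seed=seed, grid=ds.grid),
                          ds.grid, ds.seed, provenance="augmented")


def kfold_indices(n: int, k: int = 10, seed: int = 0):
    """Shuffled k-fold partition; yields (train_idx, test_idx) pairs."""
    if k > n:
        raise ValueError("k must be <= n")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))
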