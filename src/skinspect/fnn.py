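"""Forward emulator (F-NN) and best-candidate selection.

A small network approximating the adding-doubling forward map: normalized
tissue parameters in, a 321-band reflectance spectrum out (one 256-unit ReLU
hidden layer, dropout 0.2 before the output, and a single trainable
smoothing filter of length 15 over the output spectrum). It ranks the
posterior-predictive candidates of the Bayesian network by the mean absolute
error between their emulated spectra and the measured spectrum; spectra whose
best error exceeds a threshold are flagged for the slower reference fitter.
"""

from __future__ import annotations

import numpy as np

from .bnn import CandidateSet
from .data import SpectraDataset
from .nnet import Dense, Dropout, Network, ReLU, SmoothConv, TrainConfig

POOR_FIT_THRESHOLD = 0.03


def build_fnn(n_bands: int = 321, cfg: TrainConfig = TrainConfig(),
              hidden: int = 256, dropout: float = 0.2,
              smooth_kernel: int = 15, smoothing: bool = True) -> Network:
    rng = np.random.default_rng(cfg.seed)
    layers = [Dense(7, hidden, rng), ReLU(), Dropout(dropout, rng),
              Dense(hidden, n_bands, rng, w_scale=0.01)]
    if smoothing:
        layers.append(SmoothConv(n_bands, smooth_kernel, rng))
    return Network(layers, cfg)


def fit_fnn(ds: SpectraDataset, cfg: TrainConfig = TrainConfig(),
            smoothing: bool = True) -> Network:
    """Train the emulator on (normalized parameters -> spectra) pairs."""
    if np.any(ds.params_norm < 0) or np.any(ds.params_norm > 1):
        raise ValueError("training parameters must be normalized to [0, 1]")
    net = build_fnn(ds.spectra.shape[1], cfg, smoothing=smoothing)
    net.init_output_bias(ds.spectra)
    return net.fit(ds.params_norm, ds.spectra)


def predict_spectra(model: Network, params_norm: np.ndarray) -> np.ndarray:
    """Emulated spectra for rows of normalized parameters."""
    return model.predict(np.atleast_2d(np.asarray(params_norm, dtype=np.float32)))


def select_best(model: Network, candidates: CandidateSet,
                measured: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Pick the candidate whose emulated spectrum best fits ``measured``.

    Returns (best normalized 7-vector, its MAE, the per-candidate MAE
    vector). Ties resolve to the lowest draw index (argmin).
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    spectra = predict_spectra(model, candidates.draws)
    maes = np.mean(np.abs(spectra - np.asarray(measured)[None, :]), axis=1)
    best = int(np.argmin(maes))
    return candidates.draws[best], float(maes[best]), maes


def select_best_batch(model: Network, draws: np.ndarray,
                      measured: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised selection: draws (n, n_draws, 7) against measured (n, B).

    Returns (selected parameters (n, 7), best MAE per spectrum (n,)).
    """
    n, n_draws, _ = draws.shape
    spectra = predict_spectra(model, draws.reshape(n * n_draws, 7))
    spectra = spectra.reshape(n, n_draws, -1)
    maes = np.mean(np.abs(spectra - measured[:, None, :]), axis=2)
    best = np.argmin(maes, axis=1)
    return draws[np.arange(n), best], maes[np.arange(n), best]


def flag_poor_fit(best_mae: float,
                  threshold: float = POOR_FIT_THRESHOLD) -> bool:
    """True iff the best forward-fit error exceeds the threshold (strictly)."""
    return bool(best_mae > threshold)
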