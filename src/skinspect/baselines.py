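"""Deterministic comparison regressors: ridge, ANN, 1-D CNN.

All models map either raw 321-band spectra or 1000-dimensional RFF features
to the 7 normalized tissue parameters through one uniform interface
(``fit`` / ``predict`` on row matrices); the RFF variants are compositions
with :mod:`skinspect.rff`, not separate code paths. Networks share the
common training protocol of :class:`skinspect.nnet.TrainConfig`.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import Ridge

from .nnet import (Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, ReLU,
                   TrainConfig)

OUT_DIM = 7


class RidgeModel:
    """Closed-form multi-output ridge with an unpenalised intercept.

    Features are used uncentered; scikit-learn's analytic solver yields the
    normal-equations solution with the intercept excluded from the penalty.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._model = Ridge(alpha=alpha)

    def fit(self, x, y):
        self._model.fit(np.asarray(x), np.asarray(y))
        return self

    def predict(self, x) -> np.ndarray:
        return self._model.predict(np.asarray(x))

    @property
    def coef_(self):
        return self._model.coef_

    @property
    def intercept_(self):
        return self._model.intercept_

    def save(self, path):
        np.savez_compressed(path, coef=self._model.coef_,
                            intercept=self._model.intercept_,
                            alpha=self.alpha)

    @classmethod
    def load(cls, path) -> "RidgeModel":
        with np.load(path) as z:
            model = cls(float(z["alpha"]))
            model._model.coef_ = z["coef"]
            model._model.intercept_ = z["intercept"]
            model._model.n_features_in_ = z["coef"].shape[1]
        return model


def fit_ridge(x, y, alpha: float = 1.0) -> RidgeModel:
    if np.asarray(x).shape[0] != np.asarray(y).shape[0]:
        raise ValueError("X and Y row counts disagree")
    return RidgeModel(alpha).fit(x, y)


def predict_ridge(model: RidgeModel, x) -> np.ndarray:
    return model.predict(x)


def build_ann(input_dim: int, cfg: TrainConfig, hidden: int = 512,
              dropout: float = 0.2) -> Network:
    rng = np.random.default_rng(cfg.seed)
    return Network([
        Dense(input_dim, hidden, rng), ReLU(), Dropout(dropout, rng),
        Dense(hidden, OUT_DIM, rng),
    ], cfg)


def fit_ann(x, y, cfg: TrainConfig = TrainConfig()) -> Network:
    """Single-hidden-layer perceptron (512 ReLU units, dropout 0.2)."""
    x = np.asarray(x)
    net = build_ann(x.shape[1], cfg)
    net.init_output_bias(y)
    return net.fit(x, y)


def build_cnn(n_bands: int, cfg: TrainConfig, n_filters: int = 64,
              kernel: int = 3, n_conv: int = 3, fc: int = 512) -> Network:
    rng = np.random.default_rng(cfg.seed)
    layers: list = []
    c_in = 1
    length = n_bands
    for _ in range(n_conv):
        layers += [Conv1D(c_in, n_filters, kernel, rng), ReLU(), MaxPool1D(2)]
        c_in = n_filters
        length //= 2
    layers += [Flatten(), Dense(length * n_filters, fc, rng), ReLU(),
               Dense(fc, OUT_DIM, rng)]
    return Network(layers, cfg)


class _CNNWrapper:
    """Adds the (batch, bands) -> (batch, bands, 1) reshape around a Network."""

    def __init__(self, net: Network):
        self.net = net
        self.history = None

    def fit(self, x, y):
        x = np.asarray(x, dtype=np.float32)[..., None]
        self.net.init_output_bias(y)
        self.net.fit(x, y)
        self.history = self.net.history
        return self

    def predict(self, x) -> np.ndarray:
        return self.net.predict(np.asarray(x, dtype=np.float32)[..., None])


def fit_cnn(x, y, cfg: TrainConfig = TrainConfig()) -> _CNNWrapper:
    """Three 64-filter size-3 conv layers with pool-2, then 512-wide head."""
    x = np.asarray(x)
    return _CNNWrapper(build_cnn(x.shape[1], cfg)).fit(x, y)
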