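"""Shared fixtures: one small simulated corpus and models trained on it.

The expensive artefacts (dataset, emulator, variational posterior) are
session-scoped and shared across test modules; sizes are chosen so the whole
suite runs on one CPU in well under the configured timeout while leaving the
scientific thresholds unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest

import skinspect as sk
from skinspect.nnet import TrainConfig

FIXTURE_N = 1200
FIXTURE_SEED = 101
FIXTURE_N_QUAD = 8


@pytest.fixture(scope="session")
def solver8():
    return sk.ADSolver(n_quad=FIXTURE_N_QUAD)


@pytest.fixture(scope="session")
def dataset(solver8):
    """1200 uniformly sampled spectra on the default grid."""
    return sk.build_dataset(FIXTURE_N, FIXTURE_SEED, solver=solver8)


@pytest.fixture(scope="session")
def halves(dataset):
    return sk.split_halves(dataset)


@pytest.fixture(scope="session")
def fnn_model(halves):
    _, fnn_half = halves
    return sk.fit_fnn(fnn_half, TrainConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline(halves, fnn_model):
    """RFF+BNN trained on 500 spectra of the inference half (100 held out)."""
    bnn_half, _ = halves
    return sk.train_pipeline(bnn_half.spectra[:500],
                             bnn_half.params_norm[:500],
                             fnn_model, seed=13)


@pytest.fixture(scope="session")
def heldout(halves):
    """The 100 inference-half spectra the session pipeline never saw."""
    bnn_half, _ = halves
    return bnn_half.spectra[500:], bnn_half.params_norm[500:]
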