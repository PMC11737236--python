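"""Photon Monte-Carlo oracle for the two-layer slab (validation only).

An independent, unbiased estimate of the total reflectance computed by the
adding-doubling solver: photons enter at normal incidence, scatter with the
Henyey-Greenstein phase function, reflect/refract at Fresnel boundaries and
terminate by Russian roulette. Used to validate the deterministic solver,
never as part of the inference pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import mc_reflectance
from .ad import SlabLayer


@dataclass(frozen=True)
class MCEstimate:
    reflectance: float
    std_error: float
    n_photons: int
    seed: int


def mc_oracle(epidermis: SlabLayer, dermis: SlabLayer,
              n_photons: int = 10 ** 6, seed: int = 0) -> MCEstimate:
    """Photon-transport estimate of total reflectance with standard error."""
    if n_photons < 10 ** 4:
        raise ValueError("use at least 1e4 photons")
    if epidermis.n != dermis.n:
        raise ValueError("layers must share a refractive index "
                         "(matched internal interface)")
    refl, var = mc_reflectance(
        epidermis.mu_a, epidermis.mu_s, epidermis.g,
        dermis.mu_a, dermis.mu_s, dermis.g,
        epidermis.n, epidermis.d, dermis.d, n_photons, seed)
    return MCEstimate(float(refl), float(np.sqrt(var / n_photons)),
                      n_photons, seed)
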