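"""Random Fourier features approximating the unit-bandwidth Gaussian kernel.

phi(x) = sqrt(2/D) * cos(Omega x + b) with Omega ~ N(0, I) row-wise and
b ~ U(0, 2pi), so that E[phi(x)^T phi(y)] = exp(-||x - y||^2 / 2). Spectra
are fed in raw reflectance units; a lengthscale and standardisation hook are
exposed but default to the plain scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_D = 1000


@dataclass(frozen=True)
class RFFMap:
    omega: np.ndarray   # (D, input_dim)
    phase: np.ndarray   # (D,), in [0, 2pi)
    seed: int
    lengthscale: float = 1.0

    @property
    def dim(self) -> int:
        return self.omega.shape[0]

    @property
    def input_dim(self) -> int:
        return self.omega.shape[1]

    def save(self, path):
        np.savez_compressed(path, omega=self.omega, phase=self.phase,
                            seed=self.seed, lengthscale=self.lengthscale)

    @classmethod
    def load(cls, path) -> "RFFMap":
        with np.load(path) as z:
            return cls(z["omega"], z["phase"], int(z["seed"]),
                       float(z["lengthscale"]))


def sample_map(input_dim: int, dim: int = DEFAULT_D, seed: int = 0,
               lengthscale: float = 1.0) -> RFFMap:
    """Draw a feature map: omega i.i.d. N(0,1), phases i.i.d. U[0, 2pi)."""
    if dim < 1:
        raise ValueError("feature dimension must be >= 1")
    rng = np.random.default_rng(seed)
    omega = rng.standard_normal((dim, input_dim))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=dim)
    return RFFMap(omega, phase, seed, lengthscale)


def transform(rmap: RFFMap, x: np.ndarray) -> np.ndarray:
    """sqrt(2/D) cos(omega x / lengthscale + b); rows of x are inputs."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != rmap.input_dim:
        raise ValueError(
            f"input dim {x2.shape[1]} != map dim {rmap.input_dim}")
    z = x2 @ (rmap.omega.T / rmap.lengthscale) + rmap.phase
    feats = np.sqrt(2.0 / rmap.dim) * np.cos(z)
    return feats[0] if single else feats


def gaussian_kernel(x: np.ndarray, y: np.ndarray,
                    lengthscale: float = 1.0) -> float:
    """Exact kernel the map approximates (reference for tests/diagnostics)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.exp(-0.5 * np.dot(d, d) / lengthscale ** 2))
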