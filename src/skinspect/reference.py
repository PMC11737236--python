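"""Reference inversion: damped least-squares fit against the full forward model.

The iterative counterpart to the learned pipeline: Levenberg-Marquardt with a
forward-difference Jacobian, box bounds enforced by projection onto the
sampling ranges, and a hard cap of 200 iterations. Accurate but slow (every
iteration re-runs the adding-doubling solver), it serves as the accuracy
reference and as the fallback for spectra the pipeline flags as poorly fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ad import ADSolver
from .optics import PARAM_MAX, PARAM_MIN, TissueParams

MAX_ITER_DEFAULT = 200
#: forward-difference step, as a fraction of each parameter's range
FD_STEP_FRACTION = 1e-4


@dataclass(frozen=True)
class LMResult:
    params: TissueParams
    residual_mae: float
    iterations: int
    converged: bool


def fit_lm(measured: np.ndarray, init: TissueParams,
           solver: ADSolver | None = None,
           max_iter: int = MAX_ITER_DEFAULT,
           gtol: float = 1e-10, xtol: float = 1e-10) -> LMResult:
    """Levenberg-Marquardt fit of the 7 tissue parameters to a spectrum.

    Least-squares loss on the residual vector; the reported fit quality is
    the spectrum MAE for comparability with the emulator-based selection.
    """
    if not init.in_range():
        raise ValueError("initial parameters must lie within the bounds")
    solver = solver or ADSolver()
    y = np.asarray(measured, dtype=float)
    if y.shape != (len(solver.grid),):
        raise ValueError("spectrum length must match the solver grid")

    lo, hi = PARAM_MIN, PARAM_MAX
    span = hi - lo
    x = init.as_array().copy()

    def residuals(p):
        return solver.simulate_matrix(p[None])[0] - y

    r = residuals(x)
    cost = 0.5 * float(r @ r)
    lam = 1e-3
    n_iter = 0
    converged = False
    while n_iter < max_iter:
        n_iter += 1
        # forward-difference Jacobian (7 extra forward runs, batched)
        steps = FD_STEP_FRACTION * span
        steps = np.where(x + steps > hi, -steps, steps)
        probes = np.repeat(x[None], 7, axis=0) + np.diag(steps)
        jac = (solver.simulate_matrix(probes) - r - y) / steps[:, None]
        jac = jac.T                                  # (n_bands, 7)
        grad = jac.T @ r
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        jtj = jac.T @ jac
        improved = False
        for _ in range(25):
            try:
                delta = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj))
                                        + 1e-15 * np.eye(7), -grad)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            x_new = np.clip(x + delta, lo, hi)
            r_new = residuals(x_new)
            cost_new = 0.5 * float(r_new @ r_new)
            if cost_new < cost:
                step_size = np.max(np.abs(x_new - x) / span)
                x, r, cost = x_new, r_new, cost_new
                lam = max(lam / 10, 1e-12)
                improved = True
                if step_size < xtol:
                    converged = True
                break
            lam *= 10
        if not improved or converged:
            converged = converged or not improved
            break
    mae = float(np.mean(np.abs(r)))
    return LMResult(TissueParams.from_array(x), mae, n_iter, converged)


def midpoint_init() -> TissueParams:
    return TissueParams.midpoint()
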