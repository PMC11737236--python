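"""Bayesian neural network over RFF features, fitted by mean-field BBVI.

Model: y | x, W, sigma2 ~ N(f_W(phi(x)), sigma2 I) with a single hidden ReLU
layer (512 units), homoscedastic noise shared by the 7 outputs, priors
W ~ N(0, sigma_w^2 I) and sigma2 ~ InverseGamma(0.5, 0.1). The variational
family is a fully factorised Gaussian over all weights/biases and over
zeta = log sigma2 (the prior density is mapped through the change of
variables). The evidence lower bound is maximised by stochastic gradients
with the local reparameterization trick: instead of sampling weight matrices
we sample pre-activations, whose per-unit marginals under the mean-field
posterior are exactly Gaussian. Gradient clipping (global norm 5) and the
common Adam schedule are applied.

Posterior-predictive draws sample fresh (W, sigma2) per draw, add observation
noise, and clip negative parameters to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nnet import Adam, TrainConfig

BNN_TRAIN_CONFIG = TrainConfig(grad_clip=5.0)
DEFAULT_N_DRAWS = 500


@dataclass(frozen=True)
class BnnSpec:
    hidden: int = 512
    out_dim: int = 7
    sigma_w: float = 1.0          # weight-prior std (the prior variance is fixed)
    noise_alpha: float = 0.5      # InverseGamma shape for sigma2
    noise_beta: float = 0.1       # InverseGamma scale for sigma2


@dataclass
class VariationalPosterior:
    """Mean-field Gaussian over weights and log-noise; ELBO trace attached."""

    spec: BnnSpec
    input_dim: int
    mu1: np.ndarray
    rho1: np.ndarray
    b1m: np.ndarray
    b1r: np.ndarray
    mu2: np.ndarray
    rho2: np.ndarray
    b2m: np.ndarray
    b2r: np.ndarray
    zeta_m: float
    zeta_r: float
    elbo_trace: list = field(default_factory=list)
    seed: int = 0

    def scales(self):
        return (np.exp(self.rho1), np.exp(self.b1r), np.exp(self.rho2),
                np.exp(self.b2r))

    def save(self, path):
        np.savez_compressed(
            path, mu1=self.mu1, rho1=self.rho1, b1m=self.b1m, b1r=self.b1r,
            mu2=self.mu2, rho2=self.rho2, b2m=self.b2m, b2r=self.b2r,
            zeta=np.array([self.zeta_m, self.zeta_r]),
            elbo=np.asarray(self.elbo_trace), seed=self.seed,
            spec=np.array([self.spec.hidden, self.spec.out_dim,
                           self.spec.sigma_w, self.spec.noise_alpha,
                           self.spec.noise_beta]))

    @classmethod
    def load(cls, path) -> "VariationalPosterior":
        with np.load(path) as z:
            s = z["spec"]
            spec = BnnSpec(int(s[0]), int(s[1]), float(s[2]), float(s[3]),
                           float(s[4]))
            return cls(spec, z["mu1"].shape[0], z["mu1"], z["rho1"], z["b1m"],
                       z["b1r"], z["mu2"], z["rho2"], z["b2m"], z["b2r"],
                       float(z["zeta"][0]), float(z["zeta"][1]),
                       list(z["elbo"]), int(z["seed"]))


@dataclass(frozen=True)
class CandidateSet:
    """Posterior-predictive parameter draws for one spectrum.

    ``draws`` is (n_draws, 7) in normalized units, clipped at zero;
    ``sigma2`` the per-draw noise variance; ``fit_mae`` is filled by the
    forward-emulator selection step.
    """

    draws: np.ndarray
    sigma2: np.ndarray
    fit_mae: np.ndarray | None = None

    def __len__(self) -> int:
        return self.draws.shape[0]

    def as_table(self) -> np.ndarray:
        """(n_draws, 9) array: draw index, the 7 parameters, sigma2."""
        idx = np.arange(len(self), dtype=float)[:, None]
        return np.hstack([idx, self.draws, self.sigma2[:, None]])

    def save_text(self, path):
        np.savetxt(path, self.as_table(),
                   header="draw " + " ".join(
                       f"p{i}" for i in range(self.draws.shape[1]))
                   + " sigma2")


def _init_posterior(input_dim: int, spec: BnnSpec, seed: int) -> VariationalPosterior:
    rng = np.random.default_rng(seed)
    h, k = spec.hidden, spec.out_dim
    rho0 = np.log(0.05)
    return VariationalPosterior(
        spec=spec, input_dim=input_dim,
        mu1=(rng.standard_normal((input_dim, h)) * np.sqrt(2.0 / input_dim)
             ).astype(np.float32),
        rho1=np.full((input_dim, h), rho0, dtype=np.float32),
        b1m=np.zeros(h, dtype=np.float32),
        b1r=np.full(h, rho0, dtype=np.float32),
        mu2=(rng.standard_normal((h, k)) * np.sqrt(2.0 / h)).astype(np.float32),
        rho2=np.full((h, k), rho0, dtype=np.float32),
        b2m=np.zeros(k, dtype=np.float32),
        b2r=np.full(k, rho0, dtype=np.float32),
        zeta_m=float(np.log(0.01)), zeta_r=float(np.log(0.1)),
        seed=seed)


def fit_bbvi(features: np.ndarray, targets: np.ndarray,
             spec: BnnSpec = BnnSpec(), seed: int = 0,
             cfg: TrainConfig = BNN_TRAIN_CONFIG,
             verbose: bool = False) -> VariationalPosterior:
    """Maximise the ELBO; returns the fitted variational posterior."""
    x = np.asarray(features, dtype=np.float32)
    y = np.asarray(targets, dtype=np.float32)
    n, d = x.shape
    k = spec.out_dim
    post = _init_posterior(d, spec, seed)
    rng = np.random.default_rng(seed + 1)
    x_sq = x * x
    params = [post.mu1, post.rho1, post.b1m, post.b1r,
              post.mu2, post.rho2, post.b2m, post.b2r,
              np.array([post.zeta_m], dtype=np.float64),
              np.array([post.zeta_r], dtype=np.float64)]
    opt = Adam(params)
    zeta_mv, zeta_rv = params[8], params[9]
    sw2 = spec.sigma_w ** 2
    alpha, beta = spec.noise_alpha, spec.noise_beta

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        lr = cfg.lr_at(epoch)
        elbo_sum = 0.0
        for batch_i, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start:start + cfg.batch_size]
            xb, xb2, yb = x[idx], x_sq[idx], y[idx]
            b = len(idx)
            scale = n / b
            s1sq = np.exp(2.0 * post.rho1)
            b1sq = np.exp(2.0 * post.b1r)
            s2sq = np.exp(2.0 * post.rho2)
            b2sq = np.exp(2.0 * post.b2r)
            # local reparameterization, layer 1
            m1 = xb @ post.mu1 + post.b1m
            v1 = xb2 @ s1sq + b1sq
            sd1 = np.sqrt(v1)
            e1 = rng.standard_normal(m1.shape, dtype=np.float32)
            z1 = m1 + sd1 * e1
            hmask = z1 > 0
            h = z1 * hmask
            # layer 2
            h2 = h * h
            m2 = h @ post.mu2 + post.b2m
            v2 = h2 @ s2sq + b2sq
            sd2 = np.sqrt(v2)
            e2 = rng.standard_normal(m2.shape, dtype=np.float32)
            out = m2 + sd2 * e2
            resid = out - yb
            # noise draw
            ez = rng.standard_normal()
            s_z = np.exp(zeta_rv[0])
            zeta = zeta_mv[0] + s_z * ez
            inv_s2n = np.exp(-zeta)
            ss_resid = float(np.sum(resid * resid))
            # negative ELBO pieces (constants dropped); the KL value is only
            # needed for the trace, so it is evaluated once per epoch
            nll = scale * (0.5 * k * b * (np.log(2 * np.pi) + zeta)
                           + 0.5 * inv_s2n * ss_resid)
            if not np.isfinite(nll):
                raise FloatingPointError(f"non-finite ELBO at epoch {epoch}")
            if batch_i == 0:
                kl_w = 0.0
                for m_, ssq_ in ((post.mu1, s1sq), (post.b1m, b1sq),
                                 (post.mu2, s2sq), (post.b2m, b2sq)):
                    kl_w += float(np.sum(
                        np.log(spec.sigma_w) - 0.5 * np.log(ssq_)
                        + (ssq_ + m_ * m_) / (2 * sw2) - 0.5))
                kl_z = float(alpha * zeta + beta * np.exp(-zeta) - zeta_rv[0])
            elbo_sum += -(nll + kl_w + kl_z) * b
            # ---- gradients ----
            dout = (scale * inv_s2n) * resid          # (b, k)
            dm2 = dout
            dv2 = dout * e2 / (2.0 * np.maximum(sd2, 1e-12))
            g_mu2 = h.T @ dm2 + post.mu2 / sw2
            g_rho2 = 2.0 * s2sq * (h2.T @ dv2) + s2sq / sw2 - 1.0
            g_b2m = dm2.sum(axis=0) + post.b2m / sw2
            g_b2r = 2.0 * b2sq * dv2.sum(axis=0) + b2sq / sw2 - 1.0
            dh = (dm2 @ post.mu2.T + 2.0 * h * (dv2 @ s2sq.T))
            dz1 = dh * hmask
            dm1 = dz1
            dv1 = dz1 * e1 / (2.0 * np.maximum(sd1, 1e-12))
            g_mu1 = xb.T @ dm1 + post.mu1 / sw2
            g_rho1 = 2.0 * s1sq * (xb2.T @ dv1) + s1sq / sw2 - 1.0
            g_b1m = dm1.sum(axis=0) + post.b1m / sw2
            g_b1r = 2.0 * b1sq * dv1.sum(axis=0) + b1sq / sw2 - 1.0
            dzeta = (scale * (0.5 * k * b - 0.5 * inv_s2n * ss_resid)
                     + alpha - beta * np.exp(-zeta))
            g_zm = np.array([dzeta])
            g_zr = np.array([dzeta * ez * s_z - 1.0])
            opt.step([g_mu1, g_rho1, g_b1m, g_b1r, g_mu2, g_rho2, g_b2m,
                      g_b2r, g_zm, g_zr], lr, cfg.grad_clip)
        post.zeta_m, post.zeta_r = float(zeta_mv[0]), float(zeta_rv[0])
        post.elbo_trace.append(elbo_sum / n)
        if verbose and (epoch % 25 == 0 or epoch == cfg.epochs - 1):
            print(f"epoch {epoch:3d}  elbo/n {post.elbo_trace[-1]:.4f}")
    return post


# ---------------------------------------------------------------------------
# posterior-predictive sampling
# ---------------------------------------------------------------------------

def _predictive_draws(post: VariationalPosterior, features: np.ndarray,
                      n_draws: int, rng: np.random.Generator,
                      include_noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Unclipped draws (n_spectra, n_draws, out_dim) and sigma2 (n_draws,).

    Per (input, draw) the mean-field marginal of each pre-activation is
    Gaussian, so sampling activations is equivalent to sampling weights.
    """
    x = np.atleast_2d(np.asarray(features, dtype=np.float32))
    n = x.shape[0]
    s1, b1s, s2, b2s = post.scales()
    m1 = x @ post.mu1 + post.b1m                  # (n, H)
    v1 = (x * x) @ (s1 * s1) + b1s * b1s
    sd1 = np.sqrt(v1)
    zeta = post.zeta_m + np.exp(post.zeta_r) * rng.standard_normal(n_draws)
    sigma2 = np.exp(zeta)
    out = np.empty((n, n_draws, post.spec.out_dim), dtype=np.float32)
    chunk = max(1, int(2e7 // max(n_draws * post.spec.hidden, 1)))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        e1 = rng.standard_normal((sl.stop - sl.start, n_draws, m1.shape[1]),
                                 dtype=np.float32)
        z1 = m1[sl, None, :] + sd1[sl, None, :] * e1
        h = np.maximum(z1, 0.0)
        m2 = h @ post.mu2 + post.b2m
        v2 = (h * h) @ (s2 * s2) + b2s * b2s
        e2 = rng.standard_normal(m2.shape, dtype=np.float32)
        o = m2 + np.sqrt(v2) * e2
        if include_noise:
            o += (np.sqrt(sigma2)[None, :, None].astype(np.float32)
                  * rng.standard_normal(m2.shape, dtype=np.float32))
        out[sl] = o
    return out.astype(np.float64), sigma2


def sample_predictive(post: VariationalPosterior, feature_vector: np.ndarray,
                      n_draws: int = DEFAULT_N_DRAWS,
                      seed: int = 0) -> CandidateSet:
    """Draw parameter candidates for one spectrum; negatives are set to zero."""
    rng = np.random.default_rng(seed)
    draws, sigma2 = _predictive_draws(post, feature_vector, n_draws, rng)
    return CandidateSet(np.clip(draws[0], 0.0, None), sigma2)


def sample_predictive_batch(post: VariationalPosterior, features: np.ndarray,
                            n_draws: int = DEFAULT_N_DRAWS,
                            seed: int = 0) -> np.ndarray:
    """Clipped draws (n_spectra, n_draws, 7) for many spectra at once."""
    rng = np.random.default_rng(seed)
    draws, _ = _predictive_draws(post, features, n_draws, rng)
    return np.clip(draws, 0.0, None)


def posterior_mean_predict(post: VariationalPosterior, features: np.ndarray,
                           n_draws: int = DEFAULT_N_DRAWS,
                           seed: int = 0) -> np.ndarray:
    """Posterior-predictive mean (over clipped draws), the Bayes estimate."""
    single = np.asarray(features).ndim == 1
    draws = sample_predictive_batch(post, features, n_draws, seed)
    mean = np.clip(draws.mean(axis=1), 0.0, None)
    return mean[0] if single else mean
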