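# skinspect

Estimation of skin physiological parameters — melanin, deoxy- and
oxyhemoglobin volume fractions, bilirubin and cytochrome-c-oxidase
concentrations, and the scattering amplitude — from diffuse reflectance
spectra (430–750 nm, 321 bands) and hyperspectral images.

Iterative inversion of a radiative-transfer model (inverse adding-doubling)
is accurate but far too slow for per-pixel use. `skinspect` implements a
two-component learned alternative:

1. a **Bayesian neural network** over random Fourier features
   (`phi(x) = sqrt(2/D) cos(Omega x + b)`, approximating a Gaussian kernel)
   is trained by mean-field variational inference on simulated spectra and
   proposes, for each measured spectrum, hundreds of candidate parameter
   sets drawn from the posterior predictive;
2. a **forward emulator** — a small network approximating the
   adding-doubling forward map (parameters → spectrum) — scores every
   candidate by the mean absolute error of its re-synthesised spectrum and
   returns the best one. A best error above 0.03 flags the pixel for the
   slow-but-sure Levenberg–Marquardt reference fitter.

The package also contains everything around the estimator: the two-layer
skin optics (epidermis/dermis), a validated adding-doubling solver with a
photon Monte-Carlo oracle, uniform-sampling dataset simulation, the
use-error augmentation protocol (intensity tilt, ±10 nm shift, band-limited
noise), ridge/ANN/CNN baselines, 10-fold cross-validated evaluation
harnesses, and per-pixel hypercube mapping with StO₂
(= 100·fHbO₂/(fHb+fHbO₂)) and error maps. Physics, statistics and learning
components are all tested against independent oracles (exact H-functions,
photon Monte Carlo, conjugate Bayesian regression, finite-difference
gradients). See `docs/methods.md` for the model and numerical details.

## Worked example

Simulate a small corpus, train the pipeline, and invert a noisy spectrum:

```python
import numpy as np
import skinspect as sk
from skinspect.nnet import TrainConfig

solver = sk.ADSolver(n_quad=8)                 # forward model, 430-750 nm
ds = sk.build_dataset(2000, seed=1, solver=solver)
bnn_half, fnn_half = sk.split_halves(ds)

fnn = sk.fit_fnn(fnn_half, TrainConfig(seed=2))          # forward emulator
pipe = sk.train_pipeline(bnn_half.spectra, bnn_half.params_norm,
                         fnn, seed=3)                    # RFF + BNN

truth = sk.TissueParams(fm=0.02, fHb=0.01, fHbO2=0.03, fbrub=0.05,
                        fCO=1.0, fCOO2=1.0, a=50.0)
spectrum = solver.simulate(truth).reflectance

params_norm, fit_mae = pipe.predict(spectrum[None], seed=5)
phys = sk.denormalize_params(params_norm, clip=False)[0]
for name, est, true in zip(sk.PARAM_NAMES, phys, truth.as_array()):
    print(f"{name:6s} {est:8.4f}   (true {true:g})")
print(f"fit MAE {fit_mae[0]:.4f}  poor fit: {sk.flag_poor_fit(fit_mae[0])}")
```

Output of this exact script (seeds as shown):

```
fm       0.0212   (true 0.02)
fHb      0.0080   (true 0.01)
fHbO2    0.0285   (true 0.03)
fbrub    0.0378   (true 0.05)
fCO      0.6900   (true 1)
fCOO2    1.0631   (true 1)
a       52.7037   (true 50)
fit MAE 0.0039  poor fit: False
```

The well-identified parameters (melanin, hemoglobins, scattering) come back
close to truth; the cytochrome and bilirubin axes are ill-posed and scatter
more — which is exactly why the pipeline reports a forward-fit error and a
posterior spread rather than a bare point estimate.
`sk.sto2(phys[1], phys[2])` gives 78.1% oxygen saturation for this pixel
(true 75%). On noisy, shifted and tilted input (`sk.augment_spectrum`) the
forward-fit MAE rises and the hemoglobin split degrades first — the
behaviour the poor-fit flag is there to catch.

A command-line interface mirrors the library
(`skinspect simulate|augment|train|predict|evaluate|invert-reference|map`);
`skinspect train --dataset ds --out-dir model/` then
`skinspect map --cube scan --dark dark --white white --model-dir model/
--out maps/` produces parameter, error and StO₂ maps from an ENVI-style
cube.

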