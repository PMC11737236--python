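"""Experiment harness: cross-validated model comparison and refit errors.

Reproduces the simulation-study protocol: a dataset of uniformly sampled
spectra is halved (forward-emulator half / inference half); models are
trained on clean spectra inside a 10-fold cross-validation of the inference
half and evaluated on clean and use-error-augmented test folds. Reported
quantities are per-parameter MAEs in physical units and "forward refit" MAEs:
the selected/predicted parameters are pushed back through the adding-doubling
solver (or the forward emulator) and compared band-by-band with the spectra
being inverted.

All models share one interface; RFF variants are compositions with the
feature map (resampled per fold from fold-index XOR seed). One root seed
drives every random element and is echoed in the result manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from .ad import ADSolver
from .baselines import fit_ann, fit_cnn, fit_ridge
from .bnn import (BNN_TRAIN_CONFIG, BnnSpec, VariationalPosterior, fit_bbvi,
                  posterior_mean_predict, sample_predictive_batch)
from .data import SpectraDataset, augment_spectra, kfold_indices
from .fnn import fit_fnn, predict_spectra, select_best_batch
from .nnet import Network, TrainConfig
from .optics import denormalize_params
from .rff import RFFMap, sample_map, transform

ALL_MODELS = ("ridge", "rff+ridge", "ann", "rff+ann", "cnn", "rff+bnn",
              "rff+bnn+fnn")


def mae(a, b) -> float:
    """Mean absolute difference of two equal-shaped arrays."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def per_param_mae(pred_norm: np.ndarray, true_norm: np.ndarray) -> np.ndarray:
    """Per-parameter MAE in physical units (after denormalization)."""
    pred_norm = np.asarray(pred_norm, dtype=float)
    true_norm = np.asarray(true_norm, dtype=float)
    if pred_norm.shape != true_norm.shape:
        raise ValueError("shape mismatch")
    pred = denormalize_params(pred_norm, clip=False)
    true = denormalize_params(true_norm, clip=False)
    return np.mean(np.abs(pred - true), axis=0)


# ---------------------------------------------------------------------------
# pipeline object (RFF + BNN + F-NN)
# ---------------------------------------------------------------------------

@dataclass
class Pipeline:
    """Fitted RFF + BNN (+ forward-emulator selection) predictor."""

    rff_map: RFFMap
    posterior: VariationalPosterior
    fnn_model: Network | None = None
    n_draws: int = 500

    def predict(self, spectra: np.ndarray, seed: int = 0,
                select: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
        """Normalized parameter predictions (n, 7) and best-fit MAEs (n,).

        With ``select`` (and a fitted emulator) each spectrum gets the best of
        ``n_draws`` posterior-predictive candidates; otherwise the posterior
        mean is returned and the MAE vector is None.
        """
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        feats = transform(self.rff_map, spectra)
        if select and self.fnn_model is not None:
            draws = sample_predictive_batch(self.posterior, feats,
                                            self.n_draws, seed)
            return select_best_batch(self.fnn_model, draws, spectra)
        return posterior_mean_predict(self.posterior, feats, self.n_draws,
                                      seed), None


def train_pipeline(train_spectra: np.ndarray, train_params_norm: np.ndarray,
                   fnn_model: Network | None, seed: int = 0,
                   rff_dim: int = 1000, spec: BnnSpec = BnnSpec(),
                   cfg: TrainConfig = BNN_TRAIN_CONFIG,
                   n_draws: int = 500) -> Pipeline:
    rmap = sample_map(train_spectra.shape[1], rff_dim, seed)
    feats = transform(rmap, train_spectra)
    post = fit_bbvi(feats, train_params_norm, spec, seed, cfg)
    return Pipeline(rmap, post, fnn_model, n_draws)


# ---------------------------------------------------------------------------
# cross-validated experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    models: dict                      # name -> metrics dict
    manifest: dict = field(default_factory=dict)

    def table3(self) -> dict:
        return {m: v["per_param_mae"] for m, v in self.models.items()}

    def table4(self) -> dict:
        return {m: v["ad_clean"] for m, v in self.models.items()
                if v.get("ad_clean") is not None}

    def table5(self) -> dict:
        return {m: (v.get("ad_aug"), v.get("fnn_aug"))
                for m, v in self.models.items()}

    def save(self, path):
        out = {"manifest": self.manifest, "models": {}}
        for m, v in self.models.items():
            out["models"][m] = {
                k: (val.tolist() if isinstance(val, np.ndarray) else val)
                for k, val in v.items()}
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


def _predict_model(name, model, rmap, spectra):
    """Normalized predictions for a fitted deterministic model."""
    x = transform(rmap, spectra) if name.startswith("rff+") else spectra
    return np.clip(model.predict(x), 0.0, None)


def run_experiment(ds: SpectraDataset,
                   models=("ridge", "rff+ridge", "rff+bnn", "rff+bnn+fnn"),
                   seed: int = 0, k: int = 10,
                   fnn_model: Network | None = None,
                   solver: ADSolver | None = None,
                   rff_dim: int = 1000, n_draws: int = 500,
                   eval_augmented: bool = True,
                   refit_ad: bool = True,
                   refit_clean_models=("rff+bnn+fnn",),
                   refit_subsample: int | None = None,
                   clean_subsample_only: bool = False,
                   cfg: TrainConfig = TrainConfig(),
                   verbose: bool = False) -> ExperimentResult:
    """k-fold CV over ``ds`` (the inference half) for the requested models.

    Per fold and model: train on clean spectra, predict normalized parameters
    for the clean (and optionally augmented) test fold, accumulate
    per-parameter errors and forward-refit errors. ``refit_subsample`` caps
    the number of test spectra per fold pushed through the adding-doubling
    refit (None = all); the emulator refit is always computed on all.
    ``clean_subsample_only`` restricts the expensive posterior sampling of
    the clean evaluation to the refit subsample (the augmented evaluation is
    always complete).
    """
    rng = np.random.default_rng(seed)
    needs_fnn = "rff+bnn+fnn" in models
    if needs_fnn and fnn_model is None:
        raise ValueError("rff+bnn+fnn requires a fitted forward emulator")
    if refit_ad and solver is None:
        solver = ADSolver()
    folds = kfold_indices(len(ds), k, seed)
    acc = {m: {"abs_err": [], "ad_clean": [], "ad_aug": [], "fnn_aug": []}
           for m in models}
    t_start = time.time()
    for fold_i, (tr, te) in enumerate(folds):
        x_tr, y_tr = ds.spectra[tr], ds.params_norm[tr]
        x_te = ds.spectra[te]
        y_te = ds.params_norm[te]
        x_te_aug = (augment_spectra(x_te, seed=int(rng.integers(2 ** 31)))
                    if eval_augmented else None)
        rmap = (sample_map(ds.spectra.shape[1], rff_dim, seed ^ fold_i)
                if any(m.startswith("rff+") for m in models) else None)
        feats_tr = transform(rmap, x_tr) if rmap is not None else None
        sub = (np.arange(len(te)) if refit_subsample is None
               else np.sort(rng.choice(len(te),
                                       min(refit_subsample, len(te)),
                                       replace=False)))
        if clean_subsample_only:
            x_te_c, y_te_c, sub_c = x_te[sub], y_te[sub], np.arange(len(sub))
        else:
            x_te_c, y_te_c, sub_c = x_te, y_te, sub
        post = None
        for name in models:
            fold_seed = (seed * 1000 + fold_i) % (2 ** 31)
            fold_cfg = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                                   lr=cfg.lr, lr_late=cfg.lr_late,
                                   lr_switch_epoch=cfg.lr_switch_epoch,
                                   grad_clip=cfg.grad_clip, seed=fold_seed)
            preds = {}
            if name == "ridge":
                model = fit_ridge(x_tr, y_tr)
                preds["clean"] = _predict_model(name, model, None, x_te_c)
                if eval_augmented:
                    preds["aug"] = _predict_model(name, model, None, x_te_aug)
            elif name == "rff+ridge":
                model = fit_ridge(feats_tr, y_tr)
                preds["clean"] = np.clip(model.predict(transform(rmap, x_te_c)), 0, None)
                if eval_augmented:
                    preds["aug"] = np.clip(
                        model.predict(transform(rmap, x_te_aug)), 0, None)
            elif name in ("ann", "cnn"):
                fit = fit_ann if name == "ann" else fit_cnn
                model = fit(x_tr, y_tr, fold_cfg)
                preds["clean"] = np.clip(model.predict(x_te_c), 0, None)
                if eval_augmented:
                    preds["aug"] = np.clip(model.predict(x_te_aug), 0, None)
            elif name == "rff+ann":
                model = fit_ann(feats_tr, y_tr, fold_cfg)
                preds["clean"] = np.clip(model.predict(transform(rmap, x_te_c)), 0, None)
                if eval_augmented:
                    preds["aug"] = np.clip(
                        model.predict(transform(rmap, x_te_aug)), 0, None)
            elif name in ("rff+bnn", "rff+bnn+fnn"):
                if post is None:
                    spec = BnnSpec()
                    bnn_cfg = TrainConfig(
                        epochs=cfg.epochs, batch_size=cfg.batch_size,
                        lr=cfg.lr, lr_late=cfg.lr_late,
                        lr_switch_epoch=cfg.lr_switch_epoch,
                        grad_clip=5.0, seed=fold_seed)
                    post = fit_bbvi(feats_tr, y_tr, spec, fold_seed, bnn_cfg)
                if name == "rff+bnn":
                    preds["clean"] = posterior_mean_predict(
                        post, transform(rmap, x_te_c), n_draws, fold_seed + 1)
                    if eval_augmented:
                        preds["aug"] = posterior_mean_predict(
                            post, transform(rmap, x_te_aug), n_draws,
                            fold_seed + 2)
                else:
                    draws = sample_predictive_batch(
                        post, transform(rmap, x_te_c), n_draws, fold_seed + 3)
                    preds["clean"], _ = select_best_batch(fnn_model, draws,
                                                         x_te_c)
                    if eval_augmented:
                        draws = sample_predictive_batch(
                            post, transform(rmap, x_te_aug), n_draws,
                            fold_seed + 4)
                        preds["aug"], fnn_mae = select_best_batch(
                            fnn_model, draws, x_te_aug)
                        acc[name]["fnn_aug"].append(fnn_mae)
            else:
                raise ValueError(f"unknown model {name!r}")
            # emulator refit error on augmented spectra (all models)
            if eval_augmented and name != "rff+bnn+fnn" and fnn_model is not None:
                emu = predict_spectra(fnn_model, preds["aug"])
                acc[name]["fnn_aug"].append(
                    np.mean(np.abs(emu - x_te_aug), axis=1))
            # physical-unit parameter errors on the clean evaluation
            err = np.abs(denormalize_params(preds["clean"], clip=False)
                         - denormalize_params(y_te_c, clip=False))
            acc[name]["abs_err"].append(err)
            # adding-doubling refit errors
            if refit_ad:
                if name in refit_clean_models:
                    refit = solver.simulate_matrix(denormalize_params(
                        preds["clean"][sub_c], clip=False))
                    acc[name]["ad_clean"].append(
                        np.mean(np.abs(refit - x_te_c[sub_c]), axis=1))
                if eval_augmented:
                    refit = solver.simulate_matrix(denormalize_params(
                        preds["aug"][sub], clip=False))
                    acc[name]["ad_aug"].append(
                        np.mean(np.abs(refit - x_te_aug[sub]), axis=1))
        if verbose:
            print(f"fold {fold_i + 1}/{k} done ({time.time() - t_start:.0f}s)")
    result = {}
    for name in models:
        a = acc[name]
        result[name] = {
            "per_param_mae": np.mean(np.concatenate(a["abs_err"]), axis=0),
            "ad_clean": (float(np.mean(np.concatenate(a["ad_clean"])))
                         if a["ad_clean"] else None),
            "ad_aug": (float(np.mean(np.concatenate(a["ad_aug"])))
                       if a["ad_aug"] else None),
            "fnn_aug": (float(np.mean(np.concatenate(a["fnn_aug"])))
                        if a["fnn_aug"] else None),
        }
    manifest = {"n": len(ds), "k": k, "seed": seed, "rff_dim": rff_dim,
                "n_draws": n_draws, "models": list(models),
                "refit_subsample": refit_subsample,
                "dataset_seed": ds.seed,
                "elapsed_s": round(time.time() - t_start, 1)}
    return ExperimentResult(result, manifest)


def run_table3(ds: SpectraDataset, models=ALL_MODELS, seed: int = 0,
               k: int = 10, fnn_model: Network | None = None,
               **kw) -> dict:
    """Per-parameter MAE table (clean spectra, k-fold CV), physical units."""
    res = run_experiment(ds, models, seed, k, fnn_model=fnn_model,
                         eval_augmented=False, refit_ad=False, **kw)
    return res.table3()


def run_table4(ds: SpectraDataset, models, seed: int = 0, k: int = 10,
               fnn_model: Network | None = None,
               solver: ADSolver | None = None, **kw) -> dict:
    """Forward-refit MAE on clean spectra via the adding-doubling solver."""
    res = run_experiment(ds, models, seed, k, fnn_model=fnn_model,
                         solver=solver, eval_augmented=False, refit_ad=True,
                         refit_clean_models=tuple(models), **kw)
    return res.table4()


def run_table5(ds: SpectraDataset, models, seed: int = 0, k: int = 10,
               fnn_model: Network | None = None,
               solver: ADSolver | None = None, **kw) -> dict:
    """Forward-refit MAE on augmented spectra, via AD and via the emulator."""
    res = run_experiment(ds, models, seed, k, fnn_model=fnn_model,
                         solver=solver, eval_augmented=True, refit_ad=True,
                         refit_clean_models=(), **kw)
    return res.table5()
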