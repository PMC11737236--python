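"""Hypercube calibration, band cropping, per-pixel inference and maps.

A measured pushbroom hypercube (H x W x B intensities plus dark/white
reference frames) is calibrated to reflectance, resampled to the working
430-750 nm grid, and inverted pixel by pixel with the fitted pipeline to
produce parameter maps, a forward-fit error map, a poor-fit mask and a
hemoglobin oxygen-saturation map StO2 = 100 * fHbO2 / (fHb + fHbO2).

Cubes are read/written in a minimal ENVI-style layout (text header + raw
binary, BSQ/BIL/BIP interleaves) or kept in memory; a synthetic-cube builder
provides a deterministic stand-in for unavailable measured data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ad import ADSolver
from .data import augment_spectra
from .fnn import POOR_FIT_THRESHOLD
from .optics import (PARAM_MAX, PARAM_MIN, WavelengthGrid, denormalize_params,
                     normalize_params)

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


@dataclass
class Hypercube:
    """Raw intensity cube with companion dark/white reference frames."""

    raw: np.ndarray            # (H, W, B)
    dark: np.ndarray           # (H, W, B) or (B,)
    white: np.ndarray
    wavelengths: np.ndarray    # (B,)

    def __post_init__(self):
        if self.raw.ndim != 3:
            raise ValueError("raw cube must be (H, W, B)")
        if self.wavelengths.shape != (self.raw.shape[2],):
            raise ValueError("wavelengths must match the band axis")


@dataclass
class ParamMaps:
    """Per-pixel inversion products."""

    params: np.ndarray         # (H, W, 7) physical units
    mae: np.ndarray            # (H, W) forward-fit MAE
    poor_fit: np.ndarray       # (H, W) bool, MAE > threshold
    sto2: np.ndarray           # (H, W) percent, NaN where undefined
    threshold: float = POOR_FIT_THRESHOLD


def calibrate(raw: np.ndarray, dark: np.ndarray,
              white: np.ndarray) -> np.ndarray:
    """(I_raw - I_dark) / (I_white - I_dark), elementwise."""
    raw = np.asarray(raw, dtype=float)
    dark = np.broadcast_to(np.asarray(dark, dtype=float), raw.shape)
    white = np.broadcast_to(np.asarray(white, dtype=float), raw.shape)
    denom = white - dark
    bad = np.all(np.isclose(denom, 0.0), axis=tuple(range(denom.ndim - 1)))
    if np.any(bad):
        bands = np.nonzero(bad)[0]
        raise CalibrationError(
            f"white equals dark in band(s) {bands.tolist()}")
    return (raw - dark) / denom


def crop_bands(cube: np.ndarray, wavelengths: np.ndarray,
               lo: float = 430.0, hi: float = 750.0,
               step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample the band axis onto [lo, hi] at ``step`` nm (linear interp)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths[0] > lo or wavelengths[-1] < hi:
        raise ValueError(
            f"source range {wavelengths[0]:.0f}-{wavelengths[-1]:.0f} nm "
            f"does not cover {lo:.0f}-{hi:.0f} nm")
    target = np.arange(lo, hi + step / 2, step)
    if (wavelengths.size == target.size
            and np.allclose(wavelengths, target)):
        return np.asarray(cube, dtype=float), target
    flat = np.asarray(cube, dtype=float).reshape(-1, wavelengths.size)
    out = np.empty((flat.shape[0], target.size))
    for i, row in enumerate(flat):
        out[i] = np.interp(target, wavelengths, row)
    return out.reshape(cube.shape[:-1] + (target.size,)), target


def sto2(f_hb, f_hbo2):
    """Hemoglobin oxygen saturation in percent; NaN where both are zero."""
    f_hb = np.asarray(f_hb, dtype=float)
    f_hbo2 = np.asarray(f_hbo2, dtype=float)
    if np.any(f_hb < 0) or np.any(f_hbo2 < 0):
        raise ValueError("hemoglobin fractions must be >= 0")
    total = f_hb + f_hbo2
    both_zero = total == 0
    if np.any(both_zero):
        log.info("sto2 undefined for %d pixel(s) (no hemoglobin)",
                 int(np.sum(both_zero)))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(both_zero, np.nan, 100.0 * f_hbo2 / np.where(
            both_zero, 1.0, total))
    return float(out) if out.ndim == 0 else out


def infer_cube(cube: Hypercube, pipeline, batch_size: int = 256,
               seed: int = 0,
               threshold: float = POOR_FIT_THRESHOLD) -> ParamMaps:
    """Per-pixel pipeline inversion of a calibrated-and-cropped cube.

    Batching is purely an execution detail: per-pixel draw seeds are derived
    from (seed, pixel index), so batched and unbatched runs agree exactly.
    """
    refl = calibrate(cube.raw, cube.dark, cube.white)
    refl, wl = crop_bands(refl, cube.wavelengths)
    h, w, b = refl.shape
    flat = np.clip(refl.reshape(-1, b), 0.0, 1.05)
    params_norm = np.empty((h * w, 7))
    maes = np.empty(h * w)
    for start in range(0, h * w, batch_size):
        sl = slice(start, min(start + batch_size, h * w))
        # one spectrum at a time within the batch keeps the per-pixel seeds
        # independent of the batch size
        for i in range(sl.start, sl.stop):
            p, m = pipeline.predict(flat[i][None], seed=seed + i)
            params_norm[i] = p[0]
            maes[i] = m[0] if m is not None else np.nan
    phys = denormalize_params(params_norm, clip=False).reshape(h, w, 7)
    mae_map = maes.reshape(h, w)
    return ParamMaps(
        params=phys, mae=mae_map, poor_fit=mae_map > threshold,
        sto2=sto2(phys[..., 1], phys[..., 2]), threshold=threshold)


# ---------------------------------------------------------------------------
# synthetic cube fixture
# ---------------------------------------------------------------------------

def synthetic_cube(height: int = 16, width: int = 16, seed: int = 0,
                   solver: ADSolver | None = None,
                   hb_ratio: float | None = None) -> tuple[Hypercube, np.ndarray]:
    """Deterministic synthetic hypercube with known ground truth.

    Piecewise-constant parameter patches; one vertical "vessel" stripe with
    absorption far outside the sampling range (to exercise the poor-fit
    flag) and one high-noise stripe. Returns (cube, truth) where truth is
    the (H, W, 7) physical parameter map. ``hb_ratio`` overrides
    fHbO2 : fHb while keeping total hemoglobin fixed (cuff-test surrogate).
    """
    rng = np.random.default_rng(seed)
    solver = solver or ADSolver()
    nb = len(solver.grid)
    # 4x4 grid of patches with uniform in-range parameters
    truth = np.empty((height, width, 7))
    ph, pw = max(1, height // 4), max(1, width // 4)
    for i in range(0, height, ph):
        for j in range(0, width, pw):
            p = rng.uniform(PARAM_MIN, PARAM_MAX)
            if hb_ratio is not None:
                total = p[1] + p[2]
                p[2] = total * hb_ratio / (1.0 + hb_ratio)
                p[1] = total - p[2]
            truth[i:i + ph, j:j + pw] = p
    vessel_col = width // 2
    truth[:, vessel_col, 1] = 0.5        # fHb tenfold above the range: vessel
    truth[:, vessel_col, 2] = 0.2
    flat = truth.reshape(-1, 7)
    spectra = solver.simulate_matrix(flat).reshape(height, width, nb)
    # measurement noise everywhere, stronger on one stripe
    noisy = augment_spectra(spectra.reshape(-1, nb),
                            seed=int(rng.integers(2 ** 31)))
    noisy = noisy.reshape(height, width, nb)
    noise_col = max(0, width // 4)
    noisy[:, noise_col] += 0.02 * rng.standard_normal((height, nb))
    noisy = np.clip(noisy, 0.0, None)
    # wrap into raw counts with consistent dark/white frames
    dark = np.full(nb, 100.0)
    white = np.full(nb, 4000.0)
    raw = noisy * (white - dark) + dark
    cube = Hypercube(raw=raw, dark=dark, white=white,
                     wavelengths=solver.grid.wavelengths)
    return cube, truth


# ---------------------------------------------------------------------------
# minimal ENVI-style I/O
# ---------------------------------------------------------------------------

_INTERLEAVES = ("bsq", "bil", "bip")


def write_envi(path, cube: np.ndarray, wavelengths: np.ndarray,
               interleave: str = "bip"):
    """Write (H, W, B) data as a raw binary file plus a text .hdr header."""
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    path = Path(path)
    cube = np.asarray(cube, dtype=np.float32)
    h, w, b = cube.shape
    order = {"bip": cube, "bil": cube.transpose(0, 2, 1),
             "bsq": cube.transpose(2, 0, 1)}[interleave]
    order.astype("<f4").tofile(path.with_suffix(".raw"))
    hdr = (
        "ENVI\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\nbyte order = 0\n"
        f"interleave = {interleave}\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + ", ".join(f"{x:.2f}" for x in wavelengths) + "}\n")
    path.with_suffix(".hdr").write_text(hdr)


def read_envi(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a cube written by :func:`write_envi` (any interleave)."""
    path = Path(path)
    fields = {}
    text = path.with_suffix(".hdr").read_text()
    body = text.replace("\n", " ")
    for key in ("samples", "lines", "bands", "data type", "byte order"):
        for line in text.splitlines():
            if line.lower().startswith(key):
                fields[key] = int(line.split("=")[1].strip())
    interleave = "bip"
    for line in text.splitlines():
        if line.lower().startswith("interleave"):
            interleave = line.split("=")[1].strip().lower()
    wl_part = body.split("wavelength =", 1)[1]
    wl = np.array([float(x) for x in
                   wl_part.split("{")[1].split("}")[0].split(",")])
    h, w, b = fields["lines"], fields["samples"], fields["bands"]
    if fields.get("data type", 4) != 4:
        raise ValueError("only 32-bit float ENVI cubes are supported")
    data = np.fromfile(path.with_suffix(".raw"), dtype="<f4")
    shapes = {"bip": (h, w, b), "bil": (h, b, w), "bsq": (b, h, w)}
    data = data.reshape(shapes[interleave])
    if interleave == "bil":
        data = data.transpose(0, 2, 1)
    elif interleave == "bsq":
        data = data.transpose(1, 2, 0)
    return np.ascontiguousarray(data.astype(float)), wl


def save_maps(maps: ParamMaps, out_dir):
    """Write parameter/error/StO2 maps as flat binaries plus PNG previews."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "maps.npz", params=maps.params, mae=maps.mae,
                        poor_fit=maps.poor_fit, sto2=maps.sto2,
                        threshold=maps.threshold)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for name, img in (("sto2", maps.sto2), ("mae", maps.mae),
                          ("fm", maps.params[..., 0])):
            fig, ax = plt.subplots(figsize=(4, 4))
            im = ax.imshow(img)
            fig.colorbar(im, ax=ax)
            ax.set_title(name)
            fig.savefig(out / f"{name}.png", dpi=100)
            plt.close(fig)
    except Exception as exc:      # previews are best-effort
        log.warning("PNG previews skipped: %s", exc)
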