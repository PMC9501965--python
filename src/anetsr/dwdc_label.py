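"""High-resolution binary label generation (DWDC).

Labels for network training are produced from the interpolated originals
by a classical restoration chain: multilevel discrete-wavelet shrinkage
to suppress noise, Lucy-Richardson deconvolution against the optical PSF
to sharpen filament cross-sections, and a final hard binarization that
keeps only the structural sketch.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

from .core_image import IntensityImage, convert_16_to_8, tile, write_tiff
from .preprocess import OpticalModel, psf_radii


__all__ = [
    "DwdcConfig",
    "dwt_denoise",
    "gaussian_psf",
    "richardson_lucy",
    "make_label",
    "pair_dataset",
]


@dataclass(frozen=True)
class DwdcConfig:
    """Restoration-chain parameters.

    wavelet / levels / shrink_rule control the DWT denoising stage
    (shrink_rule: "bayes", "universal" or "none"); rl_iters the number of
    Lucy-Richardson iterations; binarize_threshold the final cut (None
    selects Otsu's threshold on the deconvolved image).
    """

    wavelet: str = "sym4"
    levels: int = 3
    shrink_rule: str = "bayes"
    rl_iters: int = 30
    binarize_threshold: float | None = None

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.rl_iters < 1:
            raise ValueError("rl_iters must be >= 1")
        if self.shrink_rule not in ("bayes", "universal", "none"):
            raise ValueError(f"unknown shrink_rule {self.shrink_rule!r}")


def _shrink_threshold(detail: np.ndarray, sigma: float, rule: str,
                      n_total: int) -> float:
    if rule == "none":
        return 0.0
    if rule == "universal":
        return sigma * math.sqrt(2.0 * math.log(max(n_total, 2)))
    # BayesShrink: t = sigma^2 / sigma_x with sigma_x^2 = max(var - sigma^2, 0)
    var = float(np.mean(detail**2))
    sx2 = max(var - sigma**2, 0.0)
    if sx2 == 0.0:
        return float(np.abs(detail).max())  # kill the subband
    return sigma**2 / math.sqrt(sx2)


def dwt_denoise(img, wavelet: str = "sym4", levels: int = 3,
                shrink_rule: str = "bayes"):
    """Multilevel 2D wavelet shrinkage.

    Detail coefficients are soft-thresholded per subband; the noise scale
    is the median absolute deviation of the finest diagonal subband.  With
    shrink_rule "none" the transform round-trips exactly (perfect
    reconstruction).  IntensityImage in -> IntensityImage out (clipped to
    the valid range); bare float arrays pass through as float.
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wavelet!r}")
    is_image = isinstance(img, IntensityImage)
    arr = img.astype_float() if is_image else np.asarray(img, dtype=float)
    if min(arr.shape) < 2**levels:
        raise ValueError("image sides must be >= 2**levels")
    coeffs = pywt.wavedec2(arr, wavelet, level=levels, mode="symmetric")
    finest_diag = coeffs[-1][2]
    sigma = float(np.median(np.abs(finest_diag))) / 0.6745
    out_coeffs = [coeffs[0]]
    for details in coeffs[1:]:
        shrunk = []
        for d in details:
            t = _shrink_threshold(d, sigma, shrink_rule, arr.size)
            shrunk.append(pywt.threshold(d, t, mode="soft") if t > 0 else d)
        out_coeffs.append(tuple(shrunk))
    rec = pywt.waverec2(out_coeffs, wavelet, mode="symmetric")
    rec = rec[: arr.shape[0], : arr.shape[1]]
    if not is_image:
        return rec
    hi = 2**img.bit_depth - 1
    quant = np.clip(np.floor(rec + 0.5), 0, hi).astype(img.pixels.dtype)
    return IntensityImage(quant, bit_depth=img.bit_depth, pitch_xy=img.pitch_xy)


def gaussian_psf(sigma_px: float, truncate: float = 3.0) -> np.ndarray:
    """Normalized odd-sized 2D Gaussian kernel truncated at ``truncate`` sigma."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    k = max(1, int(math.ceil(truncate * sigma_px)))
    ax = np.arange(-k, k + 1)
    g1 = np.exp(-(ax**2) / (2.0 * sigma_px**2))
    psf = np.outer(g1, g1)
    return psf / psf.sum()


def _conv_same_reflect(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size convolution with reflective boundary handling."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(arr, ((ph, ph), (pw, pw)), mode="reflect")
    return fftconvolve(padded, kernel, mode="valid")


def richardson_lucy(img, psf: np.ndarray, iters: int = 30,
                    eps: float = 1e-12) -> np.ndarray:
    """Lucy-Richardson deconvolution.

    Iterates x_{k+1} = x_k * (psf^T (*) (img / (psf (*) x_k))) starting
    from x_0 = img, with the ratio denominator guarded by ``eps`` and
    reflective padding at the boundary.  The PSF must be nonnegative and
    is normalized to unit sum; the output is nonnegative and, for signal
    supported away from the edges, conserves total intensity.
    """
    psf = np.asarray(psf, dtype=float)
    if psf.ndim != 2 or psf.shape[0] % 2 == 0 or psf.shape[1] % 2 == 0:
        raise ValueError("psf must be a 2D odd-sized kernel")
    if (psf < 0).any():
        raise ValueError("psf must be nonnegative")
    s = psf.sum()
    if s <= 0:
        raise ValueError("psf must have positive sum")
    psf = psf / s
    data = img.astype_float() if isinstance(img, IntensityImage) else np.asarray(img, dtype=float)
    if (data < 0).any():
        raise ValueError("image must be nonnegative")
    psf_mirror = psf[::-1, ::-1]
    x = data.copy()
    for _ in range(iters):
        denom = _conv_same_reflect(x, psf)
        ratio = data / np.maximum(denom, eps)
        x = x * _conv_same_reflect(ratio, psf_mirror)
        np.maximum(x, 0.0, out=x)  # clip fft round-off
    return x


def rl_poisson_loglik(data: np.ndarray, estimate: np.ndarray,
                      psf: np.ndarray) -> float:
    """Poisson log-likelihood of ``data`` under blur(estimate) — the
    objective Lucy-Richardson ascends (constants dropped)."""
    mu = np.maximum(_conv_same_reflect(estimate, psf / psf.sum()), 1e-12)
    return float(np.sum(data * np.log(mu) - mu))


def make_label(img: IntensityImage, optical: OpticalModel,
               cfg: DwdcConfig = DwdcConfig()) -> np.ndarray:
    """Full DWDC chain: denoise -> deconvolve -> binarize.

    The deconvolution PSF is the transverse optical Gaussian
    (sigma = r_perp) sampled at the image's own pitch, so the input is
    expected to be at the interpolated scale.  Returns a {0, 1} uint8
    label image.
    """
    den = dwt_denoise(img, cfg.wavelet, cfg.levels, cfg.shrink_rule)
    arr = den.astype_float()
    if arr.max() == 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    r_perp, _ = psf_radii(optical)
    sigma_px = r_perp / float(img.pitch_xy)
    psf = gaussian_psf(sigma_px)
    dec = richardson_lucy(arr, psf, cfg.rl_iters)
    t = cfg.binarize_threshold
    if t is None:
        t = threshold_otsu(dec) if dec.max() > dec.min() else np.inf
    return (dec >= t).astype(np.uint8)


def pair_dataset(originals: list, labels: list, out_dir,
                 tile_side: int = 512, force: bool = False) -> Path:
    """Pair interpolated originals with their binary labels as 8-bit tiles.

    Originals are converted 16->8 bit, labels written as {0, 255}; both are
    tiled to ``tile_side`` and paired index-wise in a CSV manifest whose
    path is returned.  Empty input lists yield an empty dataset.
    """
    if len(originals) != len(labels):
        raise ValueError("originals and labels must have equal counts")
    out_dir = Path(out_dir)
    manifest = out_dir / "pairs.csv"
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty; use force=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (orig, lab) in enumerate(zip(originals, labels)):
        lab = np.asarray(lab)
        if lab.shape != orig.shape:
            raise ValueError(f"pair {i}: size mismatch {orig.shape} vs {lab.shape}")
        orig8 = convert_16_to_8(orig) if orig.bit_depth == 16 else orig
        lab8 = IntensityImage((lab > 0).astype(np.uint8) * 255, bit_depth=8,
                              pitch_xy=orig.pitch_xy)
        og = tile(orig8, tile_side)
        lg = tile(lab8, tile_side)
        for j, (ot, lt) in enumerate(zip(og.tiles, lg.tiles)):
            orel = f"orig_{i:04d}_{j:02d}.tif"
            lrel = f"label_{i:04d}_{j:02d}.tif"
            write_tiff(out_dir / orel, ot)
            write_tiff(out_dir / lrel, lt)
            rows.append((i, j, orel, lrel))
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_index", "tile_index", "original", "label"])
        w.writerows(rows)
    return manifest
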