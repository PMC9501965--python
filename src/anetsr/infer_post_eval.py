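"""Full-image prediction, masking postprocessing, and resolution metrology.

Large images are predicted tile-by-tile (the network sees the same tile
size it was trained on) and reassembled.  The prediction's foreground
probability is binarized and multiplied with the test image, so intensities
inside the predicted structure are preserved exactly and everything else is
suppressed.  Resolution is measured as the full width at half maximum
(FWHM) of intensity line profiles; SSIM/PSNR and z-stack assembly complete
the evaluation toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .anet_model import Anet, predict_proba
from .core_image import ImageStack, IntensityImage, tile

__all__ = [
    "LineProfile",
    "predict_full",
    "binarize_mask",
    "apply_mask",
    "fwhm",
    "extract_row_profile",
    "extract_profile",
    "image_metrics",
    "stack_3d",
    "max_intensity_projection",
    "PSNR_CAP_DB",
]

PSNR_CAP_DB = 100.0  # sentinel for identical images (PSNR diverges)


@dataclass
class LineProfile:
    """Uniformly sampled 1D intensity profile (positions in nm)."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must be equal-length 1D")
        if len(self.positions) < 3:
            raise ValueError("profile needs at least 3 samples")
        d = np.diff(self.positions)
        if (d <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("positions must be uniformly spaced")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


def predict_full(img: IntensityImage, model: Anet,
                 tile_side: int | None = None) -> np.ndarray:
    """Foreground-probability map of a full image via tile/forward/assemble.

    ``tile_side`` defaults to the full image side (single pass); a 2048 px
    image with tile_side 512 runs 16 forward passes.  Output is a float
    array in [0, 1] with the same shape as the input.
    """
    h, w = img.shape
    side = tile_side if tile_side is not None else h
    grid = tile(img, side)
    out = np.zeros((h, w), dtype=np.float64)
    for i, t in enumerate(grid.tiles):
        p = predict_proba(model, t)[1]  # class 1 = filament foreground
        r, c = divmod(i, grid.cols)
        out[r * side:(r + 1) * side, c * side:(c + 1) * side] = p
    return out


def binarize_mask(prediction: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a [0, 1] probability map to a {0, 1} mask."""
    pred = np.asarray(prediction, dtype=np.float64)
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("prediction values must lie in [0, 1]")
    return (pred >= threshold).astype(np.uint8)


def apply_mask(test_img: IntensityImage, mask: np.ndarray) -> IntensityImage:
    """Multiply the binary mask with the test image: intensities inside the
    mask are preserved exactly, everything outside is zero."""
    mask = np.asarray(mask)
    if mask.shape != test_img.shape:
        raise ValueError("mask and image shapes must match")
    out = test_img.pixels * (mask > 0)
    return IntensityImage(out, bit_depth=test_img.bit_depth,
                          pitch_xy=test_img.pitch_xy)


def fwhm(profile: LineProfile) -> float:
    """Full width at half maximum of a line profile, in nm.

    The background is the profile minimum; the half-max level lies midway
    between background and peak.  Crossings on each side of the (unique)
    global maximum are located by linear interpolation between samples.
    Invariant under uniform intensity scaling and additive offsets.
    """
    y = profile.intensities
    x = profile.positions
    bg = y.min()
    peak = y.max()
    if peak == bg:
        raise ValueError("flat profile has no peak")
    level = bg + (peak - bg) / 2.0
    i_max = int(y.argmax())

    def cross(direction: int) -> float:
        i = i_max
        while 0 <= i + direction < len(y):
            j = i + direction
            if y[j] < level:
                # linear interpolation between samples i and j
                frac = (y[i] - level) / (y[i] - y[j])
                return x[i] + frac * (x[j] - x[i])
            i = j
        raise ValueError("profile does not cross half maximum on one side")

    return abs(cross(+1) - cross(-1))


def extract_row_profile(img, row: int, pitch_nm=None) -> LineProfile:
    """Horizontal intensity profile along a given row."""
    arr = img.pixels if isinstance(img, IntensityImage) else np.asarray(img)
    pitch = float(img.pitch_xy) if isinstance(img, IntensityImage) else float(pitch_nm)
    vals = arr[row].astype(np.float64)
    pos = np.arange(arr.shape[1]) * pitch
    return LineProfile(positions=pos, intensities=vals)


def extract_profile(arr: np.ndarray, pitch_nm: float, center_px: tuple,
                    direction: tuple, half_len_nm: float,
                    step_nm: float) -> LineProfile:
    """Sample a straight profile through ``center_px`` (row, col) along a
    unit ``direction`` (drow, dcol), by bilinear interpolation."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    s = np.arange(-half_len_nm, half_len_nm + step_nm / 2, step_nm)
    rows = center_px[0] + s / pitch_nm * d[0]
    cols = center_px[1] + s / pitch_nm * d[1]
    vals = map_coordinates(np.asarray(arr, dtype=np.float64), [rows, cols],
                           order=1, mode="nearest")
    return LineProfile(positions=s - s[0], intensities=np.maximum(vals, 0.0))


def image_metrics(result: IntensityImage, reference: IntensityImage):
    """(SSIM, PSNR) of a result against a reference over the full frame.

    SSIM uses the standard Gaussian window (sigma 1.5, K1=0.01, K2=0.03);
    PSNR of identical images is reported as the PSNR_CAP_DB sentinel.
    """
    if result.shape != reference.shape:
        raise ValueError("images must share the same shape")
    if result.bit_depth != reference.bit_depth:
        raise ValueError("images must share the same bit depth")
    rng = 2**result.bit_depth - 1
    a = result.astype_float()
    b = reference.astype_float()
    ssim = float(structural_similarity(
        a, b, data_range=rng, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
    ))
    if np.array_equal(result.pixels, reference.pixels):
        psnr = PSNR_CAP_DB
    else:
        psnr = min(float(peak_signal_noise_ratio(b, a, data_range=rng)),
                   PSNR_CAP_DB)
    return ssim, psnr


def stack_3d(slices: list, pitch_z=Fraction(250)) -> ImageStack:
    """Assemble registered result slices into a z-stack."""
    return ImageStack(list(slices), pitch_z=pitch_z)


def max_intensity_projection(stack: ImageStack) -> IntensityImage:
    """Maximum-intensity projection along z."""
    arr = stack.as_array().max(axis=0)
    return IntensityImage(arr, bit_depth=stack.bit_depth,
                          pitch_xy=stack.pitch_xy)
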