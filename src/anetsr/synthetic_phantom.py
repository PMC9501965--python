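"""Synthetic filament phantoms and the confocal degradation model.

No public microtubule dataset accompanies the imaging regime this package
targets, so the phantom generator provides paired data for every stage:
sparse, smoothly curved bright filaments on a dark background (the
high-resolution truth H), blurred by the confocal point-spread function f,
resampled to the detector pitch, and corrupted by Poisson shot noise plus
Gaussian read noise (N), quantized to 16 bits:

    L = H * f + N

Filaments are random splines with bounded curvature, rendered at a
supersampled pitch well below the target pixel interval.  Each phantom
carries its ground-truth centerline, so segmentation and resolution
metrics can be scored against exact geometry.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_image import IntensityImage, _as_fraction, write_tiff
from .preprocess import OpticalModel, psf_radii

__all__ = [
    "FilamentScene",
    "NoiseModel",
    "TruthRender",
    "PhantomPair",
    "PhantomConfig",
    "generate_scene",
    "render_truth",
    "degrade",
    "centerline_mask",
    "generate_pair",
    "make_pairs",
    "make_dataset",
]

# FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
FWHM_PER_SIGMA = 2.3548200450309493


@dataclass
class FilamentScene:
    """Ground-truth filament geometry within a square physical field.

    ``curves`` are dense (N, 2) arrays of (x, y) points in nm tracing each
    filament centerline; ``amplitude`` is the peak emission intensity (in
    detector counts per pixel of centerline at the rendering pitch).
    """

    curves: list
    width_nm: float = 50.0
    amplitude: float = 3000.0
    field_nm: float = 16000.0
    seed: int | None = None

    def __post_init__(self):
        if self.field_nm <= 0:
            raise ValueError("field_nm must be positive")
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        for c in self.curves:
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[1] != 2:
                raise ValueError("each curve must be an (N, 2) point array")
            if c.min() < 0 or c.max() > self.field_nm:
                raise ValueError("curves must lie within the field")


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Poisson shot noise, Gaussian read noise, dark offset."""

    gaussian_sigma: float = 10.0
    poisson: bool = True
    offset: float = 100.0

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass
class TruthRender:
    """Supersampled truth: continuous intensity plus a centerline mask."""

    intensity: np.ndarray  # float, nonnegative
    centerline: np.ndarray  # bool, same shape
    pitch_nm: Fraction


@dataclass
class PhantomPair:
    """One training/test example: truth geometry, degraded observation and
    the binary label at the observed pitch (dilated centerline)."""

    truth: TruthRender
    observed: IntensityImage
    label: np.ndarray  # bool, observed-pitch grid
    scene: FilamentScene
    index: int = 0


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for phantom generation.

    Defaults mirror the confocal regime: 250 nm detector pitch over a
    16 um field (64 px), 640 nm excitation with NA 1.4 oil immersion,
    sub-resolution 50 nm filaments, and moderate shot + read noise.
    """

    field_nm: float = 16000.0
    out_pitch_nm: Fraction = Fraction(250)
    supersample_pitch_nm: Fraction = Fraction(125, 4)  # 31.25 nm
    n_filaments: tuple = (2, 5)
    width_nm: float = 50.0
    amplitude: float = 3000.0
    optical: OpticalModel = field(default_factory=OpticalModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    label_radius_px: int = 1

    def __post_init__(self):
        object.__setattr__(self, "out_pitch_nm", _as_fraction(self.out_pitch_nm))
        object.__setattr__(
            self, "supersample_pitch_nm", _as_fraction(self.supersample_pitch_nm)
        )
        if self.out_pitch_nm % self.supersample_pitch_nm != 0:
            raise ValueError(
                "out_pitch_nm must be an integer multiple of supersample_pitch_nm"
            )


def _random_curve(rng: np.random.Generator, field_nm: float) -> np.ndarray:
    """One smooth random filament: a heading random walk with bounded
    curvature, steered back toward the field center near the borders."""
    margin = 0.05 * field_nm
    step = field_nm / 320.0
    length = rng.uniform(0.5, 0.9) * field_nm
    n = max(8, int(length / step))
    p = rng.uniform(0.15 * field_nm, 0.85 * field_nm, size=2)
    theta = rng.uniform(0, 2 * np.pi)
    pts = [p.copy()]
    for _ in range(n - 1):
        # stiff, fiber-like bending: small heading diffusion per step
        theta += np.clip(rng.normal(0.0, 0.03), -0.10, 0.10)
        cand = p + step * np.array([np.cos(theta), np.sin(theta)])
        if (cand < margin).any() or (cand > field_nm - margin).any():
            center = np.array([field_nm / 2, field_nm / 2])
            back = center - p
            theta = np.arctan2(back[1], back[0]) + rng.normal(0.0, 0.2)
            cand = p + step * np.array([np.cos(theta), np.sin(theta)])
        p = np.clip(cand, 0.0, field_nm)
        pts.append(p.copy())
    return np.array(pts)


def generate_scene(n_filaments: int, field_nm: float = 16000.0,
                   seed: int | None = 0, *, width_nm: float = 50.0,
                   amplitude: float = 3000.0,
                   rng: np.random.Generator | None = None) -> FilamentScene:
    """Draw a reproducible random scene of ``n_filaments`` smooth curves."""
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    if field_nm <= 0:
        raise ValueError("field_nm must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    curves = [_random_curve(rng, field_nm) for _ in range(n_filaments)]
    return FilamentScene(curves=curves, width_nm=width_nm, amplitude=amplitude,
                         field_nm=field_nm, seed=seed)


def _resample_arclength(curve: np.ndarray, ds: float) -> np.ndarray:
    """Resample a polyline at uniform arclength spacing ``ds``."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return curve[:1]
    u = np.arange(0.0, total, ds)
    x = np.interp(u, s, curve[:, 0])
    y = np.interp(u, s, curve[:, 1])
    return np.column_stack([x, y])


def curve_length(curve: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(curve), axis=0), axis=1).sum())


def render_truth(scene: FilamentScene,
                 supersample_pitch_nm=Fraction(125, 4)) -> TruthRender:
    """Rasterize the scene at a supersampled pitch.

    Intensity is deposited along each centerline with bilinear splatting so
    that the integrated intensity equals ``amplitude * length / pitch``; a
    Gaussian cross-section of FWHM ``width_nm`` then gives the filament its
    physical width.  The boolean mask marks centerline pixels.
    """
    pitch = _as_fraction(supersample_pitch_nm)
    if float(pitch) > 63.0:
        raise ValueError("supersample pitch must be <= 63 nm")
    npx = int(round(scene.field_nm / float(pitch)))
    img = np.zeros((npx, npx))
    mask = np.zeros((npx, npx), dtype=bool)
    p = float(pitch)
    ds = p / 4.0
    for curve in scene.curves:
        pts = _resample_arclength(np.asarray(curve, float), ds)
        # pixel-center convention: pixel (r, c) covers [c*p, (c+1)*p) in x
        cx = pts[:, 0] / p - 0.5
        cy = pts[:, 1] / p - 0.5
        w = scene.amplitude * ds / p
        x0 = np.floor(cx).astype(int)
        y0 = np.floor(cy).astype(int)
        fx = cx - x0
        fy = cy - y0
        for dx, dy, wt in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            xi = x0 + dx
            yi = y0 + dy
            ok = (xi >= 0) & (xi < npx) & (yi >= 0) & (yi < npx)
            np.add.at(img, (yi[ok], xi[ok]), w * wt[ok])
        mr = np.clip(np.rint(cy).astype(int), 0, npx - 1)
        mc = np.clip(np.rint(cx).astype(int), 0, npx - 1)
        mask[mr, mc] = True
    if scene.curves:
        sigma_px = scene.width_nm / FWHM_PER_SIGMA / p
        if sigma_px > 0.15:
            img = ndimage.gaussian_filter(img, sigma_px, mode="constant")
    return TruthRender(intensity=img, centerline=mask, pitch_nm=pitch)


def degrade(truth: TruthRender, optical: OpticalModel, noise: NoiseModel,
            out_pitch_nm=Fraction(250), seed: int | None = 0,
            rng: np.random.Generator | None = None) -> IntensityImage:
    """Apply the observation model to a truth render.

    Convolve with the transverse Gaussian PSF (sigma = r_perp, the same
    reading of the optical radii used by the interpolation kernel), sum-bin
    down to the detector pitch, add the dark offset, apply Poisson then
    Gaussian noise, and quantize to 16 bits with clipping.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out_pitch = _as_fraction(out_pitch_nm)
    ratio = out_pitch / truth.pitch_nm
    if ratio.denominator != 1 or ratio < 1:
        raise ValueError("out_pitch_nm must be an integer multiple of the supersample pitch")
    factor = int(ratio)

    r_perp, _ = psf_radii(optical)
    sigma_nm = r_perp
    p = float(truth.pitch_nm)
    field_nm = truth.intensity.shape[0] * p
    if 6.0 * sigma_nm > field_nm:
        raise ValueError("PSF support exceeds the field of view")
    sigma_px = sigma_nm / p
    blurred = truth.intensity
    if sigma_px >= 0.3:  # below this the kernel is effectively a delta
        blurred = ndimage.gaussian_filter(blurred, sigma_px, mode="constant")
    if factor > 1:
        n = blurred.shape[0] // factor * factor
        blurred = blurred[:n, :n]
        blurred = blurred.reshape(
            n // factor, factor, n // factor, factor
        ).sum(axis=(1, 3))
    counts = blurred + noise.offset
    if noise.poisson:
        counts = rng.poisson(counts).astype(np.float64)
    if noise.gaussian_sigma > 0:
        counts = counts + rng.normal(0.0, noise.gaussian_sigma, counts.shape)
    out = np.clip(np.floor(counts + 0.5), 0, 65535).astype(np.uint16)
    return IntensityImage(out, bit_depth=16, pitch_xy=out_pitch)


def centerline_mask(scene: FilamentScene, pitch_nm, shape: tuple,
                    radius_px: int = 0) -> np.ndarray:
    """Rasterize curve centerlines onto a grid of given pitch, optionally
    dilated with a disk of ``radius_px`` (the phantom's binary label)."""
    p = float(_as_fraction(pitch_nm))
    mask = np.zeros(shape, dtype=bool)
    for curve in scene.curves:
        pts = _resample_arclength(np.asarray(curve, float), p / 4.0)
        r = np.clip(np.rint(pts[:, 1] / p - 0.5).astype(int), 0, shape[0] - 1)
        c = np.clip(np.rint(pts[:, 0] / p - 0.5).astype(int), 0, shape[1] - 1)
        mask[r, c] = True
    if radius_px > 0 and mask.any():
        yy, xx = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
        disk = yy**2 + xx**2 <= radius_px**2
        mask = ndimage.binary_dilation(mask, structure=disk)
    return mask


def generate_pair(config: PhantomConfig, seed: int, index: int = 0) -> PhantomPair:
    """Generate one (truth, observed, label) phantom pair."""
    rng = np.random.default_rng(seed)
    nf = int(rng.integers(config.n_filaments[0], config.n_filaments[1] + 1))
    scene = generate_scene(
        nf, config.field_nm, seed=seed, width_nm=config.width_nm,
        amplitude=config.amplitude, rng=rng,
    )
    truth = render_truth(scene, config.supersample_pitch_nm)
    observed = degrade(truth, config.optical, config.noise,
                       config.out_pitch_nm, rng=rng)
    label = centerline_mask(scene, config.out_pitch_nm, observed.shape,
                            radius_px=config.label_radius_px)
    return PhantomPair(truth=truth, observed=observed, label=label,
                       scene=scene, index=index)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent per-image seeds derived from one dataset seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_pairs(n: int, config: PhantomConfig, seed: int = 0,
               start_index: int = 0) -> list[PhantomPair]:
    """Generate ``n`` independent phantom pairs in memory."""
    seeds = _child_seeds(seed, n)
    return [generate_pair(config, s, index=start_index + i)
            for i, s in enumerate(seeds)]


def make_dataset(n_train: int, n_test: int, config: PhantomConfig,
                 seed: int, out_dir, force: bool = False) -> Path:
    """Write a paired phantom dataset (observed + label TIFFs and a CSV
    manifest) and return the manifest path.

    Counts default to a scaled-down study (e.g. 40 train / 10 test) and are
    configurable up to the full 200/50 composition.  Two runs with the same
    seed produce byte-identical files.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    out_dir = Path(out_dir)
    manifest = out_dir / "manifest.csv"
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty; use force=True")
    (out_dir / "train").mkdir(parents=True, exist_ok=True)
    (out_dir / "test").mkdir(parents=True, exist_ok=True)

    pairs = make_pairs(n_train + n_test, config, seed)
    rows = []
    for i, pair in enumerate(pairs):
        split = "train" if i < n_train else "test"
        k = i if i < n_train else i - n_train
        obs_rel = f"{split}/observed_{k:04d}.tif"
        lab_rel = f"{split}/label_{k:04d}.tif"
        write_tiff(out_dir / obs_rel, pair.observed)
        lab8 = IntensityImage((pair.label * 255).astype(np.uint8), bit_depth=8,
                              pitch_xy=config.out_pitch_nm)
        write_tiff(out_dir / lab_rel, lab8)
        rows.append((split, k, obs_rel, lab_rel))
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["split", "index", "observed", "label"])
        w.writerows(rows)
    return manifest
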