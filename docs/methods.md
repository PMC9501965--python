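# Methods

## Observation model

The pipeline assumes the standard degradation model for a fluorescence
image: the recorded low-resolution image L is the high-resolution
structure H convolved with the system point-spread function f, plus
noise N,

    L = H ∗ f + N.

The PSF is parameterized by the excitation wavelength λₑ (nm), the
numerical aperture NA, and the medium refractive index n, through the
transverse and axial radii

    r⊥ = 0.61 λₑ / NA,        r∥ = 4 n λₑ / (2 NA²).

Defaults (λₑ = 640 nm, NA = 1.4, n = 1.515, oil immersion) give
r⊥ ≈ 278.9 nm and r∥ ≈ 989.4 nm.

**One reading of the radii everywhere.** The radii enter three places:
the 3D interpolation kernel, the phantom degradation PSF, and the
Lucy–Richardson deconvolution PSF. In all three the radii are used
directly as Gaussian σ parameters (σ⊥ = r⊥, σ∥ = r∥), i.e. the
transverse PSF FWHM is 2.355·r⊥ ≈ 656 nm. An alternative would be to
read r⊥ as the FWHM itself (σ = r⊥/2.355 ≈ 118 nm); we chose the
σ = r convention because (a) the interpolation kernel is written with r
in the σ position, and a single convention avoids a silent 2.355×
inconsistency between the stages that blur and the stage that deblurs;
and (b) the resulting degraded filament widths (measured FWHM
≈ 0.7–0.9 µm on phantoms, inflated above 656 nm by curvature, crossings
and noise) match the width regime of the confocal imagery this pipeline
targets, where observed profiles are of order 1 µm. The choice is a
modeling convention, not a fit; both conventions are internally
consistent for deconvolution since the same PSF is used to blur and to
deblur.

## Preprocessing

*Threshold denoising* zeroes pixels below a hard threshold t; when t is
not supplied, Otsu's histogram threshold is used (the threshold value is
data-dependent and not prescribed by the method).

*3D Gaussian interpolation* is applied as successive 2× passes (default
two). Each pass doubles the sampling along x, y and z; a new sub-voxel
value is the weight-normalized Gaussian average of the *original*
samples within a 3σ support, with the anisotropic kernel above sampled
at the fine pitch; original sample sites keep their values exactly.
Two passes map 512×512 at 250 nm to 2048×2048 at 62.5 nm and a 1 µm z
interval to 250 nm. "Performed twice" is implemented as two 2× passes
rather than one 4× pass because only the former reproduces the ×4 size
arithmetic in both x–y and z. Output values are convex combinations of
inputs, hence bounded by the input range; a constant stack is a fixed
point. Pitches are stored as exact rationals (62.5 nm = 125/2); the
displayed "63 nm" arises only from round-half-up display. Single-slice
stacks are interpolated in x–y only, with a logged warning.

## DWDC label generation

Binary training labels are produced classically: (1) multilevel 2D
discrete-wavelet shrinkage (default sym4, 3 levels, BayesShrink soft
thresholds, noise scale from the MAD of the finest diagonal subband;
"universal" and "none" rules are also available — "none" round-trips
exactly, which the tests use as a perfect-reconstruction check);
(2) Lucy–Richardson deconvolution, iterating

    x_{k+1} = x_k · ( f̃ ∗ ( L / (f ∗ x_k) ) ),   x_0 = L,

with the ratio denominator guarded at 1e-12 and reflective boundary
padding (zero padding causes edge ringing that corrupts tiles); 30
iterations by default; (3) hard binarization at Otsu's threshold of the
deconvolved image (configurable). The deconvolution PSF is the
transverse Gaussian sampled at the image's own pitch, truncated at 3σ.
Richardson–Lucy preserves nonnegativity and, for interior-supported
signal, total flux; the tests verify monotone ascent of the Poisson
log-likelihood against a brute-force evaluation and agreement with an
independent implementation (scikit-image) to a few percent despite its
different initialization.

On a well-separated phantom filament the binarized label's skeleton
lies within 2 px (125 nm at the interpolated pitch) of the true
centerline for 100% of its length. Where a filament approaches itself
within the PSF range, the blurred strands merge and no intensity-based
method can separate them — the skeleton then runs between the strands.
This is a resolution limit of the observation, not of the
implementation; the localization oracle therefore uses a controlled
non-self-approaching arc.

## A-net

The network is an encoder–decoder with `depth` levels (default 4).
Every block is conv3×3 → batch-norm → ReLU, twice; 2×2 max pooling
descends, 2×2 stride-2 transposed convolutions ascend, and a 1×1
convolution maps to M = 2 classes (filament / background). All
convolutions are *same* (zero-padded), so encoder and decoder maps at
equal levels have identical spatial size and skips concatenate without
cropping; the output equals the input size, which must be divisible by
2^depth. Channel widths double per level from `base_channels` (default
64, giving the 1024-channel bottleneck at depth 4; the bottleneck side
is input/2^depth: 32 for 512 input, 128 for 2048). Conv→BN→ReLU
ordering is used as stated; batch statistics are spatial (minibatch 1).

The loss is weighted cross-entropy on the pixel-wise softmax. The
printed form of the objective omits a minus sign; it is implemented as
the negative log-likelihood −Σ ω(x) log P_{g(x)}(x), the only reading
under which "penalize deviation from 1" and minimization coexist. The
weight map, computed once per label, is

    ω(x) = w_class(g(x)) + w₀ · exp(−d(x)² / 2σ_w²),

with d the Euclidean distance to the nearest class boundary,
w_class(c) = N/(2·N_c) inverse-frequency balancing, and w₀ = 10,
σ_w = 5 px (the usual boundary-emphasis convention; the method does not
prescribe values). A uniform label has no boundary and reduces to the
class term.

Training uses Adam (lr 1e-3, β = 0.9/0.999), minibatch 1, per-tile
standardization of inputs, and a single global RNG for initialization
and data order, making runs bit-reproducible for a fixed seed. The best
state by validation loss (training loss when no validation set is
given) is restored at the end. Since no GPU framework is assumed, the
forward and backward passes are written out on numpy (im2col + GEMM
convolutions, float32); at the reference scale (512×512, depth 4) this
is slow, and the shipped experiments use scaled configurations.

## Synthetic phantoms

The generator emulates sparse curved bright filaments on a dark
background. Centerlines are heading random walks with small per-step
angular diffusion (σ = 0.03 rad per 12.5 nm step, clipped at 0.1),
reflecting the near-millimetre persistence length of microtubules: at a
few-micron field they are gently curved fibers. Curves are rendered at
a supersampled pitch (default 31.25 nm) by arclength-uniform bilinear
splatting (total intensity = amplitude × length / pitch) with a
Gaussian cross-section of FWHM `width_nm` (default 50 nm — above the
24 nm physical filament, well below the PSF, so blur dominates).
Degradation follows L = H∗f+N: Gaussian PSF, sum-binning to the
detector pitch (default 250 nm), dark offset (100 counts), Poisson shot
noise, Gaussian read noise (σ = 10 counts), 16-bit quantization with
clipping. Per-image RNG streams are spawned from one dataset seed, so
datasets are byte-identical across runs with the same seed. Default
peak amplitude 3000 counts gives filament peaks a few hundred counts
above background after blur — a moderate-SNR confocal regime.

What the phantoms do **not** emulate: out-of-focus haze and "flocculent"
background structure, spatially varying background, PSF aberrations and
axial blur in 2D images, detector gain nonlinearity, and the density
and branching complexity of a real cytoskeleton. Passing phantom tests
therefore demonstrates that the pipeline's machinery is correct and
that it recovers sub-PSF structure under the stated observation model —
not that real-tissue performance figures carry over.

## Scaled end-to-end experiment

The reference-scale study (200 training pairs of 512×512 tiles, 200
epochs) is impractical on one CPU, so the shipped experiment preserves
the structure at reduced size: 40 train / 10 test phantoms of 64×64 px
generated directly at the interpolated pitch (62.5 nm, 4 µm field —
the scale at which the network operates in the full pipeline), a
depth-2, 16-channel A-net, 30 epochs, minibatch 1, Adam. Labels are the
exact centerlines dilated by 1 px (≈3 px ≈ 190 nm wide, comparable to
DWDC label sharpness); DWDC is validated separately by its skeleton
oracle rather than inside the training loop, keeping the experiment's
ground truth exact. Scores: pooled foreground IoU of the binarized
predictions against phantom truth, and the resolution gain as the ratio
of mean perpendicular-cut FWHMs (cuts at fixed arclength fractions of
each true centerline, ±1 µm window at half-pitch sampling; cuts are
discarded when they leave the frame or their peak falls more than 4
samples from the cut center, which rejects cuts contaminated by a
neighboring filament). Typical results (seeds 0–2): IoU 0.63–0.66,
degraded FWHM 0.77–0.88 µm, result FWHM 0.23–0.26 µm, gain 2.8–3.3×
over 20+ valid cuts. The absolute values reported on real cytoskeleton
data by FWHM metrology (µm-scale test widths shrinking to ~100–250 nm)
require the original microscope data and are out of scope; the ratio
and ordering properties are the desk-reproducible analog.

## Numerical choices and edge cases

- 16→8-bit conversion: fixed full-range scaling round(v·255/65535)
  (round half up), keeping intensities comparable across images;
  per-image min–max stretch available as an option. It is monotone and
  surjective onto 0…255.
- Tiling is strictly non-overlapping with no seam blending; assembly is
  its exact inverse. Non-divisible sides are an error (no padding).
- FWHM: background is the profile minimum; half-max crossings located
  by linear interpolation between samples on each side of the unique
  global maximum; flat or non-crossing profiles are errors. The measure
  is invariant to uniform scaling and additive offsets.
- SSIM/PSNR: scikit-image with the Gaussian 11-px window (σ 1.5,
  K1 = 0.01, K2 = 0.03), full frame, data range from the bit depth;
  PSNR of identical images is reported as a 100 dB cap sentinel.
- Prediction mask threshold 0.5 on the foreground probability
  (configurable).
- Degenerate inputs: empty scenes render zero images and degrade to
  pure background noise; all-zero inputs produce all-zero labels; a PSF
  wider than the field is rejected.

## Known limitations

- The numpy network is single-threaded-friendly but far slower than a
  GPU framework; reference-scale training is not practical with it.
- Deconvolution and interpolation are 2D-per-slice (plus z-aware
  interpolation); no 3D deconvolution.
- Blind deconvolution is out of scope: the PSF is always derived from
  the supplied optics.
- Filament crossings closer than the PSF width are not separable by the
  label generator (see above), and the phantom's realism limits are
  listed in the phantom section.
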