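# anetsr

Super-resolution restoration of filament-like structures (microtubules)
from low-resolution, noisy confocal fluorescence images.

Confocal images of the cytoskeleton are limited by the optical point-spread
function and by detector sampling: at a typical 0.25 µm pixel pitch, a
24 nm microtubule appears as a blurred band several hundred nanometres
wide, buried in shot noise. `anetsr` implements a full pipeline that
recovers the filament sketch from such images:

1. **Preprocessing** — hard threshold denoising, then two passes of 3D
   Gaussian interpolation with the anisotropic optical kernel
   g = g₀·exp[−((x−x_c)² + (y−y_c)²)/2r⊥² − (z−z_c)²/2r∥²], where
   r⊥ = 0.61 λₑ/NA and r∥ = 4 n λₑ/(2 NA²). Each pass doubles the x, y
   and z sampling: 512×512 px at 250 nm / 1 µm z becomes 2048×2048 at
   62.5 nm (displayed as 63 nm) / 250 nm z.
2. **Label generation (DWDC)** — discrete-wavelet shrinkage plus
   Lucy–Richardson deconvolution against the optical PSF, followed by
   binarization, turns interpolated originals into high-resolution binary
   labels.
3. **A-net** — a U-net variant in which every valid convolution is a
   *same* convolution, so encoder/decoder feature maps match in size, skip
   connections concatenate without cropping, and the output equals the
   input size. Trained with a pixel-wise softmax
   Pᵢ(x) = exp aᵢ(x) / Σⱼ exp aⱼ(x) and boundary-weighted cross-entropy
   E = −Σ_x ω(x) log P_{g(x)}(x), where ω adds a Gaussian-of-distance
   boost near label boundaries. The network is implemented directly on
   numpy (explicit forward/backward passes, Adam), sized for CPU use.
4. **Postprocessing and metrology** — tile-wise prediction and
   reassembly, binarization of the foreground probability, multiplication
   with the test image, and evaluation by the full width at half maximum
   (FWHM) of intensity line profiles, SSIM/PSNR, and 3D z-stack assembly.

Because no public dataset exists for this regime, the package includes a
**synthetic filament phantom** generator: stiff random spline filaments
with exact ground-truth centerlines, degraded through the observation
model L = H∗f + N (Gaussian PSF, pixel binning, Poisson shot noise,
Gaussian read noise, 16-bit quantization). Every pipeline stage can
therefore be scored against exact geometry, offline.

## Worked example

`examples/04_train_anet.py` trains a small A-net on 16 phantom pairs
(64×64 px at the interpolated 62.5 nm pitch) for 20 epochs and segments a
held-out phantom:

```
epoch  0  loss 3.8337
epoch  4  loss 1.6025
epoch  8  loss 0.9766
epoch 12  loss 0.6230
epoch 16  loss 0.4262
held-out foreground IoU vs phantom truth: 0.676
```

The loss is the boundary-weighted cross-entropy per pixel; IoU compares
the binarized prediction against the exact filament geometry.
`examples/05_evaluate_resolution.py` then measures resolution with
perpendicular-cut FWHM metrology:

```
test foreground IoU:        0.466
degraded FWHM (mean of 22 cuts):  710.0 nm
result   FWHM (mean of 27 cuts):  241.6 nm
resolution gain:            2.94x
```

The degraded width reflects the ~656 nm PSF blur; masking the input with
the network's binarized prediction recovers profiles a few pixels wide.
The other examples cover phantom dataset generation, preprocessing
arithmetic, and DWDC label accuracy (each prints what its numbers mean).

A thin CLI mirrors the library:

```
anet-sr phantom data/ --n-train 40 --n-test 10 --seed 1
anet-sr preprocess raw.tif interp.tif --lambda 640 --na 1.4 --n 1.515
anet-sr label interp.tif label.tif --rl-iters 30
anet-sr train --data data/manifest.csv --config cfg.yaml --out model.npz
anet-sr predict test.tif result.tif --model model.npz
anet-sr evaluate result.tif test.tif --profile-row 120
```

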