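"""Generate a binary training label with the DWDC restoration chain.

A single curved phantom filament is degraded through the confocal model,
then restored by wavelet shrinkage + Lucy-Richardson deconvolution and
binarized.  The label skeleton is compared against the exact centerline.
"""

from fractions import Fraction

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize

from anetsr import DwdcConfig, FilamentScene, NoiseModel, OpticalModel, make_label
from anetsr.synthetic_phantom import centerline_mask, degrade, render_truth

t = np.linspace(0.15, 0.85, 200)
x = t * 8000.0
y = 4000.0 + 1200.0 * np.sin(np.pi * (t - 0.15) / 0.7)
scene = FilamentScene(curves=[np.column_stack([x, y])], field_nm=8000.0)

truth = render_truth(scene, Fraction(125, 4))
observed = degrade(truth, OpticalModel(), NoiseModel(10.0, True, 100.0),
                   Fraction(125, 2), seed=7)
label = make_label(observed, OpticalModel(), DwdcConfig(rl_iters=30))

skeleton = skeletonize(label > 0)
centerline = centerline_mask(scene, Fraction(125, 2), observed.shape)
dist = distance_transform_edt(~centerline)[skeleton]
print(f"label foreground fraction: {label.mean():.4f}")
print(f"skeleton pixels: {skeleton.sum()}")
print(f"skeleton within 2 px of true centerline: {(dist <= 2).mean():.1%}")
# the deconvolved, binarized label localizes the filament to ~2 px
# (~125 nm) even though the observed blur FWHM is ~10 px
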