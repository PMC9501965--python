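"""Train a small A-net on phantom pairs and segment a held-out image.

Quick-look settings (16 pairs, 20 epochs, depth 2) so the script runs in
about half a minute; the scaled study in scripts/acceptance.py uses
40 pairs and 30 epochs and reaches a higher IoU.
"""

import numpy as np

from anetsr import AnetConfig, TrainConfig, binarize_mask, predict_full, train
from anetsr.experiments import scaled_phantom_config
from anetsr.synthetic_phantom import make_pairs

pairs = make_pairs(17, scaled_phantom_config(), seed=0)
train_pairs, test_pair = pairs[:16], pairs[16]

result = train([(p.observed, p.label) for p in train_pairs],
               AnetConfig(depth=2, base_channels=16),
               TrainConfig(epochs=20, seed=0))
for h in result.history[::4]:
    print(f"epoch {h['epoch']:2d}  loss {h['train_loss']:.4f}")

prob = predict_full(test_pair.observed, result.model)
mask = binarize_mask(prob, 0.5)
inter = ((mask > 0) & test_pair.label).sum()
union = ((mask > 0) | test_pair.label).sum()
print(f"held-out foreground IoU vs phantom truth: {inter / union:.3f}")
# the per-epoch loss is the boundary-weighted cross-entropy per pixel;
# IoU compares the binarized prediction with the exact filament geometry
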