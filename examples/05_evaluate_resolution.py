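"""Measure the resolution gain of masked results with FWHM metrology.

Runs a compact end-to-end experiment and reports the mean full width at
half maximum of intensity cuts perpendicular to the true filament
centerlines, before (degraded input) and after (binarized prediction
multiplied with the input) processing.
"""

from anetsr.experiments import scaled_end_to_end

r = scaled_end_to_end(seed=0, n_train=12, n_test=6, epochs=15, depth=2)
print(f"test foreground IoU:        {r.iou:.3f}")
print(f"degraded FWHM (mean of {r.n_cuts_degraded:2d} cuts): {r.fwhm_degraded_nm:6.1f} nm")
print(f"result   FWHM (mean of {r.n_cuts_result:2d} cuts): {r.fwhm_result_nm:6.1f} nm")
print(f"resolution gain:            {r.fwhm_ratio:.2f}x")
# the degraded width reflects the ~656 nm PSF blur; masking with the
# network prediction recovers filament profiles a few pixels wide
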