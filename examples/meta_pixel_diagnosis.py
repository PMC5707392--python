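"""Diagnose pixel locking from the meta-pixel and undo it with SPIFF.

Simulates a biased sub-pixel estimator directly: true positions are uniform
within each pixel, but the estimator compresses the fractional part toward
the pixel center by an affine factor.  The meta-pixel (pooled fractional
parts) reveals the bias, the empirical-CDF map inverts it.
"""

import numpy as np

from spifftrack import apply_spiff, build_meta_pixel, fit_spiff_map, uniformity_test

rng = np.random.default_rng(0)
n = 10_000
true = np.column_stack([5 + rng.uniform(0, 1, n), 9 + rng.uniform(0, 1, n)])
# affine pixel-locking bias: fractional parts squeezed into [0.3, 0.7)
estimated = np.floor(true) + 0.5 + 0.4 * (true - np.floor(true) - 0.5)

mp = build_meta_pixel(estimated)
report = uniformity_test(mp)
print(f"meta-pixel of {mp.n} estimates: chi2_x = {report.chi2_x:.0f} "
      f"(p = {report.p_x:.2e}), KS_x = {report.ks_x:.3f}, "
      f"verdict: {'locked' if report.locked else 'not locked'}")

corrected = apply_spiff(estimated, fit_spiff_map(mp))
post = uniformity_test(build_meta_pixel(corrected))
print(f"after SPIFF: chi2_x = {post.chi2_x:.0f} (p = {post.p_x:.2f}), "
      f"KS_x = {post.ks_x:.3f}, verdict: {'locked' if post.locked else 'not locked'}")

pre_err = np.mean(np.abs(estimated - true))
post_err = np.mean(np.abs(corrected - true))
print(f"mean |error|: {pre_err:.3f} px biased -> {post_err:.3f} px corrected")
print("The biased estimates are 0.15 px off on average; the empirical-CDF map")
print("recovers the analytic inverse of the compression, so the corrected")
print("error is limited only by the finite sample.")
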