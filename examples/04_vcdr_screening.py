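"""Measure the vertical cup-to-disc ratio and classify, with ellipse refit.

The vCDR is the number of raster rows touched by the cup divided by the
rows touched by the disc region (labels 1 and 2 together).  Ragged mask
boundaries are first smoothed by refitting each region with the
least-squares ellipse of its boundary points — the refit barely moves a
clean mask but stabilizes a noisy one.
"""

import numpy as np

from fundus_vcdr import compute_vcdr, refit_mask_ellipses
from fundus_vcdr.synthetic import generate_samples

sample = generate_samples(0, 1, rng_seed=5, image_size=640)[0]
res = compute_vcdr(sample.mask)
print(f"disc spans {res.disc_vdiam} rows, cup {res.cup_vdiam} rows")
print(f"vCDR = {res.vcdr:.4f} -> {res.label} (strict > 0.5 rule)")
print(f"generator truth: {sample.true_vcdr:.4f}")

# simulate a segmentation failure: the network "bites off" the top six
# rows of the cup, then recover via ellipse refitting
noisy = sample.mask.copy()
cup_rows = np.flatnonzero((noisy == 2).any(axis=1))
bite = cup_rows[:6]
noisy[bite] = np.where(noisy[bite] == 2, 1, noisy[bite])
v_noisy = compute_vcdr(noisy).vcdr
refit = refit_mask_ellipses(noisy)
v_refit = compute_vcdr(refit.mask).vcdr
print(f"\nafter truncating the cup top: raw vCDR {v_noisy:.4f} "
      f"(error {abs(v_noisy - sample.true_vcdr):.4f})")
print(f"ellipse-refit vCDR {v_refit:.4f} "
      f"(error {abs(v_refit - sample.true_vcdr):.4f})")
print("the fitted ellipse extrapolates the missing cap from the remaining")
print("boundary, recovering most of the lost vertical extent.")
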