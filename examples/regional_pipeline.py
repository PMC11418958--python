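"""SUVR, reference-region selection and voxelwise condition statistics.

Builds the paired-condition metabolic phantom (white-matter +62%,
stable reference regions), auto-selects the reference region from the
regional change table, and runs the voxelwise mixed model with FDR
control to localise the hyperglycemia effect.
"""

import numpy as np

from neuroglyc import regional as rg
from neuroglyc import synth

images, parc, lookup, table, truth = synth.gen_regional_images(
    synth.RegionalImageConfig(seed=0))

delta = rg.regional_delta(table)
print("per-region mean change (hyper - eu):")
print(delta.sort_values("delta").to_string(index=False))

ref = rg.select_reference_region(delta, n_regions=3)
print(f"\nauto-selected reference region: {ref.labels}")

suvr = rg.compute_suvr(images[0][2], ref, parc, lookup)
ref_mask = rg.reference_mask(ref, parc, lookup)
print(f"SUVR reference-region mean (contract: 1.0): "
      f"{suvr.data[ref_mask].mean():.6f}")

res = rg.voxelwise_condition_model(images, q=0.05, smooth_fwhm_mm=0)
wm = truth.white_mask
print(f"\nsignificant voxels: {int(res.significant.sum())} "
      f"(white-matter sensitivity {res.significant[wm].mean():.2f})")

eu = np.mean([im.data for _, c, im in images if c == "eu"], axis=0)
hy = np.mean([im.data for _, c, im in images if c == "hyper"], axis=0)
r = rg.baseline_change_correlation(rg.VoxelImage(eu), rg.VoxelImage(hy - eu))
print(f"baseline-vs-change spatial correlation r = {r:.3f}")
print("\nThe strongly negative r says the metabolic increase concentrates "
      "where baseline consumption is lowest (white matter).")
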