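"""Seed connectivity map on a synthetic brain with a planted coupled region.

Builds one subject of the toy two-group dataset, maps wSDM connectivity
against the seed region, applies the 30th-percentile proportional
threshold, and prints how the planted target region stands out.
"""

import nibabel as nib
import numpy as np

from wsdm import SeedSpec, ToyBrainSpec, gen_toy_brain, proportional_threshold, seed_map

spec = ToyBrainSpec(n_controls=1, n_patients=0)
datasets, masks = gen_toy_brain(spec, rng=3)
subject = datasets[0]

ijk = np.argwhere(masks["seed"]).mean(axis=0)
center = tuple(nib.affines.apply_affine(subject.affine, ijk))
seed = SeedSpec(name="toy-seed", centers=(center,), radius_mm=6.0)

cmap = seed_map(subject, seed, measure="wsdm")
thr = proportional_threshold(cmap, 30.0)

inmask = thr.values[thr.mask]
target, background = masks["target"], thr.mask & ~masks["target"] & ~masks["seed"]
print(f"subject {subject.subject_id}: {subject.volume.shape} volume, TR {subject.tr_seconds}s")
print(f"retained after 30th-percentile threshold: {(inmask > 0).mean():.1%} of in-mask voxels")
print(f"mean wsdm in planted target region: {thr.values[target].mean():.3f}")
print(f"mean wsdm in background:            {thr.values[background].mean():.3f}")
print("\nThe target region couples (quadratically) to the seed's latent source, "
      "so its wsdm values sit well above background.")
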