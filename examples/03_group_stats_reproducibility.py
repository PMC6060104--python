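"""Group difference maps and cross-site reproducibility on the toy dataset.

Computes thresholded wSDM seed maps for 20 controls and 20 patients spread
over two simulated sites, tests controls > patients per site, intersects
the significant voxels (conjunction), and correlates the two sites' t-maps
(the reproducibility metric) for wSDM vs the Pearson baseline.
"""

import nibabel as nib
import numpy as np

from wsdm import (
    SeedSpec,
    ToyBrainSpec,
    compare_slopes,
    conjunction,
    gen_toy_brain,
    proportional_threshold,
    reproducibility,
    seed_map,
    two_sample_tmap,
)

spec = ToyBrainSpec()  # 20/20 subjects, two heterogeneous sites
datasets, masks = gen_toy_brain(spec, rng=1)
ijk = np.argwhere(masks["seed"]).mean(axis=0)
center = tuple(nib.affines.apply_affine(datasets[0].affine, ijk))
seed = SeedSpec(name="toy-seed", centers=(center,), radius_mm=6.0)

site_tmaps, reps = {}, {}
for measure in ("wsdm", "pearson"):
    maps = [proportional_threshold(seed_map(d, seed, measure), 30.0) for d in datasets]
    for site in ("site1", "site2"):
        hc = [m for m in maps if m.site_id == site and m.group == "control"]
        pt = [m for m in maps if m.site_id == site and m.group == "patient"]
        site_tmaps[site] = two_sample_tmap(hc, pt, alpha=0.001, extent=30)
        hit = (site_tmaps[site].significant & masks["target"]).sum()
        print(f"{measure:>8} {site}: {site_tmaps[site].significant.sum():3d} significant voxels "
              f"({hit} inside the true target region)")
    overlap = conjunction(site_tmaps["site1"], site_tmaps["site2"])
    reps[measure] = reproducibility(site_tmaps["site1"], site_tmaps["site2"])
    print(f"{measure:>8} conjunction across sites: {overlap.sum()} voxels; "
          f"reproducibility rho={reps[measure].rho:.3f} (p={reps[measure].p_value:.2g}), "
          f"slope={reps[measure].slope:.3f}")

t, p = compare_slopes(reps["wsdm"], reps["pearson"])
print(f"\nslope comparison wsdm vs pearson: t={t:.2f}, p={p:.2g}")
print("Patients couple to the seed more weakly than controls (0.2 vs 0.8, "
      "quadratic), so only the non-linear measure exposes the group difference "
      "consistently at both sites.")
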