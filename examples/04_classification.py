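"""Nested-CV classification of patients vs controls from seed-map features.

Runs the full feature pipeline for all three measures with a linear SVM:
inner folds select the proportional-threshold percentile, outer folds give
unbiased accuracy; a paired sign-flip permutation test compares measures.
"""

import nibabel as nib
import numpy as np

from wsdm import SeedSpec, ToyBrainSpec, compare_measures, gen_toy_brain, nested_cv, seed_map

datasets, masks = gen_toy_brain(ToyBrainSpec(), rng=1)
ijk = np.argwhere(masks["seed"]).mean(axis=0)
center = tuple(nib.affines.apply_affine(datasets[0].affine, ijk))
seed = SeedSpec(name="toy-seed", centers=(center,), radius_mm=6.0)

reports = {}
for measure in ("wsdm", "dm", "pearson"):
    maps = [seed_map(d, seed, measure) for d in datasets]
    rep = nested_cv(maps, classifier="svm", rng=1)
    reports[measure] = rep
    print(f"{measure:>8}: outer accuracy {rep.accuracy:.1%} "
          f"(pooled {rep.pooled_accuracy:.1%}), AUC {rep.auc:.2f}, "
          f"optimal percentile {rep.optimal_percentile:g}")

stat, p = compare_measures(reports["wsdm"], reports["pearson"])
print(f"\npaired fold-accuracy difference wsdm - pearson: {stat:+.3f} (p={p:.3f})")
print("The symbolic-weighted non-linear measure separates the groups; the "
      "linear baseline stays near chance because the planted coupling is quadratic.")
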