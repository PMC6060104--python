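import nibabel as nib
import numpy as np
import pytest

from wsdm.seedmap import SeedSpec, seed_map
from wsdm.simulate import ToyBrainSpec, gen_toy_brain

TOY_SEED = 1  # study-condition seed for the planted two-group scenario


@pytest.fixture(scope="session")
def toy_scenario():
    """Default two-group toy dataset: 20/20 subjects, quadratic coupling 0.8 vs 0.2."""
    spec = ToyBrainSpec()
    datasets, masks = gen_toy_brain(spec, rng=TOY_SEED)
    ijk = np.argwhere(masks["seed"]).mean(axis=0)
    center = tuple(nib.affines.apply_affine(datasets[0].affine, ijk))
    seed = SeedSpec(name="toy-seed", centers=(center,), radius_mm=6.0)
    return spec, datasets, masks, seed


@pytest.fixture(scope="session")
def toy_seed_maps(toy_scenario):
    """Per-subject seed maps for all three measures (shared: the expensive step)."""
    _, datasets, _, seed = toy_scenario
    return {
        measure: [seed_map(d, seed, measure) for d in datasets]
        for measure in ("wsdm", "dm", "pearson")
    }
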