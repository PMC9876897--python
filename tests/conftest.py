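import numpy as np
import pytest

import lexload as ll


@pytest.fixture(scope="session")
def planted_dataset():
    """Small dataset with one planted region (Chinese word / logo, r=0.7),
    well-separated blocks so the searchlight cannot bleed across regions."""
    cfg = ll.SimulationConfig(
        n_subjects=6, seed=7, n_regions=1, region_gap_voxels=4,
        effect_map={(1, "chinese_word", "logo"): 0.7},
    )
    return ll.simulate(cfg)


@pytest.fixture(scope="session")
def planted_maps(planted_dataset):
    """Searchlight maps for the planted condition of every subject."""
    return ll.run_searchlight_all(planted_dataset, conditions=["chinese_word"])


@pytest.fixture(scope="session")
def condition_specific_dataset():
    """Each condition planted in its own region — separable by design."""
    em = {
        (1, "chinese_word", "logo"): 0.7,
        (2, "english_word", "phonology"): 0.7,
        (3, "chinese_pinyin", "semantics"): 0.7,
    }
    cfg = ll.SimulationConfig(
        n_subjects=8, seed=11, n_regions=3, region_gap_voxels=4, effect_map=em,
    )
    return ll.simulate(cfg)


@pytest.fixture(scope="session")
def condition_specific_maps(condition_specific_dataset):
    return ll.run_searchlight_all(condition_specific_dataset)


def random_rdm(rng, n=15, component="logo"):
    vals = rng.uniform(0, 1, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return ll.DissimilarityMatrix(vals, [f"i{k:02d}" for k in range(n)], component)
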