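import numpy as np
import pytest

from enhancerclass.features import build_feature_matrix
from enhancerclass.pipeline import assemble_training_set
from enhancerclass.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact strong-signal dataset shared by classifier-level tests."""
    cfg = SyntheticConfig(
        seed=101,
        n_chroms=2,
        chrom_length=120_000,
        n_positives=120,
        n_motifs=6,
        n_driver_motifs=2,
        plants_per_enhancer=4.0,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    regions = assemble_training_set(small_dataset, seed=2101)
    return build_feature_matrix(
        small_dataset.genome,
        small_dataset.tracks,
        small_dataset.pwms,
        regions,
        feature_set="ALL",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
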