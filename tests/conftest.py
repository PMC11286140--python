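import numpy as np
import pytest

from zebrarep.features import extract_feature_table
from zebrarep.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact synthetic dataset shared across tests: 4 individuals at
    each of 2 locations, all four call types, 6 calls each."""
    out = tmp_path_factory.mktemp("smallds")
    cfg = SynthConfig(n_individuals_per_location=2, locations=("KSP", "GKZ"),
                      calls_per_individual_per_type=6, seed=7)
    paths, records, truth = generate_dataset(cfg, out)
    return dict(config=cfg, paths=paths, records=records, truth=truth, dir=out)


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    table, failures = extract_feature_table(small_dataset["records"])
    assert len(failures) == 0
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
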