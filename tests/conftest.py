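import numpy as np
import pytest

import amidoqsar as aq


@pytest.fixture(scope="session")
def study_set():
    return aq.packaged_dataset()


@pytest.fixture(scope="session")
def study_descriptors(study_set):
    return aq.descriptor_table(study_set)


@pytest.fixture(scope="session")
def study_dataset(study_set, study_descriptors):
    """Packaged compounds with the canonical seeded 29/7 split."""
    y = aq.log_transform([r.pct_inh_30uM for r in study_set])
    split = aq.activity_ranked_split(y, seed=1)
    split.index = study_set.ids
    return aq.build_dataset(study_set, study_descriptors, split=split)


@pytest.fixture(scope="session")
def study_model(study_dataset):
    model, report = aq.validate_model(study_dataset, seed=1)
    return model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
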