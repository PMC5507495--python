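import pytest

from seedlong import (SimConfig, generate_annotation_and_sugars,
                      generate_expression_dataset, normalize_and_log)


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(config):
    """(counts, design, truth) for the default ten-library design."""
    return generate_expression_dataset(config)


@pytest.fixture(scope="session")
def annotation(config):
    ann, sugars = generate_annotation_and_sugars(config)
    return ann


@pytest.fixture(scope="session")
def norm(dataset):
    counts, _design, _truth = dataset
    return normalize_and_log(counts)
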