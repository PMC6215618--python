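import pytest

import metaskim as ms


@pytest.fixture(scope="session")
def mock_profiles():
    """The built-in 10-strain community with desk-scale genomes."""
    return ms.default_mock_community(genome_length=100_000)


@pytest.fixture(scope="session")
def pool(mock_profiles):
    """A labelled synthetic read pool large enough for the full sampling plan
    (max sample size 50,000 + max skip 3,000)."""
    return list(ms.simulate_reads(mock_profiles, 60_000, read_length=101, seed=7))


@pytest.fixture(scope="session")
def pool_labels(pool):
    return [r.truth_label for r in pool]


@pytest.fixture(scope="session")
def roster(mock_profiles):
    return [p.name for p in mock_profiles]


@pytest.fixture(scope="session")
def pool_truth_table(pool, roster):
    """Full-pool hit table under the truth classifier (the pool's known composition)."""
    return ms.count_hits(pool, ms.classify_truth, roster)
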