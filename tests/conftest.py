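import logging

import pytest
from hypothesis import HealthCheck, settings

from mitochar import datasets
from mitochar.synthetic_data import default_spec, generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# generator/codon modules log expected warnings (clobbered stops etc.)
logging.getLogger("mitochar").setLevel(logging.ERROR)
for name in ("mitochar.codon_usage", "mitochar.io_genbank"):
    logging.getLogger(name).setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ref_features():
    """The published MN564936 annotation (38 rows incl. control region)."""
    return datasets.reference_features()


@pytest.fixture(scope="session")
def ref_length():
    return datasets.MN564936_LENGTH


@pytest.fixture(scope="session")
def ref_codon_counts():
    return datasets.reference_codon_counts()


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One default-template synthetic genome with ground truth."""
    return generate(default_spec(seed=20240624))


@pytest.fixture(scope="session")
def synthetic_bundles():
    """A batch of seeded synthetic genomes for recovery sweeps."""
    return [generate(default_spec(seed=s)) for s in range(12)]
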