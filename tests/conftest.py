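import warnings

import numpy as np
import pytest

from netrx.catalog import default_catalog
from netrx.communities import aggregate_clusters
from netrx.ggm import GlassoConfig, estimate_network
from netrx.synthetic import CohortConfig, sample_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def cohort2000(catalog):
    """A default-generator cohort large enough for stable estimation."""
    return sample_cohort(CohortConfig(n=2000, seed=42), catalog)


@pytest.fixture(scope="session")
def cohort313(catalog):
    """A cohort at the emulated study's own sample size."""
    return sample_cohort(CohortConfig(n=313, seed=7), catalog)


@pytest.fixture(scope="session")
def item_network(cohort2000):
    return estimate_network(cohort2000.items, GlassoConfig(n_lambdas=40))


@pytest.fixture(scope="session")
def cluster_scores(cohort2000, catalog):
    return aggregate_clusters(
        cohort2000.items, catalog, ideation=cohort2000.ideation
    )
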