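import logging

import pytest
from hypothesis import settings

from cfqrmap import cfqr, pipeline, synthetic
from cfqrmap import value_sets as vs

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

logging.getLogger("cfqrmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def uk():
    return vs.load_value_set("uk_tto")


@pytest.fixture(scope="session")
def item_map():
    return cfqr.load_item_map()


@pytest.fixture(scope="session")
def cohort():
    """Small study-sized synthetic cohort shared across tests."""
    return synthetic.generate_cohort(synthetic.CohortConfig(n=400, seed=20240301))


@pytest.fixture(scope="session")
def frame(cohort):
    """Analysis frame (recoded items + domains + utility) for the cohort."""
    return pipeline.prepare_analysis_frame(cohort)
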