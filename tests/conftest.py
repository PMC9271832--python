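import numpy as np
import pandas as pd
import pytest

from recallpsych.simulate import generate_cohort, paper_like_params, with_overrides
from recallpsych.taxonomy import default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def default_params():
    """Study-condition parameters at a small cohort size for fast tests."""
    return paper_like_params(n_participants=200, n_visits=3, seed=20260901)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """(responses, participants, truth) for a 200-participant cohort."""
    return generate_cohort(default_params)


@pytest.fixture()
def tiny_responses():
    """Complete 4-participant, 1-visit dataset (both stories/conditions)."""
    params = paper_like_params(n_participants=4, n_visits=1, seed=99)
    responses, participants, _ = generate_cohort(params)
    return responses, participants
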