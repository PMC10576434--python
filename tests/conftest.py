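import numpy as np
import pytest
from hypothesis import settings

import formopt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1() -> formopt.DesignTable:
    return formopt.load_table1()


@pytest.fixture(scope="session")
def canonical(table1):
    """The (Y1, Y2) quadratic models refit to the packaged design table."""
    return formopt.canonical_models()


@pytest.fixture(scope="session")
def printed_y1() -> formopt.QuadraticModel:
    return formopt.printed_model("Y1")


@pytest.fixture(scope="session")
def problem():
    """(objective_fn, (model_y1, model_y2), bounds) of the published search."""
    return formopt.study_problem()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
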