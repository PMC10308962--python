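import numpy as np
import pytest
from hypothesis import settings

from redoxzc.synth import SurveySpec, make_gibbs_fixture, make_reference_db

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_db():
    db, _ = make_reference_db(5, zc_low=-0.35, zc_high=-0.05, seed=11)
    return db


@pytest.fixture(scope="session")
def small_db_records():
    return make_reference_db(5, zc_low=-0.35, zc_high=-0.05, seed=11)


@pytest.fixture(scope="session")
def gibbs_fixture(small_db):
    return make_gibbs_fixture(small_db, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20230608)


@pytest.fixture
def survey_spec():
    return SurveySpec(n_datasets=3, samples_per_dataset=25, seed=5)
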