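import numpy as np
import pytest

from cadbmd import PopulationConfig, generate_population, study_tables


@pytest.fixture(scope="session")
def male_rbp_table():
    return study_tables.as_dose_group_table("rbp", "male", 90)


@pytest.fixture(scope="session")
def all_study_tables_90():
    return [study_tables.as_dose_group_table(t.biomarker, t.sex, 90)
            for t in study_tables.all_tables()]


@pytest.fixture(scope="session")
def large_population():
    """One large cohort shared by the statistical recovery tests."""
    cfg = PopulationConfig(n_per_sex=2500, seed=20160818 % (2**31))
    return generate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
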