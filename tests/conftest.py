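import numpy as np
import pytest

from ipcnet import (
    PipelineConfig,
    default_cohort_params,
    load_study_design,
    preprocess,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def study_design():
    return load_study_design()


@pytest.fixture(scope="session")
def cohort(study_design):
    """A moderate default-parameter cohort shared across read-only tests."""
    return simulate_cohort(study_design, n_respondents=80, seed=11)


@pytest.fixture(scope="session")
def processed(cohort):
    return preprocess(cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_params():
    return default_cohort_params()


@pytest.fixture()
def pipeline_config(tmp_path):
    return PipelineConfig(seed=7, n_respondents=40, out_dir=tmp_path / "run")
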