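import warnings

import pytest

from diazepbpk import load_default_drug, load_study_library
from diazepbpk.engine import reference_individual
from diazepbpk.partition import load_tissue_compositions, predict_all_kp


@pytest.fixture(scope="session")
def drug():
    return load_default_drug()


@pytest.fixture(scope="session")
def study_library(drug):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return load_study_library(drug)


@pytest.fixture(scope="session")
def compositions():
    return load_tissue_compositions()


@pytest.fixture(scope="session")
def kp(drug):
    return predict_all_kp(drug)


@pytest.fixture(scope="session")
def reference_adult():
    return reference_individual()
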