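import numpy as np
import pytest

from annl36.design import load_l36
from annl36.encode import CodingConfig
from annl36.experiment import (
    build_features,
    build_model_table,
    load_prevalence,
    top_diseases,
)


@pytest.fixture(scope="session")
def l36():
    return load_l36()


@pytest.fixture(scope="session")
def prevalence():
    return load_prevalence()


@pytest.fixture(scope="session")
def model_table_2013(prevalence):
    """Canonical 2013 modelling table: top-10 diseases, region+age panels."""
    return build_model_table(prevalence, 2013, diseases=top_diseases(prevalence))


@pytest.fixture(scope="session")
def design_2013(model_table_2013):
    """Feature matrix, percent targets and fitted coders for the 2013 table."""
    vals = model_table_2013["prevalence_pct"].to_numpy(dtype=float)
    input_coder = CodingConfig.fit(vals, kind="fuzzy")
    target_coder = CodingConfig.fit(vals, kind="fuzzy", band=(0.2, 0.8))
    X = build_features(model_table_2013, input_coder)
    return X, vals, input_coder, target_coder


@pytest.fixture()
def rng():
    return np.random.default_rng(20130)
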