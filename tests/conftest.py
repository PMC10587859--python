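import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles / reference_values

from araskit.case_study import case_study_matrix, load_case_study
from araskit.entropy import entropy_weights


@pytest.fixture(scope="session")
def case_table():
    return load_case_study()


@pytest.fixture(scope="session")
def case_matrix():
    return case_study_matrix()


@pytest.fixture(scope="session")
def case_entropy_weights(case_matrix):
    w, diag = entropy_weights(case_matrix)
    return w, diag


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
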