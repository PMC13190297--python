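import warnings

import numpy as np
import pandas as pd
import pytest

from apoeprot import SimConfig, default_analyte_plan, simulate_cohort
from apoeprot.containers import ProteinMatrix


@pytest.fixture(autouse=True)
def _quiet():
    # statsmodels emits benign convergence/df warnings on tiny fixtures
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_sim():
    """A modest cohort with two analytes of each planted class."""
    cfg = SimConfig(n_subjects=1500, master_seed=42,
                    analyte_plan=default_analyte_plan(2, 2, 2, 2, 2, 20))
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """Deterministic 6-subject × 3-analyte matrix with metadata."""
    rng = np.random.default_rng(0)
    subjects = [f"S{i}" for i in range(6)]
    values = pd.DataFrame(rng.normal(0, 1, (6, 3)), index=subjects,
                          columns=["P1", "P2", "P3"])
    analytes = pd.DataFrame({"gene": ["G1", "G2", "G3"],
                             "platform": "pea"},
                            index=pd.Index(values.columns,
                                           name="analyte_id"))
    return ProteinMatrix(values, analytes)
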